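"""Config-driven orchestration of the full analysis.

``run_pipeline`` chains the stages — baseline normalization, per-region
activation contrasts, correlation matrices and group connectivity,
thresholded networks, community/centrality topology, and the
permutation comparison — and writes every table plus a JSON manifest
(parameters, seeds, file hashes) that suffices to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation import classify_engagement, compare_activation
from .connectivity import (
    activity_connectivity_association,
    compare_group_connectivity,
    correlation_matrix,
    edge_difference_table,
    group_connectivity,
)
from .data_model import (
    ConditionDesign,
    ExpressionMatrix,
    RegionAtlas,
    default_atlas,
    load_atlas,
    load_expression,
    normalize_to_baseline,
)
from .network import build_network, graph_summary
from .permutation import permutation_centrality_test
from .synthetic_data import generate_cohort, study_like_spec
from .topology import (
    centralities,
    classify_roles,
    detect_communities,
    identify_hubs,
    participation_coefficient,
    stable_hubs,
    wc_zscore,
)

log = logging.getLogger("fosnet")

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML-serializable."""

    out_dir: str
    atlas_path: str | None = None           # None -> packaged default atlas
    expression_path: str | None = None      # None -> synthetic cohort
    baseline: str = "HC"
    network_conditions: tuple[str, str] = ("CFC-5s", "CFC")
    thresholds: tuple[float, ...] = (0.05, 0.01)
    weight_scheme: str = "r"
    community_algorithm: str = "multilevel_louvain"
    community_weight_scheme: str = "fisher_z"
    pc_variant: str = "guimera"
    top_fraction: float = 0.25
    min_measures: int = 3
    wc_threshold: float = 1.5
    pc_provincial: float = 0.3
    pc_connector: float = 0.8
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if len(set(self.thresholds)) != len(self.thresholds):
            raise ValueError("duplicate p thresholds in config")
        for t in self.thresholds:
            if not (0 < t < 1):
                raise ValueError(f"p threshold {t} outside (0, 1)")
        self.network_conditions = tuple(self.network_conditions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def load_inputs(config: RunConfig) -> tuple[RegionAtlas, ExpressionMatrix]:
    atlas = load_atlas(config.atlas_path) if config.atlas_path else default_atlas()
    if config.expression_path:
        expr = load_expression(config.expression_path, atlas)
    else:
        log.info("no expression path given; generating the study-like synthetic cohort")
        expr = generate_cohort(study_like_spec(seed=config.seed))
    return atlas, expr


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write outputs under ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``).  Re-running
    with an identical config reproduces byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas, expr = load_inputs(config)

    missing = [c for c in config.network_conditions if c not in set(expr.conditions)]
    if missing:
        raise ValueError(f"conditions not present in the data: {missing}")

    design = ConditionDesign.from_expression(expr, baseline=config.baseline)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        _write_csv(df, path, index=index)
        written.append(path)

    # -- stage: normalize -------------------------------------------------
    try:
        norm = normalize_to_baseline(expr, design)
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc
    norm.to_csv(out / "expression_percent_of_baseline.csv", float_format=FLOAT_FORMAT)
    written.append(out / "expression_percent_of_baseline.csv")

    # -- stage: activation ------------------------------------------------
    try:
        act = compare_activation(norm, design)
        categories = classify_engagement(act, design, focal=config.network_conditions[0],
                                         partner=config.network_conditions[1])
    except Exception as exc:
        raise RuntimeError(f"stage 'activation' failed: {exc}") from exc
    emit(act.summary, "activation_summary.csv")
    emit(act.omnibus, "activation_omnibus.csv")
    emit(act.contrasts, "activation_contrasts.csv")
    emit(categories.rename_axis("region").reset_index(), "activation_categories.csv")

    # -- stage: connectivity ----------------------------------------------
    try:
        cond_a, cond_b = config.network_conditions
        corr = {c: correlation_matrix(norm, c) for c in (cond_a, cond_b)}
        for c, cr in corr.items():
            tag = c.replace("/", "_")
            emit(cr.r, f"correlation_r_{tag}.csv", index=True)
            emit(cr.p, f"correlation_p_{tag}.csv", index=True)
            emit(cr.n, f"correlation_n_{tag}.csv", index=True)
            emit(group_connectivity(cr, atlas), f"group_connectivity_{tag}.csv")
        emit(edge_difference_table(corr[cond_a], corr[cond_b], mode="standardized"),
             "edge_differences_standardized.csv")
        emit(edge_difference_table(corr[cond_a], corr[cond_b], mode="raw"),
             "edge_differences_raw.csv")
        emit(compare_group_connectivity(corr[cond_a], corr[cond_b], atlas),
             "group_connectivity_comparison.csv")
        assoc = activity_connectivity_association(corr[cond_a], norm)
    except Exception as exc:
        raise RuntimeError(f"stage 'connectivity' failed: {exc}") from exc

    # -- stage: networks + topology ---------------------------------------
    summaries = []
    topo_outputs = {}
    try:
        for c in (cond_a, cond_b):
            for th in config.thresholds:
                net = build_network(corr[c], th)
                tag = f"{c.replace('/', '_')}_p{th:g}"
                net.write_graphml(out / f"network_{tag}.graphml")
                net.write_edge_list(out / f"network_{tag}_edges.csv")
                written += [out / f"network_{tag}.graphml", out / f"network_{tag}_edges.csv"]
                summ = graph_summary(net)
                summaries.append(summ.scalars())

                part = detect_communities(net, algorithm=config.community_algorithm,
                                          weight_scheme=config.community_weight_scheme,
                                          seed=config.seed)
                wc = wc_zscore(net, part)
                pc = participation_coefficient(net, part, variant=config.pc_variant)
                roles = classify_roles(wc, pc, config.wc_threshold,
                                       config.pc_provincial, config.pc_connector)
                cent = centralities(net, weight_scheme=config.weight_scheme)
                hub = identify_hubs(cent, config.top_fraction, config.min_measures)
                topo_outputs[(c, th)] = hub
                part_df = pd.DataFrame(
                    {"region": list(part.membership), "community": list(part.membership.values())}
                ).sort_values("region")
                part_df["modularity_q"] = part.q
                emit(part_df, f"partition_{tag}.csv")
                emit(part.composition(atlas), f"community_composition_{tag}.csv")
                emit(roles.table.rename_axis("region").reset_index(), f"roles_{tag}.csv")
                emit(hub.table.rename_axis("region").reset_index(), f"centralities_{tag}.csv")
        emit(pd.DataFrame(summaries), "graph_summaries.csv")
        stable = {
            c: sorted(stable_hubs(*(topo_outputs[(c, th)].hubs for th in config.thresholds)))
            for c in (cond_a, cond_b)
        } if len(config.thresholds) >= 2 else {}
    except Exception as exc:
        raise RuntimeError(f"stage 'topology' failed: {exc}") from exc

    # -- stage: permutation -----------------------------------------------
    try:
        perm = permutation_centrality_test(
            norm, cond_a, cond_b,
            p_thresholds=config.thresholds,
            n_perm=config.n_perm,
            seed=config.seed,
            weight_scheme=config.weight_scheme,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'permutation' failed: {exc}") from exc
    emit(perm.table, "permutation_centrality.csv")

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "n_animals": len(expr.animals),
        "n_regions": len(atlas),
        "conditions": {c: int((expr.conditions == c).sum()) for c in expr.condition_set()},
        "activity_connectivity_association": asdict(assoc),
        "stable_hubs": stable,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
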
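"""Per-region between-condition comparison of expression.

Each region's expression is compared across behavioural conditions with
a Welch (unequal-variance) one-way ANOVA, followed — when the omnibus
test rejects — by pairwise Welch t contrasts and standardized
mean-difference effect sizes.  A permutation F variant is available for
users wary of the parametric assumptions at n = 11-12 per group.

``classify_engagement`` applies the study-style decision logic over the
contrast table: a region is *target-specific* when the focal condition
exceeds every other condition; *both-conditionings* when the two
conditioning variants do not differ from each other, both exceed a
neutral control (immediate shock or homecage), and both exceed their
respective context controls (or those context controls are themselves
indistinguishable from the neutral controls).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ConditionDesign, ExpressionMatrix

__all__ = [
    "ActivationTable",
    "compare_activation",
    "classify_engagement",
    "welch_anova_arrays",
]

CATEGORIES = ("target-specific", "both-conditionings", "contextual", "other", "none")


def welch_anova_arrays(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch one-way ANOVA over columns.

    Each element of ``groups`` is an (n_g, R) array; NaNs are ignored
    per column.  Returns (F, p) arrays of length R.  Columns where every
    group has zero variance yield NaN.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.stack([np.sum(~np.isnan(g), axis=0).astype(float) for g in groups])
    means = np.stack([np.nanmean(g, axis=0) for g in groups])
    with np.errstate(invalid="ignore", divide="ignore"):
        variances = np.stack([np.nanvar(g, axis=0, ddof=1) for g in groups])
        w = ns / variances  # inf where variance 0
        bad = ~np.isfinite(w)
        w = np.where(bad, np.nan, w)
        W = np.nansum(w, axis=0)
        mw = np.nansum(w * means, axis=0) / W
        num = np.nansum(w * (means - mw) ** 2, axis=0) / (k - 1)
        tmp = np.nansum((1 - w / W) ** 2 / (ns - 1), axis=0)
        den = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
        F = num / den
        df2 = (k**2 - 1) / (3 * tmp)
    all_zero_var = np.all(variances == 0, axis=0) | np.any(bad, axis=0)
    p = stats.f.sf(F, k - 1, df2)
    # a group with zero variance breaks the weighting; mark undefined
    F = np.where(all_zero_var, np.nan, F)
    p = np.where(all_zero_var, np.nan, p)
    return F, p


def _permutation_omnibus(
    groups: list[np.ndarray], n_perm: int, seed: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-value for the Welch F, permuting condition labels."""
    rng = np.random.default_rng(seed)
    F_obs, _ = welch_anova_arrays(groups)
    pooled = np.vstack(groups)
    sizes = [g.shape[0] for g in groups]
    edges = np.cumsum([0] + sizes)
    count = np.zeros(pooled.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        shuffled = pooled[perm]
        gs = [shuffled[edges[i] : edges[i + 1]] for i in range(len(sizes))]
        F_perm, _ = welch_anova_arrays(gs)
        count += (F_perm >= F_obs).astype(float)
    p = (count + 1.0) / (n_perm + 1.0)
    p = np.where(np.isnan(F_obs), np.nan, p)
    return F_obs, p


@dataclass
class ActivationTable:
    """Results of the per-region activation analysis.

    Attributes
    ----------
    summary
        Per-region, per-condition mean and SEM (wide layout).
    omnibus
        Per-region omnibus F and p, plus an ``undefined`` flag for
        degenerate (zero-variance-everywhere) regions.
    contrasts
        Long table of pairwise contrasts: t, p, standardized effect size
        (difference of means over pooled SD) and a significance flag.
        Contrast p-values are only filled for regions whose omnibus test
        passed the gate (when gatekeeping is on).
    """

    summary: pd.DataFrame
    omnibus: pd.DataFrame
    contrasts: pd.DataFrame
    alpha: float
    method: str
    mcc: str

    def significant_regions(self) -> list[str]:
        ok = self.omnibus.loc[self.omnibus["p"] < self.alpha, "region"]
        return ok.tolist()

    def contrast_lookup(self) -> dict[tuple[str, str, str], pd.Series]:
        return {
            (row.region, row.cond_a, row.cond_b): row
            for row in self.contrasts.itertuples()
        }


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.sum(~np.isnan(a), axis=0)
    nb = np.sum(~np.isnan(b), axis=0)
    va = np.nanvar(a, axis=0, ddof=1)
    vb = np.nanvar(b, axis=0, ddof=1)
    return np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))


def compare_activation(
    expr: ExpressionMatrix,
    design: ConditionDesign,
    method: str = "welch",
    mcc: str = "none",
    alpha: float = 0.05,
    gatekeep: bool = True,
    n_perm: int = 2000,
    seed: int | None = 0,
) -> ActivationTable:
    """Omnibus + pairwise comparison of expression across conditions.

    Parameters
    ----------
    method
        ``"welch"`` (Welch ANOVA + Welch pairwise t) or ``"permutation"``
        (label-permutation F for the omnibus; pairwise contrasts remain
        Welch t).
    mcc
        ``"none"`` (default; the study reports unadjusted p-values) or
        ``"bh"`` for Benjamini-Hochberg across regions on the omnibus.
    gatekeep
        When true, pairwise contrasts are only evaluated for regions
        whose (possibly adjusted) omnibus p is below ``alpha``.
    """
    if method not in ("welch", "welch_anova+welch_t", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    if mcc not in ("none", "bh"):
        raise ValueError(f"unknown multiple-testing correction {mcc!r}")
    by_cond = expr.group_values(design)
    conds = design.conditions
    for c in conds:
        if len(by_cond[c]) < 3:
            raise ValueError(f"condition {c!r} has fewer than 3 animals")
    regions = expr.regions
    arrays = [by_cond[c].to_numpy(dtype=float) for c in conds]

    if method == "permutation":
        F, p = _permutation_omnibus(arrays, n_perm=n_perm, seed=seed)
    else:
        F, p = welch_anova_arrays(arrays)
    undefined = np.isnan(p)
    p_adj = p.copy()
    if mcc == "bh":
        ok = ~np.isnan(p)
        p_adj[ok] = stats.false_discovery_control(p[ok], method="bh")
    omnibus = pd.DataFrame(
        {"region": regions, "F": F, "p": p_adj, "p_raw": p, "undefined": undefined}
    )

    summary = pd.DataFrame({"region": regions})
    for c in conds:
        g = by_cond[c]
        summary[f"mean_{c}"] = g.mean(axis=0, skipna=True).to_numpy()
        summary[f"sem_{c}"] = g.sem(axis=0, ddof=1).to_numpy()

    gate = omnibus["p"].to_numpy() < alpha if gatekeep else np.ones(len(regions), bool)
    gate = gate & ~undefined
    rows = []
    for (ia, ca), (ib, cb) in itertools.combinations(enumerate(conds), 2):
        a, b = arrays[ia], arrays[ib]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, pt = stats.ttest_ind(a, b, equal_var=False, nan_policy="omit", axis=0)
            es = (np.nanmean(a, axis=0) - np.nanmean(b, axis=0)) / _pooled_sd(a, b)
        pt = np.asarray(pt, dtype=float)
        pt_gated = np.where(gate, pt, np.nan)
        for j, region in enumerate(regions):
            rows.append(
                {
                    "region": region,
                    "cond_a": ca,
                    "cond_b": cb,
                    "t": float(t[j]),
                    "p": float(pt_gated[j]),
                    "effect_size": float(es[j]),
                    "significant": bool(pt_gated[j] < alpha) if np.isfinite(pt_gated[j]) else False,
                }
            )
    contrasts = pd.DataFrame(rows)
    return ActivationTable(summary, omnibus, contrasts, alpha=alpha, method=method, mcc=mcc)


def _sig_greater(lookup: dict, means: pd.Series, region: str, a: str, b: str) -> bool:
    """True when condition a's mean exceeds b's and their contrast is significant."""
    key = (region, a, b) if (region, a, b) in lookup else (region, b, a)
    row = lookup.get(key)
    if row is None or not row.significant:
        return False
    return means[f"mean_{a}"] > means[f"mean_{b}"]


def _differ(lookup: dict, region: str, a: str, b: str) -> bool:
    key = (region, a, b) if (region, a, b) in lookup else (region, b, a)
    row = lookup.get(key)
    return bool(row is not None and row.significant)


def classify_engagement(
    table: ActivationTable,
    design: ConditionDesign,
    focal: str = "CFC-5s",
    partner: str = "CFC",
    context_controls: dict[str, str] | None = None,
    neutral: tuple[str, str] = ("US", "HC"),
) -> pd.Series:
    """Assign each region an engagement category.

    Categories: ``target-specific`` (focal condition exceeds all other
    conditions), ``both-conditionings`` (see module docstring),
    ``contextual`` (both context-exposure controls exceed the baseline),
    ``other`` (some significant contrast but no rule matched) and
    ``none``.  Evaluation order is as listed; the first matching rule
    wins.
    """
    if context_controls is None:
        context_controls = {partner: "CT", focal: "CT-5s"}
    lookup = table.contrast_lookup()
    others = [c for c in design.conditions if c != focal]
    out = {}
    for row in table.summary.itertuples():
        region = row.region
        means = table.summary.set_index("region").loc[region]

        if all(_sig_greater(lookup, means, region, focal, o) for o in others):
            out[region] = "target-specific"
            continue

        fear = [partner, focal]
        not_differ = not _differ(lookup, region, partner, focal)
        above_neutral = all(
            any(_sig_greater(lookup, means, region, f, u) for u in neutral) for f in fear
        )
        ctxs = [context_controls[f] for f in fear]
        above_context = all(
            _sig_greater(lookup, means, region, f, context_controls[f]) for f in fear
        )
        context_null = all(
            not _differ(lookup, region, ct, u) for ct in ctxs for u in neutral
        )
        if not_differ and above_neutral and (above_context or context_null):
            out[region] = "both-conditionings"
            continue

        baseline = design.baseline
        if all(
            _sig_greater(lookup, means, region, ct, baseline)
            for ct in dict.fromkeys(context_controls.values())
        ):
            out[region] = "contextual"
            continue

        any_sig = any(
            _differ(lookup, region, a, b)
            for a, b in itertools.combinations(design.conditions, 2)
        )
        out[region] = "other" if any_sig else "none"
    return pd.Series(out, name="category").reindex(table.summary["region"].tolist())
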
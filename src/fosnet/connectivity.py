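"""Inter-regional correlation structure within a condition.

Functional connectivity here means the Pearson correlation, across the
animals of one condition, of the per-region expression values: regions
whose activity co-varies across subjects are inferred to be functionally
coupled.  Two-sided p-values use the exact t transform
``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` with ``df = n - 2``; missing
measurements are handled pairwise-complete with the per-pair n recorded.

Condition contrasts at the edge level use the Fisher z (atanh)
transform: either the raw difference ``z1 - z2`` flagged at |.| >= 2, or
the standardized difference divided by ``sqrt(1/(n1-3) + 1/(n2-3))``
flagged at 1.96 (an actual alpha = 0.05 two-sample z-test).  Anatomical
group summaries average coefficients within a group, between a group and
the rest, or between group pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, RegionAtlas

__all__ = [
    "CorrelationResult",
    "EdgeDifference",
    "correlation_matrix",
    "fisher_z",
    "edge_difference",
    "edge_difference_table",
    "group_connectivity",
    "compare_group_connectivity",
    "activity_connectivity_association",
    "correlation_p_value",
    "critical_r",
]


@dataclass
class CorrelationResult:
    """Per-condition symmetric r / p / n matrices over region pairs.

    Zero-variance regions (no spread across animals) have undefined
    coefficients; their rows/columns are NaN and they are listed in
    ``undefined_regions``.
    """

    condition: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    undefined_regions: list[str]

    @property
    def regions(self) -> list[str]:
        return list(self.r.columns)

    def pairs(self) -> pd.DataFrame:
        """Long-format (region_a, region_b, r, p, n) over unordered pairs."""
        rows = []
        codes = self.regions
        rv, pv, nv = self.r.to_numpy(), self.p.to_numpy(), self.n.to_numpy()
        for i, j in itertools.combinations(range(len(codes)), 2):
            rows.append((codes[i], codes[j], rv[i, j], pv[i, j], nv[i, j]))
        return pd.DataFrame(rows, columns=["region_a", "region_b", "r", "p", "n"])

    def mean_r_per_region(self) -> pd.Series:
        """Mean of each region's coefficients to all partners (NaN-aware)."""
        rv = self.r.to_numpy().copy()
        np.fill_diagonal(rv, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return pd.Series(np.nanmean(rv, axis=1), index=self.regions, name="mean_r")


def correlation_p_value(r: np.ndarray | float, n: np.ndarray | int) -> np.ndarray | float:
    """Two-sided p for a Pearson r with df = n - 2; p = 0 at |r| = 1."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(n < 4, np.nan, p)
    return p if p.ndim else float(p)


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant two-sided at ``alpha`` for sample size n."""
    df = n - 2
    tcrit = stats.t.isf(alpha / 2, df)
    return float(tcrit / np.sqrt(df + tcrit**2))


def correlation_matrix(expr: ExpressionMatrix, condition: str) -> CorrelationResult:
    """Pearson correlation of expression over the animals of one condition.

    Uses pairwise-complete observations when values are missing and
    records the per-pair animal count.
    """
    sub = expr.subset(condition)
    if len(sub.animals) < 4:
        raise ValueError(f"condition {condition!r} has fewer than 4 animals")
    X = sub.values.to_numpy(dtype=float)
    codes = sub.regions
    k = len(codes)

    valid = ~np.isnan(X)
    n_mat = (valid.astype(int).T @ valid.astype(int)).astype(float)

    sd = np.nanstd(X, axis=0, ddof=1)
    undefined = [codes[j] for j in range(k) if not np.isfinite(sd[j]) or sd[j] == 0]
    if undefined:
        warnings.warn(
            f"zero-variance regions in condition {condition!r}: {undefined}; "
            "their correlations are undefined",
            stacklevel=2,
        )

    if valid.all():
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X, rowvar=False)
    else:
        r = np.full((k, k), np.nan)
        for i in range(k):
            r[i, i] = 1.0
            for j in range(i + 1, k):
                ok = valid[:, i] & valid[:, j]
                if ok.sum() < 4:
                    continue
                with np.errstate(invalid="ignore", divide="ignore"):
                    r[i, j] = r[j, i] = np.corrcoef(X[ok, i], X[ok, j])[0, 1]
    for code in undefined:
        j = codes.index(code)
        r[j, :] = np.nan
        r[:, j] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)

    p = correlation_p_value(r, n_mat)
    p = np.asarray(p)
    np.fill_diagonal(p, np.nan)

    idx = pd.Index(codes, name="region")
    return CorrelationResult(
        condition=condition,
        r=pd.DataFrame(r, index=idx, columns=codes),
        p=pd.DataFrame(p, index=idx, columns=codes),
        n=pd.DataFrame(n_mat, index=idx, columns=codes),
        undefined_regions=undefined,
    )


def fisher_z(r):
    """Variance-stabilizing Fisher transform z = atanh(r); |r| must be < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr[np.isfinite(arr)]) >= 1.0):
        raise ValueError("|r| >= 1 has an infinite Fisher transform")
    z = np.arctanh(arr)
    return z if z.ndim else float(z)


@dataclass(frozen=True)
class EdgeDifference:
    """Fisher-z comparison of one correlation across two conditions."""

    region_a: str | None
    region_b: str | None
    r1: float
    r2: float
    n1: int
    n2: int
    z1: float
    z2: float
    statistic: float
    mode: str
    significant: bool


def edge_difference(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    mode: str = "standardized",
    region_a: str | None = None,
    region_b: str | None = None,
) -> EdgeDifference:
    """Compare one edge's correlation between two conditions.

    ``raw`` mode flags |z1 - z2| >= 2; ``standardized`` mode divides by
    the two-sample standard error and flags |.| >= 1.96 (true alpha =
    0.05).  The two conventions disagree in general; both are exposed.
    """
    if mode not in ("raw", "standardized"):
        raise ValueError(f"unknown mode {mode!r}")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| >= 1 cannot be compared on the Fisher scale")
    z1, z2 = fisher_z(r1), fisher_z(r2)
    if mode == "raw":
        statistic = z1 - z2
        significant = abs(statistic) >= 2.0
    else:
        if n1 <= 3 or n2 <= 3:
            raise ValueError("standardized mode requires n > 3 in both conditions")
        se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        statistic = (z1 - z2) / se
        significant = abs(statistic) >= stats.norm.isf(0.025)
    return EdgeDifference(region_a, region_b, r1, r2, int(n1), int(n2), z1, z2, float(statistic), mode, bool(significant))


def edge_difference_table(
    corr1: CorrelationResult, corr2: CorrelationResult, mode: str = "standardized"
) -> pd.DataFrame:
    """Edge-wise Fisher-z differences between two conditions (long format)."""
    if corr1.regions != corr2.regions:
        raise ValueError("correlation results cover different region sets")
    p1, p2 = corr1.pairs(), corr2.pairs()
    rows = []
    for a, b in zip(p1.itertuples(), p2.itertuples()):
        if not (np.isfinite(a.r) and np.isfinite(b.r)) or abs(a.r) >= 1 or abs(b.r) >= 1:
            rows.append((a.region_a, a.region_b, a.r, b.r, np.nan, False))
            continue
        d = edge_difference(a.r, int(a.n), b.r, int(b.n), mode=mode, region_a=a.region_a, region_b=a.region_b)
        rows.append((a.region_a, a.region_b, a.r, b.r, d.statistic, d.significant))
    return pd.DataFrame(rows, columns=["region_a", "region_b", "r1", "r2", "statistic", "significant"])


def _scope_values(corr: CorrelationResult, atlas: RegionAtlas) -> list[dict]:
    """Enumerate coefficient lists for internal / external / pairwise scopes."""
    rv = corr.r.to_numpy()
    codes = corr.regions
    idx = {c: i for i, c in enumerate(codes)}
    groups = atlas.groups
    members = {g: [idx[c] for c in atlas.regions_in(g) if c in idx] for g in groups}

    def collect(pairs):
        vals = np.array([rv[i, j] for i, j in pairs], dtype=float)
        finite = vals[np.isfinite(vals)]
        return vals, finite

    scopes = []
    for g in groups:
        mem = members[g]
        pairs = list(itertools.combinations(mem, 2))
        vals, finite = collect(pairs)
        scopes.append(
            {
                "scope": "internal",
                "group_a": g,
                "group_b": g,
                "values": finite,
                "n_pairs": len(pairs),
                "n_excluded": len(pairs) - len(finite),
                "undefined": len(mem) < 2,
            }
        )
    for g in groups:
        mem = set(members[g])
        pairs = [(i, j) for i in mem for j in range(len(codes)) if j not in mem]
        vals, finite = collect(pairs)
        scopes.append(
            {
                "scope": "external",
                "group_a": g,
                "group_b": None,
                "values": finite,
                "n_pairs": len(pairs),
                "n_excluded": len(pairs) - len(finite),
                "undefined": False,
            }
        )
    for ga, gb in itertools.combinations(groups, 2):
        pairs = [(i, j) for i in members[ga] for j in members[gb]]
        vals, finite = collect(pairs)
        scopes.append(
            {
                "scope": "pairwise",
                "group_a": ga,
                "group_b": gb,
                "values": finite,
                "n_pairs": len(pairs),
                "n_excluded": len(pairs) - len(finite),
                "undefined": False,
            }
        )
    return scopes


def group_connectivity(corr: CorrelationResult, atlas: RegionAtlas) -> pd.DataFrame:
    """Mean correlation within / from / between anatomical groups.

    Internal connectivity of group g averages its |g|(|g|-1)/2 internal
    coefficients; external connectivity averages the |g| x (K - |g|)
    coefficients from g to everything else; pairwise covers each of the
    C(9,2) group pairs.  Undefined coefficients are excluded with a
    count.
    """
    rows = []
    for s in _scope_values(corr, atlas):
        vals = s["values"]
        mean = float(np.mean(vals)) if len(vals) and not s["undefined"] else np.nan
        sem = float(stats.sem(vals)) if len(vals) > 1 and not s["undefined"] else np.nan
        rows.append(
            {
                "scope": s["scope"],
                "group_a": s["group_a"],
                "group_b": s["group_b"],
                "mean_r": mean,
                "sem_r": sem,
                "n_pairs": s["n_pairs"],
                "n_excluded": s["n_excluded"],
                "undefined": s["undefined"],
            }
        )
    return pd.DataFrame(rows)


def compare_group_connectivity(
    corr_a: CorrelationResult,
    corr_b: CorrelationResult,
    atlas: RegionAtlas,
    method: str = "welch_on_z",
    n_perm: int = 5000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-scope comparison of the two conditions' coefficient sets.

    ``welch_on_z`` Fisher-transforms the coefficients and applies a
    Welch t-test; ``coefficient_permutation`` permutes the pooled
    coefficients between the two sets and compares means.  Coefficients
    within a scope share animals and are therefore not independent; the
    p-values are heuristic screening values, as in the original
    GZLM-based analysis they replace.
    """
    if method not in ("welch_on_z", "coefficient_permutation"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    scopes_a = _scope_values(corr_a, atlas)
    scopes_b = _scope_values(corr_b, atlas)
    rows = []
    for sa, sb in zip(scopes_a, scopes_b):
        va, vb = sa["values"], sb["values"]
        rec = {
            "scope": sa["scope"],
            "group_a": sa["group_a"],
            "group_b": sa["group_b"],
            "mean_a": float(np.mean(va)) if len(va) else np.nan,
            "mean_b": float(np.mean(vb)) if len(vb) else np.nan,
        }
        if sa["undefined"] or len(va) < 2 or len(vb) < 2:
            rec.update(statistic=np.nan, p=np.nan)
        elif method == "welch_on_z":
            za = np.arctanh(np.clip(va, -0.999999, 0.999999))
            zb = np.arctanh(np.clip(vb, -0.999999, 0.999999))
            t, p = stats.ttest_ind(za, zb, equal_var=False)
            rec.update(statistic=float(t), p=float(p))
        else:
            obs = rec["mean_a"] - rec["mean_b"]
            pooled = np.concatenate([va, vb])
            na = len(va)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                d = perm[:na].mean() - perm[na:].mean()
                if abs(d) >= abs(obs):
                    count += 1
            rec.update(statistic=float(obs), p=(count + 1) / (n_perm + 1))
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ActivityConnectivityAssociation:
    """Across-region association between mean expression and mean coupling."""

    r_mean_r: float
    p_mean_r: float
    r_mean_r2: float
    p_mean_r2: float
    n_regions: int


def activity_connectivity_association(
    corr: CorrelationResult, expr: ExpressionMatrix
) -> ActivityConnectivityAssociation:
    """Does a region's activity level predict how strongly it correlates?

    Correlates, across regions, the mean expression with (a) the mean of
    the region's coefficients to all partners and (b) the mean of the
    squared coefficients.
    """
    sub = expr.subset(corr.condition)
    mean_expr = sub.values.mean(axis=0, skipna=True)
    mean_r = corr.mean_r_per_region()
    rsq = corr.r.to_numpy() ** 2
    np.fill_diagonal(rsq, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r2 = pd.Series(np.nanmean(rsq, axis=1), index=corr.regions)

    ok = mean_r.notna() & mean_expr.notna()
    res1 = stats.pearsonr(mean_r[ok], mean_expr[ok])
    res2 = stats.pearsonr(mean_r2[ok], mean_expr[ok])
    return ActivityConnectivityAssociation(
        r_mean_r=float(res1.statistic),
        p_mean_r=float(res1.pvalue),
        r_mean_r2=float(res2.statistic),
        p_mean_r2=float(res2.pvalue),
        n_regions=int(ok.sum()),
    )
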
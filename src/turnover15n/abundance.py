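"""PRM abundance quantification and statistics.

Targeted PRM measurements report an area-under-curve (AUC) per peptide,
replicate, technical injection and time point.  A protein's quantification
index (PQI) is the log2 of the median AUC over its proteotypic peptides;
fold changes of protein abundance (FCP) are PQI differences against the
0 h reference.  On top of these the module provides the study's inference
toolbox: equal-variance Student's t tests against the reference time,
SAM-style permutation-FDR moderated t tests (fudge factor S0), row
Z-scoring, hierarchical clustering of abundance or ratio profiles, and
protein-transcript integration (OLS correlation and transformed
protein:transcript ratio series).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import linregress, ttest_ind

__all__ = [
    "StatResult",
    "SamResult",
    "compute_pqi",
    "average_injections",
    "fold_change",
    "median_fcp",
    "ttest_vs_reference",
    "sam_permutation_fdr",
    "zscore_rows",
    "hcluster_profiles",
    "protein_transcript_ratio",
    "linear_rsq",
]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")


@dataclass
class SamResult:
    """Permutation-FDR test output for one feature set."""

    d: np.ndarray              # moderated t statistic per feature
    significant: np.ndarray    # boolean flags at the requested FDR
    cutoff: float              # |d| threshold actually applied
    est_fdr: float             # estimated FDR at the cutoff
    n_permutations: int


def compute_pqi(auc: pd.DataFrame) -> pd.DataFrame:
    """PQI = log2(median peptide AUC) per (protein, replicate, injection, time).

    Cells with no peptide observation are simply absent from the output.
    """
    required = {"protein_id", "peptide_sequence", "replicate", "injection", "time_h", "auc"}
    missing = required - set(auc.columns)
    if missing:
        raise ValueError(f"AUC table missing columns: {sorted(missing)}")
    table = auc.dropna(subset=["auc"])
    if (table["auc"] < 0).any():
        raise ValueError("negative AUC value")
    grouped = (
        table.groupby(["protein_id", "replicate", "injection", "time_h"], as_index=False)["auc"]
        .median()
    )
    grouped["pqi"] = np.log2(grouped["auc"])
    return grouped.drop(columns="auc")


def average_injections(pqi: pd.DataFrame) -> pd.DataFrame:
    """Mean PQI over technical injections within each biological replicate."""
    return (
        pqi.groupby(["protein_id", "replicate", "time_h"], as_index=False)["pqi"].mean()
    )


def fold_change(pqi: pd.DataFrame, reference_time_h: float = 0.0) -> pd.DataFrame:
    """Per-replicate log2 FCP relative to the reference time point.

    Proteins whose replicate lacks the reference are skipped for that
    replicate; proteins with no reference anywhere are dropped entirely.
    """
    rows = []
    for (protein, rep), grp in pqi.groupby(["protein_id", "replicate"]):
        ref = grp.loc[grp["time_h"] == reference_time_h, "pqi"]
        if ref.empty:
            continue
        ref_val = float(ref.iloc[0])
        out = grp[["time_h"]].copy()
        out["protein_id"] = protein
        out["replicate"] = rep
        out["log2_fcp"] = grp["pqi"].to_numpy() - ref_val
        rows.append(out)
    if not rows:
        return pd.DataFrame(columns=["protein_id", "replicate", "time_h", "log2_fcp"])
    return pd.concat(rows, ignore_index=True)[["protein_id", "replicate", "time_h", "log2_fcp"]]


def median_fcp(fold_changes: pd.DataFrame) -> pd.DataFrame:
    """Replicate-median FCP on the linear scale (input to the FCP model)."""
    med = (
        fold_changes.groupby(["protein_id", "time_h"], as_index=False)["log2_fcp"].median()
    )
    med["fcp"] = 2.0 ** med["log2_fcp"]
    return med.drop(columns="log2_fcp")


def ttest_vs_reference(values_t, values_ref, alpha: float = 0.05) -> StatResult:
    """Two-sided equal-variance Student's t test against the reference group."""
    a = np.asarray(values_t, dtype=float)
    b = np.asarray(values_ref, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return StatResult(0.0, 1.0, False)
        return StatResult(math.copysign(math.inf, a.mean() - b.mean()), 0.0, True)
    stat, p = ttest_ind(a, b, equal_var=True)
    return StatResult(float(stat), float(p), bool(p < alpha))


def _moderated_d(group1: np.ndarray, group2: np.ndarray, s0: float) -> np.ndarray:
    n1, n2 = group1.shape[1], group2.shape[1]
    m1, m2 = group1.mean(axis=1), group2.mean(axis=1)
    v1 = group1.var(axis=1, ddof=1)
    v2 = group2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return (m1 - m2) / (se + s0)


def sam_permutation_fdr(
    group1: np.ndarray,
    group2: np.ndarray,
    s0: float = 0.1,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> SamResult:
    """SAM-style permutation-FDR moderated t test.

    Per feature, d = (mean1 - mean2) / (pooled SE + s0); with s0 = 0 the
    ranking equals the ordinary Student statistic.  The null distribution
    of |d| comes from column-label permutations (exhaustive when fewer
    than ``n_perm`` distinct splits exist).  The significance cutoff is the
    smallest observed |d| at which the estimated FDR — median permutation
    exceedance count over observed exceedance count — stays at or below
    ``fdr``; features at or above the cutoff are flagged.
    """
    group1 = np.atleast_2d(np.asarray(group1, dtype=float))
    group2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if group1.shape[0] != group2.shape[0]:
        raise ValueError("groups must share the feature set")
    n1, n2 = group1.shape[1], group2.shape[1]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    d_obs = _moderated_d(group1, group2, s0)
    combined = np.hstack([group1, group2])
    n = n1 + n2

    n_distinct = math.comb(n, n1)
    if n_distinct < 10:
        warnings.warn(
            f"only {n_distinct} distinct label permutations; using all of them",
            stacklevel=2,
        )
    if n_distinct <= n_perm:
        splits = [np.array(ix) for ix in itertools.combinations(range(n), n1)]
    else:
        splits = [rng.permutation(n)[:n1] for _ in range(n_perm)]

    abs_obs = np.abs(d_obs)
    perm_abs = np.empty((len(splits), abs_obs.size))
    for i, ix in enumerate(splits):
        mask = np.zeros(n, dtype=bool)
        mask[ix] = True
        perm_abs[i] = np.abs(
            _moderated_d(combined[:, mask], combined[:, ~mask], s0)
        )
    perm_sorted = np.sort(perm_abs, axis=1)

    candidates = np.sort(np.unique(abs_obs))
    n_features = abs_obs.size
    # exceedance counts per (permutation, candidate cutoff), vectorized per row
    exceed = np.stack(
        [n_features - np.searchsorted(row, candidates, side="left") for row in perm_sorted]
    )
    median_exceed = np.median(exceed, axis=0)
    obs_sorted = np.sort(abs_obs)
    observed = n_features - np.searchsorted(obs_sorted, candidates, side="left")
    with np.errstate(divide="ignore"):
        fdr_curve = np.minimum(median_exceed / np.maximum(observed, 1), 1.0)
    ok = np.flatnonzero(fdr_curve <= fdr)
    if ok.size:
        cutoff = float(candidates[ok[0]])
        est = float(fdr_curve[ok[0]])
    else:
        cutoff = math.inf
        est = 0.0
    significant = abs_obs >= cutoff
    return SamResult(d_obs, significant, cutoff, est, len(splits))


def zscore_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Z-score; constant rows become zeros and are flagged."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns per row")
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (matrix - mean) / safe_sd
    z[constant] = 0.0
    return z, constant


def hcluster_profiles(
    matrix: np.ndarray,
    k: int = 2,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of row profiles cut into ``k`` clusters.

    Rows containing missing values are dropped (their labels are -1).
    Returns (labels, dendrogram leaf order over the retained rows).
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    keep = ~np.isnan(matrix).any(axis=1)
    clean = matrix[keep]
    if k > clean.shape[0]:
        raise ValueError(f"k={k} exceeds the {clean.shape[0]} usable rows")
    labels = np.full(matrix.shape[0], -1)
    if clean.shape[0] == 1:
        labels[keep] = 1
        return labels, np.flatnonzero(keep)
    tree = linkage(clean, method=method, metric=metric)
    labels[keep] = fcluster(tree, t=k, criterion="maxclust")
    order = np.flatnonzero(keep)[leaves_list(tree)]
    return labels, order


def protein_transcript_ratio(
    protein_series: pd.Series | np.ndarray,
    transcript_series: pd.Series | np.ndarray,
    shift: float = 5.0,
) -> np.ndarray:
    """Protein:transcript ratio over a shared time grid.

    Both series (linear-scale abundances over the same time points) are
    log10-transformed, Z-scored across their own time series, shifted by
    ``shift``, then divided protein / transcript per time point.  The
    shift keeps both transformed series positive so the ratio stays
    interpretable.  Cells where the transformed transcript is 0 are NaN.
    """
    prot = np.asarray(protein_series, dtype=float)
    tx = np.asarray(transcript_series, dtype=float)
    if prot.shape != tx.shape:
        raise ValueError("series must share the time grid")
    if np.any(prot <= 0) or np.any(tx <= 0):
        raise ValueError("abundances must be positive before log transform")

    def transform(x: np.ndarray) -> np.ndarray:
        logged = np.log10(x)
        sd = logged.std(ddof=1)
        z = np.zeros_like(logged) if sd == 0 else (logged - logged.mean()) / sd
        return z + shift

    denom = transform(tx)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = transform(prot) / denom
    ratio[denom == 0] = np.nan
    return ratio


def linear_rsq(x, y) -> tuple[float, float, float]:
    """OLS of y on x: (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
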
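"""Turnover rate-constant estimation from RIA time courses.

The kinetic model: protein synthesis is zero-order (rate ``K_s``, amount per
day, independent of pool size) and degradation first-order (rate constant
``K_d`` per day).  In a growing culture the unlabeled ("light") pool is
additionally diluted by the exponential increase of total biomass, fitted as
``A_t = A_0 * exp(K_dil * t)``.  After switching the medium to a heavy
nitrogen source, the light pool only decays, so the apparent loss rate

    K_loss * t = -ln(1 - RIA)

is the slope of ``-ln(1-RIA)`` against time (days), and the true
degradation constant is ``K_d = K_loss - K_dil``.  The synthesis constant
normalized to pool size follows from the abundance fold change FCP:

    K_s/A = (FCP - exp(-K_d t)) / (1 - exp(-K_d t)) * K_d

with ``FCP = exp(K_dil t)`` in balanced growth.  During the transition into
induced immunity the abundance is no longer growth-balanced and ``K_d`` is
instead the slope of ``-ln(FCP(t) * (1 - RIA(t)))``, with ``FCP(t)`` taken
from a quadratic model of the measured abundance fold changes.

Three conditions are distinguished throughout: C1 (steady-state growth),
C2 (the 0-16 h transition after elicitor exposure) and C3 (sustained
immunity, 16-96 h), each with its own sampling grid and QC thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "COVERAGE_MIN_TIMEPOINTS",
    "RSTDE_MAX_PCT",
    "R2_MIN",
    "CLASS_CUTOFFS",
    "KS_EVAL_DAYS",
    "FCP_GATE",
    "C2_TIMES_H",
    "C3_TIMES_H",
    "KS_C2_TIMES_H",
    "FCP_MODEL_TIMES_H",
    "ReplicateFit",
    "QCResult",
    "FCPModel",
    "TurnoverEstimate",
    "aggregate_protein_ria",
    "fit_kloss",
    "fit_kdil",
    "compute_kd_steady",
    "qc_turnover",
    "compute_ks_steady",
    "compute_ks_general",
    "fit_fcp_model",
    "fit_kd_transition",
    "ks_timecourse_transition",
    "classify_turnover",
    "estimate_steady_state",
]

# QC thresholds and schedules.
COVERAGE_MIN_TIMEPOINTS = {"C1": 5, "C2": 4, "C3": 5}
RSTDE_MAX_PCT = 40.0
R2_MIN = 0.5
CLASS_CUTOFFS = (0.055, 0.22)     # day^-1; slow / intermediate / fast
KS_EVAL_DAYS = 2.0                # evaluation time for steady-state K_s
FCP_GATE = (0.75, 1.5)            # responsive iff FCP leaves this band
C2_TIMES_H = (0.0, 2.0, 4.0, 6.0, 8.0, 16.0)
C3_TIMES_H = (0.0, 8.0, 16.0, 24.0, 32.0, 48.0, 72.0, 96.0)
KS_C2_TIMES_H = (2.0, 4.0, 6.0, 8.0, 16.0)
FCP_MODEL_TIMES_H = (0.0, 1.0, 3.0, 16.0)

_ONE_MINUS_RIA_FLOOR = 1e-6


@dataclass(frozen=True)
class ReplicateFit:
    """Per-replicate regression result (slope in day^-1)."""

    replicate: object
    slope: float
    r2: float
    n_points: int
    n_clipped: int = 0


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str
    rstde_pct: float
    median_r2: float


@dataclass
class FCPModel:
    """Quadratic abundance fold-change model FCP(t) = a t^2 + b t + c (t in hours)."""

    protein_id: str
    a: float
    b: float
    c: float
    r2: float
    responsive: bool

    def fcp_at(self, time_h: float) -> float:
        return self.a * time_h**2 + self.b * time_h + self.c


@dataclass
class TurnoverEstimate:
    protein_id: str
    condition: str
    replicate_fits: list[ReplicateFit]
    kdil: float
    kloss: float | None
    kd: float | None
    ks: float | dict[float, float] | None
    qc: QCResult
    turnover_class: str | None = None
    flags: list[str] = field(default_factory=list)


def aggregate_protein_ria(
    peptide_ria: pd.DataFrame,
    min_timepoints: int = 5,
    peptide_rule: bool = True,
) -> pd.DataFrame:
    """Aggregate peptide RIA values to protein level.

    Peptides are retained only if they have RIA values at ``min_timepoints``
    or more time points in at least one replicate (``peptide_rule``); the
    protein's RIA at each (replicate, time) is the median over surviving
    proteotypic peptides, and proteins whose aggregated series meets the
    same coverage rule in no replicate are dropped.

    Parameters
    ----------
    peptide_ria:
        Columns ``peptide_sequence, protein_id, replicate, time_h, ria``.

    Returns
    -------
    DataFrame with columns ``protein_id, replicate, time_h, ria``.
    """
    required = {"peptide_sequence", "protein_id", "replicate", "time_h", "ria"}
    missing = required - set(peptide_ria.columns)
    if missing:
        raise ValueError(f"peptide RIA table missing columns: {sorted(missing)}")
    table = peptide_ria.dropna(subset=["ria"])
    if table.empty:
        return pd.DataFrame(columns=["protein_id", "replicate", "time_h", "ria"])

    if peptide_rule:
        cover = (
            table.groupby(["protein_id", "peptide_sequence", "replicate"])["time_h"]
            .nunique()
            .groupby(["protein_id", "peptide_sequence"])
            .max()
        )
        keep = cover[cover >= min_timepoints].index
        table = table.set_index(["protein_id", "peptide_sequence"]).loc[
            table.set_index(["protein_id", "peptide_sequence"]).index.isin(keep)
        ].reset_index()
    if table.empty:
        return pd.DataFrame(columns=["protein_id", "replicate", "time_h", "ria"])

    protein = (
        table.groupby(["protein_id", "replicate", "time_h"], as_index=False)["ria"]
        .median()
    )
    cover = protein.groupby(["protein_id", "replicate"])["time_h"].nunique()
    ok = cover[cover >= min_timepoints].index.get_level_values("protein_id").unique()
    return protein[protein["protein_id"].isin(ok)].reset_index(drop=True)


def _loss_transform(ria: np.ndarray) -> tuple[np.ndarray, int]:
    """-ln(1-RIA) with the light fraction floored at a small positive value."""
    one_minus = 1.0 - np.asarray(ria, dtype=float)
    clipped = int(np.sum(one_minus < _ONE_MINUS_RIA_FLOOR))
    return -np.log(np.clip(one_minus, _ONE_MINUS_RIA_FLOOR, None)), clipped


def _ols(t_days: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.allclose(y, y[0]):
        return 0.0, 1.0    # flat series: zero slope, perfect fit
    fit = linregress(t_days, y)
    return float(fit.slope), float(fit.rvalue**2)


def fit_kloss(
    series: pd.DataFrame,
    times_h: tuple[float, ...] | None = None,
    min_points: int = 3,
) -> list[ReplicateFit]:
    """Per-replicate K_loss: OLS slope of -ln(1-RIA) on time in days.

    The regression keeps a free intercept: labeling begins 8 h before the
    nominal start of the experiment, so RIA at t=0 is already positive and
    forcing the line through the origin would bias the slope.

    Replicates with fewer than ``min_points`` usable points are skipped.
    """
    fits: list[ReplicateFit] = []
    for rep, grp in series.groupby("replicate"):
        if times_h is not None:
            grp = grp[grp["time_h"].isin(times_h)]
        grp = grp.dropna(subset=["ria"]).sort_values("time_h")
        if len(grp) < min_points:
            continue
        y, n_clipped = _loss_transform(grp["ria"].to_numpy())
        t_days = grp["time_h"].to_numpy(dtype=float) / 24.0
        slope, r2 = _ols(t_days, y)
        fits.append(ReplicateFit(rep, slope, r2, len(grp), n_clipped))
    return fits


def fit_kdil(growth: pd.DataFrame, times_h: tuple[float, ...] | None = None) -> float:
    """Growth-dilution constant: slope of ln(weight) on time (days), pooled.

    ``growth`` has columns ``time_h, weight_g`` (``replicate`` optional);
    an exponential model is fitted to the fresh-weight increase.
    """
    table = growth.dropna(subset=["weight_g"])
    if times_h is not None:
        table = table[table["time_h"].isin(times_h)]
    if len(table) < 3:
        raise ValueError("need at least 3 growth observations")
    weights = table["weight_g"].to_numpy(dtype=float)
    if np.any(weights <= 0):
        raise ValueError("non-positive culture weight")
    t_days = table["time_h"].to_numpy(dtype=float) / 24.0
    slope, _ = _ols(t_days, np.log(weights))
    return slope


def compute_kd_steady(kloss: float, kdil: float) -> float:
    """Degradation constant under balanced growth: K_d = K_loss - K_dil."""
    return kloss - kdil


def qc_turnover(
    slopes: list[float] | np.ndarray,
    r2s: list[float] | np.ndarray,
    condition: str,
    rstde_max_pct: float = RSTDE_MAX_PCT,
    r2_min: float = R2_MIN,
) -> QCResult:
    """Replicate-consistency filter on rate estimates.

    Fails when the relative standard error across replicate slopes
    (100 * sd / |mean|, sample sd) exceeds 40%, when the median regression
    R^2 falls below 0.5, or — for the steady-state conditions C1/C3 —
    when the mean slope is not positive.  At least two replicate slopes
    are required.
    """
    slopes = np.asarray(slopes, dtype=float)
    r2s = np.asarray(r2s, dtype=float)
    if slopes.size < 2:
        return QCResult(False, "insufficient replicates", math.nan, math.nan)
    mean = slopes.mean()
    sd = slopes.std(ddof=1)
    rstde = math.inf if mean == 0 else 100.0 * sd / abs(mean)
    med_r2 = float(np.median(r2s))
    if condition in ("C1", "C3") and mean <= 0:
        return QCResult(False, "negative K_loss", rstde, med_r2)
    if rstde > rstde_max_pct:
        return QCResult(False, f"RSTDE {rstde:.1f}% > {rstde_max_pct:.0f}%", rstde, med_r2)
    if med_r2 < r2_min:
        return QCResult(False, f"median R2 {med_r2:.2f} < {r2_min}", rstde, med_r2)
    return QCResult(True, "", rstde, med_r2)


def compute_ks_general(kd: float, fcp: float, t_days: float) -> float:
    """Synthesis constant from degradation constant and abundance fold change.

    K_s/A = (FCP - exp(-K_d t)) / (1 - exp(-K_d t)) * K_d, t in days.
    """
    if kd == 0:
        raise ValueError("K_s undefined at K_d = 0")
    if fcp <= 0:
        raise ValueError("FCP must be positive")
    decay = math.exp(-kd * t_days)
    return (fcp - decay) / (1.0 - decay) * kd


def compute_ks_steady(kd: float, kdil: float, t_days: float = KS_EVAL_DAYS) -> float:
    """Synthesis constant in balanced growth, where FCP = exp(K_dil t)."""
    return compute_ks_general(kd, math.exp(kdil * t_days), t_days)


def fit_fcp_model(
    median_fcp: dict[float, float] | pd.Series,
    protein_id: str = "",
    times_h: tuple[float, ...] = FCP_MODEL_TIMES_H,
    gate: tuple[float, float] = FCP_GATE,
) -> FCPModel:
    """Quadratic model of median FCP at the abundance sampling points.

    The responsiveness gate is true iff any median FCP at the non-reference
    points leaves the ``gate`` band (below 0.75 or above 1.5): only such
    proteins get transition-phase rate constants.
    """
    fcp = dict(median_fcp)
    missing = [t for t in times_h if t not in fcp or not np.isfinite(fcp[t])]
    if missing:
        raise ValueError(f"missing median FCP at time(s) {missing}")
    t = np.array(times_h, dtype=float)
    y = np.array([fcp[ti] for ti in times_h], dtype=float)
    a, b, c = np.polyfit(t, y, 2)
    fitted = np.polyval([a, b, c], t)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    lo, hi = gate
    responsive = any(fcp[ti] > hi or fcp[ti] < lo for ti in times_h if ti != 0)
    return FCPModel(protein_id, float(a), float(b), float(c), r2, responsive)


def fit_kd_transition(
    series: pd.DataFrame,
    model: FCPModel,
    times_h: tuple[float, ...] = C2_TIMES_H,
    min_points: int = 3,
) -> list[ReplicateFit]:
    """Per-replicate transition-phase K_d: slope of -ln(FCP(t)*(1-RIA)).

    The same modeled FCP(t) is shared across biological replicates.  Points
    where FCP(t)*(1-RIA) is non-positive are dropped; replicates left with
    fewer than ``min_points`` points are skipped.  Negative slopes are
    legitimate here (a stabilized pool during the transition).
    """
    fits: list[ReplicateFit] = []
    for rep, grp in series.groupby("replicate"):
        grp = grp[grp["time_h"].isin(times_h)].dropna(subset=["ria"]).sort_values("time_h")
        if grp.empty:
            continue
        t_h = grp["time_h"].to_numpy(dtype=float)
        one_minus = np.clip(1.0 - grp["ria"].to_numpy(dtype=float), _ONE_MINUS_RIA_FLOOR, None)
        n_clipped = int(np.sum(1.0 - grp["ria"].to_numpy(dtype=float) < _ONE_MINUS_RIA_FLOOR))
        fcp = np.array([model.fcp_at(ti) for ti in t_h])
        usable = fcp * one_minus > 0
        if usable.sum() < min_points:
            continue
        y = -np.log(fcp[usable] * one_minus[usable])
        slope, r2 = _ols(t_h[usable] / 24.0, y)
        fits.append(ReplicateFit(rep, slope, r2, int(usable.sum()), n_clipped))
    return fits


def ks_timecourse_transition(
    kd: float,
    model: FCPModel,
    times_h: tuple[float, ...] = KS_C2_TIMES_H,
) -> dict[float, float]:
    """K_s at each post-elicitation time from the shared FCP model."""
    return {
        t_h: compute_ks_general(kd, model.fcp_at(t_h), t_h / 24.0) for t_h in times_h
    }


def classify_turnover(kd: float, cutoffs: tuple[float, float] = CLASS_CUTOFFS) -> str:
    """Slow / intermediate / fast degradation class of a K_d (day^-1)."""
    if not np.isfinite(kd):
        raise ValueError("non-finite K_d")
    lo, hi = cutoffs
    if kd < lo:
        return "slow"
    if kd <= hi:
        return "intermediate"
    return "fast"


def estimate_steady_state(
    protein_id: str,
    series: pd.DataFrame,
    kdil: float,
    condition: str = "C1",
    times_h: tuple[float, ...] | None = None,
    ks_time_days: float = KS_EVAL_DAYS,
    rstde_max_pct: float = RSTDE_MAX_PCT,
    r2_min: float = R2_MIN,
) -> TurnoverEstimate:
    """Full steady-state estimate for one protein (conditions C1 or C3).

    Fits K_loss per replicate, applies QC, and derives K_d, K_s and the
    turnover class from the replicate-mean K_loss.
    """
    if condition == "C3" and times_h is None:
        times_h = C3_TIMES_H
    fits = fit_kloss(series, times_h=times_h)
    qc = qc_turnover(
        [f.slope for f in fits], [f.r2 for f in fits], condition,
        rstde_max_pct=rstde_max_pct, r2_min=r2_min,
    )
    flags = []
    if any(f.n_clipped for f in fits):
        flags.append("saturated RIA points clipped")
    if not qc.passed:
        return TurnoverEstimate(
            protein_id, condition, fits, kdil, None, None, None, qc, None, flags
        )
    kloss = float(np.mean([f.slope for f in fits]))
    kd = compute_kd_steady(kloss, kdil)
    ks = compute_ks_steady(kd, kdil, ks_time_days) if kd != 0 else None
    return TurnoverEstimate(
        protein_id, condition, fits, kdil, kloss, kd, ks, qc, classify_turnover(kd), flags
    )
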
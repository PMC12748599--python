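"""Design-based accuracy assessment and ground-plot defoliation analysis.

Confusion matrices with omission/commission errors, overall and stratified
area-adjusted accuracy with standard errors, plot-level percent-of-biomass
defoliated with its eligibility filters, majority-neighbourhood extraction
around validation points, temporal agreement, and the stratified sampling
plan for photo-interpreted validation points.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

from .spectral import UndefinedValueError, ValidationError


def round_half_up(x: float) -> int:
    """Integer rounding with .5 always rounding up (report convention)."""
    return int(math.floor(x + 0.5))


@dataclass
class ConfusionMatrix:
    """Map-class (rows) x reference-class (columns) counts."""

    counts: np.ndarray
    labels: list[str]
    ref_labels: list[str] | None = None
    weights: np.ndarray | None = None  # optional stratum weights, sum to 1

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.ref_labels = self.ref_labels or list(self.labels)
        if self.counts.shape != (len(self.labels), len(self.ref_labels)):
            raise ValidationError("counts shape does not match labels")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValidationError("stratum weights must sum to 1")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.ref_labels)


def confusion_matrix(pred, ref, class_order: list[str]) -> ConfusionMatrix:
    """Count matrix: rows are mapped classes, columns reference classes."""
    pred, ref = list(pred), list(ref)
    if len(pred) != len(ref):
        raise ValidationError("prediction and reference labels must pair up")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)))
    for p, r in zip(pred, ref):
        if p not in index or r not in index:
            raise ValidationError(f"unknown label in pair ({p!r}, {r!r})")
        counts[index[p], index[r]] += 1
    return ConfusionMatrix(counts, list(class_order))


def load_vilts_matrix() -> ConfusionMatrix:
    """The packaged photo-interpreted validation count matrix (6 classes)."""
    with resources.files("borealdist.data").joinpath("vilts_confusion.csv").open() as f:
        df = pd.read_csv(f, index_col=0)
    return ConfusionMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 x trace / grand total (percent, unrounded)."""
    if cm.counts.shape[0] != cm.counts.shape[1]:
        raise ValidationError("overall accuracy requires a square matrix")
    if cm.total == 0:
        raise UndefinedValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def omission_commission(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class omission and commission percentages (unrounded, NaN-flagged).

    commission_i = 100 (1 - n_ii / row_i total); omission_j likewise on the
    column. Classes with a zero row/column total get NaN.
    """
    if cm.counts.shape[0] != cm.counts.shape[1]:
        raise ValidationError("omission/commission requires a square matrix")
    diag = np.diag(cm.counts)
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        commission = 100.0 * (1.0 - np.where(row > 0, diag / row, np.nan))
        omission = 100.0 * (1.0 - np.where(col > 0, diag / col, np.nan))
    return pd.DataFrame(
        {"omission": omission, "commission": commission}, index=cm.labels
    )


def accuracy_report(cm: ConfusionMatrix) -> pd.DataFrame:
    """Rounded integer-percent report (round-half-up), as printed."""
    oc = omission_commission(cm)
    return oc.map(lambda v: round_half_up(v) if np.isfinite(v) else v)


@dataclass
class StratifiedAccuracy:
    overall: float
    overall_se: float
    per_class: pd.DataFrame  # omission/commission +/- SE per class
    proportions: np.ndarray


def area_adjusted_accuracy(
    strata: list[tuple[ConfusionMatrix, float]]
) -> StratifiedAccuracy:
    """Stratified (area-weighted) accuracy estimates with standard errors.

    Each stratum h contributes cell proportions W_h * n_hij / n_h. Overall
    accuracy is the sum of diagonal proportions; its SE is the exact
    stratified binomial variance. Per-class omission/commission are ratios
    of estimated proportions with Taylor-linearized SEs.
    """
    if not strata:
        raise ValidationError("at least one stratum required")
    weights = np.array([w for _, w in strata], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError("stratum weights must sum to 1")
    shape = strata[0][0].counts.shape
    labels = strata[0][0].labels
    if shape[0] != shape[1]:
        raise ValidationError("square matrices required")

    p = np.zeros(shape)
    var_oa = 0.0
    for (cm, w) in strata:
        if cm.counts.shape != shape:
            raise ValidationError("stratum matrices must share shape and labels")
        n_h = cm.total
        if n_h == 0:
            raise ValidationError("empty stratum")
        p += w * cm.counts / n_h
        o_h = float(np.trace(cm.counts)) / n_h
        denom = max(n_h - 1.0, 1.0)
        var_oa += w * w * o_h * (1.0 - o_h) / denom

    oa = float(np.trace(p))
    k = shape[0]
    rows = []
    for i in range(k):
        rows.append({
            "omission": _ratio_error(strata, p, i, axis=0),
            "omission_se": _ratio_error_se(strata, i, axis=0),
            "commission": _ratio_error(strata, p, i, axis=1),
            "commission_se": _ratio_error_se(strata, i, axis=1),
        })
    per_class = pd.DataFrame(rows, index=labels)
    return StratifiedAccuracy(100.0 * oa, 100.0 * math.sqrt(var_oa), per_class, p)


def _ratio_error(strata, p, i, axis) -> float:
    tot = p[:, i].sum() if axis == 0 else p[i, :].sum()
    if tot <= 0:
        return float("nan")
    return 100.0 * (1.0 - p[i, i] / tot)


def _ratio_error_se(strata, i, axis) -> float:
    # Taylor-linearized variance of R = p_ii / p_i(tot) across strata:
    # var(R) ~ sum_h W_h^2 var_h(z) / n_h with z the influence value
    # (d - R * m) / p_tot, d = diagonal indicator, m = margin indicator.
    p_diag = 0.0
    p_tot = 0.0
    for cm, w in strata:
        n_h = cm.total
        p_diag += w * cm.counts[i, i] / n_h
        margin = cm.counts[:, i].sum() if axis == 0 else cm.counts[i, :].sum()
        p_tot += w * margin / n_h
    if p_tot <= 0:
        return float("nan")
    ratio = p_diag / p_tot
    var = 0.0
    for cm, w in strata:
        n_h = cm.total
        d_h = cm.counts[i, i] / n_h
        m_h = (cm.counts[:, i].sum() if axis == 0 else cm.counts[i, :].sum()) / n_h
        # per-unit variances/covariance of the indicators within stratum h
        vd = d_h * (1 - d_h)
        vm = m_h * (1 - m_h)
        cov = d_h * (1 - m_h)  # diagonal units are margin units
        vz = (vd - 2 * ratio * cov + ratio * ratio * vm) / (p_tot * p_tot)
        var += w * w * vz / max(n_h - 1.0, 1.0)
    return 100.0 * math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# Ground plots
# ---------------------------------------------------------------------------

MIN_DBH_CM = 9.0
MIN_PLOT_AGB = 50.0
MAX_DEAD_FRACTION = 0.8

REJECT_DECIDUOUS_ONLY = "deciduous_defoliation_only"
REJECT_DEAD_UNKNOWN = "dead_fraction_above_80pct_unknown_cause"
REJECT_LOW_AGB = "plot_agb_below_50"


@dataclass
class Tree:
    species_group: str   # coniferous / deciduous
    dbh_cm: float
    agb: float           # t/ha contribution
    defoliated: bool = False
    dead: bool = False

    def __post_init__(self):
        if self.agb < 0:
            raise ValidationError("tree AGB must be >= 0")


@dataclass
class PlotMeasurement:
    plot_id: int
    year: int
    trees: list[Tree] = field(default_factory=list)
    mortality_cause_known: bool = True

    @property
    def agb_total(self) -> float:
        """Plot AGB over trees above the DBH threshold (t/ha)."""
        return sum(t.agb for t in self.trees if t.dbh_cm > MIN_DBH_CM)

    @property
    def dead_fraction(self) -> float:
        eligible = [t for t in self.trees if t.dbh_cm > MIN_DBH_CM]
        if not eligible:
            return 0.0
        return sum(t.dead for t in eligible) / len(eligible)


def pct_agb_defoliated(plot: PlotMeasurement) -> float:
    """Percent of plot AGB in defoliated coniferous trees (DBH > 9 cm only)."""
    total = plot.agb_total
    if total <= 0:
        raise UndefinedValueError("plot has no AGB above the DBH threshold")
    defol = sum(
        t.agb
        for t in plot.trees
        if t.dbh_cm > MIN_DBH_CM and t.species_group == "coniferous" and t.defoliated
    )
    return 100.0 * defol / total


def filter_plot_measurements(
    plots: list[PlotMeasurement],
) -> tuple[list[PlotMeasurement], list[tuple[PlotMeasurement, list[str]]]]:
    """Drop deciduous-only defoliation, >80% unexplained mortality, low AGB."""
    kept, rejected = [], []
    for p in plots:
        reasons = []
        defoliated = [t for t in p.trees if t.defoliated]
        if defoliated and all(t.species_group == "deciduous" for t in defoliated):
            reasons.append(REJECT_DECIDUOUS_ONLY)
        if p.dead_fraction > MAX_DEAD_FRACTION and not p.mortality_cause_known:
            reasons.append(REJECT_DEAD_UNKNOWN)
        if p.agb_total < MIN_PLOT_AGB:
            reasons.append(REJECT_LOW_AGB)
        (rejected if reasons else kept).append((p, reasons) if reasons else p)
    return kept, rejected


# ---------------------------------------------------------------------------
# Point extraction & temporal agreement
# ---------------------------------------------------------------------------

def majority_neighborhood_class(raster: np.ndarray, point: tuple[int, int]) -> int:
    """Modal code over the 3x3 window (center included) around a point.

    Ties prefer disturbed (non-zero) codes over undisturbed, then the lowest
    code. The point must have a full 3x3 neighbourhood.
    """
    raster = np.asarray(raster)
    r, c = point
    if not (1 <= r < raster.shape[0] - 1 and 1 <= c < raster.shape[1] - 1):
        raise ValidationError("point lacks a full 3x3 neighbourhood")
    window = raster[r - 1:r + 2, c - 1:c + 2].ravel()
    values, counts = np.unique(window, return_counts=True)
    best = counts.max()
    tied = values[counts == best]
    disturbed = tied[tied > 0]
    return int(disturbed.min()) if disturbed.size else int(tied.min())


def temporal_match(predicted_years, interpreted_years) -> bool:
    """Correct iff the predicted years overlap the interpreted years at all."""
    interpreted = set(interpreted_years)
    if not interpreted:
        raise ValidationError("interpreted year set must be non-empty")
    return bool(set(predicted_years) & interpreted)


def r2(pred, obs) -> float:
    """Coefficient of determination between predicted and observed years."""
    return float(r2_score(np.asarray(obs, dtype=float), np.asarray(pred, dtype=float)))


# ---------------------------------------------------------------------------
# Sampling design
# ---------------------------------------------------------------------------

@dataclass
class SamplePlan:
    allocation: dict[str, int]
    points: pd.DataFrame  # columns: stratum, x, y


def vilts_sample_plan(
    strata_areas: dict[str, float],
    candidates: pd.DataFrame,
    training_points: np.ndarray | None = None,
    n: int = 1100,
    min_distance_m: float = 200.0,
    seed: int = 0,
) -> SamplePlan:
    """Stratified random sample, proportional to stratum area.

    ``candidates`` needs columns stratum/x/y (coordinates in metres);
    candidates within ``min_distance_m`` of any training point are rejected.
    Zero-area strata are excluded with a warning. Reproducible under seed.
    """
    rng = np.random.default_rng(seed)
    areas = {k: v for k, v in strata_areas.items() if v > 0}
    for k in strata_areas:
        if strata_areas[k] <= 0:
            warnings.warn(f"stratum {k!r} has zero area; excluded", stacklevel=2)
    total = sum(areas.values())
    # largest-remainder allocation so counts sum exactly to n
    raw = {k: n * v / total for k, v in areas.items()}
    alloc = {k: int(math.floor(r)) for k, r in raw.items()}
    remainder = sorted(raw, key=lambda k: raw[k] - alloc[k], reverse=True)
    for k in remainder[: n - sum(alloc.values())]:
        alloc[k] += 1

    eligible = candidates
    if training_points is not None and len(training_points) > 0:
        tp = np.asarray(training_points, dtype=float)
        xy = candidates[["x", "y"]].to_numpy(dtype=float)
        d2 = ((xy[:, None, :] - tp[None, :, :]) ** 2).sum(axis=2)
        eligible = candidates[np.sqrt(d2.min(axis=1)) >= min_distance_m]
    if len(eligible) == 0:
        warnings.warn("no candidates clear the minimum-distance rule", stacklevel=2)

    picked = []
    for k, n_k in alloc.items():
        pool = eligible[eligible["stratum"] == k]
        if len(pool) < n_k:
            warnings.warn(
                f"stratum {k!r}: only {len(pool)} eligible candidates for {n_k}",
                stacklevel=2,
            )
            n_k = len(pool)
        if n_k:
            picked.append(pool.iloc[rng.permutation(len(pool))[:n_k]])
    points = (
        pd.concat(picked, ignore_index=True)
        if picked
        else candidates.iloc[0:0].copy()
    )
    return SamplePlan(alloc, points)
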
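"""Construction of labeled 10-year training subsequences.

Covers candidate filtering for aerial-survey pest points, dNBR severity
labeling, random event placement inside the window (never the first year, so
the model always sees a healthy start), synthetic composite classes built by
trajectory concatenation, the training-to-map class remapping, and spatial
cross-validation splits over a regular tile grid.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classes import CLASS_INDEX, MAP_CODES, TRAINING_CLASSES
from .simulate import (
    CLASS_EVENT_DEFAULTS,
    DISTURBANCE_CLASSES,
    EventSpec,
    Trajectory,
    concatenate_trajectories,
    draw_event,
    simulate_trajectory,
)
from .spectral import AnnualSpectra, SeverityClass, ValidationError, classify_severity

WINDOW_YEARS = 10

SEVERITY_TO_CLASS = {
    SeverityClass.LOW: "low_defoliation",
    SeverityClass.MEDIUM: "medium_defoliation",
    SeverityClass.HIGH: "high_defoliation",
}

#: The five supported synthetic composite pairs.
COMPOSITE_PAIRS: dict[tuple[str, str], str] = {
    ("forest", "crops"): "crops_change",
    ("forest", "urban"): "urban_change",
    ("forest", "water"): "dams",
    ("pest", "fire"): "pest_fire",
    ("pest", "harvest"): "pest_harv",
}


@dataclass
class CandidatePoint:
    """One candidate aerial-survey training pixel with its eligibility fields."""

    pixel_id: int
    source_severity: str          # aerial-survey label: light / medium / severe
    polygon_area_ha: float
    tree_cover_pct: float
    landcover: str                # coniferous / mixed / other
    overlaps_excluded_cover: bool  # urban, cropland, harvested or burned overlap
    dnbr_at_event: float
    tile_id: int = 0

    def __post_init__(self):
        for name in ("source_severity", "polygon_area_ha", "tree_cover_pct",
                     "landcover", "overlaps_excluded_cover", "dnbr_at_event"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                raise ValidationError(f"candidate point field {name!r} is missing")
        if not (0 <= self.tree_cover_pct <= 100):
            raise ValidationError("tree_cover_pct must be in [0, 100]")
        if self.polygon_area_ha < 0:
            raise ValidationError("polygon_area_ha must be >= 0")


# Enumerated rejection codes so filtering decisions are auditable.
REJECT_SEVERITY = "severity_not_medium_or_severe"
REJECT_POLYGON_TOO_LARGE = "polygon_too_large"
REJECT_EXCLUDED_COVER = "overlaps_excluded_cover"
REJECT_TREE_COVER = "tree_cover_below_50pct"
REJECT_LANDCOVER = "landcover_not_coniferous_or_mixed"
REJECT_DNBR = "dnbr_below_0.1"

MAX_POLYGON_HA = 10_000.0
MIN_TREE_COVER_PCT = 50.0


def _rejection_reasons(p: CandidatePoint) -> list[str]:
    reasons = []
    if p.source_severity not in ("medium", "severe"):
        reasons.append(REJECT_SEVERITY)
    if p.polygon_area_ha > MAX_POLYGON_HA:
        reasons.append(REJECT_POLYGON_TOO_LARGE)
    if p.overlaps_excluded_cover:
        reasons.append(REJECT_EXCLUDED_COVER)
    if p.tree_cover_pct < MIN_TREE_COVER_PCT:
        reasons.append(REJECT_TREE_COVER)
    if p.landcover not in ("coniferous", "mixed"):
        reasons.append(REJECT_LANDCOVER)
    if p.dnbr_at_event < 0.1:
        reasons.append(REJECT_DNBR)
    return reasons


def filter_pest_candidates(
    points: list[CandidatePoint],
) -> tuple[list[CandidatePoint], list[tuple[CandidatePoint, list[str]]]]:
    """Keep points passing every eligibility predicate; report why others fail.

    The filter is a pure conjunction: medium-or-severe survey severity,
    polygon <= 10,000 ha, no excluded-cover overlap, >= 50% tree cover,
    coniferous or mixed landcover, and a dNBR drop of at least 0.1.
    """
    kept, rejected = [], []
    for p in points:
        reasons = _rejection_reasons(p)
        if reasons:
            rejected.append((p, reasons))
        else:
            kept.append(p)
    return kept, rejected


def label_pest_severity(point: CandidatePoint) -> str:
    """Training class from the dNBR drop at the (midpoint-placed) event."""
    sev = classify_severity(point.dnbr_at_event)
    if sev is SeverityClass.NONE:
        raise ValidationError("dNBR drop below 0.1: point should have been filtered")
    return SEVERITY_TO_CLASS[sev]


@dataclass
class TrainingExample:
    """A 10-year x 6-band window with its label and event position."""

    window: np.ndarray            # (10, 6)
    label: str
    event_offset: int | None      # 1..9 within the window; None if undisturbed
    tile_id: int = 0

    def __post_init__(self):
        self.window = np.asarray(self.window, dtype=float)
        if self.window.shape != (WINDOW_YEARS, 6):
            raise ValidationError("window must be 10 years x 6 bands")
        if self.event_offset is not None and not (1 <= self.event_offset <= 9):
            raise ValidationError("event_offset must lie in 1..9 (never the first year)")
        if self.label not in TRAINING_CLASSES:
            raise ValidationError(f"unknown training label {self.label!r}")

    @property
    def label_index(self) -> int:
        return CLASS_INDEX[self.label]


def build_training_window(
    trajectory: Trajectory,
    label: str | None = None,
    seed: int | np.random.Generator = 0,
    event_year: int | None = None,
) -> TrainingExample:
    """Slice a 10-year window with the event at a uniform offset in {1..9}.

    Undisturbed trajectories get a uniformly random healthy slice. The event
    year defaults to the trajectory's own event onset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spectra = trajectory.spectra
    n = len(spectra)
    if n < WINDOW_YEARS:
        raise ValidationError("trajectory shorter than the 10-year window")
    label = label or (trajectory.event.class_label if trajectory.event else "forest")

    if event_year is None and trajectory.event is not None:
        event_year = trajectory.event.onset_year

    if event_year is None:
        start = int(rng.integers(0, n - WINDOW_YEARS + 1))
        offset = None
    else:
        ei = int(np.searchsorted(spectra.years, event_year))
        lo = max(1, ei - (n - WINDOW_YEARS))
        hi = min(9, ei)
        if lo > hi:
            raise ValidationError("trajectory too short to place the event at offset 1..9")
        offset = int(rng.integers(lo, hi + 1))
        start = ei - offset
    window = spectra.reflectance[start:start + WINDOW_YEARS]
    return TrainingExample(window, label, offset)


def make_composite_examples(
    class_pair: tuple[str, str],
    n: int,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.01,
) -> list[TrainingExample]:
    """Training windows for the five synthetic composite classes.

    A 10-year first-phase sequence (healthy forest, or an active pest
    outbreak for the pest pairs) is concatenated with a 10-year sequence of
    the follow-on state; windows are then drawn so the junction falls at a
    random non-first offset.
    """
    if class_pair not in COMPOSITE_PAIRS:
        raise ValidationError(f"unsupported composite pair {class_pair!r}")
    label = COMPOSITE_PAIRS[class_pair]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spectra = _composite_series(class_pair, rng, noise_sd)
        junction = int(spectra.years[WINDOW_YEARS])
        traj = Trajectory(spectra, np.full(len(spectra), None, dtype=object), None)
        out.append(build_training_window(traj, label=label, seed=rng, event_year=junction))
    return out


def _composite_series(
    class_pair: tuple[str, str], rng: np.random.Generator, noise_sd: float
) -> AnnualSpectra:
    first_kind, second_kind = class_pair
    span = (2000, 2000 + WINDOW_YEARS - 1)
    if first_kind == "forest":
        first = simulate_trajectory(None, span, noise_sd, rng).spectra
        second = simulate_trajectory(
            None, span, noise_sd, rng, baseline_class=second_kind
        ).spectra
        return concatenate_trajectories(first, second)
    # pest prefix: an outbreak still depressing NBR at the junction, then an
    # abrupt fire/harvest drop realized in the first year of the second phase.
    label = "pest_fire" if second_kind == "fire" else "pest_harv"
    d = CLASS_EVENT_DEFAULTS[label]
    duration = int(rng.integers(d["duration"][0], d["duration"][1] + 1))
    onset = span[1] - duration + 2  # pest still active at the junction
    onset = max(span[0] + 1, onset)
    ev = EventSpec(label, onset, min(duration, span[1] - onset + 1),
                   float(rng.uniform(*d["magnitude"])), d["recovery"],
                   float(rng.uniform(*d["second_magnitude"])))
    # simulate the two-phase event over a 20-year span, then re-slice so the
    # concatenation junction is exactly the abrupt-phase year
    long_span = (span[0], span[0] + 2 * WINDOW_YEARS - 1)
    ev = replace(ev, onset_year=span[0] + WINDOW_YEARS - ev.duration_years + 1)
    traj = simulate_trajectory(ev, long_span, noise_sd, rng)
    first = AnnualSpectra(
        traj.spectra.years[:WINDOW_YEARS],
        traj.spectra.reflectance[:WINDOW_YEARS],
        traj.spectra.missing[:WINDOW_YEARS],
    )
    second = AnnualSpectra(
        traj.spectra.years[WINDOW_YEARS:],
        traj.spectra.reflectance[WINDOW_YEARS:],
        traj.spectra.missing[WINDOW_YEARS:],
    )
    return concatenate_trajectories(first, second)


def remap_to_final(training_label: str) -> int:
    """Training class -> final map code (0..8)."""
    if training_label not in MAP_CODES:
        raise ValidationError(f"unknown training label {training_label!r}")
    return MAP_CODES[training_label]


@dataclass
class SplitPlan:
    """Spatial cross-validation plan over the tile grid."""

    holdout_tiles: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_tiles, test_tiles)


def spatial_cv_split(
    tile_ids: np.ndarray | None = None,
    n_tiles: int = 66,
    n_folds: int = 10,
    n_holdout_tiles: int = 4,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> SplitPlan:
    """Tile-level splits: 4 holdout tiles, then 10 independent 90/10 draws.

    Splits are always by tile, never by point; every example of a tile shares
    its assignment. The 10 iterations are independent re-draws (tiles may
    recur across test sets), mirroring a repeated-split protocol rather than
    a disjoint 10-fold partition.
    """
    rng = np.random.default_rng(seed)
    tiles = (
        np.arange(n_tiles)
        if tile_ids is None
        else np.unique(np.asarray(tile_ids))
    )
    n_test = int(round(test_fraction * (tiles.size - n_holdout_tiles)))
    if tiles.size < n_holdout_tiles + 2 or n_test < 1:
        raise ValidationError("fewer tiles than required for the requested splits")
    perm = rng.permutation(tiles)
    holdout = np.sort(perm[:n_holdout_tiles])
    remaining = np.sort(perm[n_holdout_tiles:])
    folds = []
    for _ in range(n_folds):
        p = rng.permutation(remaining)
        folds.append((np.sort(p[n_test:]), np.sort(p[:n_test])))
    return SplitPlan(holdout, folds)


# ---------------------------------------------------------------------------
# Whole-training-set generation from the simulator
# ---------------------------------------------------------------------------

def make_training_set(
    n_per_class: int,
    noise_sd: float = 0.01,
    seed: int = 0,
    years: tuple[int, int] = (1985, 2024),
    n_tiles: int = 66,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulated windows for every training class.

    Returns (X, y, tile_ids): X is (n, 10, 6), y integer class indices, and
    tile_ids uniform random tile assignments for spatial splitting.
    """
    rng = np.random.default_rng(seed)
    examples: list[TrainingExample] = []
    for label in TRAINING_CLASSES:
        if label in ("crops_change", "urban_change", "dams", "pest_fire", "pest_harv"):
            pair = {v: k for k, v in COMPOSITE_PAIRS.items()}[label]
            examples.extend(make_composite_examples(pair, n_per_class, rng, noise_sd))
        elif label in DISTURBANCE_CLASSES:
            for _ in range(n_per_class):
                ev = draw_event(label, years, rng)
                traj = simulate_trajectory(ev, years, noise_sd, rng)
                examples.append(build_training_window(traj, seed=rng))
        else:
            for _ in range(n_per_class):
                traj = simulate_trajectory(None, years, noise_sd, rng,
                                           baseline_class=label)
                examples.append(build_training_window(traj, label=label, seed=rng))
    X = np.stack([e.window for e in examples])
    y = np.array([e.label_index for e in examples])
    tile_ids = rng.integers(0, n_tiles, size=len(examples))
    return X, y, tile_ids


def examples_to_frame(examples: list[TrainingExample]) -> pd.DataFrame:
    """Serialize examples as one row each: label, offset, 60 reflectance values."""
    rows = []
    for i, e in enumerate(examples):
        row = {"example_id": i, "label": e.label,
               "event_offset": e.event_offset, "tile_id": e.tile_id}
        flat = e.window.reshape(-1)
        row.update({f"v{j}": flat[j] for j in range(flat.size)})
        rows.append(row)
    return pd.DataFrame(rows)
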
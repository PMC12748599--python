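"""Synthetic 6-band annual trajectory and scene simulator.

Generates class-conditional spectral trajectories (healthy baseline, linear
NBR decline over the event duration, exponential recovery toward baseline)
and small labeled raster scenes, so segmentation, classification, assembly
and validation can all be exercised without external data.

The NBR drop is realized exactly: the trajectory is constructed in NBR space
and NIR/SWIR2 are derived from it, so with zero noise the cumulative realized
drop equals the event magnitude to machine precision. The drop is carried
chiefly by a NIR decrease and SWIR increase; the remaining bands interpolate
toward a per-class "disturbed" profile.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import MAP_CODES, TRAINING_CLASSES
from .spectral import BANDS, N_BANDS, AnnualSpectra, ValidationError, compute_nbr

# ---------------------------------------------------------------------------
# Package-default radiometry. Fig-1-style per-class medians are not tabulated
# anywhere, so these are fixed, overridable defaults chosen for separability.
# Band order: blue, green, red, nir, swir1, swir2.
# ---------------------------------------------------------------------------
BASELINES: dict[str, np.ndarray] = {
    "forest": np.array([0.020, 0.040, 0.030, 0.350, 0.150, 0.060]),
    "no_forest": np.array([0.040, 0.070, 0.080, 0.250, 0.220, 0.120]),
    "rocks": np.array([0.100, 0.120, 0.140, 0.180, 0.220, 0.200]),
    "crops": np.array([0.050, 0.090, 0.070, 0.400, 0.200, 0.100]),
    "urban": np.array([0.120, 0.140, 0.150, 0.200, 0.220, 0.210]),
    "water": np.array([0.060, 0.050, 0.040, 0.040, 0.020, 0.030]),
}

UNDISTURBED_CLASSES = frozenset(BASELINES)

#: Disturbed-state targets: (blue, green, red, swir1) endpoint plus the
#: endpoint NIR+SWIR2 total; NIR and SWIR2 themselves follow the NBR path.
_DISTURBED_PROFILE: dict[str, tuple[np.ndarray, float]] = {
    "fire": (np.array([0.030, 0.050, 0.080, 0.300]), 0.25),
    "total_harvest": (np.array([0.080, 0.120, 0.140, 0.280]), 0.30),
    "partial_harvest": (np.array([0.060, 0.090, 0.100, 0.200]), 0.34),
    "windthrow": (np.array([0.025, 0.045, 0.055, 0.270]), 0.30),
    "low_defoliation": (np.array([0.030, 0.050, 0.060, 0.220]), 0.36),
    "medium_defoliation": (np.array([0.030, 0.050, 0.060, 0.220]), 0.34),
    "high_defoliation": (np.array([0.030, 0.050, 0.060, 0.220]), 0.30),
    "dams": (np.array([0.060, 0.050, 0.040, 0.020]), 0.07),
    "pest_fire": (np.array([0.030, 0.050, 0.080, 0.300]), 0.25),
    "pest_harv": (np.array([0.080, 0.120, 0.140, 0.280]), 0.30),
}

#: Event archetypes: (duration range, magnitude range, recovery rate).
#: Rapid classes last 1 year; intermediate pests 3-5; gradual pests 5-15
#: (durations here kept below 10 so segments stay classifiable).
CLASS_EVENT_DEFAULTS: dict[str, dict] = {
    "fire": dict(duration=(1, 1), magnitude=(0.35, 0.55), recovery=0.06),
    "total_harvest": dict(duration=(1, 1), magnitude=(0.30, 0.50), recovery=0.08),
    "partial_harvest": dict(duration=(1, 1), magnitude=(0.12, 0.25), recovery=0.10),
    "windthrow": dict(duration=(1, 1), magnitude=(0.20, 0.40), recovery=0.07),
    "low_defoliation": dict(duration=(3, 8), magnitude=(0.105, 0.145), recovery=0.15),
    "medium_defoliation": dict(duration=(3, 8), magnitude=(0.16, 0.24), recovery=0.12),
    "high_defoliation": dict(duration=(2, 6), magnitude=(0.26, 0.42), recovery=0.10),
    "dams": dict(duration=(1, 1), magnitude=(0.50, 0.56), recovery=0.0),
    "pest_fire": dict(duration=(4, 8), magnitude=(0.12, 0.22), recovery=0.06,
                      second_magnitude=(0.30, 0.40)),
    "pest_harv": dict(duration=(4, 8), magnitude=(0.12, 0.22), recovery=0.08,
                      second_magnitude=(0.28, 0.38)),
}

DISTURBANCE_CLASSES = frozenset(CLASS_EVENT_DEFAULTS)


def _add_noise(refl: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Signal-proportional interannual noise.

    ``noise_sd`` is the standard deviation for a mid-range (0.25) reflectance;
    darker targets (e.g. water) vary less in absolute terms, brighter ones
    more, keeping index noise comparable across cover types.
    """
    scale = np.clip(refl / 0.25, 0.4, 1.6)
    out = refl + rng.normal(0.0, noise_sd, refl.shape) * scale
    return np.clip(out, 1e-4, None)
#: Classes whose event is a single abrupt, stand-replacing drop.
RAPID_CLASSES = frozenset(
    {"fire", "total_harvest", "partial_harvest", "windthrow", "dams"}
)
#: Two-phase composites: gradual pest decline ending in an abrupt drop.
TWO_PHASE_CLASSES = frozenset({"pest_fire", "pest_harv"})


@dataclass
class EventSpec:
    """One disturbance event on a single pixel trajectory."""

    class_label: str
    onset_year: int
    duration_years: int = 1
    magnitude: float = 0.3
    recovery_rate: float = 0.1
    #: abrupt extra drop in the final event year (two-phase classes only)
    second_magnitude: float = 0.0

    def __post_init__(self):
        if self.class_label not in TRAINING_CLASSES:
            raise ValidationError(f"unknown class label {self.class_label!r}")
        if self.class_label in DISTURBANCE_CLASSES:
            if self.magnitude <= 0:
                raise ValidationError("magnitude must be > 0 for disturbance classes")
            if self.duration_years < 1:
                raise ValidationError("duration_years must be >= 1")

    @property
    def last_year(self) -> int:
        return self.onset_year + self.duration_years - 1

    def detection_year(self, threshold: float = 0.1) -> int:
        """First year the cumulative NBR deficit reaches the start threshold.

        This is the year a threshold-based segmenter reports as the
        disturbance start; rapid events are detected at their onset.
        """
        dur = self.duration_years
        if self.class_label in TWO_PHASE_CLASSES and dur >= 2:
            per_year = self.magnitude / (dur - 1)
        else:
            per_year = self.magnitude / dur
        k = max(0, int(np.ceil(threshold / per_year)) - 1)
        return self.onset_year + min(k, dur - 1)


@dataclass
class Trajectory:
    """A simulated pixel: spectra plus per-year true labels (None = no event)."""

    spectra: AnnualSpectra
    labels: np.ndarray  # object array aligned with spectra.years
    event: EventSpec | None = None

    @property
    def years(self) -> np.ndarray:
        return self.spectra.years


def draw_event(class_label: str, years: tuple[int, int], rng: np.random.Generator) -> EventSpec:
    """Draw an event with class-archetype duration/magnitude from the defaults.

    The onset is placed so the trajectory starts healthy and the event ends
    comfortably inside the simulated span.
    """
    if class_label not in CLASS_EVENT_DEFAULTS:
        raise ValidationError(f"{class_label!r} is not a disturbance class")
    d = CLASS_EVENT_DEFAULTS[class_label]
    duration = int(rng.integers(d["duration"][0], d["duration"][1] + 1))
    magnitude = float(rng.uniform(*d["magnitude"]))
    second = float(rng.uniform(*d["second_magnitude"])) if "second_magnitude" in d else 0.0
    lo = years[0] + 3
    hi = max(lo, years[1] - duration - 3)
    onset = int(rng.integers(lo, hi + 1))
    return EventSpec(class_label, onset, duration, magnitude, d["recovery"], second)


def _deficit_path(event: EventSpec, years: np.ndarray) -> np.ndarray:
    """NBR deficit (baseline minus trajectory) implied by one event."""
    deficit = np.zeros(years.size)
    onset = int(np.searchsorted(years, event.onset_year))
    dur = event.duration_years
    if event.class_label in TWO_PHASE_CLASSES and dur >= 2:
        # gradual decline over the first dur-1 years, abrupt drop in the last
        for k in range(dur - 1):
            deficit[onset + k] = event.magnitude * (k + 1) / (dur - 1)
        deficit[onset + dur - 1] = event.magnitude + event.second_magnitude
    else:
        for k in range(dur):
            deficit[onset + k] = event.magnitude * (k + 1) / dur
    total = deficit[onset + dur - 1]
    for t in range(onset + dur, years.size):
        total *= 1.0 - event.recovery_rate
        deficit[t] = total
    return deficit


def simulate_trajectory(
    event: EventSpec | None,
    years: tuple[int, int] = (1985, 2024),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    baseline_class: str = "forest",
) -> Trajectory:
    """Simulate one pixel's annual 6-band series.

    With ``event=None`` (or an undisturbed ``class_label``) the series is the
    stationary class baseline plus i.i.d. per-band Gaussian noise. Disturbance
    events decline linearly in NBR over their duration, then recover
    exponentially toward baseline at ``recovery_rate`` per year.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    yr = np.arange(years[0], years[1] + 1)
    labels = np.full(yr.size, None, dtype=object)

    if event is not None and event.class_label in UNDISTURBED_CLASSES:
        baseline_class = event.class_label
        event = None
    base = BASELINES[baseline_class].copy()

    if event is None:
        refl = np.tile(base, (yr.size, 1))
    else:
        if event.class_label not in DISTURBANCE_CLASSES:
            raise ValidationError(f"{event.class_label!r} has no event archetype")
        if event.onset_year <= yr[0]:
            raise ValidationError(
                "disturbance onset must be after the first simulated year "
                "(training windows require a healthy first year)"
            )
        if event.last_year > yr[-1]:
            raise ValidationError("event extends beyond the simulated span")
        refl = _synthesize(event, yr, base)
        onset = int(np.searchsorted(yr, event.onset_year))
        labels[onset:onset + event.duration_years] = event.class_label

    if noise_sd > 0:
        refl = _add_noise(refl, noise_sd, rng)
    return Trajectory(AnnualSpectra(yr, refl), labels, event)


def _synthesize(event: EventSpec, yr: np.ndarray, base: np.ndarray) -> np.ndarray:
    nir_i, swir2_i = BANDS.index("nir"), BANDS.index("swir2")
    other_i = [BANDS.index(b) for b in ("blue", "green", "red", "swir1")]
    base_nbr = compute_nbr(base[nir_i], base[swir2_i])
    deficit = _deficit_path(event, yr)
    total_mag = event.magnitude + event.second_magnitude
    progress = np.clip(deficit / total_mag, 0.0, 1.0)

    nbr = base_nbr - deficit
    target_other, target_total = _DISTURBED_PROFILE[event.class_label]
    s = (base[nir_i] + base[swir2_i]) * (1 - progress) + target_total * progress
    refl = np.tile(base, (yr.size, 1))
    refl[:, nir_i] = s * (1 + nbr) / 2
    refl[:, swir2_i] = s * (1 - nbr) / 2
    for j, bi in enumerate(other_i):
        refl[:, bi] = base[bi] + progress * (target_other[j] - base[bi])
    return refl


def concatenate_trajectories(
    first: AnnualSpectra, second: AnnualSpectra | None
) -> AnnualSpectra:
    """Splice two series, relabeling the second's years to follow the first.

    Used to build synthetic land-cover-conversion and pest-then-abrupt
    composite signatures. ``second=None`` (empty) is the identity.
    """
    if second is None or len(second) == 0:
        return first
    if second.reflectance.shape[1] != first.reflectance.shape[1]:
        raise ValidationError("band count mismatch between concatenated series")
    years = np.arange(first.years[0], first.years[0] + len(first) + len(second))
    refl = np.vstack([first.reflectance, second.reflectance])
    missing = np.concatenate([first.missing, second.missing])
    return AnnualSpectra(years, refl, missing)


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    """An event shared by a footprint of pixels (list of (row, col))."""

    event: EventSpec
    pixels: list[tuple[int, int]]


@dataclass
class SceneSpec:
    width: int
    height: int
    years: tuple[int, int] = (1985, 2024)
    patches: list[Patch] = field(default_factory=list)
    cloud_rate: float = 0.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.cloud_rate < 1.0):
            raise ValidationError("cloud_rate must be in [0, 1)")


@dataclass
class Scene:
    """Simulated raster scene: (years, 6, H, W) reflectance plus labels."""

    stack: np.ndarray       # (Y, 6, H, W), NaN where missing
    labels: np.ndarray      # (Y, H, W) int map codes 0-8
    years: np.ndarray       # (Y,)
    missing: np.ndarray     # (Y, H, W) bool

    def pixel(self, row: int, col: int) -> AnnualSpectra:
        refl = self.stack[:, :, row, col].copy()
        miss = self.missing[:, row, col]
        refl[miss] = 0.0
        return AnnualSpectra(self.years, refl, miss)


def simulate_scene(spec: SceneSpec) -> Scene:
    """Simulate a labeled scene; reproducible bit-for-bit under a fixed seed.

    Labels carry final-map codes: rapid events are labeled at their onset
    year only, multi-year pest events across their whole span.
    """
    rng = np.random.default_rng(spec.seed)
    yr = np.arange(spec.years[0], spec.years[1] + 1)
    ny, h, w = yr.size, spec.height, spec.width

    by_pixel: dict[tuple[int, int], list[EventSpec]] = {}
    for patch in spec.patches:
        for (r, c) in patch.pixels:
            if not (0 <= r < h and 0 <= c < w):
                raise ValidationError(f"patch pixel {(r, c)} outside the grid")
            by_pixel.setdefault((r, c), []).append(patch.event)
    for px, events in by_pixel.items():
        spans = sorted((e.onset_year, e.last_year) for e in events)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError(f"conflicting same-year events at pixel {px}")

    base = BASELINES["forest"]
    stack = np.empty((ny, N_BANDS, h, w))
    stack[:] = base[None, :, None, None]
    if spec.noise_sd > 0:
        stack = _add_noise(stack, spec.noise_sd, rng)
    labels = np.zeros((ny, h, w), dtype=np.int8)

    for (r, c), events in sorted(by_pixel.items()):
        refl = np.tile(base, (ny, 1))
        for ev in sorted(events, key=lambda e: e.onset_year):
            refl_ev = _synthesize(ev, yr, base)
            onset = int(np.searchsorted(yr, ev.onset_year))
            refl[onset:] = refl_ev[onset:]
            code = MAP_CODES[ev.class_label]
            if ev.class_label in RAPID_CLASSES:
                labels[onset, r, c] = code
            else:
                labels[onset:onset + ev.duration_years, r, c] = code
        if spec.noise_sd > 0:
            refl = _add_noise(refl, spec.noise_sd, rng)
        stack[:, :, r, c] = refl

    missing = (
        rng.random((ny, h, w)) < spec.cloud_rate
        if spec.cloud_rate > 0
        else np.zeros((ny, h, w), dtype=bool)
    )
    stack[:, :, :, :] = np.where(missing[:, None, :, :], np.nan, stack)
    return Scene(stack, labels, yr, missing)


def make_demo_scene_spec(
    seed: int = 0,
    width: int = 50,
    height: int = 50,
    years: tuple[int, int] = (1985, 2024),
    class_labels: tuple[str, ...] = (
        "fire", "total_harvest", "windthrow", "dams",
        "low_defoliation", "medium_defoliation", "high_defoliation",
    ),
    patches_per_class: int = 6,
    patch_size: int = 4,
    cloud_rate: float = 0.0,
    noise_sd: float = 0.01,
) -> SceneSpec:
    """Non-overlapping rectangular patches on a cell grid, one event each."""
    rng = np.random.default_rng(seed)
    cell = patch_size + 2
    cells = [
        (r, c)
        for r in range(height // cell)
        for c in range(width // cell)
    ]
    need = len(class_labels) * patches_per_class
    if need > len(cells):
        raise ValidationError("too many patches for the grid size")
    chosen = rng.permutation(len(cells))[:need]
    patches = []
    k = 0
    for label in class_labels:
        for _ in range(patches_per_class):
            cr, cc = cells[chosen[k]]
            k += 1
            r0, c0 = cr * cell + 1, cc * cell + 1
            pixels = [
                (r0 + i, c0 + j) for i in range(patch_size) for j in range(patch_size)
            ]
            patches.append(Patch(draw_event(label, years, rng), pixels))
    return SceneSpec(width, height, years, patches, cloud_rate, noise_sd, int(seed))
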
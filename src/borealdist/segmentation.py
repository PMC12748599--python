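"""Temporal segmentation of annual NBR series into piecewise-linear segments.

A continuous piecewise-linear trend is fitted by greedy knot insertion on a
hinge (truncated-linear) basis: starting from a single least-squares line,
the candidate knot year giving the largest squared-error reduction is added
while an F-statistic deems the reduction significant and the vertex budget
allows. Declining runs of the fitted trend whose cumulative drop reaches the
start threshold become candidate disturbance segments; the most recent five
are retained.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import ValidationError


@dataclass
class SegmentationParams:
    """Controls for fitting and disturbance extraction.

    max_segments is the piecewise-segment budget (vertices = segments + 1).
    min_start_drop is the cumulative fitted NBR decrease that both qualifies
    a declining run as a disturbance and defines its start year.
    """

    max_segments: int = 6
    min_start_drop: float = 0.1
    max_returned: int = 5
    noise_dampening: bool = True
    f_enter: float = 2.0  # F threshold for accepting one more knot
    #: fitted segments declining slower than this (index units / year) are
    #: treated as stable, not as part of a disturbance run
    min_decline_per_year: float = 0.003

    def __post_init__(self):
        if self.min_start_drop <= 0:
            raise ValidationError("min_start_drop must be > 0")
        if self.max_returned < 1:
            raise ValidationError("max_returned must be >= 1")
        if self.max_segments < 1:
            raise ValidationError("max_segments must be >= 1")


@dataclass(frozen=True)
class Vertex:
    year: int
    value: float


@dataclass(frozen=True)
class DisturbanceSegment:
    """A detected decline interval on the fitted trend.

    start_nbr is the pre-disturbance fitted level (the run-start vertex), so
    magnitude = start_nbr - end_nbr is the full fitted drop of the run.
    """

    start_year: int
    end_year: int
    start_nbr: float
    end_nbr: float
    #: first declining year of the run (the year after the break vertex);
    #: classifier windows anchor one year before this, the reported
    #: disturbance start_year is the threshold-crossing year
    onset_year: int | None = None

    def __post_init__(self):
        if self.onset_year is None:
            object.__setattr__(self, "onset_year", self.start_year)

    @property
    def magnitude(self) -> float:
        return self.start_nbr - self.end_nbr

    @property
    def duration(self) -> int:
        return self.end_year - self.start_year


def is_classifiable(segment: DisturbanceSegment) -> bool:
    """Segments lasting less than 10 years go on to type classification."""
    return segment.duration < 10


def despike(values: np.ndarray, threshold: float = 0.33) -> np.ndarray:
    """Attenuate single-year down-up (or up-down) spikes.

    An interior value is replaced by its neighbours' mean when the excursion
    from that mean dwarfs the neighbour-to-neighbour change (undetected cloud
    or shadow signature).
    """
    out = values.astype(float).copy()
    for t in range(1, len(out) - 1):
        neigh_mean = 0.5 * (values[t - 1] + values[t + 1])
        spike = abs(values[t] - neigh_mean)
        if spike > 1e-12 and abs(values[t + 1] - values[t - 1]) < threshold * spike:
            out[t] = neigh_mean
    return out


def _hinge_design(t: np.ndarray, knots: list[float]) -> np.ndarray:
    cols = [np.ones_like(t), t] + [np.maximum(t - k, 0.0) for k in knots]
    return np.column_stack(cols)


def _fit_sse(t, y, knots):
    X = _hinge_design(t, knots)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def fit_piecewise(
    nbr_series: np.ndarray,
    years: np.ndarray | None = None,
    params: SegmentationParams | None = None,
    missing: np.ndarray | None = None,
) -> list[Vertex]:
    """Fit a continuous piecewise-linear trend; return its vertices.

    Missing values (NaN or flagged) are linearly interpolated before fitting.
    Requires at least 6 non-missing years.
    """
    params = params or SegmentationParams()
    y = np.asarray(nbr_series, dtype=float).copy()
    n = y.size
    t = np.arange(n, dtype=float)
    yrs = np.arange(n) if years is None else np.asarray(years, dtype=int)
    if yrs.size != n:
        raise ValidationError("years must align with the series")

    miss = np.isnan(y)
    if missing is not None:
        miss |= np.asarray(missing, dtype=bool)
    if (n - int(miss.sum())) < 6:
        raise ValidationError("piecewise fit requires at least 6 non-missing years")
    if miss.any():
        y[miss] = np.interp(t[miss], t[~miss], y[~miss])

    if params.noise_dampening:
        y = despike(y)

    knots: list[float] = []
    sse, beta = _fit_sse(t, y, knots)
    candidates = list(t[1:-1])
    while len(knots) + 1 < params.max_segments and candidates:
        best = None
        for k in candidates:
            if k in knots:
                continue
            s, b = _fit_sse(t, y, sorted(knots + [k]))
            if best is None or s < best[0]:
                best = (s, k, b)
        if best is None:
            break
        new_sse, k, b = best
        p = len(knots) + 3  # params after insertion: intercept, slope, hinges
        dof = max(n - p, 1)
        if new_sse < 1e-12:
            accept = sse - new_sse > 1e-12
        else:
            f = (sse - new_sse) / (new_sse / dof)
            accept = f > params.f_enter
        if not accept:
            break
        knots = sorted(knots + [k])
        sse, beta = _fit_sse(t, y, knots)

    # local refinement: nudge each knot up to +/-2 years while SSE improves
    improved = bool(knots)
    passes = 0
    while improved and passes < 10:
        improved = False
        passes += 1
        for ki, k in enumerate(list(knots)):
            for cand in (k - 1, k + 1, k - 2, k + 2):
                if cand <= 0 or cand >= n - 1 or cand in knots:
                    continue
                trial = sorted(knots[:ki] + knots[ki + 1:] + [cand])
                s, b = _fit_sse(t, y, trial)
                if s < sse - 1e-15:
                    knots, sse, beta = trial, s, b
                    improved = True
                    break

    X = _hinge_design(t, knots)
    fitted = X @ beta
    vertex_pos = [0] + [int(k) for k in knots] + [n - 1]
    return [Vertex(int(yrs[i]), float(fitted[i])) for i in vertex_pos]


def fitted_series(vertices: list[Vertex], years: np.ndarray) -> np.ndarray:
    """Evaluate the piecewise-linear trend at each requested year."""
    vy = np.array([v.year for v in vertices], dtype=float)
    vv = np.array([v.value for v in vertices], dtype=float)
    return np.interp(np.asarray(years, dtype=float), vy, vv)


def extract_disturbance_segments(
    vertices: list[Vertex], params: SegmentationParams | None = None
) -> list[DisturbanceSegment]:
    """Candidate disturbance segments from the fitted vertices.

    Maximal runs of consecutive declining fitted segments qualify when their
    cumulative drop reaches min_start_drop. The start year is the first year
    within the run at which the cumulative fitted decrease from the run start
    reaches the threshold; the end year is the run's last vertex year. At
    most max_returned segments are kept, most recent first.
    """
    params = params or SegmentationParams()
    years = [v.year for v in vertices]
    if any(b <= a for a, b in zip(years, years[1:])):
        raise ValidationError("vertex years must be strictly increasing")
    if not all(np.isfinite(v.value) for v in vertices):
        raise ValidationError("vertex values must be finite")

    declining = [
        (vertices[i].value - vertices[i + 1].value)
        / (vertices[i + 1].year - vertices[i].year)
        > params.min_decline_per_year
        for i in range(len(vertices) - 1)
    ]
    segments: list[DisturbanceSegment] = []
    i = 0
    while i < len(declining):
        if not declining[i]:
            i += 1
            continue
        j = i
        while j < len(declining) and declining[j]:
            j += 1
        run_start, run_end = vertices[i], vertices[j]
        drop = run_start.value - run_end.value
        if drop >= params.min_start_drop - 1e-12:
            span = np.arange(run_start.year, run_end.year + 1)
            fit = fitted_series(vertices[i:j + 1], span)
            cum = run_start.value - fit
            idx = int(np.argmax(cum >= params.min_start_drop - 1e-12))
            segments.append(
                DisturbanceSegment(
                    start_year=int(span[idx]),
                    end_year=int(run_end.year),
                    start_nbr=float(run_start.value),
                    end_nbr=float(run_end.value),
                    onset_year=int(run_start.year) + 1,
                )
            )
        i = j

    segments.sort(key=lambda s: s.end_year, reverse=True)
    return segments[: params.max_returned]
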
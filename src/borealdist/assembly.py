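"""Inference-time window extraction, annual series construction and filters.

Turns classified disturbance segments into per-pixel annual map-code series
(rapid classes stamped at a single year, pest classes across their whole
segment), derives latest-disturbance products, and applies the sieve and
wetland post-processing filters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .classes import MULTI_YEAR_CODES, RAPID_CODES
from .segmentation import DisturbanceSegment
from .spectral import AnnualSpectra, ValidationError

logger = logging.getLogger(__name__)

WINDOW_YEARS = 10
#: wildfire segments stretched past this duration by missing data are stamped
#: at their end year instead of their start year
WILDFIRE_MAX_SPAN = 2
#: codes removed inside wetlands (harvesting and all pest codes)
WETLAND_FILTERED_CODES = (2, 5, 6, 7, 8)
SIEVE_MIN_PIXELS = 12
SIEVE_WINDOW_YEARS = 5


@dataclass
class Subsequence:
    """A 10-year x 6-band classifier input anchored near a detected break."""

    anchor_year: int
    window: np.ndarray           # (10, 6)
    imputed: np.ndarray          # (10,) bool: year was missing, interpolated

    def __post_init__(self):
        self.window = np.asarray(self.window, dtype=float)
        if self.window.shape != (WINDOW_YEARS, 6):
            raise ValidationError("subsequence must be 10 years x 6 bands")


@dataclass
class AnnualDisturbanceSeries:
    """Per-year map codes (0..8) for one pixel."""

    years: np.ndarray
    codes: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != self.years.shape:
            raise ValidationError("codes must align with years")
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) > 8:
            raise ValidationError("codes must lie in 0..8")


def extract_inference_window(spectra: AnnualSpectra, break_year: int) -> Subsequence:
    """Window starting the year before the detected disturbance begins.

    If that year is missing, the first following year with data is used; the
    anchor is clamped so a full 10-year window fits inside the series (the
    generalization of the fixed late-series start rule).
    """
    if len(spectra) < WINDOW_YEARS:
        raise ValidationError("series shorter than the 10-year window")
    first, last = int(spectra.years[0]), int(spectra.years[-1])
    if not (first <= break_year <= last):
        raise ValidationError("break year outside the series")

    anchor = max(break_year - 1, first)
    i = int(anchor - first)
    while i < len(spectra) and spectra.missing[i]:
        i += 1
        anchor += 1
    anchor = min(anchor, last - (WINDOW_YEARS - 1))
    i = int(anchor - first)

    window = spectra.reflectance[i:i + WINDOW_YEARS].copy()
    imputed = spectra.missing[i:i + WINDOW_YEARS].copy()
    if imputed.any():
        t = np.arange(WINDOW_YEARS, dtype=float)
        if imputed.all():
            raise ValidationError("all years missing in the inference window")
        for b in range(window.shape[1]):
            window[imputed, b] = np.interp(t[imputed], t[~imputed], window[~imputed, b])
    return Subsequence(int(anchor), window, imputed)


def assemble_series(
    classified: list[tuple[DisturbanceSegment, int]],
    span: tuple[int, int],
) -> AnnualDisturbanceSeries:
    """Per-pixel annual map codes from classified segments.

    Rapid codes (1-4) are stamped at the segment start year — except wildfire
    segments stretched to more than 2 years (missing-data artifact), which
    are stamped at the segment end. Multi-year pest codes (5-8) are stamped
    for every year of the segment. Code 0 (undisturbed prediction) stamps
    nothing. If two segments would stamp the same year, the more recent
    segment wins (logged).
    """
    years = np.arange(span[0], span[1] + 1)
    codes = np.zeros(years.size, dtype=np.int8)
    for seg, code in sorted(classified, key=lambda sc: sc[0].end_year):
        if code == 0:
            continue
        if code in RAPID_CODES:
            year = seg.start_year
            if code == 1 and seg.duration > WILDFIRE_MAX_SPAN:
                year = seg.end_year
            stamp = [year]
        elif code in MULTI_YEAR_CODES:
            stamp = list(range(seg.start_year, seg.end_year + 1))
        else:
            raise ValidationError(f"invalid map code {code}")
        for y in stamp:
            if span[0] <= y <= span[1]:
                i = y - span[0]
                if codes[i] != 0 and codes[i] != code:
                    logger.debug("year %d restamped %d -> %d", y, codes[i], code)
                codes[i] = code
    return AnnualDisturbanceSeries(years, codes)


def latest_products(series: AnnualDisturbanceSeries) -> tuple[int, int | None, int | None]:
    """(latest disturbance code, its first stamped year, its last stamped year).

    Consecutive years sharing a pest code form one event; rapid codes are
    single-year events. An all-zero series yields (0, None, None).
    """
    nz = np.flatnonzero(series.codes)
    if nz.size == 0:
        return 0, None, None
    last = nz[-1]
    code = int(series.codes[last])
    start = last
    if code in MULTI_YEAR_CODES:
        while start > 0 and series.codes[start - 1] == code:
            start -= 1
    return code, int(series.years[start]), int(series.years[last])


def sieve_filter(
    stack: np.ndarray,
    min_pixels: int = SIEVE_MIN_PIXELS,
    window_years: int = SIEVE_WINDOW_YEARS,
) -> tuple[np.ndarray, int]:
    """Remove isolated disturbance components; returns (filtered, n_removed).

    For each year a binary disturbed mask is built from the union of
    disturbed pixels within the centered moving window (+/-2 years);
    8-connected components strictly smaller than ``min_pixels`` are erased in
    the central year. Passes repeat until a fixed point, so the filter is
    idempotent; pixels are only ever removed, never added.
    """
    out = np.asarray(stack).copy()
    half = window_years // 2
    removed_total = 0
    while True:
        removed_this_pass = 0
        nxt = out.copy()
        for t in range(out.shape[0]):
            lo, hi = max(0, t - half), min(out.shape[0], t + half + 1)
            union = (out[lo:hi] > 0).any(axis=0)
            if not union.any():
                continue
            comps = cc_label(union, connectivity=2)
            sizes = np.bincount(comps.ravel())
            small = sizes < min_pixels
            small[0] = False
            erase = small[comps] & (out[t] > 0)
            removed_this_pass += int(erase.sum())
            nxt[t][erase] = 0
        out = nxt
        removed_total += removed_this_pass
        if removed_this_pass == 0:
            break
    return out, removed_total


def wetland_filter(stack: np.ndarray, wetland_mask: np.ndarray) -> np.ndarray:
    """Zero out harvesting and pest codes inside wetlands; fire et al. untouched."""
    stack = np.asarray(stack)
    wetland_mask = np.asarray(wetland_mask, dtype=bool)
    if wetland_mask.shape != stack.shape[-2:]:
        raise ValidationError("wetland mask shape does not match the stack grid")
    out = stack.copy()
    target = np.isin(out, WETLAND_FILTERED_CODES) & wetland_mask[None, :, :]
    out[target] = 0
    return out
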
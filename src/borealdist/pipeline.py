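"""End-to-end glue: per-pixel detection/classification and scene mapping."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import (
    AnnualDisturbanceSeries,
    assemble_series,
    extract_inference_window,
    latest_products,
)
from .classes import MULTI_YEAR_CODES, RAPID_CODES, TRAINING_CLASSES
from .segmentation import (
    SegmentationParams,
    extract_disturbance_segments,
    fit_piecewise,
    is_classifiable,
)
from .simulate import Scene
from .spectral import AnnualSpectra
from .tempcnn import TempCNN
from .training import remap_to_final


@dataclass
class PixelResult:
    series: AnnualDisturbanceSeries
    segments: list  # (DisturbanceSegment, training label, map code)


def map_pixel(
    spectra: AnnualSpectra,
    model: TempCNN,
    params: SegmentationParams | None = None,
) -> PixelResult:
    """Detect (segmentation), classify (CNN) and assemble one pixel's series."""
    params = params or SegmentationParams()
    vertices = fit_piecewise(
        spectra.nbr(), spectra.years, params, missing=spectra.missing
    )
    segments = extract_disturbance_segments(vertices, params)
    classified = []
    annotated = []
    windows, keep = [], []
    for seg in segments:
        if not is_classifiable(seg):
            continue
        sub = extract_inference_window(spectra, seg.onset_year)
        windows.append(sub.window)
        keep.append(seg)
    if windows:
        pred = model.predict(np.stack(windows))
        for seg, ci in zip(keep, np.atleast_1d(pred)):
            label = TRAINING_CLASSES[int(ci)]
            code = remap_to_final(label)
            classified.append((seg, code))
            annotated.append((seg, label, code))
    span = (int(spectra.years[0]), int(spectra.years[-1]))
    return PixelResult(assemble_series(classified, span), annotated)


def map_scene(
    scene: Scene,
    model: TempCNN,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-pixel mapping of a scene; returns (code stack (Y,H,W), segment table)."""
    params = params or SegmentationParams()
    ny, _, h, w = scene.stack.shape
    codes = np.zeros((ny, h, w), dtype=np.int8)
    rows = []
    for r in range(h):
        for c in range(w):
            result = map_pixel(scene.pixel(r, c), model, params)
            codes[:, r, c] = result.series.codes
            for seg, label, code in result.segments:
                rows.append({
                    "row": r, "col": c,
                    "start_year": seg.start_year, "end_year": seg.end_year,
                    "magnitude": seg.magnitude, "label": label, "code": code,
                })
    columns = ["row", "col", "start_year", "end_year", "magnitude", "label", "code"]
    return codes, pd.DataFrame(rows, columns=columns)


def latest_stack(codes: np.ndarray, years: np.ndarray):
    """Latest-disturbance rasters (type, start year, end year) from a code stack."""
    _, h, w = codes.shape
    latest_type = np.zeros((h, w), dtype=np.int16)
    latest_year = np.zeros((h, w), dtype=np.int16)
    ending_year = np.zeros((h, w), dtype=np.int16)
    for r in range(h):
        for c in range(w):
            code, start, end = latest_products(
                AnnualDisturbanceSeries(years, codes[:, r, c])
            )
            latest_type[r, c] = code
            latest_year[r, c] = start or 0
            ending_year[r, c] = end or 0
    return latest_type, latest_year, ending_year


def event_recall(
    true_labels: np.ndarray,
    pred_codes: np.ndarray,
    code: int,
    tolerance_years: int = 1,
) -> float:
    """Fraction of true events of a map code recovered by the prediction.

    Rapid codes count a pixel as detected when the same code is predicted
    within +/- tolerance years of the true event year. Multi-year pest codes
    count a pixel when the predicted code-years overlap the true span
    (extended by the tolerance).
    """
    ny = true_labels.shape[0]
    hits = misses = 0
    pixels = np.argwhere((true_labels == code).any(axis=0))
    for r, c in pixels:
        true_years = np.flatnonzero(true_labels[:, r, c] == code)
        pred_years = np.flatnonzero(pred_codes[:, r, c] == code)
        if code in RAPID_CODES:
            events = [np.array([t]) for t in true_years]
        else:
            assert code in MULTI_YEAR_CODES
            events = _runs(true_years)
        for ev in events:
            lo = max(0, ev.min() - tolerance_years)
            hi = min(ny - 1, ev.max() + tolerance_years)
            if np.any((pred_years >= lo) & (pred_years <= hi)):
                hits += 1
            else:
                misses += 1
    if hits + misses == 0:
        return float("nan")
    return hits / (hits + misses)


def _runs(idx: np.ndarray) -> list[np.ndarray]:
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, breaks)
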
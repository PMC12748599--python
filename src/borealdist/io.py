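"""Raster and table I/O plus the pipeline configuration.

Annual stacks are one multi-band TIFF per year named ``annual_<year>.tif``
(band-major, float32, NaN = missing); georeferencing is passed through via a
``georef.json`` sidecar. Map products follow the published naming:
``annual_<year>.tif`` code rasters plus ``latest_type``/``latest_year``/
``ending_year`` and a ``legend_type.csv``.
"""
from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classes import CODE_LABELS
from .spectral import ValidationError

_YEAR_RE = re.compile(r"(\d{4})")


def _year_of(path: Path) -> int:
    m = _YEAR_RE.search(path.stem)
    if not m:
        raise ValidationError(f"no 4-digit year in filename {path.name!r}")
    return int(m.group(1))


def write_annual_stack(
    directory: str | Path,
    stack: np.ndarray,
    years: np.ndarray,
    georef: dict | None = None,
    prefix: str = "annual",
) -> list[Path]:
    """One float32 multi-band TIFF per year; NaN marks missing data."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, year in enumerate(years):
        p = directory / f"{prefix}_{int(year)}.tif"
        tifffile.imwrite(p, stack[i].astype(np.float32))
        paths.append(p)
    if georef is not None:
        (directory / "georef.json").write_text(json.dumps(georef))
    return paths


def read_annual_stack(
    pattern: str | Path,
) -> tuple[np.ndarray, np.ndarray, dict | None]:
    """Read an annual stack back; returns (stack (Y,B,H,W), years, georef).

    Years are inferred from filenames. A missing year inside the span is
    tolerated and filled with NaN (flagged missing); grids that disagree in
    shape raise, naming the offenders.
    """
    pattern = Path(pattern)
    paths = sorted(pattern.parent.glob(pattern.name), key=_year_of)
    if len(paths) < 10:
        raise ValidationError("need at least 10 annual files")
    years_present = [_year_of(p) for p in paths]
    arrays = [tifffile.imread(p) for p in paths]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        offenders = [
            f"{p.name}: {a.shape}" for p, a in zip(paths, arrays)
            if a.shape != arrays[0].shape
        ]
        raise ValidationError("grid mismatch between years: " + "; ".join(offenders))
    years = np.arange(years_present[0], years_present[-1] + 1)
    stack = np.full((years.size,) + arrays[0].shape, np.nan, dtype=np.float32)
    for y, a in zip(years_present, arrays):
        stack[y - years[0]] = a
    georef = None
    sidecar = pattern.parent / "georef.json"
    if sidecar.exists():
        georef = json.loads(sidecar.read_text())
    return stack, years, georef


def write_legend(path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"code": code, "label": label, "color": color}
        for code, (label, color) in CODE_LABELS.items()
        if code != 0
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_products(
    directory: str | Path,
    code_stack: np.ndarray,
    years: np.ndarray,
    latest: tuple[np.ndarray, np.ndarray, np.ndarray],
    georef: dict | None = None,
) -> dict[str, Path]:
    """Coded annual rasters + latest products + legend CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if code_stack.min() < 0 or code_stack.max() > 8:
        raise ValidationError("map codes must lie in 0..8")
    out: dict[str, Path] = {}
    for i, year in enumerate(years):
        p = directory / f"annual_{int(year)}.tif"
        tifffile.imwrite(p, code_stack[i].astype(np.uint8))
        out[f"annual_{int(year)}"] = p
    for name, arr in zip(("latest_type", "latest_year", "ending_year"), latest):
        p = directory / f"{name}.tif"
        tifffile.imwrite(p, arr.astype(np.int16))
        out[name] = p
    out["legend"] = write_legend(directory / "legend_type.csv")
    if georef is not None:
        (directory / "georef.json").write_text(json.dumps(georef))
    return out


def read_products(directory: str | Path) -> tuple[np.ndarray, np.ndarray]:
    directory = Path(directory)
    paths = sorted(directory.glob("annual_*.tif"), key=_year_of)
    years = np.array([_year_of(p) for p in paths])
    stack = np.stack([tifffile.imread(p) for p in paths])
    return stack, years


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable threshold in the pipeline, with one home each."""

    input_pattern: str = "annual_*.tif"
    output_dir: str = "products"
    seed: int = 0
    # segmentation
    max_segments: int = 6
    min_start_drop: float = 0.1
    max_returned: int = 5
    noise_dampening: bool = True
    f_enter: float = 2.0
    # model
    kernel_size: int = 3
    n_filters: int = 64
    dense_units: int = 64
    dropout: float = 0.4
    n_conv_blocks: int = 3
    # training
    epochs: int = 50
    batch_size: int = 64
    weight_decay: float = 1e-5
    initial_lr: float = 1e-3
    lr_decay: float = 0.95
    n_per_class: int = 500
    # simulation
    scene_width: int = 50
    scene_height: int = 50
    year_start: int = 1985
    year_end: int = 2024
    noise_sd: float = 0.01
    cloud_rate: float = 0.0
    patches_per_class: int = 6
    patch_size: int = 4
    # post-processing
    sieve_min_pixels: int = 12
    sieve_window_years: int = 5
    apply_sieve: bool = True
    apply_wetland_filter: bool = False
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def segmentation_params(self):
        from .segmentation import SegmentationParams
        return SegmentationParams(
            max_segments=self.max_segments,
            min_start_drop=self.min_start_drop,
            max_returned=self.max_returned,
            noise_dampening=self.noise_dampening,
            f_enter=self.f_enter,
        )

    def model_config(self):
        from .tempcnn import ModelConfig
        return ModelConfig(
            kernel_size=self.kernel_size, n_filters=self.n_filters,
            dense_units=self.dense_units, dropout=self.dropout,
            n_conv_blocks=self.n_conv_blocks,
        )

    def train_config(self):
        from .tempcnn import TrainConfig
        return TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            weight_decay=self.weight_decay, initial_lr=self.initial_lr,
            lr_decay=self.lr_decay, seed=self.seed,
        )


def save_model(model, path: str | Path) -> Path:
    """Weights + normalization statistics in one versioned .npz file."""
    path = Path(path)
    payload = {f"param_{k}": v for k, v in model.params.items()}
    payload["format_version"] = np.array([1])
    payload["cfg"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    if model.normalizer is not None:
        payload["norm_mean"] = model.normalizer.mean
        payload["norm_std"] = model.normalizer.std
    np.savez(path, **payload)
    return path


def load_model(path: str | Path):
    from .tempcnn import ModelConfig, Normalizer, TempCNN
    with np.load(path) as z:
        cfg = ModelConfig(**json.loads(bytes(z["cfg"]).decode()))
        model = TempCNN(cfg)
        for k in list(model.params):
            model.params[k] = z[f"param_{k}"]
        if "norm_mean" in z:
            model.normalizer = Normalizer(z["norm_mean"], z["norm_std"])
    return model
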
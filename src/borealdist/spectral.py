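"""Spectral index computation and dNBR-based defoliation severity rules.

The normalized burn ratio (NBR) contrasts the NIR and SWIR2 bands; year-over-
year NBR *decreases* (dNBR, decline-positive) are the severity discriminator:
drops below 0.1 are ignored, [0.1, 0.15) is low, [0.15, 0.25) medium and
>= 0.25 high severity.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")
N_BANDS = len(BANDS)

#: Severity thresholds on the decline-positive dNBR, in index units.
DNBR_MIN_DROP = 0.1
DNBR_MEDIUM = 0.15
DNBR_HIGH = 0.25


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class UndefinedValueError(ValueError):
    """Raised when a quantity is mathematically undefined for the input."""


class SeverityClass(enum.Enum):
    """Defoliation severity class with its final-map legend code."""

    NONE = ("none", 0)
    LOW = ("low", 6)
    MEDIUM = ("medium", 7)
    HIGH = ("high", 8)

    def __init__(self, label: str, code: int):
        self.label = label
        self.code = code


@dataclass
class AnnualSpectra:
    """One pixel's 6-band annual surface-reflectance series.

    Attributes
    ----------
    years : (n,) int array, strictly increasing, annual step.
    reflectance : (n, 6) float array in band order blue, green, red, nir,
        swir1, swir2; finite for every non-missing year.
    missing : (n,) bool array flagging cloud/composite gaps.
    """

    years: np.ndarray
    reflectance: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.years.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.years.ndim != 1 or self.years.size == 0:
            raise ValidationError("years must be a non-empty 1-D array")
        if np.any(np.diff(self.years) != 1):
            raise ValidationError("years must be strictly increasing with annual step")
        if self.reflectance.shape != (self.years.size, N_BANDS):
            raise ValidationError(
                f"reflectance must have shape (n_years, {N_BANDS}), "
                f"got {self.reflectance.shape}"
            )
        if self.missing.shape != self.years.shape:
            raise ValidationError("missing flags must align with years")
        if not np.all(np.isfinite(self.reflectance[~self.missing])):
            raise ValidationError("reflectance must be finite for non-missing years")

    def __len__(self) -> int:
        return self.years.size

    @property
    def n_valid(self) -> int:
        return int(np.sum(~self.missing))

    def band(self, name: str) -> np.ndarray:
        return self.reflectance[:, BANDS.index(name)]

    def nbr(self) -> np.ndarray:
        """Per-year NBR; NaN at missing years."""
        out = np.full(len(self), np.nan)
        valid = ~self.missing
        out[valid] = compute_nbr(
            self.reflectance[valid, BANDS.index("nir")],
            self.reflectance[valid, BANDS.index("swir2")],
        )
        return out


def compute_nbr(nir, swir2):
    """Normalized burn ratio (NIR − SWIR2)/(NIR + SWIR2), in [-1, 1].

    Accepts scalars or arrays; raises :class:`UndefinedValueError` when both
    inputs are zero anywhere.
    """
    nir = np.asarray(nir, dtype=float)
    swir2 = np.asarray(swir2, dtype=float)
    if np.any(nir < 0) or np.any(swir2 < 0):
        raise ValidationError("reflectance must be non-negative")
    denom = nir + swir2
    if np.any(denom == 0):
        raise UndefinedValueError("NBR undefined where NIR + SWIR2 == 0")
    out = (nir - swir2) / denom
    return float(out) if out.ndim == 0 else out


def compute_dnbr_series(spectra: AnnualSpectra) -> np.ndarray:
    """Decline-positive year-over-year NBR decrease, aligned to `spectra.years`.

    dNBR at year t is NBR(previous valid year) − NBR(t), computed between the
    nearest flanking non-missing observations and assigned to the later year.
    The first valid year and all missing years carry NaN.
    """
    if spectra.n_valid < 2:
        raise ValidationError("dNBR requires at least 2 non-missing years")
    nbr = spectra.nbr()
    valid_idx = np.flatnonzero(~spectra.missing)
    out = np.full(len(spectra), np.nan)
    out[valid_idx[1:]] = nbr[valid_idx[:-1]] - nbr[valid_idx[1:]]
    return out


def classify_severity(dnbr_drop: float) -> SeverityClass:
    """Map a decline-positive dNBR value to a severity class.

    Half-open bins guarantee a partition of [0, inf): drops below 0.1 are
    NONE (excluded), [0.1, 0.15) LOW, [0.15, 0.25) MEDIUM, >= 0.25 HIGH.
    """
    drop = float(dnbr_drop)
    if not np.isfinite(drop):
        raise ValidationError("dNBR drop must be finite")
    if drop < DNBR_MIN_DROP:
        return SeverityClass.NONE
    if drop < DNBR_MEDIUM:
        return SeverityClass.LOW
    if drop < DNBR_HIGH:
        return SeverityClass.MEDIUM
    return SeverityClass.HIGH
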
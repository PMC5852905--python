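"""Calibration curves, quantification and LOD/LOQ assignment.

Calibration is ordinary unweighted least squares of the mean peak area per
level against nominal concentration; linearity is gated on the coefficient
of determination (R^2 >= 0.99 by default).  Three preparation modes are
distinguished because their slopes differ systematically: standards in pure
solvent, standards spiked into blank extract after the preparation steps
(fortified extract, reflecting ionization matrix effects only), and
standards spiked into blank tissue before preparation (matrix matched,
additionally reflecting preparation losses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CurveMode",
    "CalibrationLevel",
    "CalibrationCurve",
    "QuantResult",
    "Chromatogram",
    "DEFAULT_R2_THRESHOLD",
    "SNR_LOD_THRESHOLD",
    "LOQ_CV_LIMIT",
    "fit_curve",
    "quantify",
    "estimate_snr",
    "assign_lod",
    "assign_loq",
]

DEFAULT_R2_THRESHOLD = 0.99
SNR_LOD_THRESHOLD = 3.0
LOQ_CV_LIMIT = 20.0  # percent


class CurveMode(str, Enum):
    SOLVENT = "solvent"
    FORTIFIED_EXTRACT = "fortified_extract"
    MATRIX_MATCHED = "matrix_matched"


@dataclass(frozen=True)
class CalibrationLevel:
    """One nominal concentration with its replicate areas."""

    nominal: float  # ng/g
    areas: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.nominal < 0:
            raise ValueError("nominal concentration must be non-negative")
        if len(self.areas) < 1:
            raise ValueError("at least one replicate area is required")

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas))


@dataclass(frozen=True)
class CalibrationCurve:
    mode: CurveMode
    slope: float  # counts per ng/g
    intercept: float  # counts
    r_squared: float
    levels: Tuple[CalibrationLevel, ...] = ()
    linearity_pass: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class QuantResult:
    """Back-calculated tissue concentration with a below-curve flag."""

    concentration: float  # ng/g
    below_curve: bool = False

    def __float__(self) -> float:
        return self.concentration


@dataclass(frozen=True)
class Chromatogram:
    """A uniform-grid intensity trace (substrate for S/N estimation)."""

    times: Tuple[float, ...]
    intensities: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities must have equal length")
        t = np.asarray(self.times)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")


def fit_curve(
    levels: Sequence[CalibrationLevel],
    mode: CurveMode = CurveMode.MATRIX_MATCHED,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> CalibrationCurve:
    """Unweighted OLS of mean area vs nominal concentration.

    Requires at least 3 distinct nominal levels.  ``r_squared`` is
    1 - SS_res/SS_tot of the fitted line through the level means; a
    degenerate zero-variance response with zero residuals scores 1.
    """
    nominals = np.array([lv.nominal for lv in levels], dtype=float)
    if len(set(nominals.tolist())) < 3:
        raise ValueError("calibration requires >=3 distinct nominal levels")
    y = np.array([lv.mean_area for lv in levels], dtype=float)
    slope, intercept = np.polyfit(nominals, y, 1)
    pred = slope * nominals + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return CalibrationCurve(
        mode=CurveMode(mode),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        levels=tuple(levels),
        linearity_pass=r2 >= r2_threshold,
    )


def quantify(
    area: float,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
    tissue_factor: float = 1.0,
    clamp: bool = True,
) -> QuantResult:
    """Back-calculate a tissue concentration from a peak area.

    ``dilution_factor`` is the extract dilution applied before injection
    (>= 1); ``tissue_factor`` converts extract concentration (ng/mL) to
    tissue concentration (ng/g) and is 1.0 for the default preparation
    (2.5 g -> 10 mL, 2 mL aliquot reconstituted in 0.5 mL).  Negative
    back-calculated values clamp to 0 with ``below_curve=True``; pass
    ``clamp=False`` to keep the raw signed value (validation statistics
    need the unbiased estimator, clamping is a reporting rule).
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    if area < 0:
        raise ValueError("area must be non-negative")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if not tissue_factor > 0:
        raise ValueError("tissue factor must be positive")
    conc = (area - curve.intercept) / curve.slope * dilution_factor / tissue_factor
    if conc < 0:
        return QuantResult(0.0 if clamp else float(conc), below_curve=True)
    return QuantResult(float(conc), below_curve=False)


def _window_mask(times: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"window {window!r} is empty")
    return (times >= lo) & (times <= hi)


def estimate_snr(
    chrom: Chromatogram,
    peak_window: Tuple[float, float],
    noise_window: Tuple[float, float],
) -> float:
    """Signal-to-noise ratio of a peak against an analyte-free region.

    Signal is the apex intensity in ``peak_window`` minus the median of the
    noise window; noise is the sample standard deviation of the noise
    window.  Windows must be disjoint and contain >= 5 points each.
    """
    if peak_window[1] > noise_window[0] and noise_window[1] > peak_window[0]:
        raise ValueError("peak and noise windows must be disjoint")
    t = np.asarray(chrom.times, dtype=float)
    y = np.asarray(chrom.intensities, dtype=float)
    pk = _window_mask(t, peak_window)
    nz = _window_mask(t, noise_window)
    if pk.sum() < 5 or nz.sum() < 5:
        raise ValueError("each window must contain at least 5 points")
    noise_sd = float(np.std(y[nz], ddof=1))
    if noise_sd == 0.0:
        raise ValueError("zero noise variance in noise window")
    return float((np.max(y[pk]) - np.median(y[nz])) / noise_sd)


def assign_lod(
    levels_with_snr: Sequence[Tuple[float, float]],
    snr_threshold: float = SNR_LOD_THRESHOLD,
) -> Optional[float]:
    """Lowest nominal concentration whose S/N meets the threshold (inclusive).

    Returns ``None`` when no level qualifies.
    """
    if not levels_with_snr:
        raise ValueError("no (nominal, S/N) pairs supplied")
    nominals = [lv for lv, _ in levels_with_snr]
    if len(set(nominals)) != len(nominals):
        raise ValueError("nominal concentrations must be distinct")
    qualifying = [lv for lv, snr in levels_with_snr if snr >= snr_threshold]
    return min(qualifying) if qualifying else None


def assign_loq(
    level_measurements: Mapping[float, Sequence[float]],
    cv_limit: float = LOQ_CV_LIMIT,
) -> Optional[float]:
    """Lowest curve level whose replicate CV% is within the limit (inclusive).

    ``level_measurements`` maps nominal concentration to replicate measured
    concentrations (>= 2 replicates each).  Returns ``None`` when no level
    qualifies.
    """
    if not level_measurements:
        raise ValueError("no levels supplied")
    from .validation import cv_percent  # deferred: avoids a module cycle

    for nominal in sorted(level_measurements):
        values = level_measurements[nominal]
        if len(values) < 2:
            raise ValueError(f"level {nominal}: need >=2 replicates for a CV")
        if cv_percent(values) <= cv_limit:
            return nominal
    return None
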
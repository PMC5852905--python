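"""Method-validation statistics.

Matrix effect, recovery, intraday/interday precision (CV%), and the
decision limit / detection capability pair:

* CCalpha = MRL + k * SD of >= 20 blanks fortified at the MRL (k = 1.64,
  one-sided 5% error),
* CCbeta = CCalpha + k * SD of >= 20 blanks fortified at CCalpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CCALPHA_K",
    "ME_RELEVANCE_LIMIT",
    "PRECISION_CV_LIMIT",
    "MatrixEffect",
    "FortifiedSet",
    "PrecisionSummary",
    "ValidationRecord",
    "cv_percent",
    "matrix_effect",
    "recovery_percent",
    "precision_summary",
    "cc_alpha",
    "cc_beta",
]

CCALPHA_K = 1.64
ME_RELEVANCE_LIMIT = 20.0  # percent
PRECISION_CV_LIMIT = 20.0  # percent


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation, 100 * sample SD (n-1) / mean."""
    if len(values) < 2:
        raise ValueError("CV requires at least 2 values")
    arr = np.asarray(values, dtype=float)
    mean = float(np.mean(arr))
    if mean == 0.0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * np.std(arr, ddof=1) / mean)


class MatrixEffect(NamedTuple):
    percent: float
    relevant: bool


def matrix_effect(
    area_solvent: float,
    area_extract: float,
    relevance_limit: float = ME_RELEVANCE_LIMIT,
) -> MatrixEffect:
    """Signed matrix effect, 100 * (extract - solvent) / solvent.

    Negative values mean ionization suppression.  ``relevant`` flags
    |ME| above the acceptance limit (20% by default).
    """
    if not area_solvent > 0:
        raise ValueError("solvent area must be positive")
    pct = 100.0 * (area_extract - area_solvent) / area_solvent
    return MatrixEffect(percent=pct, relevant=abs(pct) > relevance_limit)


def recovery_percent(measured: float, nominal: float) -> float:
    """Recovery of a spiked blank, 100 * measured / nominal."""
    if not nominal > 0:
        raise ValueError("nominal concentration must be positive")
    if measured < 0:
        raise ValueError("measured concentration must be non-negative")
    return 100.0 * measured / nominal


@dataclass(frozen=True)
class FortifiedSet:
    """Replicate measured concentrations for one spike level on one day."""

    level: float  # ng/g
    day: int
    measured: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.level > 0:
            raise ValueError("spike level must be positive")
        if len(self.measured) < 2:
            raise ValueError("need >=2 replicates per (level, day)")


@dataclass
class PrecisionSummary:
    """Intraday CV per (level, day) and interday CV per level.

    Interday pools all replicates of a level across days into one CV;
    levels observed on a single day map to ``None`` (undefined).
    """

    intraday: Dict[Tuple[float, int], float]
    interday: Dict[float, Optional[float]]
    cv_limit: float = PRECISION_CV_LIMIT

    @property
    def passed(self) -> bool:
        cvs = list(self.intraday.values()) + [
            v for v in self.interday.values() if v is not None
        ]
        # a negative CV (negative pooled mean) is a quantification failure
        return all(0.0 <= cv <= self.cv_limit for cv in cvs)


def precision_summary(
    sets: Sequence[FortifiedSet], cv_limit: float = PRECISION_CV_LIMIT
) -> PrecisionSummary:
    """Repeatability and intermediate precision from fortified replicates."""
    if not sets:
        raise ValueError("no fortified sets supplied")
    intraday: Dict[Tuple[float, int], float] = {}
    pooled: Dict[float, List[float]] = {}
    days_seen: Dict[float, set] = {}
    for fs in sets:
        key = (fs.level, fs.day)
        if key in intraday:
            raise ValueError(f"duplicate fortified set for level {fs.level}, day {fs.day}")
        intraday[key] = cv_percent(fs.measured)
        pooled.setdefault(fs.level, []).extend(fs.measured)
        days_seen.setdefault(fs.level, set()).add(fs.day)
    interday: Dict[float, Optional[float]] = {}
    for level, values in pooled.items():
        interday[level] = cv_percent(values) if len(days_seen[level]) >= 2 else None
    return PrecisionSummary(intraday=intraday, interday=interday, cv_limit=cv_limit)


def cc_alpha(mrl: float, sd_at_mrl: float, k: float = CCALPHA_K) -> float:
    """Decision limit: MRL + k * SD of blanks fortified at the MRL."""
    if not mrl > 0:
        raise ValueError("MRL must be positive")
    if sd_at_mrl < 0:
        raise ValueError("standard deviation must be non-negative")
    return mrl + k * sd_at_mrl


def cc_beta(cc_alpha_val: float, sd_at_ccalpha: float, k: float = CCALPHA_K) -> float:
    """Detection capability: CCalpha + k * SD of blanks fortified at CCalpha."""
    if sd_at_ccalpha < 0:
        raise ValueError("standard deviation must be non-negative")
    return cc_alpha_val + k * sd_at_ccalpha


@dataclass
class ValidationRecord:
    """Per-analyte validation results (report row material)."""

    analyte: str
    working_range: Tuple[float, float] = (0.0, 0.0)
    r_squared: float = 0.0
    sensitivity: float = 0.0  # matrix-matched slope, counts per ng/g
    matrix_effect_pct: Dict[float, float] = field(default_factory=dict)
    recovery_pct: Dict[float, Tuple[float, float]] = field(default_factory=dict)
    intraday_cv: Dict[float, float] = field(default_factory=dict)
    interday_cv: Dict[float, float] = field(default_factory=dict)
    cc_alpha: float = float("nan")
    cc_beta: float = float("nan")
    lod: Optional[float] = None
    loq: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "working_range": list(self.working_range),
            "r_squared": self.r_squared,
            "sensitivity": self.sensitivity,
            "matrix_effect_pct": {str(k): v for k, v in self.matrix_effect_pct.items()},
            "recovery_pct": {str(k): list(v) for k, v in self.recovery_pct.items()},
            "intraday_cv": {str(k): v for k, v in self.intraday_cv.items()},
            "interday_cv": {str(k): v for k, v in self.interday_cv.items()},
            "cc_alpha": self.cc_alpha,
            "cc_beta": self.cc_beta,
            "lod": self.lod,
            "loq": self.loq,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationRecord":
        return cls(
            analyte=d["analyte"],
            working_range=tuple(d.get("working_range", (0.0, 0.0))),
            r_squared=d.get("r_squared", 0.0),
            sensitivity=d.get("sensitivity", 0.0),
            matrix_effect_pct={float(k): v for k, v in d.get("matrix_effect_pct", {}).items()},
            recovery_pct={float(k): tuple(v) for k, v in d.get("recovery_pct", {}).items()},
            intraday_cv={float(k): v for k, v in d.get("intraday_cv", {}).items()},
            interday_cv={float(k): v for k, v in d.get("interday_cv", {}).items()},
            cc_alpha=d.get("cc_alpha", float("nan")),
            cc_beta=d.get("cc_beta", float("nan")),
            lod=d.get("lod"),
            loq=d.get("loq"),
        )
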
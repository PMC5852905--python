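"""Identity confirmation of candidate peaks.

A candidate chromatographic peak is matched against an analyte target on
accurate mass (ppm tolerance) and retention time, then scored with additive
identification points: a high-resolution precursor ion earns 2.0 points and
each matched high-resolution fragment (transition product) earns 2.5.
Confirmation requires both the match and an IP score at or above the
per-group threshold (default 4.0 for prohibited-substance targets, 3.0 for
authorized ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Tuple

from .chem_mass import (
    DEFAULT_MASS_TABLE,
    AtomicMassTable,
    ElementalFormula,
    adduct_mz,
    parse_formula,
    ppm_error,
)

__all__ = [
    "Group",
    "AnalyteTarget",
    "PeakObservation",
    "IdentityResult",
    "IP_PRECURSOR_HR",
    "IP_FRAGMENT_HR",
    "IP_PRECURSOR_LR",
    "IP_FRAGMENT_LR",
    "DEFAULT_PPM_TOL",
    "DEFAULT_RT_TOL",
    "DEFAULT_IP_THRESHOLDS",
    "identification_points",
    "match_feature",
    "confirm_identity",
    "select_best_peak",
]

# IP weights for high-resolution MS; low-resolution weights are provided for
# completeness but the assay is HRMS-only.
IP_PRECURSOR_HR = 2.0
IP_FRAGMENT_HR = 2.5
IP_PRECURSOR_LR = 1.0
IP_FRAGMENT_LR = 1.5

DEFAULT_PPM_TOL = 5.0  # ppm; conventional Q-TOF screening tolerance
DEFAULT_RT_TOL = 0.1  # minutes


class Group(str, Enum):
    """Regulatory group of a target substance."""

    A_PROHIBITED = "A"
    B_AUTHORIZED = "B"


#: Minimum IP score required for confirmation, by regulatory group.
DEFAULT_IP_THRESHOLDS = {Group.A_PROHIBITED: 4.0, Group.B_AUTHORIZED: 3.0}


@dataclass(frozen=True)
class AnalyteTarget:
    """One monitored compound.

    ``precursor_mz`` must agree with the theoretical [M+H]+ m/z of
    ``formula`` within 1 mDa (accommodating experimentally refined values).
    """

    name: str
    formula: ElementalFormula
    rt_expected: float  # minutes
    precursor_mz: float  # Da
    fragment_mz: Tuple[float, ...] = ()
    group: Group = Group.B_AUTHORIZED
    mrl: Optional[float] = None  # ng/g
    residue_class: str = "other"

    def __post_init__(self) -> None:
        if not self.rt_expected > 0:
            raise ValueError(f"{self.name}: expected retention time must be positive")
        theoretical = adduct_mz(self.formula)
        if abs(self.precursor_mz - theoretical) > 1e-3:
            raise ValueError(
                f"{self.name}: precursor m/z {self.precursor_mz:.4f} inconsistent with "
                f"formula ([M+H]+ = {theoretical:.4f})"
            )

    @classmethod
    def from_formula(
        cls,
        name: str,
        formula: str,
        rt_expected: float,
        fragment_mz: Sequence[float] = (),
        group: Group = Group.B_AUTHORIZED,
        mrl: Optional[float] = None,
        residue_class: str = "other",
        table: AtomicMassTable = DEFAULT_MASS_TABLE,
    ) -> "AnalyteTarget":
        f = parse_formula(formula, table)
        return cls(
            name=name,
            formula=f,
            rt_expected=rt_expected,
            precursor_mz=adduct_mz(f, "[M+H]+", table),
            fragment_mz=tuple(fragment_mz),
            group=group,
            mrl=mrl,
            residue_class=residue_class,
        )


@dataclass(frozen=True)
class PeakObservation:
    """One integrated chromatographic peak from a sample."""

    sample_id: str
    mz_observed: float
    rt_observed: float
    area: float
    height: float
    fragments_observed: Tuple[float, ...] = ()
    analyte_hint: str = ""
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.area < 0 or self.height < 0:
            raise ValueError("peak area and height must be non-negative")
        if self.rt_observed < 0:
            raise ValueError("retention time must be non-negative")


@dataclass
class IdentityResult:
    matched: bool
    ppm: float
    rt_delta: float
    ip_score: float = 0.0
    confirmed: bool = False
    reasons: List[str] = field(default_factory=list)


def identification_points(
    n_precursor_hr: int,
    n_fragment_hr: int,
    precursor_weight: float = IP_PRECURSOR_HR,
    fragment_weight: float = IP_FRAGMENT_HR,
) -> float:
    """Additive IP score for the given ion counts."""
    if n_precursor_hr < 0 or n_fragment_hr < 0:
        raise ValueError("ion counts must be non-negative")
    return precursor_weight * n_precursor_hr + fragment_weight * n_fragment_hr


def match_feature(
    target: AnalyteTarget,
    peak: PeakObservation,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> IdentityResult:
    """Accurate-mass + retention-time match of one peak against one target.

    The result is partial: ``ip_score`` and ``confirmed`` are left at their
    defaults and filled in by :func:`confirm_identity`.
    """
    if not ppm_tol > 0 or not rt_tol > 0:
        raise ValueError("tolerances must be positive")
    ppm = ppm_error(peak.mz_observed, target.precursor_mz)
    rt_delta = peak.rt_observed - target.rt_expected
    reasons: List[str] = []
    if abs(ppm) > ppm_tol:
        reasons.append("mass tolerance")
    if abs(rt_delta) > rt_tol:
        reasons.append("retention time")
    return IdentityResult(matched=not reasons, ppm=ppm, rt_delta=rt_delta, reasons=reasons)


def _matched_fragment_count(
    target_fragments: Iterable[float], observed: Iterable[float], ppm_tol: float
) -> int:
    # Each target fragment counts at most once, however many observed ions hit it.
    n = 0
    obs = list(observed)
    for frag in target_fragments:
        if any(abs(ppm_error(o, frag)) <= ppm_tol for o in obs):
            n += 1
    return n


def confirm_identity(
    target: AnalyteTarget,
    peak: PeakObservation,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
    ip_threshold: Optional[float] = None,
) -> IdentityResult:
    """Full identity decision: match + IP scoring against a threshold.

    ``ip_threshold`` defaults to the target's group threshold.  The IP score
    counts the precursor (if matched) plus every target fragment with an
    observed ion inside ``ppm_tol``.
    """
    if ip_threshold is None:
        ip_threshold = DEFAULT_IP_THRESHOLDS[target.group]
    if not ip_threshold > 0:
        raise ValueError("ip_threshold must be positive")
    result = match_feature(target, peak, ppm_tol, rt_tol)
    n_frag = _matched_fragment_count(target.fragment_mz, peak.fragments_observed, ppm_tol)
    result.ip_score = identification_points(1 if result.matched else 0, n_frag)
    if result.ip_score < ip_threshold:
        result.reasons.append("identification points")
    result.confirmed = result.matched and result.ip_score >= ip_threshold
    return result


def select_best_peak(
    target: AnalyteTarget,
    peaks: Sequence[PeakObservation],
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> Optional[Tuple[PeakObservation, IdentityResult]]:
    """Pick the matching peak with smallest |ppm|, then smallest |rt delta|.

    Returns ``None`` when no peak matches the target.
    """
    best: Optional[Tuple[PeakObservation, IdentityResult]] = None
    for peak in peaks:
        res = match_feature(target, peak, ppm_tol, rt_tol)
        if not res.matched:
            continue
        if best is None or (abs(res.ppm), abs(res.rt_delta)) < (
            abs(best[1].ppm),
            abs(best[1].rt_delta),
        ):
            best = (peak, res)
    return best
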
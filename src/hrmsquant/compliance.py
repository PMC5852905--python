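"""MRL compliance screening.

A sample analyte is nonconforming only when its identity is confirmed and
its concentration is at or above the decision limit (CCalpha), giving the
5% false-positive protection the decision limit encodes.  Sulfonamide-class
analytes are additionally screened as a group against a summed-residue MRL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional

from .identification import Group, IdentityResult

__all__ = [
    "Status",
    "MRLEntry",
    "MRLRegistry",
    "ComplianceDecision",
    "screen_sample",
    "loq_policy_check",
    "DEFAULT_GROUP_MRL_SULFONAMIDES",
    "DEFAULT_MRL_TRIMETHOPRIM",
]

DEFAULT_GROUP_MRL_SULFONAMIDES = 100.0  # ng/g, individual or summed
DEFAULT_MRL_TRIMETHOPRIM = 50.0  # ng/g


class Status(str, Enum):
    NOT_DETECTED = "not_detected"
    BELOW_LOQ = "below_loq"
    CONFORMING = "conforming"
    NONCONFORMING = "nonconforming"


@dataclass(frozen=True)
class MRLEntry:
    mrl: float  # ng/g
    group: Group = Group.B_AUTHORIZED
    sulfonamide: bool = False


@dataclass
class MRLRegistry:
    per_analyte: Dict[str, MRLEntry] = field(default_factory=dict)
    group_mrl_sulfonamides: float = DEFAULT_GROUP_MRL_SULFONAMIDES

    def entry(self, name: str) -> MRLEntry:
        try:
            return self.per_analyte[name]
        except KeyError:
            raise KeyError(f"analyte {name!r} not present in MRL registry") from None


@dataclass
class ComplianceDecision:
    sample_id: str
    per_analyte_status: Dict[str, Status]
    concentrations: Dict[str, float]
    sum_sulfonamides: float
    group_status: Status
    rationale: List[str] = field(default_factory=list)


def screen_sample(
    sample_id: str,
    concs: Mapping[str, float],
    identities: Mapping[str, IdentityResult],
    registry: MRLRegistry,
    ccalphas: Mapping[str, float],
    loqs: Mapping[str, float],
) -> ComplianceDecision:
    """Classify one sample against per-analyte CCalpha and the group MRL.

    Per analyte: not_detected (conc <= 0), below_loq, conforming, or
    nonconforming (requires confirmed identity AND conc >= CCalpha).  An
    unconfirmed identity is never actionable regardless of concentration.
    The sulfonamide sum pools confirmed, quantifiable (>= LOQ) analytes and
    is compared against the group MRL.
    """
    statuses: Dict[str, Status] = {}
    rationale: List[str] = []
    sum_sulfa = 0.0
    for name, conc in concs.items():
        if name not in ccalphas or name not in loqs:
            raise KeyError(f"analyte {name!r} lacks a CCalpha and/or LOQ entry")
        entry = registry.entry(name)
        ident = identities.get(name)
        confirmed = bool(ident is not None and ident.confirmed)
        if conc <= 0:
            statuses[name] = Status.NOT_DETECTED
            continue
        if conc < loqs[name]:
            statuses[name] = Status.BELOW_LOQ
            continue
        if not confirmed:
            statuses[name] = Status.CONFORMING
            rationale.append(
                f"{name}: identity not confirmed at {conc:.1f} ng/g; not actionable"
            )
            continue
        if entry.sulfonamide:
            sum_sulfa += conc
        if conc >= ccalphas[name]:
            statuses[name] = Status.NONCONFORMING
            rationale.append(
                f"{name}: {conc:.1f} ng/g >= CCalpha {ccalphas[name]:.1f} ng/g "
                f"(decision-limit rule, 5% error)"
            )
        else:
            statuses[name] = Status.CONFORMING
    if sum_sulfa >= registry.group_mrl_sulfonamides and sum_sulfa > 0:
        group_status = Status.NONCONFORMING
        rationale.append(
            f"sum of sulfonamides {sum_sulfa:.1f} ng/g >= group MRL "
            f"{registry.group_mrl_sulfonamides:.1f} ng/g (group rule is MRL-based; "
            f"no group CCalpha is defined)"
        )
    else:
        group_status = Status.CONFORMING
    return ComplianceDecision(
        sample_id=sample_id,
        per_analyte_status=statuses,
        concentrations=dict(concs),
        sum_sulfonamides=sum_sulfa,
        group_status=group_status,
        rationale=rationale,
    )


def loq_policy_check(
    loqs: Mapping[str, float],
    policy: Mapping[str, float],
    analyte_class: Mapping[str, str],
) -> Dict[str, bool]:
    """Check each analyte's LOQ against a per-class ceiling (inclusive)."""
    result: Dict[str, bool] = {}
    for name, loq in loqs.items():
        if name not in analyte_class:
            raise KeyError(f"analyte {name!r} has no residue-class mapping")
        cls = analyte_class[name]
        if cls not in policy:
            raise KeyError(f"residue class {cls!r} not covered by the LOQ policy")
        result[name] = loq <= policy[cls]
    return result
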
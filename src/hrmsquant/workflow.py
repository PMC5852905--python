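"""End-to-end campaign analysis and screening workflows.

``analyze_campaign`` turns a simulated (or file-loaded) validation bundle
into per-analyte validation records; ``run_validate`` adds gate checking
(R^2 and CV acceptance limits) and report writing; ``run_screen`` matches a
peak table against the target list, quantifies via the matrix-matched
curves and renders compliance decisions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .calibration import (
    CalibrationCurve,
    CurveMode,
    assign_lod,
    assign_loq,
    estimate_snr,
    fit_curve,
    quantify,
)
from .compliance import ComplianceDecision, MRLEntry, MRLRegistry, screen_sample
from .identification import (
    DEFAULT_PPM_TOL,
    DEFAULT_RT_TOL,
    AnalyteTarget,
    PeakObservation,
    confirm_identity,
    select_best_peak,
)
from .simulate import CampaignBundle, SimulationConfig, simulate_validation_campaign
from .validation import (
    PRECISION_CV_LIMIT,
    FortifiedSet,
    ValidationRecord,
    cc_alpha,
    cc_beta,
    cv_percent,
    matrix_effect,
    precision_summary,
    recovery_percent,
)

__all__ = [
    "ValidationOutcome",
    "analyze_campaign",
    "run_validate",
    "run_screen",
    "registry_from_targets",
]

log = logging.getLogger("hrmsquant")


@dataclass
class ValidationOutcome:
    records: List[ValidationRecord]
    curves: Dict[str, Dict[str, CalibrationCurve]]
    failures: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failures


def analyze_campaign(
    bundle: CampaignBundle,
    r2_threshold: float = 0.99,
    cv_limit: float = PRECISION_CV_LIMIT,
) -> ValidationOutcome:
    """Compute every validation parameter from a campaign bundle.

    Recovery is read against the fortified-extract curve so that it
    reflects preparation losses only; routine quantification (LOQ scan,
    fortified blanks for the decision limits, incurred samples) uses the
    matrix-matched curve.
    """
    cfg = bundle.config
    records: List[ValidationRecord] = []
    curves_out: Dict[str, Dict[str, CalibrationCurve]] = {}
    failures: List[str] = []

    for a in cfg.analytes:
        name = a.name
        mrl = cfg.target(name).mrl
        curves = {
            mode.value: fit_curve(
                bundle.curve_levels[mode.value][name], mode, r2_threshold
            )
            for mode in CurveMode
        }
        curves_out[name] = curves
        mm = curves[CurveMode.MATRIX_MATCHED.value]
        fe = curves[CurveMode.FORTIFIED_EXTRACT.value]
        if not mm.linearity_pass:
            failures.append(
                f"{name}: linearity gate R2>={r2_threshold} failed "
                f"(matrix-matched R2={mm.r_squared:.4f})"
            )

        # Matrix effect from mean areas at the shared comparison levels.
        me_pct: Dict[float, float] = {}
        solvent_by_level = {
            lv.nominal: lv.mean_area
            for lv in bundle.curve_levels[CurveMode.SOLVENT.value][name]
        }
        extract_by_level = {
            lv.nominal: lv.mean_area
            for lv in bundle.curve_levels[CurveMode.FORTIFIED_EXTRACT.value][name]
        }
        for lv in cfg.me_levels:
            me = matrix_effect(solvent_by_level[lv], extract_by_level[lv])
            me_pct[lv] = me.percent
            if me.relevant:
                log.warning("%s: matrix effect %.1f%% exceeds the 20%% limit at %g ng/g",
                            name, me.percent, lv)

        # Spike design: recovery + precision.
        spikes = bundle.spike_areas[name]
        fortified_sets: List[FortifiedSet] = []
        recovery: Dict[float, Tuple[float, float]] = {}
        per_level_measured: Dict[float, List[float]] = {}
        for j, lv in enumerate(cfg.spike_levels):
            for d in range(cfg.days):
                measured = tuple(
                    quantify(area, fe, clamp=False).concentration
                    for area in spikes[d, j, :]
                )
                fortified_sets.append(FortifiedSet(level=lv, day=d, measured=measured))
                per_level_measured.setdefault(lv, []).extend(measured)
            # raw (unclamped) ratios: keeps the level mean unbiased even when
            # single replicates back-calculate below zero
            recs = [100.0 * m / lv for m in per_level_measured[lv]]
            recovery[lv] = (float(np.mean(recs)), cv_percent(recs))
        prec = precision_summary(fortified_sets, cv_limit)
        if not prec.passed:
            failures.append(f"{name}: precision gate CV<={cv_limit:g}% failed")
        intraday_by_level: Dict[float, float] = {}
        for lv in cfg.spike_levels:
            day_cvs = [prec.intraday[(lv, d)] for d in range(cfg.days)]
            intraday_by_level[lv] = float(np.mean(day_cvs))
        interday_by_level = {
            lv: cv for lv, cv in prec.interday.items() if cv is not None
        }

        # LOD via S/N on low-level chromatograms; LOQ via replicate CV scan.
        peak_win, noise_win = bundle.chrom_windows(name)
        snr_pairs = [
            (lv, estimate_snr(chrom, peak_win, noise_win))
            for lv, chrom in sorted(bundle.lod_chromatograms[name].items())
        ]
        lod = assign_lod(snr_pairs)
        loq = assign_loq(
            {
                lv: [quantify(area, mm, clamp=False).concentration for area in areas]
                for lv, areas in bundle.loq_areas[name].items()
            },
            cv_limit,
        )

        # Decision limit / detection capability from fortified blanks.
        mrl_concs = [
            quantify(area, mm, clamp=False).concentration
            for area in bundle.mrl_fortified_areas[name]
        ]
        cca = cc_alpha(mrl, float(np.std(mrl_concs, ddof=1)))
        cca_concs = [
            quantify(area, mm, clamp=False).concentration
            for area in bundle.ccalpha_fortified_areas[name]
        ]
        ccb = cc_beta(cca, float(np.std(cca_concs, ddof=1)))

        records.append(
            ValidationRecord(
                analyte=name,
                working_range=(min(cfg.calibration_levels), max(cfg.calibration_levels)),
                r_squared=mm.r_squared,
                sensitivity=mm.slope,
                matrix_effect_pct=me_pct,
                recovery_pct=recovery,
                intraday_cv=intraday_by_level,
                interday_cv=interday_by_level,
                cc_alpha=cca,
                cc_beta=ccb,
                lod=lod,
                loq=loq,
            )
        )
    return ValidationOutcome(records=records, curves=curves_out, failures=failures)


def run_validate(
    config: SimulationConfig,
    outdir: Optional[Path] = None,
    r2_threshold: float = 0.99,
    cv_limit: float = PRECISION_CV_LIMIT,
) -> ValidationOutcome:
    """Simulate a campaign, analyze it, and optionally write the reports."""
    bundle = simulate_validation_campaign(config)
    outcome = analyze_campaign(bundle, r2_threshold, cv_limit)
    for failure in outcome.failures:
        log.warning("gate failure: %s", failure)
    if outdir is not None:
        from .io import write_curves, write_validation_records, write_validation_reports

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_validation_records(outcome.records, outdir / "records.json")
        write_curves(outcome.curves, outdir / "curves.csv")
        write_validation_reports(outcome.records, outdir)
    return outcome


def registry_from_targets(targets: Sequence[AnalyteTarget]) -> MRLRegistry:
    return MRLRegistry(
        per_analyte={
            t.name: MRLEntry(
                mrl=t.mrl if t.mrl is not None else float("inf"),
                group=t.group,
                sulfonamide=t.residue_class == "sulfonamide",
            )
            for t in targets
        }
    )


def run_screen(
    peaks: Sequence[PeakObservation],
    targets: Sequence[AnalyteTarget],
    curves: Mapping[str, Mapping[str, CalibrationCurve]],
    records: Sequence[ValidationRecord],
    registry: Optional[MRLRegistry] = None,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
    tissue_factor: float = 1.0,
) -> List[ComplianceDecision]:
    """Screen every sample of a peak table against the MRL framework.

    Per sample and target: pick the best-matching peak (smallest |ppm|,
    then |rt delta|), confirm identity (IP scoring), quantify against the
    matrix-matched curve applying the peak's dilution factor, and classify.
    """
    if registry is None:
        registry = registry_from_targets(targets)
    target_names = {t.name for t in targets}
    for p in peaks:
        if p.analyte_hint and p.analyte_hint not in target_names:
            raise ValueError(f"peak table names unknown analyte {p.analyte_hint!r}")
    by_record = {r.analyte: r for r in records}

    by_sample: Dict[str, List[PeakObservation]] = {}
    for p in peaks:
        by_sample.setdefault(p.sample_id, []).append(p)

    decisions: List[ComplianceDecision] = []
    for sample_id in sorted(by_sample):
        sample_peaks = by_sample[sample_id]
        concs: Dict[str, float] = {}
        identities = {}
        for t in targets:
            best = select_best_peak(t, sample_peaks, ppm_tol, rt_tol)
            if best is None:
                concs[t.name] = 0.0
                continue
            peak, _ = best
            identities[t.name] = confirm_identity(t, peak, ppm_tol, rt_tol)
            if t.name not in curves or CurveMode.MATRIX_MATCHED.value not in curves[t.name]:
                raise KeyError(f"analyte {t.name!r} lacks a matrix-matched calibration curve")
            curve = curves[t.name][CurveMode.MATRIX_MATCHED.value]
            concs[t.name] = quantify(
                peak.area, curve, peak.dilution_factor, tissue_factor
            ).concentration
        ccalphas = {}
        loqs = {}
        for t in targets:
            rec = by_record.get(t.name)
            if rec is None:
                raise KeyError(f"analyte {t.name!r} has no validation record")
            ccalphas[t.name] = rec.cc_alpha
            loqs[t.name] = rec.loq if rec.loq is not None else float("inf")
        decisions.append(
            screen_sample(sample_id, concs, identities, registry, ccalphas, loqs)
        )
    return decisions
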
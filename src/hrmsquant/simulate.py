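"""Synthetic LC-MS measurement generator.

Emits integrated peak tables, chromatograms and a full validation-campaign
bundle with the statistical structure of a matrix-matched residue assay.
The measurement model is multiplicative:

    area = intercept + slope * f_matrix * f_recovery * conc * (1 + eps)

where ``f_matrix = 1 + matrix_effect`` applies to fortified-extract and
matrix-matched preparations, ``f_recovery = recovery`` applies to
matrix-matched preparations only (losses during sample preparation), and
``1 + eps`` is lognormal multiplicative noise with mean 1 and coefficient
of variation ``noise_cv`` (truncated at -0.99).  Everything is
deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .calibration import CalibrationLevel, Chromatogram, CurveMode
from .identification import AnalyteTarget
from .io import read_targets
from .validation import CCALPHA_K

__all__ = [
    "AnalyteSimParams",
    "SimulationConfig",
    "GroundTruth",
    "CampaignBundle",
    "default_sim_params",
    "default_config",
    "noise_factors",
    "simulate_peak_table",
    "simulate_chromatogram",
    "simulate_validation_campaign",
]


@dataclass(frozen=True)
class AnalyteSimParams:
    """Ground-truth measurement parameters for one analyte."""

    name: str
    slope: float  # counts per ng/g
    recovery: float = 1.0  # fraction in (0, 1.5]
    matrix_effect: float = 0.0  # signed fraction; -0.2 = 20% suppression
    intercept: float = 0.0  # counts

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"{self.name}: slope must be positive")
        if not 0 < self.recovery <= 1.5:
            raise ValueError(f"{self.name}: recovery must lie in (0, 1.5]")
        if self.matrix_effect <= -1:
            raise ValueError(f"{self.name}: matrix effect must exceed -1")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    analytes: Tuple[AnalyteSimParams, ...]
    targets: Tuple[AnalyteTarget, ...]
    noise_cv: float = 0.10
    between_day_cv: float = 0.0
    mz_jitter_ppm: float = 2.0  # SD of the relative m/z error
    calibration_levels: Tuple[float, ...] = (5.0, 12.5, 25.0, 50.0, 75.0, 100.0, 125.0, 250.0)
    calibration_replicates: int = 2
    me_levels: Tuple[float, ...] = (12.5, 50.0, 100.0)
    spike_levels: Tuple[float, ...] = (10.0, 20.0, 40.0)
    replicates_per_day: int = 5
    days: int = 3
    n_fortified_mrl: int = 20
    loq_replicates: int = 10
    lod_levels: Tuple[float, ...] = (1.0, 2.5, 5.0)
    chrom_height_per_conc: float = 400.0  # counts per ng/g at the apex
    chrom_noise_sd: float = 100.0  # counts
    chrom_width_sd: float = 0.02  # minutes
    chrom_halfspan: float = 0.25  # minutes either side of the apex
    chrom_dt: float = 0.005  # minutes per grid point
    incurred_analyte: str = "sulfamethazine"
    incurred_conc: float = 1062.9  # ng/g, well above the curve maximum
    incurred_n: int = 10
    incurred_dilution: float = 10.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.noise_cv < 0 or self.between_day_cv < 0:
            raise ValueError("noise CVs must be non-negative")
        if self.n_fortified_mrl < 2:
            raise ValueError("need at least 2 fortified blanks")
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate analyte names in simulation config")
        target_names = {t.name for t in self.targets}
        missing = set(names) - target_names
        if missing:
            raise ValueError(f"analytes missing from target list: {sorted(missing)}")

    def params(self, name: str) -> AnalyteSimParams:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    def target(self, name: str) -> AnalyteTarget:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class GroundTruth:
    """True parameters and per-sample true concentrations of a simulation."""

    seed: int
    params: Dict[str, AnalyteSimParams]
    true_conc: Dict[Tuple[str, str], float] = field(default_factory=dict)  # (sample, analyte)


def default_sim_params() -> Tuple[AnalyteSimParams, ...]:
    """Per-analyte defaults (slope/recovery/matrix effect) shipped with the
    package, representative of a QuEChERS fish-tissue assay."""
    from importlib import resources

    path = resources.files("hrmsquant.data") / "sim_defaults.csv"
    df = pd.read_csv(path)
    return tuple(
        AnalyteSimParams(
            name=r["name"],
            slope=float(r["slope"]),
            recovery=float(r["recovery"]),
            matrix_effect=float(r["matrix_effect"]),
        )
        for r in df.to_dict("records")
    )


def default_config(seed: int, **overrides) -> SimulationConfig:
    """The stock 8-analyte campaign configuration."""
    overrides.setdefault("analytes", default_sim_params())
    overrides.setdefault("targets", tuple(read_targets()))
    return SimulationConfig(seed=seed, **overrides)


def noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and SD ``cv`` (lognormal).

    Factors are floored at 0.01, i.e. the additive form 1 + eps is truncated
    at eps = -0.99 so areas stay positive.
    """
    if cv < 0:
        raise ValueError("noise CV must be non-negative")
    if cv == 0:
        return np.ones(size)
    slog = math.sqrt(math.log1p(cv * cv))
    f = np.exp(rng.normal(-0.5 * slog * slog, slog, size))
    return np.maximum(f, 0.01)


def _mode_factor(params: AnalyteSimParams, mode: CurveMode) -> float:
    mode = CurveMode(mode)
    if mode is CurveMode.SOLVENT:
        return 1.0
    if mode is CurveMode.FORTIFIED_EXTRACT:
        return 1.0 + params.matrix_effect
    return (1.0 + params.matrix_effect) * params.recovery


def _areas(
    rng: np.random.Generator,
    params: AnalyteSimParams,
    concs: np.ndarray,
    mode: CurveMode,
    noise_cv: float,
) -> np.ndarray:
    concs = np.asarray(concs, dtype=float)
    clean = params.slope * _mode_factor(params, mode) * concs
    return params.intercept + clean * noise_factors(rng, noise_cv, concs.shape)


def simulate_peak_table(
    config: SimulationConfig,
    concentrations: Optional[Sequence[float]] = None,
    mode: CurveMode = CurveMode.MATRIX_MATCHED,
    sample_prefix: str = "sample",
    dilution_factor: float = 1.0,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Generate an integrated peak table for a batch of samples.

    Each sample carries every configured analyte at the same true tissue
    concentration (defaults to the calibration levels, one sample per
    level).  The observed m/z of precursor and fragments jitter around
    their theoretical values with SD ``mz_jitter_ppm``.  The peak area
    corresponds to the injected extract, i.e. the true concentration
    divided by ``dilution_factor``.
    """
    rng = np.random.default_rng(config.seed)
    if concentrations is None:
        concentrations = config.calibration_levels
    truth = GroundTruth(seed=config.seed, params={a.name: a for a in config.analytes})
    rows: List[dict] = []
    for i, conc in enumerate(concentrations):
        if conc < 0:
            raise ValueError("concentrations must be non-negative")
        sample_id = f"{sample_prefix}-{i:03d}"
        for a in config.analytes:
            target = config.target(a.name)
            area = float(
                _areas(rng, a, np.array([conc / dilution_factor]), mode, config.noise_cv)[0]
            )
            jitter = rng.normal(0.0, config.mz_jitter_ppm * 1e-6)
            mz_obs = target.precursor_mz * (1.0 + jitter)
            frag_obs = [
                f * (1.0 + rng.normal(0.0, config.mz_jitter_ppm * 1e-6))
                for f in target.fragment_mz
            ]
            rt_obs = target.rt_expected + rng.normal(0.0, 0.005)
            rows.append(
                {
                    "sample_id": sample_id,
                    "analyte_hint": a.name,
                    "mz": mz_obs,
                    "rt": rt_obs,
                    "area": area,
                    "height": 0.1 * area,
                    "fragments": ";".join(f"{f:.6f}" for f in frag_obs),
                    "dilution_factor": dilution_factor,
                }
            )
            truth.true_conc[(sample_id, a.name)] = float(conc)
    return pd.DataFrame(rows), truth


def simulate_chromatogram(
    rt: float,
    height: float,
    width_sd: float,
    noise_sd: float,
    grid: Sequence[float],
    seed: Union[int, np.random.Generator],
) -> Chromatogram:
    """A Gaussian peak on a uniform time grid plus white noise."""
    if not width_sd > 0:
        raise ValueError("peak width must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(grid, dtype=float)
    if t[0] > rt - 5 * width_sd or t[-1] < rt + 5 * width_sd:
        raise ValueError("grid must cover rt +/- 5 peak widths")
    n_across = int(np.sum(np.abs(t - rt) <= 3 * width_sd))
    if n_across < 10:
        raise ValueError(f"grid too coarse: only {n_across} points across the peak")
    y = height * np.exp(-0.5 * ((t - rt) / width_sd) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, t.shape)
    return Chromatogram(times=tuple(t.tolist()), intensities=tuple(y.tolist()))


@dataclass
class CampaignBundle:
    """Everything a full method validation consumes, from one seed.

    Areas are raw instrument responses; quantification against the fitted
    curves is the analysis step, not the simulation step.
    """

    config: SimulationConfig
    truth: GroundTruth
    # mode -> analyte -> list of CalibrationLevel (replicate areas per level)
    curve_levels: Dict[str, Dict[str, List[CalibrationLevel]]]
    # analyte -> array (days, n_spike_levels, replicates) of areas
    spike_areas: Dict[str, np.ndarray]
    # analyte -> n_fortified_mrl areas of blanks fortified at the MRL
    mrl_fortified_areas: Dict[str, np.ndarray]
    # analyte -> areas of blanks fortified at the (true) decision limit
    ccalpha_fortified_areas: Dict[str, np.ndarray]
    ccalpha_fortified_level: Dict[str, float]
    # analyte -> nominal -> loq_replicates areas (matrix matched)
    loq_areas: Dict[str, Dict[float, np.ndarray]]
    # analyte -> nominal -> chromatogram for S/N-based LOD
    lod_chromatograms: Dict[str, Dict[float, Chromatogram]]
    # high-concentration samples quantified via dilution
    incurred_areas: np.ndarray
    incurred_analyte: str
    incurred_dilution: float

    def chrom_windows(self, analyte: str) -> Tuple[Tuple[float, float], Tuple[float, float]]:
        """(peak_window, noise_window) for this analyte's LOD chromatograms."""
        cfg = self.config
        rt = cfg.target(analyte).rt_expected
        w = cfg.chrom_width_sd
        peak = (rt - 3 * w, rt + 3 * w)
        noise = (rt + 6 * w, rt + cfg.chrom_halfspan)
        return peak, noise


def simulate_validation_campaign(config: SimulationConfig) -> CampaignBundle:
    """Generate the full validation input bundle for every analyte.

    Includes calibration in all three preparation modes, the spike design
    (levels x days x replicates), fortified blanks at the MRL and at the
    true decision limit, replicate sets at every curve level for the LOQ
    rule, low-level chromatograms for the S/N LOD rule, and incurred-like
    high-concentration samples measured after dilution.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(seed=config.seed, params={a.name: a for a in config.analytes})
    levels = np.asarray(config.calibration_levels, dtype=float)

    curve_levels: Dict[str, Dict[str, List[CalibrationLevel]]] = {
        m.value: {} for m in CurveMode
    }
    spike_areas: Dict[str, np.ndarray] = {}
    mrl_areas: Dict[str, np.ndarray] = {}
    cca_areas: Dict[str, np.ndarray] = {}
    cca_level: Dict[str, float] = {}
    loq_areas: Dict[str, Dict[float, np.ndarray]] = {}
    lod_chroms: Dict[str, Dict[float, Chromatogram]] = {}

    for a in config.analytes:
        mrl = config.target(a.name).mrl
        if mrl is None:
            raise ValueError(f"{a.name}: an MRL is required to fortify blanks")
        for mode in CurveMode:
            per_level = []
            for lv in levels:
                areas = _areas(
                    rng,
                    a,
                    np.full(config.calibration_replicates, lv),
                    mode,
                    config.noise_cv,
                )
                per_level.append(CalibrationLevel(float(lv), tuple(areas.tolist())))
            curve_levels[mode.value][a.name] = per_level

        day_factors = 1.0 + np.zeros(config.days)
        if config.between_day_cv > 0:
            day_factors = noise_factors(rng, config.between_day_cv, config.days)
        spikes = np.empty((config.days, len(config.spike_levels), config.replicates_per_day))
        for d in range(config.days):
            for j, lv in enumerate(config.spike_levels):
                spikes[d, j, :] = day_factors[d] * _areas(
                    rng,
                    a,
                    np.full(config.replicates_per_day, lv),
                    CurveMode.MATRIX_MATCHED,
                    config.noise_cv,
                )
        spike_areas[a.name] = spikes

        mrl_areas[a.name] = _areas(
            rng,
            a,
            np.full(config.n_fortified_mrl, mrl),
            CurveMode.MATRIX_MATCHED,
            config.noise_cv,
        )
        # Blanks for the detection-capability step are fortified at the true
        # decision limit implied by the configured noise level.
        cca_true = mrl * (1.0 + CCALPHA_K * config.noise_cv)
        cca_level[a.name] = cca_true
        cca_areas[a.name] = _areas(
            rng,
            a,
            np.full(config.n_fortified_mrl, cca_true),
            CurveMode.MATRIX_MATCHED,
            config.noise_cv,
        )

        loq_areas[a.name] = {
            float(lv): _areas(
                rng,
                a,
                np.full(config.loq_replicates, lv),
                CurveMode.MATRIX_MATCHED,
                config.noise_cv,
            )
            for lv in levels
        }

        rt = config.target(a.name).rt_expected
        grid = np.arange(
            rt - config.chrom_halfspan, rt + config.chrom_halfspan, config.chrom_dt
        )
        lod_chroms[a.name] = {
            float(lv): simulate_chromatogram(
                rt=rt,
                height=config.chrom_height_per_conc * float(lv),
                width_sd=config.chrom_width_sd,
                noise_sd=config.chrom_noise_sd,
                grid=grid,
                seed=rng,
            )
            for lv in config.lod_levels
        }

    inc = config.params(config.incurred_analyte)
    incurred = _areas(
        rng,
        inc,
        np.full(config.incurred_n, config.incurred_conc / config.incurred_dilution),
        CurveMode.MATRIX_MATCHED,
        config.noise_cv,
    )
    for i in range(config.incurred_n):
        truth.true_conc[(f"incurred-{i:03d}", inc.name)] = config.incurred_conc

    return CampaignBundle(
        config=config,
        truth=truth,
        curve_levels=curve_levels,
        spike_areas=spike_areas,
        mrl_fortified_areas=mrl_areas,
        ccalpha_fortified_areas=cca_areas,
        ccalpha_fortified_level=cca_level,
        loq_areas=loq_areas,
        lod_chromatograms=lod_chroms,
        incurred_areas=incurred,
        incurred_analyte=inc.name,
        incurred_dilution=config.incurred_dilution,
    )
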
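"""File ingestion and serialization (delimited text throughout).

All files are comma-separated UTF-8 with dot decimals; a ``decimal_comma``
option normalizes European-style numbers on ingest.  The package ships a
default target list (8 analytes) used when no path is given.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .calibration import CalibrationCurve, CalibrationLevel, CurveMode
from .identification import AnalyteTarget, Group, PeakObservation
from .validation import ValidationRecord

__all__ = [
    "read_targets",
    "write_targets",
    "read_peaks",
    "write_peaks",
    "read_curves",
    "write_curves",
    "read_validation_records",
    "write_validation_records",
    "write_validation_reports",
]

PathLike = Union[str, Path]


def _default_targets_path():
    return resources.files("hrmsquant.data") / "targets.csv"


def _tofloat(value, decimal_comma: bool = False) -> float:
    if isinstance(value, str):
        s = value.strip()
        if decimal_comma and "," in s and "." not in s:
            s = s.replace(",", ".")
        return float(s)
    return float(value)


def _parse_mz_list(cell) -> tuple:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return ()
    return tuple(float(x) for x in str(cell).split(";") if x.strip())


def read_targets(
    path: Optional[PathLike] = None, decimal_comma: bool = False
) -> List[AnalyteTarget]:
    """Load an analyte target list; the bundled default when ``path`` is None.

    Expected columns: name, formula, rt_min, fragment_mz (semicolon list),
    group, mrl_ng_g and optionally residue_class.  Theoretical precursor m/z
    is computed from the formula on load.  Underscore subscript markup in
    formulas (``C_14_H_18_...``) is tolerated.
    """
    src = _default_targets_path() if path is None else Path(path)
    df = pd.read_csv(src, dtype=str)
    required = {"name", "formula", "rt_min", "fragment_mz", "group", "mrl_ng_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"target list missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"target list contains no records: {src}")
    targets: List[AnalyteTarget] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            name = str(row["name"]).strip()
            cls = str(row.get("residue_class", "") or "").strip()
            if not cls or cls == "nan":
                cls = "sulfonamide" if name.lower().startswith("sulfa") else "other"
            targets.append(
                AnalyteTarget.from_formula(
                    name=name,
                    formula=str(row["formula"]).replace("_", "").strip(),
                    rt_expected=_tofloat(row["rt_min"], decimal_comma),
                    fragment_mz=_parse_mz_list(row["fragment_mz"]),
                    group=Group(str(row["group"]).strip()),
                    mrl=_tofloat(row["mrl_ng_g"], decimal_comma),
                    residue_class=cls,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{src}, line {line}: {exc}") from exc
    return targets


def write_targets(targets: Sequence[AnalyteTarget], path: PathLike) -> None:
    from .chem_mass import format_formula

    rows = [
        {
            "name": t.name,
            "formula": format_formula(t.formula),
            "rt_min": t.rt_expected,
            "fragment_mz": ";".join(f"{f:.4f}" for f in t.fragment_mz),
            "group": t.group.value,
            "mrl_ng_g": t.mrl,
            "residue_class": t.residue_class,
        }
        for t in targets
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_peaks(path: PathLike, decimal_comma: bool = False) -> List[PeakObservation]:
    """Load a peak table (sample_id, analyte_hint, mz, rt, area, height,
    fragments[, dilution_factor])."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "analyte_hint", "mz", "rt", "area", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    peaks: List[PeakObservation] = []
    for _, row in df.iterrows():
        peaks.append(
            PeakObservation(
                sample_id=str(row["sample_id"]),
                analyte_hint=str(row["analyte_hint"]),
                mz_observed=_tofloat(row["mz"], decimal_comma),
                rt_observed=_tofloat(row["rt"], decimal_comma),
                area=_tofloat(row["area"], decimal_comma),
                height=_tofloat(row["height"], decimal_comma),
                fragments_observed=_parse_mz_list(row.get("fragments")),
                dilution_factor=(
                    _tofloat(row["dilution_factor"], decimal_comma)
                    if "dilution_factor" in df.columns and not pd.isna(row["dilution_factor"])
                    else 1.0
                ),
            )
        )
    return peaks


def write_peaks(peaks: Sequence[PeakObservation], path: PathLike) -> None:
    rows = [
        {
            "sample_id": p.sample_id,
            "analyte_hint": p.analyte_hint,
            "mz": repr(p.mz_observed),
            "rt": repr(p.rt_observed),
            "area": repr(p.area),
            "height": repr(p.height),
            "fragments": ";".join(repr(f) for f in p.fragments_observed),
            "dilution_factor": repr(p.dilution_factor),
        }
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _levels_to_str(levels: Sequence[CalibrationLevel]) -> str:
    return ";".join(
        f"{lv.nominal}:" + "|".join(repr(a) for a in lv.areas) for lv in levels
    )


def _levels_from_str(s: str) -> tuple:
    if not s or str(s) == "nan":
        return ()
    out = []
    for part in str(s).split(";"):
        nom, areas = part.split(":")
        out.append(CalibrationLevel(float(nom), tuple(float(a) for a in areas.split("|"))))
    return tuple(out)


def write_curves(curves: Dict[str, Dict[str, CalibrationCurve]], path: PathLike) -> None:
    """Persist curves as rows (analyte, mode, slope, intercept, r2, levels)."""
    rows = []
    for analyte, by_mode in curves.items():
        for mode, c in by_mode.items():
            rows.append(
                {
                    "analyte": analyte,
                    "mode": CurveMode(mode).value,
                    "slope": repr(c.slope),
                    "intercept": repr(c.intercept),
                    "r2": repr(c.r_squared),
                    "levels": _levels_to_str(c.levels),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves(path: PathLike) -> Dict[str, Dict[str, CalibrationCurve]]:
    df = pd.read_csv(path, dtype=str)
    curves: Dict[str, Dict[str, CalibrationCurve]] = {}
    for _, row in df.iterrows():
        curve = CalibrationCurve(
            mode=CurveMode(row["mode"]),
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r_squared=float(row["r2"]),
            levels=_levels_from_str(row.get("levels", "")),
        )
        curves.setdefault(str(row["analyte"]), {})[curve.mode.value] = curve
    return curves


def write_validation_records(records: Sequence[ValidationRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in records], fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_validation_records(path: PathLike) -> List[ValidationRecord]:
    with open(path, encoding="utf-8") as fh:
        return [ValidationRecord.from_dict(d) for d in json.load(fh)]


def write_validation_reports(records: Sequence[ValidationRecord], outdir: PathLike) -> None:
    """Write the three report tables: method parameters, precision grids,
    and decision limits."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = [r.analyte for r in records]

    params = {"parameter": []}
    for n in names:
        params[n] = []

    def add_row(label, values):
        params["parameter"].append(label)
        for n, v in zip(names, values):
            params[n].append(v)

    add_row(
        "working_range_ng_g",
        [f"{r.working_range[0]:g}-{r.working_range[1]:g}" for r in records],
    )
    add_row("linearity_r2", [round(r.r_squared, 4) for r in records])
    add_row("sensitivity", [round(r.sensitivity, 2) for r in records])
    me_levels = sorted({lv for r in records for lv in r.matrix_effect_pct})
    for lv in me_levels:
        add_row(
            f"matrix_effect_pct_{lv:g}",
            [round(r.matrix_effect_pct.get(lv, float("nan")), 2) for r in records],
        )
    rec_levels = sorted({lv for r in records for lv in r.recovery_pct})
    for lv in rec_levels:
        add_row(
            f"recovery_pct_{lv:g}",
            [
                "{:.1f} ({:.1f})".format(*r.recovery_pct[lv])
                if lv in r.recovery_pct
                else ""
                for r in records
            ],
        )
    add_row("lod_ng_g", [r.lod for r in records])
    add_row("loq_ng_g", [r.loq for r in records])
    pd.DataFrame(params).to_csv(outdir / "method_parameters.csv", index=False)

    prec = {"parameter": []}
    for n in names:
        prec[n] = []
    intra_levels = sorted({lv for r in records for lv in r.intraday_cv})
    for lv in intra_levels:
        prec["parameter"].append(f"intraday_cv_pct_{lv:g}")
        for r in records:
            prec[r.analyte].append(round(r.intraday_cv.get(lv, float("nan")), 1))
    inter_levels = sorted({lv for r in records for lv in r.interday_cv})
    for lv in inter_levels:
        prec["parameter"].append(f"interday_cv_pct_{lv:g}")
        for r in records:
            prec[r.analyte].append(round(r.interday_cv.get(lv, float("nan")), 1))
    pd.DataFrame(prec).to_csv(outdir / "precision.csv", index=False)

    limits = {
        "parameter": ["cc_alpha_ng_g", "cc_beta_ng_g"],
    }
    for r in records:
        limits[r.analyte] = [round(r.cc_alpha, 1), round(r.cc_beta, 1)]
    pd.DataFrame(limits).to_csv(outdir / "decision_limits.csv", index=False)
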
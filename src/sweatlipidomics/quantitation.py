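"""Matrix-matched class calibration, isotopic type-I correction and
concentration estimation.

One isotopically labeled standard represents each lipid class.  A 6-point
calibration curve (standard serially diluted in the pooled QC matrix) is
fitted by ordinary least squares; analyte areas are back-calculated through
the class curve and multiplied by an isotopic correction factor that
adjusts for the differing monoisotopic fractions of analyte and standard:

    factor = (1 - p13)^(nC_standard - nC_analyte)

with p13 the natural ¹³C abundance and nC the molecular carbon counts.
Only the monoisotopic (type-I) effect is corrected; isotopologue overlap
(type II) does not occur with chromatographically resolved species and is
deliberately not modeled.  Back-calculated values outside the calibration
range are masked as missing and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library import elemental_formula, parse_label
from .peaktable import STANDARD_PREFIX, PeakTable

__all__ = [
    "CalibrationCurve",
    "IsotopeParams",
    "fit_calibration",
    "isotope_correction_factor",
    "curves_from_table",
    "quantify",
    "class_composition",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IsotopeParams:
    """¹³C natural abundance used in the type-I correction."""

    p13: float = 0.0107

    def __post_init__(self) -> None:
        if not 0 < self.p13 < 1:
            raise ValueError("p13 must be in (0, 1)")


@dataclass
class CalibrationCurve:
    standard_label: str
    class_code: str
    standard_carbons: int           # molecular carbon count of the standard
    concentrations: np.ndarray      # mol/L, one per level
    areas: np.ndarray
    slope: float
    intercept: float
    r2: float

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(np.min(self.concentrations)), float(np.max(self.concentrations))


def fit_calibration(concentrations, areas, standard_label: str = "",
                    class_code: str = "", standard_carbons: int = 0,
                    weighting: str = "none") -> CalibrationCurve:
    """Least-squares line ``area = slope·conc + intercept``.

    ``weighting`` is ``none`` (ordinary least squares), ``1/x`` or ``1/x2``.
    Signal noise in LC-MS is close to multiplicative, so over a calibration
    series spanning orders of magnitude the unweighted intercept is driven
    by the top levels and can rival the low-level areas themselves;
    ``1/x2`` weighting equalizes the relative residuals and is the usual
    choice for wide-range bioanalytical curves.
    """
    conc = np.asarray(concentrations, dtype=float)
    area = np.asarray(areas, dtype=float)
    ok = ~(np.isnan(conc) | np.isnan(area))
    conc, area = conc[ok], area[ok]
    if len(np.unique(conc)) < 2:
        raise ValueError("calibration needs >=2 distinct concentration levels")
    if weighting == "none":
        fit = stats.linregress(conc, area)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue ** 2)
    elif weighting in ("1/x", "1/x2"):
        w = 1.0 / conc if weighting == "1/x" else 1.0 / conc ** 2
        W = np.diag(w)
        X = np.column_stack([conc, np.ones_like(conc)])
        beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * area, rcond=None)
        slope, intercept = float(beta[0]), float(beta[1])
        fitted = slope * conc + intercept
        sst = float(np.sum(w * (area - np.average(area, weights=w)) ** 2))
        ssr = float(np.sum(w * (area - fitted) ** 2))
        r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return CalibrationCurve(
        standard_label=standard_label,
        class_code=class_code,
        standard_carbons=standard_carbons,
        concentrations=conc,
        areas=area,
        slope=slope,
        intercept=intercept,
        r2=r2,
    )


def isotope_correction_factor(nc_analyte: int, nc_standard: int,
                              params: IsotopeParams = IsotopeParams()) -> float:
    """Type-I isotopic correction: ratio of monoisotopic fractions.

    The monoisotopic peak of a molecule with n carbons carries a fraction
    (1-p13)^n of the total signal, so an analyte with more carbons than the
    class standard is under-read; multiplying the area ratio by
    ``(1-p13)^(nC_standard-nC_analyte)`` removes the bias.
    """
    if nc_analyte < 0 or nc_standard < 0:
        raise ValueError("carbon counts must be non-negative")
    return float((1.0 - params.p13) ** (nc_standard - nc_analyte))


def curves_from_table(table: PeakTable, cal_concs: pd.DataFrame,
                      weighting: str = "1/x2") -> dict[str, CalibrationCurve]:
    """Fit per-class curves from a table's calibration injections.

    ``cal_concs``: levels × class codes, mol/L (level index must match the
    manifest's ``cal_level``).  Standard channels are the ``STD``-prefixed
    columns; the standard's molecular carbon count comes from its shorthand.
    """
    cal_ids = table.cal_ids
    if len(cal_ids) == 0:
        raise ValueError("table has no calibration injections")
    levels = table.manifest.loc[cal_ids, "cal_level"].astype(int)
    curves: dict[str, CalibrationCurve] = {}
    for col in table.standard_labels():
        shorthand = col[len(STANDARD_PREFIX):]
        species = parse_label(shorthand)
        cls = species.class_code
        if cls not in cal_concs.columns:
            logger.warning("no calibration concentrations for class %s; skipped", cls)
            continue
        conc = cal_concs.loc[levels, cls].to_numpy(dtype=float)
        area = table.areas.loc[cal_ids, col].to_numpy(dtype=float)
        curves[cls] = fit_calibration(
            conc, area, standard_label=shorthand, class_code=cls,
            standard_carbons=elemental_formula(species).get("C", 0),
            weighting=weighting,
        )
    return curves


def quantify(table_or_areas, curves: dict[str, CalibrationCurve],
             params: IsotopeParams = IsotopeParams()
             ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Back-calculate concentrations (mol/L) through the class curves.

    Accepts a :class:`PeakTable` (study rows are quantified) or a plain
    areas DataFrame.  Returns ``(concentrations, out_of_range_mask,
    report)``; back-calculated values outside a curve's concentration range
    are masked as missing.  Analytes of classes without a curve are skipped.
    """
    if isinstance(table_or_areas, PeakTable):
        areas = table_or_areas.study_areas[table_or_areas.analyte_labels()]
    else:
        areas = table_or_areas
    conc = pd.DataFrame(np.nan, index=areas.index, columns=areas.columns)
    mask = pd.DataFrame(False, index=areas.index, columns=areas.columns)
    skipped: list[str] = []
    n_masked = 0
    for analyte in areas.columns:
        cls = parse_label(analyte).class_code
        curve = curves.get(cls)
        if curve is None:
            skipped.append(analyte)
            logger.warning("no calibration curve for class %s; %s skipped",
                           cls, analyte)
            continue
        nc = elemental_formula(parse_label(analyte)).get("C", 0)
        icf = isotope_correction_factor(nc, curve.standard_carbons, params)
        back = (areas[analyte] - curve.intercept) / curve.slope
        lo, hi = curve.valid_range
        out = (back < lo) | (back > hi)
        ok = back.notna() & ~out
        conc.loc[ok, analyte] = back[ok] * icf
        mask[analyte] = out.fillna(False)
        n_masked += int(mask[analyte].sum())
    report = {
        "skipped_analytes": skipped,
        "n_out_of_range": n_masked,
        "n_quantified": int(conc.notna().sum().sum()),
    }
    return conc, mask, report


def class_composition(concentrations: pd.DataFrame) -> pd.DataFrame:
    """Per-class summed concentration, percent of total and lipid counts.

    Sums run over non-missing cells; percentages are of the grand total and
    sum to 100.
    """
    if concentrations.notna().sum().sum() == 0:
        raise ValueError("no quantified lipids")
    classes = pd.Series({c: parse_label(c).class_code
                         for c in concentrations.columns})
    per_lipid_total = concentrations.sum(axis=0, skipna=True)
    sums = per_lipid_total.groupby(classes).sum()
    counts = (concentrations.notna().any(axis=0)).groupby(classes).sum()
    total = sums.sum()
    out = pd.DataFrame({
        "summed_concentration": sums,
        "percent_of_total": sums / total * 100.0,
        "n_lipids": counts.astype(int),
    })
    return out.sort_values("summed_concentration", ascending=False)
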
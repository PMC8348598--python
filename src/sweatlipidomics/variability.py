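"""Coefficient-of-variation statistics and injection-volume linearity.

Three CVs summarize each lipid: CVqc across the pooled-QC injections
(analytical repeatability), CVg across all 60 study samples (group
variability) and CVi, the mean across individuals of the CV over each
individual's six samples (intra-individual variability).  Comparing the
``ln`` and ``lnPQN`` conditions — raw versus PQN-scaled intensities — shows
how much apparent variability is pure dilution.  CVs are always computed on
the linear scale; the condition only decides whether intensities are
PQN-scaled first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library import parse_label
from .normalization import pqn
from .peaktable import PeakTable

__all__ = ["VariabilityReport", "cv", "variability_report", "linearity_check"]

logger = logging.getLogger(__name__)

CONDITIONS = ("ln", "lnPQN")


def cv(values) -> float:
    """Coefficient of variation in percent: sample sd / mean × 100.

    Returns NaN for fewer than 2 non-missing values or non-positive mean.
    """
    v = pd.Series(values, dtype=float).dropna()
    if len(v) < 2:
        return float("nan")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(v.std(ddof=1) / m * 100.0)


@dataclass
class VariabilityReport:
    """Per-lipid CVi/CVg/CVqc (percent) and per-class summaries."""

    per_lipid: pd.DataFrame      # columns: class, CVi, CVg, CVqc
    per_class: pd.DataFrame      # median/q1/q3 of each CV per class
    condition: str

    def medians(self) -> dict[str, float]:
        return {
            "CVi": float(self.per_lipid["CVi"].median()),
            "CVg": float(self.per_lipid["CVg"].median()),
            "CVqc": float(self.per_lipid["CVqc"].median()),
        }


def _cv_frame(df: pd.DataFrame) -> pd.Series:
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    counts = df.notna().sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (sd / mean * 100.0).where((mean > 0) & (counts >= 2))
    return out


def variability_report(table: PeakTable, condition: str = "lnPQN"
                       ) -> VariabilityReport:
    """CVi/CVg/CVqc per lipid for one transformation condition.

    ``lnPQN`` divides every sample (QCs by their own quotients, against the
    study-sample reference) by its PQN quotient before computing CVs;
    ``ln`` uses the areas as-is.  Individuals with fewer than two samples
    are excluded from CVi with a warning.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    study = table.study_areas
    qc = table.qc_areas
    if condition == "lnPQN":
        res_study = pqn(study)
        study = res_study.matrix
        if len(qc.index) >= 2:
            qc = pqn(qc, reference=res_study.reference).matrix
        elif len(qc.index) == 1:
            ratios = qc.div(res_study.reference, axis=1)
            qc = qc.div(ratios.median(axis=1), axis=0)

    cvqc = _cv_frame(qc) if len(qc.index) else pd.Series(np.nan, index=study.columns)
    cvg = _cv_frame(study)

    individuals = table.manifest.loc[table.study_ids, "individual"]
    per_ind = []
    for ind, ids in individuals.groupby(individuals).groups.items():
        if len(ids) < 2:
            warnings.warn(f"individual {ind} has <2 samples; excluded from CVi",
                          stacklevel=2)
            continue
        per_ind.append(_cv_frame(study.loc[ids]))
    cvi = (pd.concat(per_ind, axis=1).mean(axis=1) if per_ind
           else pd.Series(np.nan, index=study.columns))

    classes = pd.Series({l: parse_label(l).class_code for l in study.columns})
    per_lipid = pd.DataFrame({
        "class": classes, "CVi": cvi, "CVg": cvg, "CVqc": cvqc,
    })
    grouped = per_lipid.groupby("class")[["CVi", "CVg", "CVqc"]]
    per_class = pd.concat(
        {
            "median": grouped.median(),
            "q1": grouped.quantile(0.25),
            "q3": grouped.quantile(0.75),
        },
        axis=1,
    )
    return VariabilityReport(per_lipid=per_lipid, per_class=per_class,
                             condition=condition)


def linearity_check(areas_by_volume: pd.DataFrame, r2_threshold: float = 0.95
                    ) -> pd.DataFrame:
    """Injection-volume linearity per lipid.

    ``areas_by_volume``: rows indexed by injected volume (µL), columns =
    lipids.  Ordinary least squares of area against volume gives R² per
    lipid; the pass flag requires R² above ``r2_threshold``.  Constant
    response leaves R² undefined and fails.
    """
    volumes = np.asarray(areas_by_volume.index, dtype=float)
    if len(np.unique(volumes)) < 3:
        raise ValueError("linearity check needs at least 3 distinct volumes")
    rows = {}
    for lipid in areas_by_volume.columns:
        y = areas_by_volume[lipid].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 3 or np.ptp(y[ok]) == 0:
            rows[lipid] = {"slope": np.nan, "r2": np.nan, "passed": False}
            continue
        fit = stats.linregress(volumes[ok], y[ok])
        r2 = fit.rvalue ** 2
        rows[lipid] = {"slope": fit.slope, "r2": r2,
                       "passed": bool(r2 > r2_threshold)}
    out = pd.DataFrame(rows).T
    out["passed"] = out["passed"].astype(bool)
    return out
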
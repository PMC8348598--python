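"""Blank subtraction, QC-anchored LOESS drift correction and QC-CV filtering.

These are the three preprocessing stages applied, in this order, before any
transformation or statistics:

1. the mean process-blank area of each analyte is subtracted from every
   non-blank injection; analytes whose blank level exceeds the sample in
   more than five *study* samples are discarded, remaining deficit cells
   are imputed with half the analyte's minimum positive post-subtraction
   value;
2. per analyte, a locally-weighted regression of QC area against injection
   order estimates the instrument drift curve and every injection is divided
   by the drift factor (normalized to the QC median);
3. analytes whose QC coefficient of variation exceeds 30 % are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .peaktable import PeakTable

__all__ = [
    "BlankReport",
    "LoessReport",
    "CvFilterReport",
    "NoBlankError",
    "subtract_blank",
    "loess_correct",
    "qc_cv_filter",
]

logger = logging.getLogger(__name__)


class NoBlankError(ValueError):
    """No process blanks in the table; skip the stage explicitly instead."""


@dataclass
class BlankReport:
    blank_level: pd.Series
    dropped_analytes: list[str] = field(default_factory=list)
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)  # (injection, analyte)

    def to_dict(self) -> dict:
        return {
            "dropped_analytes": self.dropped_analytes,
            "imputed_cells": [list(c) for c in self.imputed_cells],
            "blank_level": {k: float(v) for k, v in self.blank_level.items()},
        }


@dataclass
class LoessReport:
    span: float
    skipped_analytes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"span": self.span, "skipped_analytes": self.skipped_analytes}


@dataclass
class CvFilterReport:
    threshold: float
    qc_cv: pd.Series = field(default_factory=pd.Series)
    excluded_analytes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "excluded_analytes": self.excluded_analytes,
            "qc_cv": {k: (None if pd.isna(v) else float(v)) for k, v in self.qc_cv.items()},
        }


def subtract_blank(table: PeakTable, max_deficit_samples: int = 5
                   ) -> tuple[PeakTable, BlankReport]:
    """Subtract the mean process-blank area per analyte.

    Cells whose area does not exceed the blank level become deficit
    candidates.  An analyte with deficit candidates in more than
    ``max_deficit_samples`` study samples is discarded outright; otherwise
    its candidate cells (in any non-blank injection) are set to half the
    minimum positive post-subtraction value of that analyte.  Blank
    injections themselves are passed through unchanged.
    """
    blank_ids = table.blank_ids
    if len(blank_ids) == 0:
        raise NoBlankError(
            "table has no blank injections; omit the blank-subtraction stage "
            "explicitly if none were acquired"
        )
    areas = table.areas.copy()
    blank_level = areas.loc[blank_ids].mean(axis=0).fillna(0.0)
    nonblank = areas.index.difference(blank_ids, sort=False)
    study_ids = table.study_ids

    report = BlankReport(blank_level=blank_level)
    keep: list[str] = []
    for analyte in areas.columns:
        b = blank_level[analyte]
        col = areas[analyte]
        if b <= 0:
            keep.append(analyte)
            continue
        deficit = col.loc[nonblank].notna() & (col.loc[nonblank] <= b)
        n_study_deficit = int(deficit.loc[deficit.index.intersection(study_ids)].sum())
        if n_study_deficit > max_deficit_samples:
            report.dropped_analytes.append(analyte)
            continue
        sub = col.loc[nonblank] - b
        positive = sub[sub > 0]
        if positive.empty:
            report.dropped_analytes.append(analyte)
            logger.warning("analyte %s has no positive area after blank "
                           "subtraction; dropped", analyte)
            continue
        half_min = 0.5 * positive.min()
        sub[deficit] = half_min
        areas.loc[nonblank, analyte] = sub
        report.imputed_cells.extend((i, analyte) for i in deficit.index[deficit])
        keep.append(analyte)
    areas = areas[keep]
    return PeakTable(areas=areas, manifest=table.manifest.copy()), report


def loess_correct(table: PeakTable, span: float = 0.75, min_qc: int = 4,
                  factor_bounds: tuple[float, float] = (0.1, 10.0)
                  ) -> tuple[PeakTable, LoessReport]:
    """Divide every injection by the QC-anchored LOESS drift factor.

    Per analyte, QC area is regressed on injection order with a
    locally-weighted linear smoother (``span`` = fraction of QCs in each
    local window); the fitted curve, interpolated to every injection order
    and normalized to the QC median, is the multiplicative drift factor.
    Factors are clipped to ``factor_bounds``.  Analytes with fewer than
    ``min_qc`` non-missing QC areas pass through uncorrected.
    """
    qc_ids = table.qc_ids
    orders = table.manifest["order"].astype(float)
    qc_orders = orders.loc[qc_ids]
    areas = table.areas.copy()
    report = LoessReport(span=span)
    for analyte in areas.columns:
        qc_y = areas.loc[qc_ids, analyte]
        ok = qc_y.notna()
        if int(ok.sum()) < min_qc:
            report.skipped_analytes.append(analyte)
            logger.warning("analyte %s: only %d usable QCs (<%d); left "
                           "uncorrected", analyte, int(ok.sum()), min_qc)
            continue
        x = qc_orders[ok].to_numpy()
        y = qc_y[ok].to_numpy(dtype=float)
        fitted = lowess(y, x, frac=span, it=0, return_sorted=True)
        ref = float(np.median(y))
        if ref <= 0:
            report.skipped_analytes.append(analyte)
            logger.warning("analyte %s: non-positive QC median; left "
                           "uncorrected", analyte)
            continue
        interp = np.interp(orders.to_numpy(), fitted[:, 0], fitted[:, 1])
        factor = np.clip(interp / ref, *factor_bounds)
        areas[analyte] = areas[analyte] / pd.Series(factor, index=areas.index)
    return PeakTable(areas=areas, manifest=table.manifest.copy()), report


def qc_cv_filter(table: PeakTable, threshold: float = 30.0
                 ) -> tuple[PeakTable, CvFilterReport]:
    """Exclude analytes whose QC coefficient of variation exceeds ``threshold`` %."""
    qc = table.qc_areas
    if len(qc.index) < 2:
        raise ValueError("QC-CV filtering needs at least 2 QC injections")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sd / mean * 100.0).where(mean > 0)
    excluded = cv.index[(cv > threshold) | cv.isna()].tolist()
    keep = [c for c in table.areas.columns if c not in excluded]
    report = CvFilterReport(threshold=threshold, qc_cv=cv,
                            excluded_analytes=excluded)
    out = PeakTable(areas=table.areas[keep].copy(), manifest=table.manifest.copy())
    return out, report
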
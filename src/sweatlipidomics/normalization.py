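"""Probabilistic quotient normalization and the ln / lnPQN transforms.

Apocrine sweat cannot be collected at a standardized volume, so every
sample carries an unknown multiplicative dilution factor shared by all its
lipids.  Probabilistic quotient normalization (PQN) estimates that factor
as the median, across analytes, of the ratios between a sample's spectrum
and a reference spectrum (the median spectrum of the study samples), and
divides the sample by it.  ``lnPQN`` denotes PQN followed by the natural
log; the plain ``ln`` transform is the comparison condition.

PQN is applied before the log transform — the quotient is a ratio of
linear-scale intensities and is only meaningful there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormalizationResult", "pqn", "scale_matrix", "lnpqn"]

logger = logging.getLogger(__name__)


@dataclass
class NormalizationResult:
    """PQN output: normalized matrix, per-sample quotients, reference."""

    matrix: pd.DataFrame
    quotients: pd.Series
    reference: pd.Series
    mode: str = "pqn"


def pqn(matrix: pd.DataFrame,
        reference_rows: pd.Index | list | None = None,
        reference: pd.Series | None = None) -> NormalizationResult:
    """Probabilistic quotient normalization of a samples × analytes matrix.

    The reference spectrum is the per-analyte median over
    ``reference_rows`` (default: all rows); pass the study-sample index so
    pooled QCs do not bias the dilution estimate.  Each row's quotient is
    the median over analytes of row/reference, using non-missing entries;
    analytes with non-positive reference are excluded from quotient
    estimation.  Rows are divided by their quotient.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PQN needs at least 2 samples")
    if (matrix < 0).any().any():
        raise ValueError("PQN expects non-negative intensities")
    if reference is None:
        ref_rows = matrix.index if reference_rows is None else reference_rows
        reference = matrix.loc[ref_rows].median(axis=0, skipna=True)
    usable = reference > 0
    if not usable.all():
        logger.warning("PQN: %d analytes with non-positive reference excluded "
                       "from quotient estimation", int((~usable).sum()))
    if not usable.any():
        raise ValueError("PQN reference spectrum has no positive entries")
    ratios = matrix.loc[:, usable].div(reference[usable], axis=1)
    quotients = ratios.median(axis=1, skipna=True)
    if (quotients <= 0).any() or quotients.isna().any():
        bad = quotients.index[(quotients <= 0) | quotients.isna()].tolist()
        raise ValueError(f"non-positive or undefined PQN quotient for rows {bad}")
    normalized = matrix.div(quotients, axis=0)
    return NormalizationResult(matrix=normalized, quotients=quotients,
                               reference=reference, mode="pqn")


def scale_matrix(matrix: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Elementwise/columnwise transforms: ``ln``, ``center`` or ``pareto``.

    ``ln``: natural log (strictly positive input required).  ``center``:
    subtract column means.  ``pareto``: center, then divide each column by
    the square root of its standard deviation.
    """
    if mode == "ln":
        bad = (matrix <= 0) & matrix.notna()
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"ln transform needs positive entries; first offender at "
                f"row {matrix.index[r]!r}, column {matrix.columns[c]!r}"
            )
        return np.log(matrix)
    if mode == "center":
        return matrix - matrix.mean(axis=0)
    if mode == "pareto":
        centered = matrix - matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=1)
        scale = np.sqrt(sd).replace(0.0, 1.0)  # constant columns pass through
        return centered / scale
    raise ValueError(f"unknown scaling mode {mode!r}")


def lnpqn(matrix: pd.DataFrame,
          reference_rows: pd.Index | list | None = None) -> NormalizationResult:
    """The lnPQN transform: PQN followed by the natural log."""
    result = pqn(matrix, reference_rows=reference_rows)
    return NormalizationResult(
        matrix=scale_matrix(result.matrix, "ln"),
        quotients=result.quotients,
        reference=result.reference,
        mode="lnPQN",
    )
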
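"""Pseudotargeted MRM lipidomics of apocrine sweat.

Theoretical transition libraries, a synthetic study-design generator,
blank/LOESS/CV preprocessing, lnPQN normalization, variability statistics,
class quantitation with isotopic correction, and multivariate analysis.
"""

from .library import (
    LipidSpecies,
    TransitionRecord,
    UnsupportedClassError,
    elemental_formula,
    enumerate_library,
    monoisotopic_mass,
    parse_label,
    rt_pattern_check,
    transitions_for,
)
from .multivariate import (
    PairedComparison,
    PcaResult,
    bh_reject,
    correlation_matrix,
    critical_r,
    hca,
    paired_compare,
    pca,
)
from .normalization import NormalizationResult, lnpqn, pqn, scale_matrix
from .peaktable import InjectionRecord, PeakTable
from .pipeline import PipelineConfig, PipelineError, run_pipeline
from .preprocessing import loess_correct, qc_cv_filter, subtract_blank
from .quantitation import (
    CalibrationCurve,
    IsotopeParams,
    class_composition,
    fit_calibration,
    isotope_correction_factor,
    quantify,
)
from .synthetic import GeneratorParams, GeneratorTruth, generate_dataset
from .variability import cv, linearity_check, variability_report

__version__ = "0.1.0"
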
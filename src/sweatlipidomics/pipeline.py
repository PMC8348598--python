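"""End-to-end pipeline: preprocessing → normalization branches → reports.

Stage order follows the processing protocol: blank subtraction, QC-LOESS
drift correction, QC-CV filtering, then both transformation branches (ln
and lnPQN) feeding the variability, quantitation and multivariate reports.
Both branches are always computed so the ln-vs-lnPQN comparison is a
first-class output.  Given identical inputs, configuration and seed the
result bundle is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocessing, synthetic
from .multivariate import (correlation_matrix, critical_r, hca, network_summary,
                           paired_compare, pca)
from .normalization import pqn, scale_matrix
from .peaktable import PeakTable
from .quantitation import class_composition, curves_from_table, quantify
from .synthetic import GeneratorParams, GeneratorTruth, generate_dataset
from .variability import variability_report

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    Either ``input_dir`` (areas.tsv + manifest.tsv written by this package)
    or ``simulate=True`` with generator parameters must be given.
    """

    output_dir: str | Path = "results"
    input_dir: str | Path | None = None
    simulate: bool = False
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    do_blank_subtraction: bool = True
    do_loess: bool = True
    do_cv_filter: bool = True
    loess_span: float = 0.75
    min_qc: int = 4
    cv_threshold: float = 30.0
    alpha: float = 0.05
    fdr_q: float = 0.25
    hca_k: int = 10
    n_components: int = 2
    paired_condition: str = "lnPQN"

    def validate(self) -> None:
        if not self.simulate and self.input_dir is None:
            raise ValueError("either input_dir or simulate=True is required")
        if self.simulate:
            self.generator.validate()
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.cv_threshold < 0:
            raise ValueError("cv_threshold must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["input_dir"] = None if self.input_dir is None else str(self.input_dir)
        for key in ("class_counts", "class_median_conc"):
            d["generator"][key] = dict(d["generator"][key])
        return d


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the result bundle under ``output_dir``.

    Returns a dict of in-memory results keyed by stage; raises
    :class:`PipelineError` (after writing a failure manifest) if a stage
    cannot proceed.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))

    results: dict = {}
    try:
        # --- input ----------------------------------------------------------
        truth: GeneratorTruth | None = None
        if config.simulate:
            table, truth = generate_dataset(config.generator)
            synthetic.write_dataset(table, truth, out / "input")
        else:
            table = PeakTable.read(Path(config.input_dir))
        results["input_table"] = table

        # standards are calibration-only channels; keep them aside
        std_labels = table.standard_labels()
        analyte_table = table.select_labels(table.analyte_labels())

        # --- preprocessing (blank -> LOESS -> CV filter) --------------------
        stage_reports = {}
        if config.do_blank_subtraction and len(analyte_table.blank_ids) > 0:
            analyte_table, blank_report = preprocessing.subtract_blank(analyte_table)
            stage_reports["blank_subtraction"] = blank_report.to_dict()
        if config.do_loess:
            analyte_table, loess_report = preprocessing.loess_correct(
                analyte_table, span=config.loess_span, min_qc=config.min_qc)
            stage_reports["loess"] = loess_report.to_dict()
        if config.do_cv_filter:
            analyte_table, cv_report = preprocessing.qc_cv_filter(
                analyte_table, threshold=config.cv_threshold)
            stage_reports["cv_filter"] = cv_report.to_dict()
        _write_json(out / "preprocessing_report.json", stage_reports)
        results["preprocessed"] = analyte_table
        results["stage_reports"] = stage_reports
        if analyte_table.areas.shape[1] == 0:
            raise PipelineError(
                "no analytes survived preprocessing (CV threshold "
                f"{config.cv_threshold}%); nothing to analyze")
        analyte_table.write(out, prefix="preprocessed_")

        # --- normalization branches ----------------------------------------
        study = analyte_table.study_areas
        pqn_result = pqn(study)
        pqn_result.quotients.rename("quotient").to_csv(
            out / "pqn_quotients.tsv", sep="\t")
        results["pqn"] = pqn_result

        branches: dict[str, pd.DataFrame] = {
            "ln": scale_matrix(study, "ln"),
            "lnPQN": scale_matrix(pqn_result.matrix, "ln"),
        }

        # --- variability -----------------------------------------------------
        results["variability"] = {}
        for cond in ("ln", "lnPQN"):
            rep = variability_report(analyte_table, condition=cond)
            rep.per_lipid.rename_axis("lipid").to_csv(
                out / f"variability_{cond}.tsv", sep="\t", float_format="%.4f")
            results["variability"][cond] = rep
        _write_json(out / "variability_medians.json", {
            cond: results["variability"][cond].medians() for cond in branches})

        # --- multivariate ----------------------------------------------------
        individuals = analyte_table.manifest.loc[analyte_table.study_ids,
                                                 "individual"]
        results["multivariate"] = {}
        for cond, matrix in branches.items():
            scaled = scale_matrix(matrix, "pareto")
            p = pca(scaled, n_components=min(config.n_components,
                                             *scaled.shape))
            h = hca(scaled, k=config.hca_k, groups=individuals)
            p.scores.rename_axis("injection_id").to_csv(
                out / f"pca_scores_{cond}.tsv", sep="\t", float_format="%.6g")
            np.savetxt(out / f"hca_merge_heights_{cond}.tsv",
                       h.linkage_matrix, delimiter="\t", fmt="%.6g")
            results["multivariate"][cond] = {"pca": p, "hca": h}
        _write_json(out / "multivariate_summary.json", {
            cond: {
                "explained_variance_pct": [
                    round(float(v) * 100.0, 4)
                    for v in results["multivariate"][cond]["pca"].explained_variance_ratio
                ],
                "hca_purity": results["multivariate"][cond]["hca"].purity,
            }
            for cond in branches
        })

        r, mask = correlation_matrix(branches["lnPQN"], alpha=config.alpha)
        r.rename_axis("lipid").to_csv(out / "correlation_lnPQN.tsv", sep="\t",
                                      float_format="%.4f")
        results["correlation"] = (r, mask)
        results["critical_r"] = critical_r(len(study.index), config.alpha)

        comparison = paired_compare(analyte_table, q=config.fdr_q,
                                    condition=config.paired_condition)
        comparison.results.rename_axis("lipid").to_csv(
            out / "paired_comparison.tsv", sep="\t", float_format="%.6g")
        results["paired"] = comparison
        _write_json(out / "network_lnPQN.json", network_summary(
            comparison,
            variability=results["variability"]["lnPQN"].per_lipid))

        # --- quantitation ----------------------------------------------------
        if std_labels and len(table.cal_ids) > 0:
            if truth is not None:
                cal_concs = truth.cal_concs
            else:
                cal_path = (Path(config.input_dir) / "cal_concentrations.tsv"
                            if config.input_dir else None)
                cal_concs = (pd.read_csv(cal_path, sep="\t", index_col=0)
                             if cal_path and cal_path.exists() else None)
            if cal_concs is not None:
                cal_table = table.select_labels(
                    std_labels + analyte_table.analyte_labels())
                curves = curves_from_table(cal_table, cal_concs)
                conc, mask_oor, quant_report = quantify(
                    analyte_table, curves)
                conc.rename_axis("injection_id").to_csv(
                    out / "concentrations.tsv", sep="\t", float_format="%.6g")
                composition = class_composition(conc)
                composition.rename_axis("class").to_csv(
                    out / "class_composition.tsv", sep="\t", float_format="%.6g")
                _write_json(out / "quantitation_report.json", {
                    **quant_report,
                    "curves": {
                        cls: {"slope": c.slope, "intercept": c.intercept,
                              "r2": c.r2, "standard": c.standard_label}
                        for cls, c in curves.items()
                    },
                })
                results["concentrations"] = conc
                results["composition"] = composition
                results["curves"] = curves
    except PipelineError:
        _write_json(out / "FAILURE.json", {"failed": True})
        raise
    except Exception as exc:
        _write_json(out / "FAILURE.json", {"failed": True, "error": str(exc)})
        raise PipelineError(f"pipeline stage failed: {exc}") from exc
    return results
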
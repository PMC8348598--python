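"""Synthetic peak-area datasets with the apocrine-sweat study design.

The generator emulates the data-generating process the pipeline is built
for: 10 individuals (A–J) sampled on 3 days from both axillae (60 study
samples), a pooled QC injected every 5th position, process blanks, and a
6-level matrix-matched calibration series, acquired in one randomized
sequence.

The statistical model is multiplicative (log-normal) on the area scale.
For study sample *s* and lipid *j*:

    area[s, j] = k_class(j) * (1 - p13)^nC(j) * c[s, j] * d_s
                 * drift_j(order_s) * exp(eps)

where ``c[s, j]`` is the true concentration (lipid baseline × individual ×
day × side effects, all log-normal), ``d_s`` the per-sample dilution factor
— the un-standardizable sweat volume that probabilistic quotient
normalization has to estimate — ``drift_j`` a smooth instrument drift
curve, ``k_class`` a class response factor and ``(1-p13)^nC`` the
monoisotopic fraction of a lipid with nC carbons.  QC areas are the mean of
the study samples' pre-dilution signals (a pooled aliquot) times drift and
QC noise; process blanks carry only contamination for a configurable set of
analytes (which also contaminates every other injection additively);
calibration injections carry the labeled class standards at known
concentrations in the QC matrix.

All hidden parameters are returned as :class:`GeneratorTruth` so recovery
tests can compare pipeline estimates against the simulated ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .library import CLASS_RULES, elemental_formula, parse_label
from .peaktable import STANDARD_PREFIX, InjectionRecord, PeakTable

__all__ = [
    "GeneratorParams",
    "GeneratorTruth",
    "DEFAULT_CLASS_COUNTS",
    "DEFAULT_CLASS_MEDIAN_CONC",
    "DEFAULT_STANDARDS",
    "generate_dataset",
    "write_dataset",
    "read_truth",
]

INDIVIDUALS = tuple("ABCDEFGHIJ")
DAYS = (1, 2, 3)
SIDES = ("L", "R")

#: Lipids detected per class, proportional to the sweat panel (240 total).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "Cer": 61, "TG": 37, "SM": 23, "PC": 20, "DG": 17, "FA": 17,
    "CE": 12, "PE": 10, "HexCer": 9, "PEO": 8, "PCO": 7, "LPC": 6,
    "LPE": 5, "PS": 5, "PI": 3,
}

#: Class-median true concentrations (mol/L).  Free fatty acids dominate the
#: summed concentration, with DG/CE/TG next and the phospholipid and
#: sphingolipid classes orders of magnitude lower, so the overall dispersion
#: spans > 4 orders of magnitude.
DEFAULT_CLASS_MEDIAN_CONC: dict[str, float] = {
    "FA": 2e-5, "DG": 2e-6, "CE": 1.5e-6, "TG": 2.5e-7,
    "Cer": 8e-9, "SM": 4e-9, "PC": 5e-9, "PE": 3e-9, "HexCer": 3e-9,
    "PI": 2e-9, "PS": 2e-9, "PCO": 1e-9, "PEO": 1e-9, "LPC": 1e-9,
    "LPE": 8e-10,
}

#: One labeled standard per class (shorthand of the unlabeled analogue).
DEFAULT_STANDARDS: dict[str, str] = {
    "CE": "CE 18:1", "Cer": "Cer d18:1/15:0", "HexCer": "HexCer d18:1/18:1",
    "LPC": "LPC 18:1", "PC": "PC 33:1", "PCO": "PCO 34:1",
    "LPE": "LPE 18:1", "PE": "PE 33:1", "PEO": "PEO 34:1",
    "PI": "PI 33:1", "PS": "PS 33:1", "SM": "SM d18:1/18:1",
    "DG": "DG 33:1", "TG": "TG 48:1", "FA": "FA 20:4",
}


@dataclass
class GeneratorParams:
    """Tunable parameters of the synthetic study.

    Standard deviations are on the natural-log scale unless noted.
    """

    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    lipid_scale: float = 1.0              # multiplies class_counts (>=1 lipid/class)
    class_median_conc: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEDIAN_CONC))
    base_log_sd: float = 1.0              # lipid-to-lipid spread within a class
    individual_log_sd: float = 0.35       # individual-specific lipid profile
    day_log_sd: float = 0.20              # day-to-day biological variation
    sample_log_sd: float = 0.25           # residual per-sample biological noise
    side_log2_shift: float = 0.10         # L/R shift (log2) for shifted classes
    side_up_classes: tuple[str, ...] = ("Cer", "DG")
    side_down_classes: tuple[str, ...] = ("PC", "PCO", "PE", "PEO")
    dilution_log_sd: float = 0.50         # per-sample multiplicative dilution
    drift_amplitude: float = 0.20         # fractional drift over the run
    drift_mode: str = "smooth"            # smooth | linear | none
    analytical_log_sd: float = 0.08
    qc_log_sd: float = 0.07
    blank_contaminated: tuple[str, ...] = ("FA 16:0", "FA 18:0", "Cer d20:1/18:0")
    blank_level: float = 0.30             # contamination vs mean study signal
    blank_log_sd: float = 0.10
    n_blanks: int = 3
    qc_every: int = 5                     # a QC at every 5th sample position
    cal_levels: tuple[float, ...] = (1.0, 0.2, 0.04, 0.008, 0.0016, 0.00032)
    cal_top_factor: float = 100.0         # top level = factor x class median conc
    cal_log_sd: float = 0.02
    p13: float = 0.0107                   # 13C natural abundance
    seed: int = 2021

    def validate(self) -> None:
        bad: list[str] = []
        for name in ("base_log_sd", "individual_log_sd", "day_log_sd", "sample_log_sd",
                     "dilution_log_sd", "analytical_log_sd", "qc_log_sd",
                     "blank_log_sd", "cal_log_sd", "drift_amplitude",
                     "blank_level"):
            if getattr(self, name) < 0:
                bad.append(name)
        if self.lipid_scale <= 0:
            bad.append("lipid_scale")
        if self.drift_mode not in ("smooth", "linear", "none"):
            bad.append("drift_mode")
        if self.n_blanks < 0:
            bad.append("n_blanks")
        if self.qc_every < 2:
            bad.append("qc_every")
        if not 0 < self.p13 < 1:
            bad.append("p13")
        if len(self.cal_levels) < 2 or any(l <= 0 for l in self.cal_levels):
            bad.append("cal_levels")
        unknown = set(self.class_counts) - set(CLASS_RULES)
        if unknown:
            bad.append(f"class_counts (unknown classes {sorted(unknown)})")
        if bad:
            raise ValueError(f"invalid generator parameters: {', '.join(bad)}")


@dataclass
class GeneratorTruth:
    """Hidden parameters of a generated dataset, for recovery tests."""

    dilution: pd.Series                 # per study injection
    drift: pd.DataFrame                 # orders x lipid labels (incl. standards)
    concentrations: pd.DataFrame        # study injections x analyte labels (mol/L)
    individual_effects: pd.DataFrame    # individuals x analyte labels (ln scale)
    lipid_classes: pd.Series            # analyte label -> class code
    responses: pd.Series                # class -> area per (mol/L)
    cal_concs: pd.DataFrame             # levels x class (mol/L)
    standard_labels: pd.Series          # class -> standard column label
    p13: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dilution": self.dilution.to_dict(),
            "drift": self.drift.to_dict(orient="split"),
            "concentrations": self.concentrations.to_dict(orient="split"),
            "individual_effects": self.individual_effects.to_dict(orient="split"),
            "lipid_classes": self.lipid_classes.to_dict(),
            "responses": self.responses.to_dict(),
            "cal_concs": self.cal_concs.to_dict(orient="split"),
            "standard_labels": self.standard_labels.to_dict(),
            "p13": self.p13,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_truth(path: str | Path) -> GeneratorTruth:
    payload = json.loads(Path(path).read_text())

    def _frame(d):
        return pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])

    return GeneratorTruth(
        dilution=pd.Series(payload["dilution"]),
        drift=_frame(payload["drift"]),
        concentrations=_frame(payload["concentrations"]),
        individual_effects=_frame(payload["individual_effects"]),
        lipid_classes=pd.Series(payload["lipid_classes"]),
        responses=pd.Series(payload["responses"]),
        cal_concs=_frame(payload["cal_concs"]),
        standard_labels=pd.Series(payload["standard_labels"]),
        p13=payload["p13"],
    )


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------

def _class_panel(cls: str, count: int, rng: np.random.Generator,
                 force: list[str]) -> list[str]:
    """Choose `count` species labels for a class, keeping any forced labels."""
    from .library import enumerate_library

    records = [r for r in enumerate_library({cls: CLASS_RULES[cls]["enumerate"]})]
    labels = [r.species.label for r in records]
    chosen = [l for l in force if l in labels]
    pool = [l for l in labels if l not in chosen]
    n_extra = max(count - len(chosen), 0)
    if n_extra > len(pool):
        n_extra = len(pool)
    if n_extra:
        idx = rng.choice(len(pool), size=n_extra, replace=False)
        chosen += [pool[i] for i in sorted(idx)]
    return sorted(chosen, key=labels.index)


def _build_panel(params: GeneratorParams, rng: np.random.Generator) -> list[str]:
    forced = list(params.blank_contaminated)
    labels: list[str] = []
    for cls, count in params.class_counts.items():
        n = max(int(round(count * params.lipid_scale)), 1)
        force = [l for l in forced if parse_label(l).class_code == cls]
        labels.extend(_class_panel(cls, n, rng, force))
    return labels


def _carbon_counts(labels: list[str]) -> np.ndarray:
    return np.array(
        [elemental_formula(parse_label(l)).get("C", 0) for l in labels], dtype=float
    )


# ---------------------------------------------------------------------------
# Drift curves
# ---------------------------------------------------------------------------

def _drift_curves(params: GeneratorParams, n_orders: int, n_channels: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Multiplicative drift, one smooth curve per channel, mean ~1."""
    t = np.linspace(0.0, 1.0, n_orders)
    if params.drift_mode == "none" or params.drift_amplitude == 0:
        return np.ones((n_orders, n_channels))
    if params.drift_mode == "linear":
        # Same monotone drift for every channel: amplitude fractional change.
        g = params.drift_amplitude * (t - 0.5)
        return np.exp(np.tile(g[:, None], (1, n_channels)))
    # smooth: random cubic polynomial per channel, centred, scaled to amplitude
    coefs = rng.normal(size=(3, n_channels))
    basis = np.stack([t, t ** 2, t ** 3], axis=1)  # orders x 3
    g = basis @ coefs
    g -= g.mean(axis=0, keepdims=True)
    span = np.maximum(g.max(axis=0) - g.min(axis=0), 1e-12)
    g *= params.drift_amplitude / span
    return np.exp(g)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _injection_sequence(params: GeneratorParams,
                        rng: np.random.Generator) -> list[InjectionRecord]:
    """Randomized study sequence: blanks, S/QC interleaved, calibration."""
    study = [(ind, day, side) for ind in INDIVIDUALS for day in DAYS for side in SIDES]
    order_perm = rng.permutation(len(study))
    study = [study[i] for i in order_perm]
    records: list[InjectionRecord] = []
    order = 1
    for i in range(params.n_blanks):
        records.append(InjectionRecord(f"BLANK{i + 1}", "blank", order))
        order += 1
    qc_i = 0
    position = 0  # position within the sample stream (study + qc)
    for ind, day, side in study:
        records.append(
            InjectionRecord(f"{ind}{day}{side}", "study", order,
                            individual=ind, day=day, side=side)
        )
        order += 1
        position += 1
        if (position + qc_i + 1) % params.qc_every == 0:
            qc_i += 1
            records.append(InjectionRecord(f"QC{qc_i}", "qc", order))
            order += 1
    for lvl in range(len(params.cal_levels), 0, -1):  # low to high concentration
        records.append(InjectionRecord(f"CAL{lvl}", "cal", order, cal_level=lvl))
        order += 1
    return records


def generate_dataset(params: GeneratorParams | None = None
                     ) -> tuple[PeakTable, GeneratorTruth]:
    """Simulate one full study run.

    Returns the peak table (study + QC + blank + cal injections; analyte and
    ``STD``-prefixed standard columns) and the hidden truth.  Fixed seed ⇒
    bit-identical output.
    """
    params = params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    labels = _build_panel(params, rng)
    classes = pd.Series({l: parse_label(l).class_code for l in labels})
    n_lip = len(labels)
    n_carbons = _carbon_counts(labels)

    std_classes = [c for c in params.class_counts if c in DEFAULT_STANDARDS]
    std_labels = {c: STANDARD_PREFIX + DEFAULT_STANDARDS[c] for c in std_classes}
    std_carbons = {
        c: elemental_formula(parse_label(DEFAULT_STANDARDS[c])).get("C", 0)
        for c in std_classes
    }

    records = _injection_sequence(params, rng)
    ids = [r.injection_id for r in records]
    orders = np.array([r.order for r in records])
    study_records = [r for r in records if r.type == "study"]
    study_ids = [r.injection_id for r in study_records]

    # class response factors (area units per mol/L), deterministic given seed
    responses = pd.Series(
        10 ** (10.5 + 0.3 * rng.standard_normal(len(params.class_counts))),
        index=list(params.class_counts),
    )
    mono_frac = (1.0 - params.p13) ** n_carbons

    # --- true concentrations -----------------------------------------------
    base = np.array([
        np.log(params.class_median_conc.get(classes[l], 1e-9)) for l in labels
    ]) + params.base_log_sd * rng.standard_normal(n_lip)
    ind_eff = params.individual_log_sd * rng.standard_normal((len(INDIVIDUALS), n_lip))
    day_eff = params.day_log_sd * rng.standard_normal(
        (len(INDIVIDUALS), len(DAYS), n_lip))
    side_shift_ln = np.zeros(n_lip)
    shift = params.side_log2_shift * np.log(2.0)
    for j, l in enumerate(labels):
        if classes[l] in params.side_up_classes:
            side_shift_ln[j] = +shift / 2.0
        elif classes[l] in params.side_down_classes:
            side_shift_ln[j] = -shift / 2.0

    sample_eff = params.sample_log_sd * rng.standard_normal(
        (len(study_records), n_lip))

    ind_index = {ind: i for i, ind in enumerate(INDIVIDUALS)}
    day_index = {d: i for i, d in enumerate(DAYS)}
    ln_conc = np.empty((len(study_records), n_lip))
    for s, rec in enumerate(study_records):
        sgn = 1.0 if rec.side == "L" else -1.0
        ln_conc[s] = (base + ind_eff[ind_index[rec.individual]]
                      + day_eff[ind_index[rec.individual], day_index[rec.day]]
                      + sgn * side_shift_ln + sample_eff[s])
    conc = np.exp(ln_conc)

    dilution = np.exp(params.dilution_log_sd * rng.standard_normal(len(study_records)))

    all_channels = labels + [std_labels[c] for c in std_classes]
    drift = _drift_curves(params, len(records), len(all_channels), rng)
    drift_df = pd.DataFrame(drift, index=orders, columns=all_channels)
    order_pos = {o: i for i, o in enumerate(orders)}

    resp_vec = np.array([responses[classes[l]] for l in labels])
    signal = conc * resp_vec * mono_frac  # pre-dilution study signals

    # additive blank contamination (applies to every injection)
    contam = np.zeros(n_lip)
    mean_signal = signal.mean(axis=0)
    for l in params.blank_contaminated:
        if l in labels:
            j = labels.index(l)
            contam[j] = params.blank_level * mean_signal[j] * dilution.mean()

    areas = pd.DataFrame(np.nan, index=ids, columns=all_channels, dtype=float)
    areas.index.name = "injection_id"
    for s, rec in enumerate(study_records):
        dr = drift[order_pos[rec.order], :n_lip]
        noise = np.exp(params.analytical_log_sd * rng.standard_normal(n_lip))
        contam_noise = np.exp(params.blank_log_sd * rng.standard_normal(n_lip))
        areas.loc[rec.injection_id, labels] = (
            signal[s] * dilution[s] * dr * noise + contam * contam_noise
        )
    qc_base = signal.mean(axis=0)  # pooled pre-dilution aliquots
    for rec in records:
        if rec.type == "qc":
            dr = drift[order_pos[rec.order], :n_lip]
            noise = np.exp(params.qc_log_sd * rng.standard_normal(n_lip))
            contam_noise = np.exp(params.blank_log_sd * rng.standard_normal(n_lip))
            areas.loc[rec.injection_id, labels] = (
                qc_base * dr * noise + contam * contam_noise
            )
        elif rec.type == "blank":
            contam_noise = np.exp(params.blank_log_sd * rng.standard_normal(n_lip))
            areas.loc[rec.injection_id, labels] = contam * contam_noise

    # calibration: standards in QC matrix; analyte channels see the QC matrix
    top_conc = {
        c: params.cal_top_factor * params.class_median_conc.get(c, 1e-9)
        for c in std_classes
    }
    cal_concs = pd.DataFrame(
        {c: [top_conc[c] * lv for lv in params.cal_levels] for c in std_classes},
        index=pd.RangeIndex(1, len(params.cal_levels) + 1, name="level"),
    )
    for rec in records:
        if rec.type != "cal":
            continue
        dr_an = drift[order_pos[rec.order], :n_lip]
        noise = np.exp(params.qc_log_sd * rng.standard_normal(n_lip))
        contam_noise = np.exp(params.blank_log_sd * rng.standard_normal(n_lip))
        areas.loc[rec.injection_id, labels] = (
            qc_base * dr_an * noise + contam * contam_noise
        )
        for c in std_classes:
            mono_std = (1.0 - params.p13) ** std_carbons[c]
            dr = drift_df.loc[rec.order, std_labels[c]]
            eps = np.exp(params.cal_log_sd * rng.standard_normal())
            areas.loc[rec.injection_id, std_labels[c]] = (
                responses[c] * mono_std * cal_concs.loc[rec.cal_level, c] * dr * eps
            )
    # standards are absent outside the calibration series
    std_cols = [std_labels[c] for c in std_classes]
    cal_ids = [r.injection_id for r in records if r.type == "cal"]
    non_cal = [i for i in ids if i not in cal_ids]
    areas.loc[non_cal, std_cols] = 0.0

    table = PeakTable.from_records(records, areas)
    truth = GeneratorTruth(
        dilution=pd.Series(dilution, index=study_ids, name="dilution"),
        drift=drift_df,
        concentrations=pd.DataFrame(conc, index=study_ids, columns=labels),
        individual_effects=pd.DataFrame(
            ind_eff, index=list(INDIVIDUALS), columns=labels),
        lipid_classes=classes,
        responses=responses,
        cal_concs=cal_concs,
        standard_labels=pd.Series(std_labels),
        p13=params.p13,
    )
    return table, truth


def write_dataset(table: PeakTable, truth: GeneratorTruth | None,
                  directory: str | Path) -> None:
    """Write areas + manifest as delimited text (and truth as JSON)."""
    directory = Path(directory)
    table.write(directory)
    if truth is not None:
        truth.to_json(directory / "truth.json")
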
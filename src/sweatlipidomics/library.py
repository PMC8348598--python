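"""Theoretical lipid species, elemental formulas and MRM transition libraries.

Pseudotargeted lipidomics starts from the full combinatorial space of lipid
species that could plausibly occur in the sample: for every lipid class, every
total acyl-carbon / double-bond combination (and, for sphingolipids, every
long-chain base) is converted into an elemental formula, a monoisotopic mass
and a class-specific MRM transition (precursor/product ion pair).  The
resulting panel of a few thousand transitions is then filtered against pooled
QC measurements; only detected transitions are retained for the scheduled
method.

The chemistry itself — class backbone compositions, adducts, product-ion
rules and default enumeration ranges — lives in an editable YAML table
shipped with the package (``data/class_rules.yaml``), not in code.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "LipidSpecies",
    "TransitionRecord",
    "UnsupportedClassError",
    "CLASS_RULES",
    "LIPID_CLASSES",
    "PROTON_MASS",
    "parse_label",
    "elemental_formula",
    "formula_string",
    "monoisotopic_mass",
    "transitions_for",
    "enumerate_library",
    "rt_pattern_check",
    "transitions_to_frame",
    "write_transition_list",
    "read_transition_list",
]

# Monoisotopic atomic masses (Da), CODATA/IUPAC values.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

# Mass of a proton; charging is (de)protonation throughout.
PROTON_MASS = 1.007276

_NH3 = {"N": 1, "H": 3}
_H2O = {"H": 2, "O": 1}


class UnsupportedClassError(ValueError):
    """Raised when a lipid class is not in the configured vocabulary."""


def _load_class_rules() -> dict:
    with resources.files("sweatlipidomics.data").joinpath("class_rules.yaml").open() as fh:
        return yaml.safe_load(fh)["classes"]


CLASS_RULES: dict[str, dict] = _load_class_rules()
LIPID_CLASSES: tuple[str, ...] = tuple(CLASS_RULES)

_LCB_RE = re.compile(r"^d(\d+):(\d+)$")


def _parse_lcb(lcb: str) -> tuple[int, int]:
    m = _LCB_RE.match(lcb)
    if m is None:
        raise ValueError(f"malformed long-chain base shorthand: {lcb!r}")
    return int(m.group(1)), int(m.group(2))


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at species-level annotation: class + total carbons:double bonds.

    Sphingolipids additionally carry a long-chain base (e.g. ``d18:1``);
    ``total_carbons``/``total_double_bonds`` then include the base.
    """

    class_code: str
    total_carbons: int
    total_double_bonds: int
    long_chain_base: str | None = None

    def __post_init__(self) -> None:
        if self.class_code not in CLASS_RULES:
            raise UnsupportedClassError(
                f"unknown lipid class {self.class_code!r}; known: {sorted(CLASS_RULES)}"
            )
        if not (self.total_carbons >= self.total_double_bonds >= 0):
            raise ValueError(
                f"need total_carbons >= total_double_bonds >= 0, got "
                f"{self.total_carbons}:{self.total_double_bonds}"
            )
        if self.long_chain_base is not None:
            m, k = _parse_lcb(self.long_chain_base)
            if self.total_carbons < m or self.total_double_bonds < k:
                raise ValueError(
                    f"totals {self.total_carbons}:{self.total_double_bonds} smaller "
                    f"than long-chain base {self.long_chain_base}"
                )

    @property
    def label(self) -> str:
        if self.long_chain_base is not None:
            m, k = _parse_lcb(self.long_chain_base)
            return (
                f"{self.class_code} {self.long_chain_base}/"
                f"{self.total_carbons - m}:{self.total_double_bonds - k}"
            )
        return f"{self.class_code} {self.total_carbons}:{self.total_double_bonds}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


_LABEL_RE = re.compile(r"^(\w+)\s+(?:(d\d+:\d+)/)?(\d+):(\d+)$")


def parse_label(label: str) -> LipidSpecies:
    """Parse shorthand like ``PC 34:1`` or ``Cer d18:1/16:0``.

    Round-trips with :attr:`LipidSpecies.label`.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"cannot parse lipid shorthand {label!r}")
    cls, lcb, carbons, dbs = m.group(1), m.group(2), int(m.group(3)), int(m.group(4))
    if lcb is not None:
        lm, lk = _parse_lcb(lcb)
        return LipidSpecies(cls, lm + carbons, lk + dbs, long_chain_base=lcb)
    return LipidSpecies(cls, carbons, dbs)


@dataclass(frozen=True)
class TransitionRecord:
    """One MRM ion pair for a lipid species."""

    species: LipidSpecies
    polarity: str  # "+" or "-"
    adduct: str
    precursor_mz: float
    product_mz: float
    product_rule: str
    expected_rt_window: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("m/z values must be positive")
        if self.product_mz > self.precursor_mz + 0.01:
            raise ValueError(
                f"product m/z {self.product_mz} exceeds precursor {self.precursor_mz}"
            )


# ---------------------------------------------------------------------------
# Elemental formulas and masses
# ---------------------------------------------------------------------------

def _add(formula: dict[str, int], other: Mapping[str, int], mult: int = 1) -> None:
    for el, n in other.items():
        formula[el] = formula.get(el, 0) + mult * n


def elemental_formula(species: LipidSpecies) -> dict[str, int]:
    """Elemental composition of a neutral lipid species.

    Ester classes: backbone + jointly C(n) H(2n-2d-2k) O(k) for k ester-linked
    chains (ether subclasses exchange one ester for an ether: +2 H, -1 O).
    Sphingolipids: long-chain base C(M) H(2M+3-2k) N O2 + amide-linked N-acyl
    chain + head-group addition.
    """
    rules = CLASS_RULES[species.class_code]
    n, d = species.total_carbons, species.total_double_bonds
    formula: dict[str, int] = {}
    if rules["kind"] == "ester":
        k = rules["n_chains"]
        _add(formula, rules.get("backbone", {}))
        h = 2 * n - 2 * d - 2 * k
        _add(formula, {"C": n, "H": h, "O": k})
        if rules.get("ether", False):
            _add(formula, {"H": 2, "O": -1})
    elif rules["kind"] == "sphingo":
        lcb = species.long_chain_base
        if lcb is None:
            raise ValueError(
                f"{species.class_code} species need an explicit long-chain base"
            )
        m, k = _parse_lcb(lcb)
        na_c, na_d = n - m, d - k
        _add(formula, {"C": m, "H": 2 * m + 3 - 2 * k, "N": 1, "O": 2})
        _add(formula, {"C": na_c, "H": 2 * na_c - 2 * na_d - 2, "O": 1})
        _add(formula, rules.get("head_addition", {}))
    else:  # pragma: no cover - config error
        raise UnsupportedClassError(f"unknown class kind {rules['kind']!r}")
    formula = {el: cnt for el, cnt in formula.items() if cnt != 0}
    if any(cnt < 0 for cnt in formula.values()):
        raise ValueError(
            f"composition {species.label} is chemically impossible ({formula})"
        )
    return formula


_HILL_ORDER = ("C", "H", "N", "O", "P", "S")


def formula_string(formula: Mapping[str, int]) -> str:
    """Hill-style string (C first, then H, then alphabetical)."""
    keys = [el for el in _HILL_ORDER if el in formula]
    keys += sorted(set(formula) - set(_HILL_ORDER))
    return "".join(f"{el}{formula[el]}" if formula[el] != 1 else el for el in keys)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of an element→count map."""
    try:
        return float(sum(ATOMIC_MASS[el] * n for el, n in formula.items()))
    except KeyError as exc:
        raise KeyError(f"no monoisotopic mass tabulated for element {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# Transitions
# ---------------------------------------------------------------------------

_ADDUCT_SHIFT = {
    "[M+H]+": PROTON_MASS,
    "[M+NH4]+": PROTON_MASS + monoisotopic_mass(_NH3),
    "[M-H]-": -PROTON_MASS,
}


def _normalize_polarity(polarity: str) -> str:
    p = polarity.strip().lower()
    if p in {"+", "pos", "positive"}:
        return "+"
    if p in {"-", "neg", "negative", "−"}:
        return "-"
    raise ValueError(f"unknown polarity {polarity!r}")


def transitions_for(species: LipidSpecies, polarity: str) -> list[TransitionRecord]:
    """Class-rule MRM transition(s) for a species in the requested polarity.

    A class not measured in the requested polarity yields an empty list.
    """
    rules = CLASS_RULES[species.class_code]
    polarity = _normalize_polarity(polarity)
    class_pol = _normalize_polarity(rules["polarity"])
    if polarity != class_pol:
        return []
    mass = monoisotopic_mass(elemental_formula(species))
    adduct = rules["adduct"]
    precursor = mass + _ADDUCT_SHIFT[adduct]
    prod = rules["product"]
    rule = prod["rule"]
    if rule == "pseudo":
        product = precursor
    elif rule == "fragment":
        sign = 1.0 if polarity == "+" else -1.0
        product = monoisotopic_mass(prod["formula"]) + sign * PROTON_MASS
    elif rule == "neutral_loss":
        product = precursor - monoisotopic_mass(prod["formula"])
    elif rule == "lcb_fragment":
        m, k = _parse_lcb(species.long_chain_base)
        lcb_mass = monoisotopic_mass({"C": m, "H": 2 * m + 3 - 2 * k, "N": 1, "O": 2})
        product = lcb_mass - 2 * monoisotopic_mass(_H2O) + PROTON_MASS
    else:  # pragma: no cover - config error
        raise ValueError(f"unknown product rule {rule!r}")
    return [
        TransitionRecord(
            species=species,
            polarity=polarity,
            adduct=adduct,
            precursor_mz=round(precursor, 4),
            product_mz=round(product, 4),
            product_rule=rule,
        )
    ]


def _default_ranges() -> dict[str, dict]:
    return {cls: rules["enumerate"] for cls, rules in CLASS_RULES.items()}


def enumerate_library(
    class_ranges: Mapping[str, Mapping] | None = None,
) -> list[TransitionRecord]:
    """Enumerate the theoretical MRM panel over per-class composition ranges.

    ``class_ranges`` maps class code to either ``{"carbons": (lo, hi),
    "double_bonds": (lo, hi)}`` or, for sphingolipid classes,
    ``{"long_chain_bases": [...], "n_acyl_carbons": (lo, hi),
    "n_acyl_double_bonds": (lo, hi)}`` (inclusive bounds).  ``None`` uses the
    ranges shipped in the class-rule table, which yield a panel of roughly
    3,700 transitions.  Output is deterministic (classes in table order,
    then base, carbons, double bonds ascending) and deduplicated on species
    identity + adduct.
    """
    if class_ranges is None:
        class_ranges = _default_ranges()
    records: list[TransitionRecord] = []
    seen: set[tuple] = set()
    for cls in CLASS_RULES:
        if cls not in class_ranges:
            continue
        rng = class_ranges[cls]
        rules = CLASS_RULES[cls]
        species_iter: Iterable[LipidSpecies]
        if rules["kind"] == "sphingo":
            lcbs = list(rng["long_chain_bases"])
            c_lo, c_hi = rng["n_acyl_carbons"]
            d_lo, d_hi = rng["n_acyl_double_bonds"]
            species_iter = (
                LipidSpecies(cls, m + nc, k + nd, long_chain_base=lcb)
                for lcb in lcbs
                for (m, k) in [_parse_lcb(lcb)]
                for nc in range(c_lo, c_hi + 1)
                for nd in range(d_lo, d_hi + 1)
            )
        else:
            c_lo, c_hi = rng["carbons"]
            d_lo, d_hi = rng["double_bonds"]
            species_iter = (
                LipidSpecies(cls, nc, nd)
                for nc in range(c_lo, c_hi + 1)
                for nd in range(d_lo, min(nc, d_hi) + 1)
            )
        for sp in species_iter:
            for rec in transitions_for(sp, rules["polarity"]):
                key = (sp.class_code, sp.long_chain_base, sp.total_carbons,
                       sp.total_double_bonds, rec.adduct)
                if key in seen:
                    continue
                seen.add(key)
                records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Retention-pattern verification
# ---------------------------------------------------------------------------

def rt_pattern_check(
    class_code: str,
    observations: Sequence[tuple[LipidSpecies, float]],
) -> list[bool]:
    """Flag identifications that break the class retention trend.

    Within a lipid class under reversed-phase separation, retention time is
    close to linear in total carbons (up) and double bonds (down).  A plane
    ``rt = a + b*carbons + c*double_bonds`` is fitted by least squares and
    observations with externally studentized residual magnitude above 3 are
    flagged as suspect identifications.  Fewer than 4 observations, or a
    degenerate design, yields no flags.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    n = len(observations)
    flags = [False] * n
    if n < 4:
        return flags
    X = np.array(
        [[1.0, sp.total_carbons, sp.total_double_bonds] for sp, _ in observations]
    )
    y = np.array([rt for _, rt in observations], dtype=float)
    rank = np.linalg.matrix_rank(X)
    # External studentization deletes one point; needs >=2 residual dof.
    if rank < X.shape[1] or n - rank - 1 < 1:
        warnings.warn(
            f"degenerate retention-trend design for class {class_code}; "
            "no outlier flags assigned",
            stacklevel=2,
        )
        return flags
    res = sm.OLS(y, X).fit()
    if res.ssr < 1e-18:  # perfect fit, nothing to studentize
        return flags
    student = OLSInfluence(res).resid_studentized_external
    return [bool(abs(r) > 3.0) for r in student]


# ---------------------------------------------------------------------------
# Transition list I/O
# ---------------------------------------------------------------------------

_TRANSITION_COLUMNS = [
    "label", "class", "polarity", "adduct",
    "precursor_mz", "product_mz", "rt_window",
]


def transitions_to_frame(records: Iterable[TransitionRecord]) -> pd.DataFrame:
    rows = [
        {
            "label": rec.species.label,
            "class": rec.species.class_code,
            "polarity": rec.polarity,
            "adduct": rec.adduct,
            "precursor_mz": rec.precursor_mz,
            "product_mz": rec.product_mz,
            "rt_window": rec.expected_rt_window,
        }
        for rec in records
    ]
    return pd.DataFrame(rows, columns=_TRANSITION_COLUMNS)


def write_transition_list(records: Iterable[TransitionRecord], path) -> None:
    """Write a transition list as tab-delimited text (lossless round trip)."""
    transitions_to_frame(records).to_csv(path, sep="\t", index=False)


def read_transition_list(path) -> list[TransitionRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        species = parse_label(row.label)
        rt = None if pd.isna(row.rt_window) else float(row.rt_window)
        records.append(
            TransitionRecord(
                species=species,
                polarity=row.polarity,
                adduct=row.adduct,
                precursor_mz=float(row.precursor_mz),
                product_mz=float(row.product_mz),
                product_rule=CLASS_RULES[species.class_code]["product"]["rule"],
                expected_rt_window=rt,
            )
        )
    return records
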
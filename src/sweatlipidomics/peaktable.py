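"""Injection manifests and peak-area tables.

The :class:`PeakTable` is the object every pipeline stage consumes and
returns: a non-negative (or missing) matrix of MRM peak areas, one row per
injection and one column per transition, paired with an injection manifest
describing each run (study sample / pooled QC / process blank / calibration
level, plus the study factors individual, day and side).

Missing areas are encoded as NaN, never as zero; zeros are legitimate
measured areas (e.g. an uncontaminated analyte in a process blank).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["InjectionRecord", "PeakTable", "INJECTION_TYPES", "STANDARD_PREFIX"]

INJECTION_TYPES = ("study", "qc", "blank", "cal")

#: Column-label prefix marking calibration-standard transitions.
STANDARD_PREFIX = "STD "

_MANIFEST_COLUMNS = ["type", "order", "individual", "day", "side", "cal_level"]


@dataclass(frozen=True)
class InjectionRecord:
    """Metadata for one injection."""

    injection_id: str
    type: str
    order: int
    individual: str | None = None
    day: int | None = None
    side: str | None = None
    cal_level: int | None = None

    def __post_init__(self) -> None:
        if self.type not in INJECTION_TYPES:
            raise ValueError(f"injection type must be one of {INJECTION_TYPES}")
        if self.order < 1:
            raise ValueError("injection order starts at 1")
        if self.type == "study" and None in (self.individual, self.day, self.side):
            raise ValueError(
                f"study injection {self.injection_id} needs individual, day and side"
            )
        if self.type == "cal" and self.cal_level is None:
            raise ValueError(f"cal injection {self.injection_id} needs cal_level")


@dataclass
class PeakTable:
    """Peak areas (injections × transitions) plus the injection manifest."""

    areas: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if not self.areas.index.equals(self.manifest.index):
            raise ValueError("areas and manifest must share the injection index")
        missing_cols = set(_MANIFEST_COLUMNS) - set(self.manifest.columns)
        if missing_cols:
            raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
        orders = self.manifest["order"]
        if orders.duplicated().any():
            raise ValueError("injection orders must be unique")
        bad_type = ~self.manifest["type"].isin(INJECTION_TYPES)
        if bad_type.any():
            raise ValueError(
                f"unknown injection types: {self.manifest['type'][bad_type].unique()}"
            )
        study = self.manifest[self.manifest["type"] == "study"]
        for col in ("individual", "day", "side"):
            if study[col].isna().any():
                raise ValueError(f"study injections must carry {col!r}")
        cal = self.manifest[self.manifest["type"] == "cal"]
        if cal["cal_level"].isna().any():
            raise ValueError("cal injections must carry cal_level")
        vals = self.areas.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("peak areas must be non-negative or missing (NaN)")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Sequence[InjectionRecord],
        areas: pd.DataFrame,
    ) -> "PeakTable":
        manifest = pd.DataFrame(
            {
                "type": [r.type for r in records],
                "order": [r.order for r in records],
                "individual": [r.individual for r in records],
                "day": pd.array([r.day for r in records], dtype="Int64"),
                "side": [r.side for r in records],
                "cal_level": pd.array([r.cal_level for r in records], dtype="Int64"),
            },
            index=pd.Index([r.injection_id for r in records], name="injection_id"),
        )
        return cls(areas=areas.loc[manifest.index], manifest=manifest)

    # -- selection helpers --------------------------------------------------
    def _rows(self, kind: str) -> pd.Index:
        return self.manifest.index[self.manifest["type"] == kind]

    @property
    def study_ids(self) -> pd.Index:
        return self._rows("study")

    @property
    def qc_ids(self) -> pd.Index:
        return self._rows("qc")

    @property
    def blank_ids(self) -> pd.Index:
        return self._rows("blank")

    @property
    def cal_ids(self) -> pd.Index:
        return self._rows("cal")

    @property
    def study_areas(self) -> pd.DataFrame:
        return self.areas.loc[self.study_ids]

    @property
    def qc_areas(self) -> pd.DataFrame:
        return self.areas.loc[self.qc_ids]

    @property
    def labels(self) -> list[str]:
        return list(self.areas.columns)

    def analyte_labels(self) -> list[str]:
        """Transition labels excluding calibration-standard channels."""
        return [c for c in self.areas.columns if not c.startswith(STANDARD_PREFIX)]

    def standard_labels(self) -> list[str]:
        return [c for c in self.areas.columns if c.startswith(STANDARD_PREFIX)]

    def select_labels(self, labels: Iterable[str]) -> "PeakTable":
        return PeakTable(areas=self.areas[list(labels)].copy(), manifest=self.manifest.copy())

    def copy(self) -> "PeakTable":
        return PeakTable(areas=self.areas.copy(), manifest=self.manifest.copy())

    # -- I/O -----------------------------------------------------------------
    def write(self, directory: str | Path, prefix: str = "") -> tuple[Path, Path]:
        """Write ``<prefix>areas.tsv`` and ``<prefix>manifest.tsv``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        areas_path = directory / f"{prefix}areas.tsv"
        manifest_path = directory / f"{prefix}manifest.tsv"
        self.areas.rename_axis("injection_id").to_csv(
            areas_path, sep="\t", float_format="%.6g"
        )
        self.manifest.rename_axis("injection_id").to_csv(manifest_path, sep="\t")
        return areas_path, manifest_path

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "") -> "PeakTable":
        directory = Path(directory)
        areas = pd.read_csv(directory / f"{prefix}areas.tsv", sep="\t", index_col=0)
        manifest = pd.read_csv(
            directory / f"{prefix}manifest.tsv",
            sep="\t",
            index_col=0,
            dtype={"individual": "string", "side": "string"},
        )
        manifest["day"] = manifest["day"].astype("Int64")
        manifest["cal_level"] = manifest["cal_level"].astype("Int64")
        manifest["individual"] = manifest["individual"].astype(object).where(
            manifest["individual"].notna(), None
        )
        manifest["side"] = manifest["side"].astype(object).where(
            manifest["side"].notna(), None
        )
        return cls(areas=areas, manifest=manifest)
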
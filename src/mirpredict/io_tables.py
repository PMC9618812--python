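"""Typed containers and CSV/TSV readers for expression, Ct and clinical tables.

Three table kinds circulate through the pipeline:

* :class:`ExpressionMatrix` — patients x miRNAs relative expression on the
  2^-dCt scale (positive reals; missing entries are explicit NaN, never 0);
* :class:`CtMatrix` — raw qPCR threshold cycles for a two-arm screening
  experiment, with "Undetermined" wells stored at the cycle ceiling and
  flagged;
* :class:`ClinicalTable` — per-patient response outcomes (complete remission,
  blood and bone-marrow minimal residual disease), baseline covariates and
  progression-free survival follow-up.

All readers auto-detect the delimiter (comma or tab) unless one is given,
treat empty cells and "NA" as missing, and round-trip losslessly through the
matching writers.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "CtMatrix",
    "ClinicalTable",
    "read_expression",
    "write_expression",
    "read_ct",
    "write_ct",
    "read_clinical",
    "write_clinical",
    "CLINICAL_CATEGORIES",
]


class ValidationError(ValueError):
    """A table violated one of its declared invariants."""


_NA_VALUES = ["", "NA"]


def _sniff_sep(path: str | Path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifier(s): {dup}")


@dataclasses.dataclass
class ExpressionMatrix:
    """Relative miRNA expression, patients as rows and miRNAs as columns.

    Values are dimensionless 2^-dCt quantities and must be strictly
    positive; a missing measurement is NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index.name = None
        _check_unique(self.data.index, "patient")
        _check_unique(self.data.columns, "miRNA")
        bad = (self.data.to_numpy() <= 0) & ~np.isnan(self.data.to_numpy())
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "non-positive expression value "
                f"{self.data.iat[i, j]!r} for patient "
                f"{self.data.index[i]!r}, miRNA {self.data.columns[j]!r}"
            )

    @property
    def patient_ids(self) -> list:
        return list(self.data.index)

    @property
    def mirna_ids(self) -> list:
        return list(self.data.columns)

    def values_for(self, mirna: str) -> pd.Series:
        return self.data[mirna]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclasses.dataclass
class CtMatrix:
    """Raw threshold cycles for a two-group screening card.

    ``ct`` holds samples x assays cycle numbers in (0, max_cycles];
    "Undetermined" wells are stored at ``max_cycles`` and flagged in
    ``undetected``. ``group`` labels each sample with one of exactly two
    screening arms.
    """

    ct: pd.DataFrame
    group: pd.Series
    undetected: pd.DataFrame | None = None
    max_cycles: int = 40

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        self.ct.index.name = None
        _check_unique(self.ct.index, "sample")
        _check_unique(self.ct.columns, "assay")
        if self.undetected is None:
            self.undetected = pd.DataFrame(
                False, index=self.ct.index, columns=self.ct.columns
            )
        self.undetected = self.undetected.astype(bool)
        if not self.undetected.index.equals(self.ct.index) or not (
            self.undetected.columns.equals(self.ct.columns)
        ):
            raise ValidationError("undetected flags must align with the Ct grid")
        self.group = self.group.reindex(self.ct.index)
        if self.group.isna().any():
            missing = list(self.group.index[self.group.isna()])
            raise ValidationError(f"samples without a group label: {missing}")
        labels = self.group.unique()
        if len(labels) != 2:
            raise ValidationError(
                f"a screening matrix needs exactly two arms, got {list(labels)}"
            )
        arr = self.ct.to_numpy()
        if np.any(arr <= 0) or np.any(arr > self.max_cycles):
            raise ValidationError(
                f"Ct values must lie in (0, {self.max_cycles}]"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.ct.index)

    @property
    def assay_ids(self) -> list:
        return list(self.ct.columns)

    @property
    def group_labels(self) -> list:
        return list(pd.unique(self.group))


#: Allowed category levels for each categorical clinical column.
CLINICAL_CATEGORIES: dict[str, tuple[str, ...]] = {
    "cr": ("CR", "no-CR"),
    "blood_mrd": ("uMRD", "MRD"),
    "bm_mrd": ("uMRD", "MRD"),
    "sex": ("F", "M"),
    "binet": ("AB", "C"),
    "ighv": ("mutated", "unmutated"),
    "del13q": ("yes", "no"),
    "del11q": ("yes", "no"),
    "tri12": ("yes", "no"),
    "arm": ("FCR", "Dense-FCR"),
}

_NUMERIC_COLUMNS = ("age", "ecog", "lymphocytes", "b2m", "cycles", "pfs_time")
_REQUIRED_COLUMNS = ("cr", "blood_mrd", "bm_mrd", "pfs_time", "pfs_event")


@dataclasses.dataclass
class ClinicalTable:
    """Per-patient outcomes, covariates and follow-up.

    Index is the patient id. Outcome trichotomies (``cr``, ``blood_mrd``,
    ``bm_mrd``) use the levels in :data:`CLINICAL_CATEGORIES` with NaN as
    the explicit missing marker; nothing is ever imputed. ``pfs_time`` is
    months from treatment initiation, ``pfs_event`` is 1 for
    progression/relapse, 0 for censoring.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        df.index.name = None
        _check_unique(df.index, "patient")
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"required clinical column missing: {col!r}")
        for col, levels in CLINICAL_CATEGORIES.items():
            if col not in df.columns:
                continue
            vals = df[col].dropna()
            bad = set(vals) - set(levels)
            if bad:
                raise ValidationError(
                    f"column {col!r} has values outside {levels}: {sorted(bad)}"
                )
        t = pd.to_numeric(df["pfs_time"], errors="coerce")
        if (t.dropna() < 0).any():
            pid = df.index[t < 0][0]
            raise ValidationError(f"negative pfs_time for patient {pid!r}")
        self.data["pfs_time"] = t
        ev = df["pfs_event"]
        if ev.dtype == object:
            ev = ev.replace({"event": 1, "censored": 0})
        ev = pd.to_numeric(ev, errors="coerce")
        bad_ev = set(ev.dropna().unique()) - {0, 1}
        if bad_ev:
            raise ValidationError(f"pfs_event must be 0/1 or event/censored, got {bad_ev}")
        self.data["pfs_event"] = ev

    @property
    def patient_ids(self) -> list:
        return list(self.data.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClinicalTable):
            return NotImplemented
        return self.data.equals(other.data)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path: str | Path,
    sep: str | None = None,
    orientation: str = "patients-rows",
) -> ExpressionMatrix:
    """Read a relative-expression CSV/TSV.

    First column holds ids, header row the other axis. ``orientation``
    says what the rows are (``"patients-rows"`` or ``"mirnas-rows"``);
    the latter is transposed on load.
    """
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False, float_precision="round_trip"
    )
    if orientation == "mirnas-rows":
        df = df.T
    elif orientation != "patients-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str = ",") -> None:
    expr.data.to_csv(path, sep=sep, na_rep="", index_label="patient_id")


def read_ct(
    path: str | Path, sep: str | None = None, max_cycles: int = 40
) -> CtMatrix:
    """Read a screening Ct CSV/TSV: sample id, group, then one column per assay.

    Wells recorded as ``Undetermined`` (any case) are stored at
    ``max_cycles`` and flagged undetected.
    """
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False, float_precision="round_trip"
    )
    if "group" not in df.columns:
        raise ValidationError("Ct table needs a 'group' column after the sample id")
    group = df["group"].astype(str)
    ct_raw = df.drop(columns="group")
    undet = ct_raw.apply(
        lambda col: col.astype(str).str.strip().str.lower() == "undetermined"
    )
    ct = ct_raw.mask(undet, max_cycles).astype(float)
    ct.index = ct.index.astype(str)
    return CtMatrix(ct=ct, group=group, undetected=undet, max_cycles=max_cycles)


def write_ct(ct: CtMatrix, path: str | Path, sep: str = ",") -> None:
    out = ct.ct.astype(object).mask(ct.undetected, "Undetermined")
    out.insert(0, "group", ct.group)
    out.to_csv(path, sep=sep, na_rep="", index_label="sample_id")


def read_clinical(
    path: str | Path,
    sep: str | None = None,
    schema: Mapping[str, str] | None = None,
) -> ClinicalTable:
    """Read a clinical annotation CSV/TSV.

    ``schema`` maps canonical column names (``cr``, ``bm_mrd`` ...) to the
    file's column headers when they differ. Empty cells and "NA" become
    explicit missing values; unknown category strings are rejected.
    """
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, na_values=_NA_VALUES, keep_default_na=False, float_precision="round_trip"
    )
    if schema:
        missing = [v for v in schema.values() if v not in df.columns]
        if missing:
            raise ValidationError(f"schema maps to absent column(s): {missing}")
        df = df.rename(columns={v: k for k, v in schema.items()})
    id_col = "patient_id" if "patient_id" in df.columns else df.columns[0]
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    for col in _NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: str | Path, sep: str = ",") -> None:
    clin.data.to_csv(path, sep=sep, na_rep="", index_label="patient_id")


def frame_to_csv_bytes(df: pd.DataFrame, **kwargs) -> bytes:
    """Render a frame to CSV bytes (deterministic; used by the CLI run log)."""
    buf = io.StringIO()
    df.to_csv(buf, na_rep="", **kwargs)
    return buf.getvalue().encode()
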
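"""Readers and writers for every table the pipeline touches.

All tables are plain UTF-8 text with a mandatory header. The delimiter is
auto-detected from the file extension (``.tsv`` -> tab, ``.csv`` -> comma)
and can be overridden. Empty cells and ``"."`` mark missing values; a blank
mutation cell means *unassayed*, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, FormatError

_MISSING = {"", "."}
_META_FIXED = ("sample_id", "cohort_id", "os_time", "os_event")


def _delimiter(path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class SampleMetadata:
    """Per-sample clinical annotation.

    ``mutation_flags`` maps gene name -> 0/1; genes not assayed for this
    sample are absent from the map. ``os_time`` (days) and ``os_event``
    (1 = death observed, 0 = censored) may both be None.
    """

    sample_id: str
    cohort_id: str
    mutation_flags: dict = field(default_factory=dict)
    os_time: Optional[float] = None
    os_event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.os_time is not None:
            if self.os_time < 0:
                raise FormatError(f"negative os_time for sample {self.sample_id!r}")
            if self.os_event is None:
                raise FormatError(
                    f"sample {self.sample_id!r} has os_time but no os_event"
                )
        if self.os_event is not None and self.os_event not in (0, 1):
            raise FormatError(f"os_event must be 0/1, got {self.os_event!r}")


@dataclass
class DoseResponseRecord:
    """One well of a drug screen: viability at one concentration."""

    sample_id: str
    drug_id: str
    concentration: float  # µM, strictly positive
    viability: float  # fraction of control, >= 0
    replicate: int = 1

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise FormatError(
                f"concentration must be > 0 µM "
                f"({self.sample_id}/{self.drug_id}: {self.concentration})"
            )
        if self.viability < 0:
            raise FormatError(
                f"negative viability ({self.sample_id}/{self.drug_id})"
            )
        if self.replicate < 1:
            raise FormatError("replicate index must be >= 1")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path, cohort_id: str, sep: Optional[str] = None,
                           scale: str = "raw_counts") -> ExpressionMatrix:
    """Read a genes x samples table (first column ``gene_id``)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, sep), dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene_id column plus >=1 sample")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    return ExpressionMatrix(cohort_id, df, scale)


def write_expression_matrix(em: ExpressionMatrix, path, sep: Optional[str] = None) -> None:
    path = Path(path)
    em.values.to_csv(path, sep=_delimiter(path, sep), index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path, sep: Optional[str] = None) -> list[SampleMetadata]:
    """Read per-sample metadata; mutation columns are any non-reserved columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, sep), dtype=str,
                     keep_default_na=False)
    for col in ("sample_id", "cohort_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    mut_cols = [c for c in df.columns if c not in _META_FIXED]
    records: list[SampleMetadata] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        key = (row["cohort_id"], row["sample_id"])
        if key in seen:
            raise FormatError(
                f"{path}: duplicate sample {row['sample_id']!r} in cohort {row['cohort_id']!r}"
            )
        seen.add(key)
        flags = {}
        for c in mut_cols:
            v = row[c].strip()
            if v in _MISSING:
                continue
            if v not in ("0", "1"):
                raise FormatError(f"{path}: mutation column {c!r} must be 0/1/blank, got {v!r}")
            flags[c] = int(v)
        t = row.get("os_time", "").strip() if "os_time" in df.columns else ""
        e = row.get("os_event", "").strip() if "os_event" in df.columns else ""
        records.append(SampleMetadata(
            sample_id=row["sample_id"],
            cohort_id=row["cohort_id"],
            mutation_flags=flags,
            os_time=None if t in _MISSING else float(t),
            os_event=None if e in _MISSING else int(float(e)),
        ))
    return records


def write_sample_metadata(records: list[SampleMetadata], path,
                          sep: Optional[str] = None) -> None:
    path = Path(path)
    mut_cols = sorted({g for r in records for g in r.mutation_flags})
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "cohort_id": r.cohort_id}
        for g in mut_cols:
            row[g] = "" if g not in r.mutation_flags else str(r.mutation_flags[g])
        row["os_time"] = "" if r.os_time is None else repr(float(r.os_time))
        row["os_event"] = "" if r.os_event is None else str(int(r.os_event))
        rows.append(row)
    cols = ["sample_id", "cohort_id", *mut_cols, "os_time", "os_event"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_delimiter(path, sep), index=False)


# ---------------------------------------------------------------------------
# drug screens
# ---------------------------------------------------------------------------

_DRC_COLS = ("sample_id", "drug_id", "concentration_uM", "viability", "replicate")


def read_dose_response_table(path, sep: Optional[str] = None) -> list[DoseResponseRecord]:
    """Read a long-format drug screen table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, sep))
    for col in _DRC_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        DoseResponseRecord(
            sample_id=str(row.sample_id),
            drug_id=str(row.drug_id),
            concentration=float(row.concentration_uM),
            viability=float(row.viability),
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]


def write_dose_response_table(records: list[DoseResponseRecord], path,
                              sep: Optional[str] = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [(r.sample_id, r.drug_id, r.concentration, r.viability, r.replicate)
         for r in records],
        columns=_DRC_COLS,
    )
    df.to_csv(path, sep=_delimiter(path, sep), index=False)
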
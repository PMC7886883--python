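"""Gene-by-sample expression container used throughout the pipeline.

A cohort's expression data is carried as a :class:`ExpressionMatrix`: a thin,
validated wrapper around a genes x samples ``pandas.DataFrame`` plus a scale
tag recording where the values sit in the processing chain (raw negative
binomial counts, log2 median-of-ratios normalized values, or per-gene
z-scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: allowed values of :attr:`ExpressionMatrix.scale`
SCALES = ("raw_counts", "log_normalized", "zscored")


class FormatError(ValueError):
    """A table violates the on-disk or in-memory contract."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Expression values for one cohort.

    Parameters
    ----------
    cohort_id : str
        Name of the cohort the samples belong to.
    values : pandas.DataFrame
        Genes in rows, samples in columns. Row/column order is meaningful
        and preserved by every operation.
    scale : str
        One of ``raw_counts``, ``log_normalized``, ``zscored``.
    """

    cohort_id: str
    values: pd.DataFrame
    scale: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if self.scale == "raw_counts":
            if not np.all(np.isfinite(arr)):
                raise FormatError("raw counts must be finite")
            if (arr < 0).any():
                raise FormatError("raw counts must be non-negative")

    # -- convenience views ------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        return ExpressionMatrix(self.cohort_id, self.values.loc[list(genes)], self.scale)

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return ExpressionMatrix(self.cohort_id, values, scale)

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.cohort_id == other.cohort_id
            and self.scale == other.scale
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values.to_numpy(), other.values.to_numpy())
        )
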
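"""Gene filtering, count normalization and clustering feature construction.

The chain is raw counts -> zero-fraction gene filter -> median-of-ratios
log2 normalization -> top-variance gene selection with per-gene z-scoring.
Genes with a zero count in strictly more than ``max_zero_fraction`` of the
cohort's samples are dropped before normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    max_zero_fraction : genes with zeros in strictly more than this
        fraction of samples are removed (default 0.10).
    pseudocount : added inside the log2 after size-factor division.
    n_variable_genes : number of top-variance genes kept for clustering.
    """

    max_zero_fraction: float = 0.10
    pseudocount: float = 1.0
    n_variable_genes: int = 5000

    def __post_init__(self) -> None:
        if not 0 <= self.max_zero_fraction <= 1:
            raise ValueError("max_zero_fraction must lie in [0, 1]")
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be positive")
        if self.n_variable_genes < 2:
            raise ValueError("n_variable_genes must be >= 2")


def filter_low_expressed_genes(em: ExpressionMatrix,
                               cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Drop genes whose zero fraction exceeds the threshold (strictly)."""
    cfg = cfg or PreprocessConfig()
    if em.scale != "raw_counts":
        raise ValueError("zero-fraction filter applies to raw counts")
    zero_frac = (em.values.to_numpy() == 0).mean(axis=1)
    keep = zero_frac <= cfg.max_zero_fraction
    if not keep.any():
        raise ValueError(
            "zero-fraction filter removed every gene; raise max_zero_fraction"
        )
    return em.with_values(em.values.loc[keep], "raw_counts")


def size_factors(counts: pd.DataFrame, min_reference_genes: int = 50) -> pd.Series:
    """Median-of-ratios size factors (library-size fallback).

    The reference for each gene is its geometric mean across samples,
    computed on genes with no zero count anywhere. When fewer than
    ``min_reference_genes`` such genes exist, per-sample library sizes
    divided by their mean are used instead.
    """
    arr = counts.to_numpy(dtype=float)
    all_zero = arr.sum(axis=0) == 0
    if all_zero.any():
        bad = counts.columns[all_zero][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    nonzero = (arr > 0).all(axis=1)
    if nonzero.sum() >= min_reference_genes:
        ref = np.exp(np.log(arr[nonzero]).mean(axis=1, keepdims=True))
        sf = np.median(arr[nonzero] / ref, axis=0)
    else:
        log.info("fewer than %d all-nonzero genes; using library-size factors",
                 min_reference_genes)
        lib = arr.sum(axis=0)
        sf = lib / lib.mean()
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_log(em: ExpressionMatrix,
                  cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount) per cell."""
    cfg = cfg or PreprocessConfig()
    if em.scale != "raw_counts":
        raise ValueError("normalize_log expects raw counts")
    if em.n_samples < 2:
        raise ValueError("normalization needs >= 2 samples")
    sf = size_factors(em.values)
    norm = np.log2(em.values / sf + cfg.pseudocount)
    return em.with_values(norm, "log_normalized")


def prepare_clustering_matrix(em: ExpressionMatrix,
                              cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Top-variance gene selection followed by per-gene z-scoring."""
    cfg = cfg or PreprocessConfig()
    if em.scale != "log_normalized":
        raise ValueError("prepare_clustering_matrix expects log-normalized values")
    if em.n_genes < 2 or em.n_samples < 3:
        raise ValueError("need >= 2 genes and >= 3 samples")
    arr = em.values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    variable = sd > 0
    if not variable.any():
        raise ValueError("all genes are constant; nothing to cluster on")
    var_idx = np.flatnonzero(variable)
    order = var_idx[np.argsort(arr.var(axis=1, ddof=1)[var_idx], kind="stable")[::-1]]
    keep = np.sort(order[: min(cfg.n_variable_genes, len(order))])  # preserve gene order
    sub = arr[keep]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
    zdf = pd.DataFrame(z, index=em.values.index[keep], columns=em.values.columns)
    return em.with_values(zdf, "zscored")
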
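"""Differential expression between subtypes with cross-cohort meta-analysis.

Per cohort, each gene's effect is the difference of group means on the
log2-normalized scale (primitive minus committed) with a Welch standard
error. Cohort effects are then combined by fixed-effect inverse-variance
weighting; two-sided normal p-values are Benjamini-Hochberg adjusted.
The cross-cohort combination is the step of interest here; the per-cohort
estimator is a deliberately simple Welch contrast on normalized values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

SE_FLOOR = 1e-8


def per_cohort_effect(em_log: ExpressionMatrix, subtypes: pd.Series) -> pd.DataFrame:
    """Per-gene (lfc, se) for primitive vs committed in one cohort.

    ``subtypes`` maps sample id -> {"primitive", "committed"}. Genes with
    zero variance in both groups get their standard error floored at
    ``SE_FLOOR`` and are flagged in the ``se_floored`` column.
    """
    if em_log.scale != "log_normalized":
        raise ValueError("per_cohort_effect expects log-normalized values")
    subtypes = subtypes[subtypes.index.isin(em_log.sample_ids)]
    prim = subtypes.index[subtypes == "primitive"]
    comm = subtypes.index[subtypes == "committed"]
    for name, grp in (("primitive", prim), ("committed", comm)):
        if len(grp) == 0:
            raise ValueError(f"cohort {em_log.cohort_id!r} has no {name} samples")
        if len(grp) < 3:
            raise ValueError(
                f"cohort {em_log.cohort_id!r} has < 3 {name} samples"
            )
    a = em_log.values[list(prim)].to_numpy(dtype=float)
    b = em_log.values[list(comm)].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    floored = se < SE_FLOOR
    se = np.maximum(se, SE_FLOOR)
    if floored.any():
        log.info("%s: %d gene(s) with zero variance in both groups; "
                 "SE floored at %g", em_log.cohort_id, int(floored.sum()), SE_FLOOR)
    return pd.DataFrame(
        {"lfc": lfc, "se": se, "se_floored": floored},
        index=em_log.values.index,
    )


def meta_combine(lfc: np.ndarray, se: np.ndarray):
    """Fixed-effect inverse-variance combination of one gene's effects.

    ``lfc``/``se`` are per-cohort values (NaN where the cohort lacks the
    gene). Returns (meta_estimate, meta_se, z, p).
    """
    lfc = np.asarray(lfc, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(lfc) & np.isfinite(se)
    if not ok.any():
        raise ValueError("no cohort contributes to this gene")
    if (se[ok] <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / se[ok] ** 2
    est = float(np.sum(w * lfc[ok]) / np.sum(w))
    mse = float(np.sqrt(1.0 / np.sum(w)))
    z = est / mse
    p = float(2.0 * stats.norm.sf(abs(z)))
    return est, mse, z, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def differential_expression_meta(effects: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-cohort effect tables into the meta DE table.

    ``effects`` maps cohort_id -> output of :func:`per_cohort_effect`.
    Genes absent from some cohorts are combined over the cohorts that have
    them; genes absent everywhere cannot occur by construction.
    """
    cohorts = sorted(effects)
    genes: list = []
    seen = set()
    for c in cohorts:
        for g in effects[c].index:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    L = np.full((len(genes), len(cohorts)), np.nan)
    S = np.full((len(genes), len(cohorts)), np.nan)
    gi = {g: i for i, g in enumerate(genes)}
    for j, c in enumerate(cohorts):
        tab = effects[c]
        rows = [gi[g] for g in tab.index]
        L[rows, j] = tab["lfc"].to_numpy()
        S[rows, j] = tab["se"].to_numpy()
    ok = np.isfinite(L) & np.isfinite(S)
    W = np.where(ok, 1.0 / np.where(ok, S, 1.0) ** 2, 0.0)
    wsum = W.sum(axis=1)
    est = (W * np.where(ok, L, 0.0)).sum(axis=1) / wsum
    mse = np.sqrt(1.0 / wsum)
    z = est / mse
    p = 2.0 * stats.norm.sf(np.abs(z))
    partial = ok.sum(axis=1) < len(cohorts)
    if partial.any():
        log.info("%d gene(s) absent from >= 1 cohort; combined over the "
                 "available cohorts", int(partial.sum()))
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for j, c in enumerate(cohorts):
        out[f"lfc_{c}"] = L[:, j]
        out[f"se_{c}"] = S[:, j]
    out["n_cohorts"] = ok.sum(axis=1)
    out["meta_estimate"] = est
    out["meta_se"] = mse
    out["z"] = z
    out["p"] = p
    out["q"] = bh_adjust(p)
    return out
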
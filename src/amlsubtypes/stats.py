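"""Survival and association statistics used to characterize the subtypes.

Kaplan-Meier curves and the log-rank test compare overall survival between
the primitive and committed groups; the Wilcoxon rank-sum test compares
drug AUC_d distributions; Matthews correlation and AUPRC quantify how well
a binary mutation flag predicts the subtype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from sklearn.metrics import average_precision_score


@dataclass
class SurvivalRecord:
    time: float          # days
    event: int           # 1 = death observed, 0 = censored
    group: str           # "primitive" | "committed"

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"invalid survival time {self.time}")
        if self.event not in (0, 1):
            raise ValueError("event must be 0/1")
        if not self.group:
            raise ValueError("group must be non-missing")


@dataclass
class BinaryAssociationResult:
    mcc: float
    auprc: float
    contingency: np.ndarray  # [[TN, FP], [FN, TP]]


# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y, mode: str = "auto", exact_max_n: int = 12):
    """Two-sided Wilcoxon / Mann-Whitney rank-sum test.

    Exact enumeration when the combined sample is small (<= ``exact_max_n``)
    and tie-free; otherwise the normal approximation with midranks, tie
    correction and continuity correction. Returns (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "auto":
        mode = "exact" if (len(x) + len(y) <= exact_max_n and not ties) else "normal"
    if mode == "exact" and ties:
        raise ValueError("exact mode is undefined with ties; use normal")
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------

def km_curve(records: list[SurvivalRecord]):
    """Product-limit survival estimate for one group.

    Returns (times, survival probabilities); the curve starts at S(0) = 1
    and only drops at observed event times.
    """
    if not records:
        raise ValueError("no survival records")
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(records: list[SurvivalRecord]):
    """Two-group log-rank test. Returns (chi2 statistic, p, df=1)."""
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    if sum(r.event for r in records) == 0:
        raise ValueError("no events observed")
    a = [r for r in records if r.group == groups[0]]
    b = [r for r in records if r.group == groups[1]]
    res = _ll_logrank(
        np.array([r.time for r in a]), np.array([r.time for r in b]),
        event_observed_A=np.array([r.event for r in a]),
        event_observed_B=np.array([r.event for r in b]),
    )
    return float(res.test_statistic), float(res.p_value), 1


# ---------------------------------------------------------------------------

def _drop_missing_pairs(a, b):
    a = pd.Series(a).to_numpy(dtype=float)
    b = pd.Series(b).to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def matthews_cc(binary_a, binary_b) -> BinaryAssociationResult:
    """Matthews correlation of two binary vectors (missing pairs dropped)."""
    a, b = _drop_missing_pairs(binary_a, binary_b)
    if len(a) == 0:
        raise ValueError("no complete pairs")
    a = a.astype(int)
    b = b.astype(int)
    tp = int(np.sum((a == 1) & (b == 1)))
    tn = int(np.sum((a == 0) & (b == 0)))
    fp = int(np.sum((a == 0) & (b == 1)))
    fn = int(np.sum((a == 1) & (b == 0)))
    table = np.array([[tn, fp], [fn, tp]])
    margins = [tp + fp, tp + fn, tn + fp, tn + fn]
    if 0 in margins:
        raise ValueError("a margin of the 2x2 table is zero; MCC undefined")
    mcc = (tp * tn - fp * fn) / np.sqrt(float(margins[0]) * margins[1]
                                        * margins[2] * margins[3])
    return BinaryAssociationResult(mcc=float(mcc), auprc=np.nan, contingency=table)


def au_prc(scores, binary_labels) -> BinaryAssociationResult:
    """Area under the precision-recall curve by the step-wise rule.

    Tied scores are grouped at a single threshold; the area is the sum of
    precision x recall-increment rectangles over descending thresholds.
    """
    s, y = _drop_missing_pairs(scores, binary_labels)
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    auprc = float(average_precision_score(y, s))
    return BinaryAssociationResult(mcc=np.nan, auprc=auprc,
                                   contingency=np.zeros((2, 2), dtype=int))


def mutation_subtype_association(flags: pd.Series, subtype: pd.Series
                                 ) -> BinaryAssociationResult:
    """MCC and AUPRC of one mutation flag against the subtype call.

    ``flags``: 0/1/NaN per sample (NaN = unassayed, dropped);
    ``subtype``: "primitive"/"committed" per sample. The flag plays the
    score role for AUPRC with primitive as the positive class.
    """
    common = flags.index.intersection(subtype.index)
    f = flags.loc[common]
    s = (subtype.loc[common] == "primitive").astype(int)
    mcc = matthews_cc(s, f)
    prc = au_prc(f, s)
    return BinaryAssociationResult(mcc=mcc.mcc, auprc=prc.auprc,
                                   contingency=mcc.contingency)
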
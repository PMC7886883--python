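"""Dose-response fitting, subtype transfer, and concordance-index drug ranking.

Viability curves are fitted to the two-parameter Hill equation

    y(x) = 1 / (1 + (x / EC50)^H)

in log10-concentration space; the drug response summary AUC_d is the area
under the fitted viability curve over the tested log10 range, normalized to
[0, 1] (lower AUC_d = more sensitive). An elastic-net logistic model trained
on patient subtypes is transferred to a cell-line panel, and drugs are
ranked by the concordance index between predicted primitive probability and
AUC_d, with a permutation null and BH correction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .demeta import bh_adjust
from .io import DoseResponseRecord
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

LN10 = np.log(10.0)
VIABILITY_CEILING = 1.2


# ---------------------------------------------------------------------------
# Hill curve
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseCurve:
    """Fitted Hill curve for one (sample, drug) pair."""

    sample_id: str
    drug_id: str
    concentrations: np.ndarray          # µM, ascending
    viabilities: np.ndarray             # replicate-averaged fractions
    ec50: float                          # µM
    hill: float
    rss: float
    auc_d: float = np.nan
    fit_status: str = "ok"               # ok | degenerate_flat | boundary

    def predict(self, x: np.ndarray) -> np.ndarray:
        return hill_curve(np.asarray(x, dtype=float), self.ec50, self.hill)


def hill_curve(x: np.ndarray, ec50: float, h: float) -> np.ndarray:
    """Viability y = 1 / (1 + (x / EC50)^H), evaluated stably in log space."""
    t = h * (np.log10(x) - np.log10(ec50))
    # 1/(1+10^t) = expit(-t ln10)
    from scipy.special import expit
    return expit(-t * LN10)


def _average_replicates(records: list[DoseResponseRecord]):
    by_conc: dict = {}
    for r in records:
        by_conc.setdefault(r.concentration, []).append(r.viability)
    x = np.array(sorted(by_conc))
    y = np.array([np.mean(by_conc[c]) for c in x])
    return x, y


def fit_hill(records: list[DoseResponseRecord]) -> DoseResponseCurve:
    """Least-squares Hill fit in log10-concentration space.

    Replicates are averaged per concentration first. The optimizer starts
    from the best cell of a 20 x 20 grid over log10(EC50) in
    [log10(x_min) - 2, log10(x_max) + 2] and H in [0.1, 10], then refines
    with bounded least squares. A fit explaining < 5% of the variance of
    the data relative to a flat line is flagged ``degenerate_flat``.
    """
    if not records:
        raise ValueError("no dose-response records")
    sample_id, drug_id = records[0].sample_id, records[0].drug_id
    x, y = _average_replicates(records)
    if len(x) < 4:
        raise ValueError(
            f"{sample_id}/{drug_id}: need >= 4 distinct concentrations, got {len(x)}"
        )
    if (y > VIABILITY_CEILING).any():
        warnings.warn(
            f"{sample_id}/{drug_id}: viabilities > {VIABILITY_CEILING} "
            "clipped", stacklevel=2)
        y = np.minimum(y, VIABILITY_CEILING)

    u = np.log10(x)
    lo, hi = u.min() - 2.0, u.max() + 2.0
    sst = float(np.sum((y - y.mean()) ** 2))

    def resid(p):
        u0, h = p
        from scipy.special import expit
        return expit(-h * (u - u0) * LN10) - y

    # grid start over (log10 EC50, H)
    grid_u0 = np.linspace(lo, hi, 20)
    grid_h = np.linspace(0.1, 10.0, 20)
    from scipy.special import expit
    T = grid_h[:, None, None] * (u[None, None, :] - grid_u0[None, :, None])
    sse = ((expit(-T * LN10) - y[None, None, :]) ** 2).sum(axis=2)
    ih, iu = np.unravel_index(np.argmin(sse), sse.shape)
    p0 = (grid_u0[iu], grid_h[ih])

    sol = least_squares(resid, p0, bounds=([lo, 0.1], [hi, 10.0]))
    u0, h = sol.x
    rss = float(np.sum(sol.fun ** 2))
    status = "ok"
    if sst <= 0 or 1.0 - rss / sst < 0.05:
        status = "degenerate_flat"
        u0 = hi if y.mean() >= 0.5 else lo  # flat-high -> EC50 beyond range
    elif np.isclose(u0, lo) or np.isclose(u0, hi):
        status = "boundary"
    return DoseResponseCurve(
        sample_id=sample_id, drug_id=drug_id, concentrations=x, viabilities=y,
        ec50=float(10.0 ** u0), hill=float(h), rss=rss, fit_status=status,
    )


def compute_auc(curve: DoseResponseCurve | None, u_range: tuple[float, float],
                records: list[DoseResponseRecord] | None = None,
                mode: str = "fitted") -> float:
    """Normalized area under the viability curve over ``u_range`` (log10 µM).

    ``fitted`` mode integrates the Hill curve in closed form:
    int expit(-H ln10 (u - u0)) du = Du - [softplus] / (H ln10).
    ``raw`` mode applies the trapezoid rule to replicate-averaged points.
    Higher AUC_d = more viable = more resistant.
    """
    u_min, u_max = u_range
    if not u_max > u_min:
        raise ValueError("u_max must exceed u_min")
    width = u_max - u_min
    if mode == "raw":
        if records is None:
            raise ValueError("raw mode needs records")
        x, y = _average_replicates(records)
        u = np.log10(x)
        auc = float(np.trapezoid(y, u)) / width
    else:
        if curve is None:
            raise ValueError("fitted mode needs a curve")
        h, u0 = curve.hill, np.log10(curve.ec50)
        t_lo = h * LN10 * (u_min - u0)
        t_hi = h * LN10 * (u_max - u0)
        integral = width - (np.logaddexp(0.0, t_hi) - np.logaddexp(0.0, t_lo)) / (h * LN10)
        auc = float(integral) / width
    return float(np.clip(auc, 0.0, 1.0))


def fit_drug_panel(records: list[DoseResponseRecord],
                   auc_mode: str = "fitted") -> pd.DataFrame:
    """Fit every (sample, drug) group and tabulate EC50, H and AUC_d."""
    groups: dict = {}
    for r in records:
        groups.setdefault((r.sample_id, r.drug_id), []).append(r)
    rows = []
    for (sample_id, drug_id), recs in groups.items():
        curve = fit_hill(recs)
        u = np.log10(curve.concentrations)
        curve.auc_d = compute_auc(curve, (u.min(), u.max()),
                                  records=recs, mode=auc_mode)
        rows.append((sample_id, drug_id, curve.ec50, curve.hill,
                     curve.auc_d, curve.rss, curve.fit_status))
    return pd.DataFrame(rows, columns=["sample_id", "drug_id", "ec50_uM",
                                       "hill", "auc_d", "rss", "fit_status"])


# ---------------------------------------------------------------------------
# feature harmonization and elastic-net transfer
# ---------------------------------------------------------------------------

def harmonize_features(train: ExpressionMatrix, test: ExpressionMatrix,
                       min_shared: int = 50):
    """Align two cohorts on their gene intersection, z-scoring per dataset.

    Genes constant in either dataset are dropped from both (logged).
    Returns the two matrices gene-aligned and per-gene standardized.
    """
    shared = [g for g in train.gene_ids if g in set(test.gene_ids)]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared genes between {train.cohort_id!r} "
            f"and {test.cohort_id!r} (need >= {min_shared})")
    a = train.values.loc[shared].to_numpy(dtype=float)
    b = test.values.loc[shared].to_numpy(dtype=float)
    ok = (a.std(axis=1) > 0) & (b.std(axis=1) > 0)
    if not ok.all():
        dropped = [g for g, keep in zip(shared, ok) if not keep]
        log.info("dropping %d constant gene(s) during harmonization: %s...",
                 len(dropped), dropped[:5])
        shared = [g for g, keep in zip(shared, ok) if keep]
        a, b = a[ok], b[ok]
    if len(shared) < min_shared:
        raise ValueError("fewer than the minimum shared genes after "
                         "dropping constant genes")

    def _z(m):
        return (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, ddof=1, keepdims=True)

    za = ExpressionMatrix(train.cohort_id,
                          pd.DataFrame(_z(a), index=shared, columns=train.sample_ids),
                          "zscored")
    zb = ExpressionMatrix(test.cohort_id,
                          pd.DataFrame(_z(b), index=shared, columns=test.sample_ids),
                          "zscored")
    return za, zb


class ElasticNetSubtypeClassifier(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic regression with CV over mixing and penalty.

    ``fit(X, y)`` takes samples x genes features and binary labels
    (1 = primitive). The mixing parameter alpha (1 = lasso, 0 = ridge) and
    penalty strength lambda are chosen to minimize mean cross-validated
    binomial deviance over stratified, seeded folds, warm-starting down a
    per-alpha lambda path; the winning pair is refit on all data.
    Features are standardized internally using training-set statistics.

    Parameters
    ----------
    alpha_grid : elastic-net mixing values to scan (default 0.1..1.0).
    n_lambdas : length of the log-spaced penalty path.
    lambda_min_ratio : smallest lambda as a fraction of the data-driven
        lambda_max (the smallest penalty that zeroes every coefficient
        at alpha = 1).
    cv : number of stratified folds.
    random_state : seed for fold assignment.
    """

    def __init__(self, alpha_grid=tuple(np.round(np.arange(0.1, 1.01, 0.1), 1)),
                 n_lambdas: int = 50, lambda_min_ratio: float = 1e-3,
                 cv: int = 10, random_state: int = 0, max_iter: int = 2000):
        self.alpha_grid = alpha_grid
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.random_state = random_state
        self.max_iter = max_iter

    def _lambda_path(self, X, y, alpha):
        n = len(y)
        resid = y - y.mean()
        lam_max = np.max(np.abs(X.T @ resid)) / (n * max(alpha, 1e-3))
        lam_max = max(lam_max, 1e-6)
        return np.geomspace(lam_max, lam_max * self.lambda_min_ratio,
                            self.n_lambdas)

    def fit(self, X, y, gene_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("need exactly two classes")
        counts = {c: int((y == c).sum()) for c in classes}
        if min(counts.values()) < self.cv:
            raise ValueError(
                f"each class needs >= {self.cv} members for {self.cv}-fold "
                f"stratified CV, got {counts}")
        self.classes_ = classes
        ybin = (y == classes[1]).astype(float)

        self.scaling_mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        self.scaling_sd_ = sd
        Z = (X - self.scaling_mean_) / self.scaling_sd_

        skf = StratifiedKFold(n_splits=self.cv, shuffle=True,
                              random_state=self.random_state)
        folds = list(skf.split(Z, ybin))
        n = len(ybin)
        cv_rows = []
        best = None
        for alpha in self.alpha_grid:
            lambdas = self._lambda_path(Z, ybin, alpha)
            dev = np.zeros(len(lambdas))
            for tr, te in folds:
                clf = LogisticRegression(
                    solver="saga", l1_ratio=float(alpha),
                    warm_start=True, max_iter=self.max_iter, tol=1e-4,
                    fit_intercept=True, C=1.0, random_state=self.random_state)
                for j, lam in enumerate(lambdas):
                    clf.C = 1.0 / (lam * len(tr))
                    clf.fit(Z[tr], ybin[tr])
                    prob = clf.predict_proba(Z[te])[:, 1]
                    dev[j] += 2.0 * log_loss(ybin[te], prob, labels=[0.0, 1.0],
                                             normalize=False)
            dev /= n
            for lam, d in zip(lambdas, dev):
                cv_rows.append((float(alpha), float(lam), float(d)))
            j = int(np.argmin(dev))
            if best is None or dev[j] < best[2]:
                best = (float(alpha), float(lambdas[j]), float(dev[j]))
        self.alpha_, self.lambda_, self.cv_deviance_ = best
        self.cv_table_ = pd.DataFrame(cv_rows,
                                      columns=["alpha", "lambda", "mean_cv_deviance"])
        final = LogisticRegression(
            solver="saga", l1_ratio=self.alpha_,
            C=1.0 / (self.lambda_ * n), max_iter=self.max_iter, tol=1e-4,
            random_state=self.random_state)
        final.fit(Z, ybin)
        self.coef_ = final.coef_.ravel()
        self.intercept_ = float(final.intercept_[0])
        self.gene_ids_ = list(gene_ids) if gene_ids is not None else None
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        Z = (np.asarray(X, dtype=float) - self.scaling_mean_) / self.scaling_sd_
        return Z @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        from scipy.special import expit
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return np.where(self.predict_proba(X)[:, 1] >= 0.5,
                        self.classes_[1], self.classes_[0])

    # -- plain-text serialization ----------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "gene_ids": self.gene_ids_,
            "coefficients": self.coef_.tolist(),
            "intercept": self.intercept_,
            "alpha": self.alpha_,
            "lambda": self.lambda_,
            "scaling_mean": self.scaling_mean_.tolist(),
            "scaling_sd": self.scaling_sd_.tolist(),
            "classes": [str(c) for c in self.classes_],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ElasticNetSubtypeClassifier":
        d = json.loads(text)
        obj = cls()
        obj.gene_ids_ = d["gene_ids"]
        obj.coef_ = np.array(d["coefficients"])
        obj.intercept_ = float(d["intercept"])
        obj.alpha_ = float(d["alpha"])
        obj.lambda_ = float(d["lambda"])
        obj.scaling_mean_ = np.array(d["scaling_mean"])
        obj.scaling_sd_ = np.array(d["scaling_sd"])
        obj.classes_ = np.array(d["classes"])
        obj.n_features_in_ = len(obj.coef_)
        return obj


def fit_elasticnet_classifier(X: np.ndarray, y, gene_ids=None, seed: int = 0,
                              **kwargs) -> ElasticNetSubtypeClassifier:
    """Functional wrapper over :class:`ElasticNetSubtypeClassifier`."""
    return ElasticNetSubtypeClassifier(random_state=seed, **kwargs).fit(
        X, y, gene_ids=gene_ids)


def predict_subtype_prob(model: ElasticNetSubtypeClassifier,
                         X: ExpressionMatrix | np.ndarray) -> pd.Series | np.ndarray:
    """Per-sample probability of the *primitive* class."""
    if isinstance(X, ExpressionMatrix):
        if model.gene_ids_ is None:
            raise ValueError("model carries no gene ids")
        missing = [g for g in model.gene_ids_ if g not in set(X.gene_ids)]
        if missing:
            raise ValueError(f"{len(missing)} model gene(s) absent from input, "
                             f"e.g. {missing[:5]}")
        arr = X.values.loc[model.gene_ids_].to_numpy(dtype=float).T
        return pd.Series(model.predict_proba(arr)[:, 1], index=X.sample_ids,
                         name="prob_primitive")
    return model.predict_proba(np.asarray(X))[:, 1]


# ---------------------------------------------------------------------------
# concordance index and drug ranking
# ---------------------------------------------------------------------------

def concordance_index(score, response) -> float:
    """Fraction of response-discordant pairs ordered concordantly by score.

    Pairs with equal responses are not comparable; score ties earn 0.5.
    """
    score = np.asarray(score, dtype=float)
    response = np.asarray(response, dtype=float)
    ok = np.isfinite(score) & np.isfinite(response)
    score, response = score[ok], response[ok]
    if len(score) < 2:
        raise ValueError("need >= 2 usable pairs")
    ds = np.sign(score[:, None] - score[None, :])
    dr = np.sign(response[:, None] - response[None, :])
    comparable = dr != 0
    iu = np.triu_indices(len(score), k=1)
    comp = comparable[iu]
    if not comp.any():
        raise ValueError("all responses tied; no comparable pairs")
    agree = (ds[iu] * dr[iu])[comp]
    credit = np.where(agree > 0, 1.0, np.where(agree < 0, 0.0, 0.5))
    return float(credit.mean())


@dataclass
class DrugAssociation:
    drug_id: str
    ci: float
    n: int
    p: float
    q: float = np.nan
    rank: int = 0
    direction: str = ""


def _ci_permutation_p(score, response, n_perm: int, rng) -> tuple[float, float]:
    """Observed CI and two-sided permutation p for its distance from 0.5."""
    ci_obs = concordance_index(score, response)
    score = np.asarray(score, dtype=float)
    response = np.asarray(response, dtype=float)
    n = len(score)
    i, j = np.triu_indices(n, k=1)
    dr = np.sign(response[i] - response[j])
    comp = dr != 0
    i, j, dr = i[comp], j[comp], dr[comp]
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    sp = score[perms]                       # (n_perm, n)
    ds = np.sign(sp[:, i] - sp[:, j])       # (n_perm, n_pairs)
    agree = ds * dr[None, :]
    credit = np.where(agree > 0, 1.0, np.where(agree < 0, 0.0, 0.5))
    ci_perm = credit.mean(axis=1)
    extreme = np.abs(ci_perm - 0.5) >= np.abs(ci_obs - 0.5) - 1e-12
    p = (1.0 + int(extreme.sum())) / (1.0 + n_perm)
    return ci_obs, p


def _ci_normal_p(score, response) -> tuple[float, float]:
    """Observed CI and a two-sided normal-approximation p.

    Uses the Kendall-tau null variance (tie-naive): under independence
    CI ~ N(0.5, (2n + 5) / (18 n (n - 1))).
    """
    from scipy.stats import norm
    ci = concordance_index(score, response)
    n = len(np.asarray(score))
    sd = np.sqrt((2 * n + 5) / (18.0 * n * (n - 1)))
    return ci, float(2.0 * norm.sf(abs(ci - 0.5) / sd))


def rank_drugs(probabilities: pd.Series, auc_table: pd.DataFrame,
               n_perm: int = 1000, seed: int = 0,
               min_lines: int = 10, p_method: str = "permutation"
               ) -> pd.DataFrame:
    """Rank drugs by subtype-probability / AUC_d concordance.

    ``probabilities``: per-cell-line primitive probability (pass hard 0/1
    labels here for a binary-label CI).
    ``auc_table``: columns sample_id, drug_id, auc_d.
    Each drug gets its CI, a two-sided p (seeded permutation null by
    default; ``p_method="normal"`` uses a tie-naive normal
    approximation), a BH q across drugs and a 1-based rank (ascending q,
    then |CI - 0.5| descending, then drug id). ``direction`` is
    ``sensitive_in_primitive`` when CI < 0.5 (higher primitive
    probability pairs with lower AUC_d).
    """
    drugs = sorted(auc_table["drug_id"].unique())
    if len(drugs) < 2:
        raise ValueError("need >= 2 drugs to rank")
    ss = np.random.SeedSequence(seed)
    rows = []
    for drug, child in zip(drugs, ss.spawn(len(drugs))):
        sub = auc_table[auc_table["drug_id"] == drug]
        sub = sub[sub["sample_id"].isin(probabilities.index)]
        if len(sub) < min_lines:
            raise ValueError(f"drug {drug!r} screened on {len(sub)} "
                             f"cell lines (need >= {min_lines})")
        score = probabilities.loc[sub["sample_id"]].to_numpy()
        resp = sub["auc_d"].to_numpy()
        if p_method == "normal":
            ci, p = _ci_normal_p(score, resp)
        else:
            ci, p = _ci_permutation_p(score, resp, n_perm,
                                      np.random.default_rng(child))
        rows.append((drug, ci, len(sub), p))
    out = pd.DataFrame(rows, columns=["drug_id", "ci", "n", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["ci"] < 0.5, "sensitive_in_primitive",
                                "resistant_in_primitive")
    order = out.assign(dist=-(out["ci"] - 0.5).abs()).sort_values(
        ["q", "dist", "drug_id"]).index
    out = out.loc[order].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
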
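import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from amlsubtypes import (
    DoseResponseRecord, ElasticNetSubtypeClassifier, ExpressionMatrix,
    compute_auc, concordance_index, fit_hill, harmonize_features, hill_curve,
    predict_subtype_prob, rank_drugs,
)
from amlsubtypes.pharmaco import fit_drug_panel


def _records(x, y, sample="p1", drug="d1"):
    return [DoseResponseRecord(sample, drug, float(c), float(v), 1)
            for c, v in zip(x, y)]


class TestHillFit:
    @pytest.mark.parametrize("ec50,h", [(1.0, 1.0), (0.2, 2.5), (5.0, 0.8)])
    def test_noiseless_curve_recovered(self, ec50, h):
        x = np.logspace(-2, 2, 10)
        curve = fit_hill(_records(x, hill_curve(x, ec50, h)))
        assert curve.ec50 == pytest.approx(ec50, rel=1e-4)
        assert curve.hill == pytest.approx(h, rel=1e-4)
        assert curve.fit_status == "ok"

    def test_half_maximal_at_ec50_for_any_h(self):
        for h in (0.3, 1.0, 4.0, 9.0):
            x = np.logspace(-2, 2, 10)
            curve = fit_hill(_records(x, hill_curve(x, 0.7, h)))
            assert curve.predict(np.array([curve.ec50]))[0] == pytest.approx(0.5)

    def test_constant_viability_is_degenerate_flat(self):
        x = np.logspace(-2, 2, 10)
        curve = fit_hill(_records(x, np.ones(10)))
        assert curve.fit_status == "degenerate_flat"

    def test_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_hill(_records([0.1, 1.0, 10.0], [1.0, 0.5, 0.1]))

    def test_high_viability_clipped_with_warning(self):
        x = np.logspace(-2, 2, 10)
        y = hill_curve(x, 1.0, 1.0)
        y[0] = 1.5
        with pytest.warns(UserWarning, match="clip"):
            curve = fit_hill(_records(x, y))
        assert curve.viabilities.max() <= 1.2

    def test_replicates_averaged_before_fit(self):
        x = np.logspace(-1.2, 1.2, 10)
        y = hill_curve(x, 1.0, 1.0)
        recs = (_records(x, y + 0.04) + [DoseResponseRecord("p1", "d1",
                float(c), float(v - 0.04), 2) for c, v in zip(x, y)])
        curve = fit_hill(recs)
        assert curve.ec50 == pytest.approx(1.0, rel=1e-3)

    def test_fitted_curve_strictly_decreasing(self):
        x = np.logspace(-2, 2, 10)
        curve = fit_hill(_records(x, hill_curve(x, 1.0, 1.5)))
        grid = np.logspace(-3, 3, 200)
        assert (np.diff(curve.predict(grid)) < 0).all()


class TestAUC:
    def test_constant_viability_one_gives_auc_one(self):
        x = np.logspace(-2, 2, 10)
        auc = compute_auc(None, (-2, 2), records=_records(x, np.ones(10)),
                          mode="raw")
        assert auc == pytest.approx(1.0)

    def test_steep_hill_approaches_step_function_fraction(self):
        # H = 10, EC50 mid-range: area ~ fraction of log-range left of EC50
        curve = fit_hill(_records(np.logspace(-2, 2, 12),
                                  hill_curve(np.logspace(-2, 2, 12), 1.0, 10.0)))
        auc = compute_auc(curve, (-2, 2))
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_closed_form_matches_numerical_quadrature(self):
        for ec50, h, rng in [(1.0, 1.0, (-2, 2)), (0.3, 2.2, (-3, 1)),
                             (4.0, 0.5, (-1, 3))]:
            curve = fit_hill(_records(np.logspace(rng[0], rng[1], 10),
                                      hill_curve(np.logspace(rng[0], rng[1], 10),
                                                 ec50, h)))
            numeric = quad(lambda u: hill_curve(10.0**u, curve.ec50, curve.hill),
                           rng[0], rng[1], epsabs=1e-10)[0] / (rng[1] - rng[0])
            assert compute_auc(curve, rng) == pytest.approx(numeric, abs=1e-6)

    def test_log_translation_invariance(self):
        x = np.logspace(-2, 2, 10)
        c1 = fit_hill(_records(x, hill_curve(x, 1.0, 1.3)))
        c2 = fit_hill(_records(10 * x, hill_curve(10 * x, 10.0, 1.3)))
        assert compute_auc(c1, (-2, 2)) == pytest.approx(
            compute_auc(c2, (-1, 3)), abs=1e-9)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="u_max"):
            compute_auc(None, (2, 2), records=[], mode="raw")


class TestHarmonize:
    def _em(self, arr, cohort, genes):
        cols = [f"{cohort}_s{j}" for j in range(arr.shape[1])]
        return ExpressionMatrix(cohort, pd.DataFrame(arr, index=genes,
                                                     columns=cols),
                                "log_normalized")

    def test_identical_gene_sets_aligned_and_zscored(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(60)]
        a = self._em(rng.normal(size=(60, 10)), "a", genes)
        b = self._em(rng.normal(size=(60, 8)), "b", list(reversed(genes)))
        za, zb = harmonize_features(a, b)
        assert za.gene_ids == zb.gene_ids
        np.testing.assert_allclose(za.values.to_numpy().mean(axis=1), 0,
                                   atol=1e-12)
        np.testing.assert_allclose(zb.values.to_numpy().std(axis=1, ddof=1), 1,
                                   atol=1e-12)

    def test_disjoint_gene_sets_rejected(self):
        rng = np.random.default_rng(1)
        a = self._em(rng.normal(size=(60, 5)), "a", [f"g{i}" for i in range(60)])
        b = self._em(rng.normal(size=(60, 5)), "b", [f"h{i}" for i in range(60)])
        with pytest.raises(ValueError, match="shared"):
            harmonize_features(a, b)

    def test_constant_gene_dropped_from_both(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(60)]
        arr_a = rng.normal(size=(60, 6))
        arr_b = rng.normal(size=(60, 6))
        arr_b[3] = 7.0  # constant in the test panel
        a = self._em(arr_a, "a", genes)
        b = self._em(arr_b, "b", genes)
        za, zb = harmonize_features(a, b)
        assert "g3" not in za.gene_ids
        assert "g3" not in zb.gene_ids


class TestElasticNet:
    def _separable(self, n=60, p=20, seed=0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        X = rng.normal(size=(n, p))
        X[:, 0] = y * 3.0 + rng.normal(0, 0.3, n)
        return X, y

    def test_perfectly_separating_gene_classifies_fresh_draws(self):
        X, y = self._separable(seed=0)
        clf = ElasticNetSubtypeClassifier(alpha_grid=(0.5,), n_lambdas=10,
                                          cv=5, random_state=0).fit(X, y)
        Xt, yt = self._separable(seed=99)
        assert (clf.predict(Xt) == yt).mean() == 1.0

    def test_strong_penalty_gives_null_model_predicting_prevalence(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 15))
        y = np.r_[np.zeros(20), np.ones(40)].astype(int)   # prevalence 2/3
        clf = ElasticNetSubtypeClassifier(alpha_grid=(1.0,), n_lambdas=3,
                                          lambda_min_ratio=1.0, cv=5,
                                          random_state=0).fit(X, y)
        assert np.abs(clf.coef_).max() < 1e-6
        prob = clf.predict_proba(rng.normal(size=(5, 15)))[:, 1]
        np.testing.assert_allclose(prob, 2 / 3, atol=0.02)

    def test_same_seed_reproduces_model_exactly(self):
        X, y = self._separable(seed=1)
        kw = dict(alpha_grid=(0.2, 0.8), n_lambdas=8, cv=4, random_state=7)
        a = ElasticNetSubtypeClassifier(**kw).fit(X, y)
        b = ElasticNetSubtypeClassifier(**kw).fit(X, y)
        assert (a.alpha_, a.lambda_) == (b.alpha_, b.lambda_)
        np.testing.assert_array_equal(a.coef_, b.coef_)

    def test_single_class_rejected(self):
        X = np.zeros((20, 3))
        with pytest.raises(ValueError, match="two classes"):
            ElasticNetSubtypeClassifier(cv=3).fit(X, np.zeros(20))

    def test_json_round_trip_preserves_predictions(self):
        X, y = self._separable(seed=2)
        clf = ElasticNetSubtypeClassifier(alpha_grid=(0.5,), n_lambdas=5,
                                          cv=5, random_state=0).fit(
            X, y, gene_ids=[f"g{i}" for i in range(X.shape[1])])
        back = ElasticNetSubtypeClassifier.from_json(clf.to_json())
        np.testing.assert_allclose(back.predict_proba(X), clf.predict_proba(X))

    def test_probability_symmetry_with_zero_intercept(self):
        clf = ElasticNetSubtypeClassifier()
        clf.coef_ = np.array([1.0, -2.0])
        clf.intercept_ = 0.0
        clf.scaling_mean_ = np.zeros(2)
        clf.scaling_sd_ = np.ones(2)
        x = np.array([[0.5, 1.5]])
        p = clf.predict_proba(x)[:, 1] + clf.predict_proba(-x)[:, 1]
        assert p[0] == pytest.approx(1.0)

    def test_expression_matrix_prediction_requires_model_genes(self):
        X, y = self._separable(seed=4)
        genes = [f"g{i}" for i in range(X.shape[1])]
        clf = ElasticNetSubtypeClassifier(alpha_grid=(0.5,), n_lambdas=5,
                                          cv=5).fit(X, y, gene_ids=genes)
        em = ExpressionMatrix("t", pd.DataFrame(
            X[:5].T, index=genes, columns=[f"s{i}" for i in range(5)]),
            "zscored")
        prob = predict_subtype_prob(clf, em)
        assert ((prob > 0) & (prob < 1)).all()
        with pytest.raises(ValueError, match="absent"):
            predict_subtype_prob(clf, em.subset_genes(genes[:10]))


def brute_force_ci(score, response):
    credit = n_pairs = 0.0
    for i in range(len(score)):
        for j in range(i + 1, len(score)):
            if response[i] == response[j]:
                continue
            n_pairs += 1
            if score[i] == score[j]:
                credit += 0.5
            elif (score[i] > score[j]) == (response[i] > response[j]):
                credit += 1.0
    return credit / n_pairs


class TestConcordanceIndex:
    def test_perfect_and_reversed_orderings(self):
        s = np.arange(6, dtype=float)
        assert concordance_index(s, s) == 1.0
        assert concordance_index(s, -s) == 0.0

    def test_tied_scores_match_pairwise_enumeration(self):
        score = np.array([0.1, 0.4, 0.4, 0.8, 0.2, 0.9])
        resp = np.array([1.0, 3.0, 2.0, 5.0, 1.5, 4.0])
        assert concordance_index(score, resp) == pytest.approx(
            brute_force_ci(score, resp))

    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
                    min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_and_complement_identity(self, pairs):
        score = np.array([a for a, _ in pairs])
        resp = np.array([b for _, b in pairs])
        if len(np.unique(resp)) < 2:
            return
        ci = concordance_index(score, resp)
        assert ci == pytest.approx(brute_force_ci(score, resp))
        if len(np.unique(score)) == len(score):
            assert ci + concordance_index(-score, resp) == pytest.approx(1.0)

    def test_all_tied_responses_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            concordance_index([1.0, 2.0], [3.0, 3.0])


class TestRankDrugs:
    def _panel(self, seed=0, n_lines=40):
        rng = np.random.default_rng(seed)
        prob = pd.Series(rng.uniform(0, 1, n_lines),
                         index=[f"cl{i}" for i in range(n_lines)])
        rows = []
        for drug, effect in [("hit", -0.4), ("null1", 0.0), ("null2", 0.0)]:
            auc = (0.55 + rng.normal(0, 0.05, n_lines)
                   + effect * (prob.to_numpy() - 0.5))
            rows += [(s, drug, a) for s, a in zip(prob.index, auc)]
        return prob, pd.DataFrame(rows, columns=["sample_id", "drug_id", "auc_d"])

    def test_planted_drug_ranks_first_with_direction(self):
        prob, table = self._panel()
        ranking = rank_drugs(prob, table, n_perm=300, seed=0)
        top = ranking.iloc[0]
        assert top["drug_id"] == "hit"
        assert top["direction"] == "sensitive_in_primitive"
        assert top["q"] < 0.05
        assert list(ranking["rank"]) == [1, 2, 3]

    def test_permutation_p_lower_bound(self):
        prob, table = self._panel(seed=1)
        ranking = rank_drugs(prob, table, n_perm=200, seed=0)
        assert (ranking["p"] >= 1 / 201 - 1e-12).all()

    def test_deterministic_given_seed(self):
        prob, table = self._panel(seed=2)
        r1 = rank_drugs(prob, table, n_perm=100, seed=5)
        r2 = rank_drugs(prob, table, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_normal_approximation_p_agrees_with_permutation(self):
        prob, table = self._panel(seed=4, n_lines=50)
        perm = rank_drugs(prob, table, n_perm=2000, seed=0)
        norm = rank_drugs(prob, table, p_method="normal")
        merged = perm.merge(norm, on="drug_id", suffixes=("_perm", "_norm"))
        # the strong hit is significant under both nulls, the nulls not
        hit = merged[merged["drug_id"] == "hit"].iloc[0]
        assert hit["p_perm"] < 0.01 and hit["p_norm"] < 0.01
        nulls = merged[merged["drug_id"] != "hit"]
        assert (nulls["p_norm"] > 0.05).all() == (nulls["p_perm"] > 0.05).all()

    def test_too_few_lines_rejected(self):
        prob, table = self._panel(n_lines=5)
        with pytest.raises(ValueError, match="cell lines"):
            rank_drugs(prob, table, n_perm=50, seed=0)


class TestDrugPanelTable:
    def test_fit_drug_panel_tabulates_all_pairs(self):
        x = np.logspace(-2, 2, 10)
        recs = (_records(x, hill_curve(x, 1.0, 1.0), "s1", "d1")
                + _records(x, hill_curve(x, 0.1, 2.0), "s1", "d2")
                + _records(x, hill_curve(x, 5.0, 1.0), "s2", "d1"))
        tab = fit_drug_panel(recs)
        assert len(tab) == 3
        # lower EC50 within the same dose range -> lower AUC (more sensitive)
        auc = tab.set_index(["sample_id", "drug_id"])["auc_d"]
        assert auc[("s1", "d2")] < auc[("s1", "d1")] < auc[("s2", "d1")]
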
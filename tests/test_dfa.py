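"""Discriminant-analysis oracles: matrix-algebra equivalence, affine
invariance, permutation-null behavior."""

import numpy as np
import pandas as pd
import pytest

from vocalid import (fit_dfa, classify, classify_loo, wilks_contributions,
                     permutation_null, significance, gaussian_null_table,
                     SingularCovarianceError)
from vocalid.dfa import PermutationNull

VARS3 = ["v1", "v2", "v3"]


def toy_table(rng, k=3, n_per=8, p=3, sep=3.0):
    centers = rng.standard_normal((k, p)) * sep
    X = np.vstack([centers[g] + rng.standard_normal((n_per, p))
                   for g in range(k)])
    df = pd.DataFrame(X, columns=[f"v{j + 1}" for j in range(p)])
    df["individual_id"] = np.repeat([f"g{g}" for g in range(k)], n_per)
    return df


def brute_force_scores(df, variables):
    """Classification functions evaluated straight from their textbook
    definition: C_g = S^-1 m_g, c_g = -0.5 m_g' S^-1 m_g, with S the
    elementwise pooled within-group covariance."""
    groups = sorted(df["individual_id"].unique())
    X = df[variables].to_numpy()
    n, p = X.shape
    S = np.zeros((p, p))
    means = {}
    for g in groups:
        sub = X[df["individual_id"].to_numpy() == g]
        means[g] = sub.mean(axis=0)
        for row in sub:
            d = row - means[g]
            S += np.outer(d, d)
    S /= n - len(groups)
    Sinv = np.linalg.inv(S)
    scores = np.empty((n, len(groups)))
    for gi, g in enumerate(groups):
        C = Sinv @ means[g]
        c = -0.5 * means[g] @ Sinv @ means[g]
        scores[:, gi] = X @ C + c
    return scores


class TestFitClassify:
    def test_matches_brute_force_matrix_algebra(self, rng):
        df = toy_table(rng)
        m = fit_dfa(df, VARS3)
        expected = brute_force_scores(df, VARS3)
        got = m.scores(df[VARS3].to_numpy()) - np.log(m.priors)
        np.testing.assert_allclose(got, expected, rtol=1e-8)

    def test_matches_sklearn_predictions(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        df = toy_table(rng, k=4, n_per=10, p=5, sep=1.0)
        variables = [f"v{j + 1}" for j in range(5)]
        m = fit_dfa(df, variables)
        X = df[variables].to_numpy()
        mine = m.groups[np.argmax(m.scores(X), axis=1)]
        lda = LinearDiscriminantAnalysis(priors=[0.25] * 4).fit(
            X, df["individual_id"])
        assert (mine == lda.predict(X)).all()

    def test_separated_clusters_classified_perfectly(self, rng):
        df = toy_table(rng, sep=50.0)
        res = classify(fit_dfa(df, VARS3), df)
        assert res.average_pct_correct == 100.0

    def test_two_cluster_boundary_at_midpoint(self):
        df = pd.DataFrame({
            "v1": [-1.0, -1.2, -0.8, 1.0, 1.2, 0.8],
            "v2": [0.1, -0.1, 0.0, 0.1, -0.1, 0.0],
            "individual_id": ["a"] * 3 + ["b"] * 3,
        })
        m = fit_dfa(df, ["v1", "v2"])
        s = m.scores(np.array([[0.0, 0.0]]))[0]
        assert s[0] == pytest.approx(s[1], abs=1e-10)

    def test_single_group_rejected(self, rng):
        df = toy_table(rng)
        df["individual_id"] = "only"
        with pytest.raises(ValueError, match="2 groups"):
            fit_dfa(df, VARS3)

    def test_duplicated_variable_raises_singularity(self, rng):
        df = toy_table(rng)
        df["v4"] = df["v1"]
        with pytest.raises(SingularCovarianceError, match="v"):
            fit_dfa(df, VARS3 + ["v4"])

    def test_ridge_rescues_singular_fit(self, rng):
        df = toy_table(rng)
        df["v4"] = df["v1"]
        m = fit_dfa(df, VARS3 + ["v4"], ridge=1e-8)
        assert np.isfinite(m.coef).all()

    def test_too_few_rows_rejected(self, rng):
        df = toy_table(rng, k=3, n_per=2, p=5)
        with pytest.raises(ValueError, match="must exceed"):
            fit_dfa(df, [f"v{j + 1}" for j in range(5)])

    def test_unknown_group_in_classify_rejected(self, rng):
        df = toy_table(rng)
        m = fit_dfa(df, VARS3)
        other = df.copy()
        other["individual_id"] = other["individual_id"].replace("g0", "gX")
        with pytest.raises(ValueError, match="unseen"):
            classify(m, other)

    def test_affine_invariance(self, rng):
        df = toy_table(rng, k=4, n_per=10, p=4, sep=1.0)
        variables = [f"v{j + 1}" for j in range(4)]
        base = classify(fit_dfa(df, variables), df)
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        shifted = df.copy()
        shifted[variables] = df[variables].to_numpy() @ A.T + rng.standard_normal(4)
        res = classify(fit_dfa(shifted, variables), shifted)
        np.testing.assert_array_equal(base.confusion, res.confusion)

    def test_confusion_counts_conserved(self, signal_table):
        from vocalid.core import DFA_VARIABLES
        res = classify(fit_dfa(signal_table, DFA_VARIABLES), signal_table)
        assert res.confusion.sum() == res.n_calls == len(signal_table)
        np.testing.assert_array_equal(
            res.confusion.sum(axis=1),
            signal_table.groupby("individual_id").size().sort_index().to_numpy())


class TestLeaveOneOut:
    def test_loo_below_resubstitution_on_noise(self):
        t = gaussian_null_table([8] * 4, 6, seed=3)
        variables = [f"var{j + 1:02d}" for j in range(6)]
        resub = classify(fit_dfa(t, variables), t)
        loo = classify_loo(t, variables)
        assert loo.average_pct_correct < resub.average_pct_correct

    def test_loo_chance_near_one_over_k(self):
        # large per-group n: LOO accuracy on noise approaches 1/k, unlike
        # resubstitution whose overfitting keeps it far above
        t = gaussian_null_table([60, 60], 4, seed=4)
        loo = classify_loo(t, [f"var{j + 1:02d}" for j in range(4)])
        assert abs(loo.average_pct_correct - 50.0) < 12


class TestWilks:
    def test_uninformative_variable_has_unit_lambda(self, rng):
        df = toy_table(rng, k=3, n_per=40, p=2, sep=4.0)
        df["noise"] = rng.standard_normal(len(df))
        contrib = {c.variable: c for c in
                   wilks_contributions(df, ["v1", "v2", "noise"])}
        assert contrib["noise"].partial_lambda > 0.9
        assert contrib["noise"].f_to_remove < 6.5

    def test_planted_informative_variable_has_minimum_lambda(self, rng):
        n_per, k = 12, 3
        df = pd.DataFrame(rng.standard_normal((n_per * k, 10)),
                          columns=[f"n{j}" for j in range(10)])
        df["signal"] = np.repeat([0.0, 3.0, 6.0], n_per) + \
            rng.standard_normal(n_per * k)
        df["individual_id"] = np.repeat(list("abc"), n_per)
        contrib = wilks_contributions(df, [f"n{j}" for j in range(10)]
                                      + ["signal"])
        best = min(contrib, key=lambda c: c.partial_lambda)
        assert best.variable == "signal"

    def test_smaller_lambda_means_larger_f(self, rng):
        df = toy_table(rng, k=3, n_per=15, p=4, sep=2.0)
        contrib = wilks_contributions(df, [f"v{j + 1}" for j in range(4)])
        lam = np.array([c.partial_lambda for c in contrib])
        f = np.array([c.f_to_remove for c in contrib])
        assert (np.argsort(lam) == np.argsort(-f)).all()
        assert ((0 < lam) & (lam <= 1)).all()

    def test_collinear_variables_raise(self, rng):
        df = toy_table(rng)
        df["v4"] = 2 * df["v1"] - df["v2"]
        with pytest.raises(SingularCovarianceError):
            wilks_contributions(df, VARS3 + ["v4"])


class TestPermutationNull:
    def test_null_mean_above_one_over_k_and_shrinks_with_n(self):
        variables = [f"var{j + 1:02d}" for j in range(6)]
        means = []
        for n_per in (8, 30):
            t = gaussian_null_table([n_per] * 4, 6, seed=5)
            null = permutation_null(t, variables, n_perm=150, seed=6)
            means.append(null.mean)
            assert null.mean > 100 / 4
        assert means[1] < means[0]

    def test_observed_with_signal_exceeds_null(self, signal_table):
        from vocalid.core import DFA_VARIABLES
        res = classify(fit_dfa(signal_table, DFA_VARIABLES), signal_table)
        null = permutation_null(signal_table, DFA_VARIABLES, n_perm=200,
                                seed=7)
        assert significance(res.average_pct_correct, null) == "p < 0.001"

    def test_no_signal_observed_within_null_band(self):
        # icc = 0: the "observed" labels carry no information, so the
        # observed accuracy is itself a draw from the null
        from vocalid import PopulationSpec, make_population, \
            sample_features_direct
        from vocalid.core import DFA_VARIABLES
        spec = PopulationSpec("hind", icc=0.0)
        profiles = make_population(spec, 10, seed=8)
        t = sample_features_direct(spec, profiles, 8, seed=9,
                                   call_types=("oral",))
        res = classify(fit_dfa(t, DFA_VARIABLES), t)
        null = permutation_null(t, DFA_VARIABLES, n_perm=200, seed=10)
        lo, hi = null.percentile(1), null.percentile(99)
        assert lo <= res.average_pct_correct <= hi

    def test_deterministic_under_seed(self, null_table):
        variables = [f"var{j + 1:02d}" for j in range(6)]
        a = permutation_null(null_table, variables, n_perm=50, seed=11)
        b = permutation_null(null_table, variables, n_perm=50, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_tiny_design_runs_with_bounded_mean(self):
        t = gaussian_null_table([3, 3], 1, seed=12)
        null = permutation_null(t, ["var01"], n_perm=50, seed=13)
        assert 0 < null.mean < 100

    def test_zero_permutations_rejected(self, null_table):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(null_table, ["var01"], n_perm=0, seed=1)


class TestSignificance:
    def test_percentile_threshold_semantics(self):
        null = PermutationNull(samples=np.arange(1.0, 1001.0) / 10, seed=0)
        assert significance(200.0, null) == "p < 0.001"
        assert significance(null.percentile(50), null) == "n.s."
        at96 = null.percentile(96)
        assert significance(at96, null) == "p < 0.05"
        assert significance(null.percentile(99.5), null) == "p < 0.01"

    def test_summary_consistent_with_samples(self):
        null = PermutationNull(samples=np.array([10.0, 20.0, 30.0]), seed=0)
        assert null.mean == 20.0
        assert null.sd == pytest.approx(10.0)
        assert null.n_permutations == 3
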
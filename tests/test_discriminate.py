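"""PCA reduction, linear DFA with leave-one-out, and the two study analyses."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from kittencall._lda import LinearDiscriminant, fast_lda_eval
from kittencall.discriminate import (arousal_analysis, chance_percent,
                                     dfa_classify, identity_analysis,
                                     pca_reduce)
from kittencall.stats import binomial_above_chance
from kittencall.synth import (DEFAULT_EFFECTS, PARAMETER_COLUMNS, make_cohort,
                              sample_feature_table)


class TestChancePercent:
    @pytest.mark.parametrize("k,exact,rounded", [
        (16, 6.25, 6), (18, 100.0 / 18, 6), (2, 50.0, 50)])
    def test_levels(self, k, exact, rounded):
        e, r = chance_percent(k)
        assert e == pytest.approx(exact)
        assert r == rounded
        assert e * k == pytest.approx(100.0)

    def test_too_few_classes(self):
        with pytest.raises(ValueError):
            chance_percent(1)


class TestPCA:
    def test_eigenvalues_match_correlation_matrix(self, table_cohort):
        """Oracle: direct eigendecomposition of the correlation matrix."""
        res = pca_reduce(table_cohort)
        X = table_cohort[PARAMETER_COLUMNS].to_numpy()
        oracle = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        assert np.allclose(res.eigenvalues, oracle, atol=1e-8)
        assert res.retained == int((oracle > 1.0).sum())
        assert res.variance_explained == pytest.approx(
            100.0 * oracle[:res.retained].sum() / len(PARAMETER_COLUMNS))
        assert (res.loadings.abs() <= 1.0 + 1e-9).all().all()

    def test_two_perfectly_correlated_parameters(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        ft = pd.DataFrame({"MeanF0 [Hz]": x, "MaxF0 [Hz]": 2 * x + 3})
        res = pca_reduce(ft, parameters=["MeanF0 [Hz]", "MaxF0 [Hz]"])
        assert res.retained == 1
        assert res.variance_explained == pytest.approx(100.0)

    def test_score_variances_equal_eigenvalues(self, table_cohort):
        res = pca_reduce(table_cohort)
        var = res.scores.var(axis=0, ddof=1)
        assert np.allclose(var, res.eigenvalues[:res.retained], rtol=1e-6)

    def test_constant_column_named_in_error(self, table_cohort):
        ft = table_cohort.copy()
        ft["Voiced [%]"] = 100.0
        with pytest.raises(ValueError, match="Voiced"):
            pca_reduce(ft)

    def test_loading_flags(self, table_cohort):
        res = pca_reduce(table_cohort, loading_flag=0.7)
        assert res.flagged.to_numpy().sum() == (
            res.loadings.abs() > 0.7).to_numpy().sum()


class TestLDA:
    def test_matches_sklearn_predictions(self):
        """Our equal-prior LDA agrees with scikit-learn's on well-posed data."""
        rng = np.random.default_rng(1)
        means = rng.normal(0, 2, (5, 4))
        y = np.repeat(np.arange(5), 30)
        X = means[y] + rng.normal(0, 1, (y.size, 4))
        ours = LinearDiscriminant().fit(X, y).predict(X)
        ref = LinearDiscriminantAnalysis(priors=[0.2] * 5).fit(X, y).predict(X)
        assert np.mean(ours == ref) > 0.99

    def test_fast_eval_agrees_with_refitting_loo(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            y = np.repeat(np.arange(6), 8)
            X = rng.normal(0, 1, (y.size, 5)) + rng.normal(0, 1.5, (6, 5))[y]
            lda = LinearDiscriminant().fit(X, y)
            loo_ref = 100.0 * np.mean(lda.loo_predict() == y)
            orig_ref = 100.0 * np.mean(lda.predict(X) == y)
            orig, loo = fast_lda_eval(X, y, 6)
            assert orig == pytest.approx(orig_ref)
            assert loo == pytest.approx(loo_ref)


class TestDFA:
    def test_separated_classes_high_accuracy(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 20)
        X = rng.normal(0, 1, (40, 3))
        X[y == 1, 0] += 6.0  # d' = 6
        res = dfa_classify(X, y)
        assert res.original_accuracy >= 95.0
        assert res.loo_accuracy >= 95.0
        assert res.chance == 50.0

    def test_permuted_labels_classify_at_chance(self):
        """Oracle: the permutation distribution defines chance. Mean LOO
        accuracy over label permutations of a 16-class, 10-calls-each table
        sits within 2 SE of 6.25%."""
        rng = np.random.default_rng(4)
        y = np.repeat(np.arange(16), 10)
        X = rng.normal(0, 1, (160, 7)) + rng.normal(0, 1.0, (16, 7))[y]
        accs = []
        for _ in range(300):
            perm = rng.permutation(y)
            _, loo = fast_lda_eval(X, perm, 16)
            accs.append(loo)
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(accs.size)
        assert abs(accs.mean() - 6.25) < 2 * se + 0.5

    def test_loo_never_beats_resubstitution_much(self, table_cohort):
        """Resubstitution optimism: LOO <= original + 5 points."""
        for cond in ("Low", "High"):
            rep = identity_analysis(table_cohort, cond)
            assert (rep["dfa"].loo_accuracy
                    <= rep["dfa"].original_accuracy + 5.0)

    def test_confusion_rows_sum_to_class_sizes(self, table_cohort):
        rep = identity_analysis(table_cohort, "High")
        sizes = rep["dfa"].per_class.set_index("class")["n"]
        assert (rep["dfa"].confusion.sum(axis=1) == sizes).all()


class TestIdentityAnalysis:
    def test_above_chance_with_signatures(self, table_cohort):
        rep = identity_analysis(table_cohort, "Low")
        dfa = rep["dfa"]
        k = rep["n_kittens"]
        total_correct = int(dfa.per_class["n_correct_loo"].sum())
        n = int(dfa.per_class["n"].sum())
        assert binomial_above_chance(total_correct, n, 1.0 / k).p < 0.001
        assert rep["fisher_omnibus"].p < 0.001

    def test_null_without_signatures(self):
        """Signatures off: the per-parameter ANOVA omnibus gate stays
        non-significant in >= 90% of 20 replicate cohorts."""
        ok = 0
        for rep_i in range(20):
            profiles = make_cohort(16, 4, seed=100 + rep_i,
                                   signature_ratio=0.0)
            ft = sample_feature_table(profiles, calls_per_cell=10,
                                      seed=100 + rep_i, signature_ratio=0.0,
                                      low_counts={})
            rep = identity_analysis(ft, "Low")
            ok += rep["fisher_omnibus"].p > 0.05
        assert ok >= 18

    def test_signature_recovery_beats_chance_in_replicates(self):
        """Identity DFA beats chance (binomial p < 0.001) in >= 95% of 20
        replicate cohorts with the default signature strength."""
        ok = 0
        for rep_i in range(20):
            profiles = make_cohort(16, 4, seed=200 + rep_i)
            ft = sample_feature_table(profiles, calls_per_cell=10,
                                      seed=200 + rep_i, low_counts={})
            rep = identity_analysis(ft, "Low")
            dfa = rep["dfa"]
            total = int(dfa.per_class["n_correct_loo"].sum())
            n = int(dfa.per_class["n"].sum())
            ok += binomial_above_chance(total, n, 1.0 / 16).p < 0.001
        assert ok >= 19

    def test_indistinguishable_kittens_classify_at_chance(self):
        rng = np.random.default_rng(7)
        calls = rng.normal(0, 1, (30, 4))
        cols = PARAMETER_COLUMNS[:4]
        base = pd.DataFrame(calls, columns=cols)
        ft = pd.concat([base.assign(kitten_id="K1", condition="Low"),
                        base.assign(kitten_id="K2", condition="Low")],
                       ignore_index=True)
        rep = identity_analysis(ft, "Low")
        assert rep["dfa"].original_accuracy == pytest.approx(50.0)

    def test_rescaling_invariance(self, table_cohort):
        """Accuracy is invariant to per-parameter affine rescaling:
        standardization absorbs units."""
        ft = table_cohort.copy()
        for i, c in enumerate(PARAMETER_COLUMNS):
            ft[c] = ft[c] * (2.0 + i) - 7.0 * i
        a = identity_analysis(table_cohort, "High")["dfa"]
        b = identity_analysis(ft, "High")["dfa"]
        assert a.original_accuracy == pytest.approx(b.original_accuracy)
        assert a.loo_accuracy == pytest.approx(b.loo_accuracy)


class TestArousalAnalysis:
    def test_direction_arrows_on_default_cohort(self, table_cohort):
        rep = arousal_analysis(table_cohort)
        arrows = dict(zip(rep["t_tests"]["parameter"],
                          rep["t_tests"]["direction"]))
        assert arrows["Call duration [ms]"] == "↑"
        assert arrows["ICI [ms]"] == "↓"
        assert arrows["MeanF0 [Hz]"] == "↓"
        assert arrows["Voiced [%]"] == "↓"
        assert rep["dfa"].loo_accuracy > 50.0
        assert rep["fisher_omnibus"].p < 0.001

    def test_null_conditions_near_chance(self):
        """With both conditions drawn from the same distribution, the
        two-class LOO accuracy distribution centres at or below the 50%
        chance level (leave-one-out is pessimistically biased under the
        null) and the omnibus gate is usually quiet."""
        import dataclasses
        low = DEFAULT_EFFECTS["Low"]
        null_effects = {"Low": low,
                        "High": dataclasses.replace(low, condition="High")}
        loos, omnibus_quiet = [], 0
        for rep_i in range(30):
            profiles = make_cohort(18, 6, seed=300 + rep_i)
            ft = sample_feature_table(profiles, null_effects,
                                      calls_per_cell=10, seed=300 + rep_i,
                                      low_counts={})
            rep = arousal_analysis(ft)
            loos.append(rep["dfa"].loo_accuracy)
            omnibus_quiet += rep["fisher_omnibus"].p > 0.05
        assert np.mean(loos) <= 55.0
        assert omnibus_quiet >= 24

    def test_single_kitten_flagged_insufficient(self):
        profiles = make_cohort(1, 1, seed=1)
        ft = sample_feature_table(profiles, calls_per_cell=10, seed=1)
        rep = arousal_analysis(ft)
        assert rep["dfa"] is None
        assert np.isnan(rep["t_tests"]["p"]).all()

    def test_missing_condition_kitten_dropped(self, table_cohort):
        ft = table_cohort[~((table_cohort.kitten_id == "K01")
                            & (table_cohort.condition == "High"))]
        rep = arousal_analysis(ft)
        assert rep["excluded_kittens"] == ["K01"]
        assert rep["n_kittens"] == 17
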
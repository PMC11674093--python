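import numpy as np
import pytest
from scipy import stats as sps

import panelboost.ranking as ranking
from panelboost import (
    ExpressionMatrix,
    LabelVector,
    LearnerSpec,
    anova_f,
    correlation_with_label,
    rfe_rank,
    standardize_genes,
)


def _matrix(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(gene_ids, sample_ids, values)


class TestAnovaF:
    def test_closed_form_example(self):
        """Groups (1,2,3), (2,3,4), (3,4,5): SSB=6 (df 2), SSW=6 (df 6) -> F=3."""
        X = _matrix([[1, 2, 3, 2, 3, 4, 3, 4, 5]])
        y = LabelVector(X.sample_ids, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        F = anova_f(X, y).f_scores["g0"]
        assert F == pytest.approx(3.0, abs=1e-10)

    def test_equal_group_means_give_zero(self):
        X = _matrix([[1, 2, 3, 3, 1, 2, 2, 3, 1]])
        y = LabelVector(X.sample_ids, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        assert anova_f(X, y).f_scores["g0"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_flagged_degenerate(self):
        X = _matrix([[5.0] * 6, [1, 2, 3, 4, 5, 6]])
        y = LabelVector(X.sample_ids, ["A"] * 3 + ["B"] * 3)
        res = anova_f(X, y)
        assert res.f_scores["g0"] == 0.0
        assert res.degenerate["g0"] and not res.degenerate["g1"]

    def test_perfect_separation_flagged(self):
        X = _matrix([[1, 1, 1, 2, 2, 2]])
        y = LabelVector(X.sample_ids, ["A"] * 3 + ["B"] * 3)
        res = anova_f(X, y)
        assert np.isinf(res.f_scores["g0"]) and res.degenerate["g0"]

    def test_singleton_class_rejected(self):
        X = _matrix(np.arange(8.0).reshape(2, 4))
        y = LabelVector(X.sample_ids, ["A", "A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_f(X, y)

    def test_matches_scipy_oneway_on_random_genes(self):
        rng = np.random.default_rng(0)
        X = _matrix(rng.normal(size=(1000, 18)))
        y = LabelVector(X.sample_ids, ["A"] * 6 + ["B"] * 6 + ["C"] * 6)
        ours = anova_f(X, y).f_scores
        codes = y.codes()
        groups = [X.values[:, codes == c] for c in range(3)]
        expected = sps.f_oneway(*groups, axis=1).statistic
        got = np.array([ours[g] for g in X.gene_ids])
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = _matrix(rng.normal(size=(20, 12)))
        y = LabelVector(X.sample_ids, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        perm = rng.permutation(12)
        Xp = _matrix(X.values[:, perm], sample_ids=[X.sample_ids[i] for i in perm])
        yp = LabelVector(Xp.sample_ids, [y.labels[i] for i in perm])
        a, b = anova_f(X, y).f_scores, anova_f(Xp, yp).f_scores
        for g in X.gene_ids:
            assert a[g] == pytest.approx(b[g], rel=1e-12)


class TestCorrelationWithLabel:
    def _y(self, n_per=4):
        ids = [f"s{j}" for j in range(3 * n_per)]
        return LabelVector(ids, ["A"] * n_per + ["B"] * n_per + ["C"] * n_per)

    def test_gene_equal_to_coding_correlates_one(self):
        y = self._y()
        coded = [0.0] * 4 + [1.0] * 4 + [2.0] * 4
        X = _matrix([coded, [-c for c in coded]], sample_ids=y.sample_ids)
        res = correlation_with_label(X, y)
        corr = res.correlations
        label_col = res.correlation_names.index("label")
        assert corr[0, label_col] == pytest.approx(1.0)
        assert corr[1, label_col] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T)

    def test_independent_noise_nearly_uncorrelated(self):
        rng = np.random.default_rng(2)
        n = 1000
        ids = [f"s{j}" for j in range(n)]
        y = LabelVector(ids, ["A"] * (n // 2) + ["B"] * (n // 2))
        X = _matrix(rng.normal(size=(2, n)), sample_ids=ids)
        corr = correlation_with_label(X, y).correlations
        assert abs(corr[0, 1]) < 0.1

    def test_zero_variance_gene_flagged_undefined(self):
        y = self._y()
        X = _matrix([[3.0] * 12, list(range(12))], sample_ids=y.sample_ids)
        res = correlation_with_label(X, y)
        assert res.undefined[0, 1] and np.isnan(res.correlations[0, 1])
        assert res.correlations[0, 0] == 1.0

    def test_coding_must_be_distinct(self):
        y = self._y()
        X = _matrix(np.ones((1, 12)) * np.arange(12), sample_ids=y.sample_ids)
        with pytest.raises(ValueError, match="distinct"):
            correlation_with_label(X, y, coding={"A": 0, "B": 0, "C": 1})


class _StubFitted:
    """Importance = mean expression of each surviving gene (deterministic)."""

    def __init__(self, X):
        self._imp = X.mean(axis=0)

    def importances(self, X, rng):
        return self._imp.copy()


def _stub_fit(spec, X, labels, classes):
    return _StubFitted(X)


@pytest.fixture
def stub_learner(monkeypatch):
    monkeypatch.setattr(ranking, "fit_learner", _stub_fit)
    return LearnerSpec("gbdt")


class TestRfeRank:
    def _dataset(self, p=12, seed=0):
        # gene g_i has constant value i -> strictly ordered stable importances
        values = np.tile(np.arange(p, dtype=float)[:, None], (1, 6))
        values += np.random.default_rng(seed).normal(0, 1e-6, values.shape)
        X = _matrix(values)
        y = LabelVector(X.sample_ids, ["A"] * 3 + ["B"] * 3)
        return X, y

    def test_target_size_equals_p_returns_everything(self, stub_learner):
        X, y = self._dataset()
        res = rfe_rank(X, y, stub_learner, target_size=X.n_genes)
        assert len(res.gene_ids) == X.n_genes
        assert res.elimination_trace == []

    def test_survivors_ordered_by_importance(self, stub_learner):
        X, y = self._dataset()
        res = rfe_rank(X, y, stub_learner, target_size=4, step_fraction=0.25)
        assert res.gene_ids == ["g11", "g10", "g9", "g8"]
        assert all(a >= b for a, b in zip(res.scores, res.scores[1:]))

    def test_trace_plus_survivors_partition_input(self, stub_learner):
        X, y = self._dataset()
        res = rfe_rank(X, y, stub_learner, target_size=5, step_fraction=0.3)
        removed = [g for _, gs in res.elimination_trace for g in gs]
        assert sorted(removed + res.gene_ids) == sorted(X.gene_ids)
        assert len(set(removed) & set(res.gene_ids)) == 0

    def test_block_elimination_matches_one_at_a_time_oracle(self, stub_learner):
        """With stable, strictly ordered importances the surviving set is
        independent of the elimination step size."""
        X, y = self._dataset()
        fraction = rfe_rank(X, y, stub_learner, target_size=4, step_fraction=0.4)
        one_by_one = rfe_rank(X, y, stub_learner, target_size=4, step_fraction=1e-9 + 1 / 12)
        # independent oracle: drop the smallest-mean gene one at a time
        order = np.argsort(-X.values.mean(axis=1))
        expected = {X.gene_ids[i] for i in order[:4]}
        assert set(fraction.gene_ids) == expected
        assert set(one_by_one.gene_ids) == expected

    def test_never_drops_below_target_size(self, stub_learner):
        X, y = self._dataset()
        res = rfe_rank(X, y, stub_learner, target_size=11, step_fraction=0.5)
        assert len(res.gene_ids) == 11
        assert sum(len(g) for _, g in res.elimination_trace) == 1

    def test_invalid_arguments(self, stub_learner):
        X, y = self._dataset()
        with pytest.raises(ValueError, match="target_size"):
            rfe_rank(X, y, stub_learner, target_size=13)
        with pytest.raises(ValueError, match="step_fraction"):
            rfe_rank(X, y, stub_learner, target_size=2, step_fraction=1.5)
        y1 = LabelVector(X.sample_ids, ["A"] * 6)
        with pytest.raises(ValueError, match="two classes"):
            rfe_rank(X, y1, stub_learner, target_size=2)

    def test_sample_permutation_invariance(self, stub_learner):
        X, y = self._dataset()
        perm = np.random.default_rng(3).permutation(X.n_samples)
        Xp = _matrix(X.values[:, perm], sample_ids=[X.sample_ids[i] for i in perm])
        yp = LabelVector(Xp.sample_ids, [y.labels[i] for i in perm])
        a = rfe_rank(X, y, stub_learner, target_size=4)
        b = rfe_rank(Xp, yp, stub_learner, target_size=4)
        assert a.gene_ids == b.gene_ids


class TestRealLearnerRfe:
    def test_planted_gene_survives_with_real_boosters(self):
        """p=20 with one strong planted gene: survives to the final set in
        >= 4 of 5 seeds for every learner kind."""
        from panelboost import SimulationConfig, simulate

        for kind in ("gbdt", "catboost_like", "xgboost_like"):
            survived = 0
            for seed in range(5):
                ds = simulate(
                    SimulationConfig(
                        p=20, classes=("A", "B"), n_per_class=30,
                        n_informative=1, effect=3.0, block_size=1, seed=seed,
                    )
                )
                spec = LearnerSpec(kind, seed=seed)
                res = rfe_rank(ds.matrix, ds.labels, spec, target_size=5)
                survived += ds.truth[0] in res.gene_ids
            assert survived >= 4, kind


def test_standardize_genes_zero_mean_unit_sd():
    rng = np.random.default_rng(4)
    V = rng.normal(3, 5, size=(7, 40))
    V[2] = 9.0  # constant gene stays finite
    Z = standardize_genes(V)
    np.testing.assert_allclose(Z.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(np.delete(Z, 2, 0).std(axis=1), 1, rtol=1e-12)
    assert np.all(Z[2] == 0)
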
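import math

import numpy as np
import pytest

from panelboost import (
    ExpressionMatrix,
    GanConfig,
    LabelVector,
    gan_losses,
    generate,
    train_gan,
)
from panelboost.gan import ShortGenerationWarning, _forward, _init_params


def _uniform_class(p, n):
    return np.full((n, p), 1.0 / p)


class TestGanLosses:
    def test_perfect_discriminator_gives_zero(self):
        n = 4
        probs = np.ones(n)
        cls = _uniform_class(3, n) * 0  # then set true to 1
        cls[:, 1] = 1.0
        idx = np.full(n, 1)
        res = gan_losses(probs, probs, cls, idx, cls, idx)
        assert res.loss_x == pytest.approx(0.0)
        assert res.loss_c == pytest.approx(0.0)

    def test_chance_source_probabilities(self):
        n = 10
        half = np.full(n, 0.5)
        cls = _uniform_class(3, n)
        idx = np.zeros(n, dtype=int)
        res = gan_losses(half, half, cls, idx, cls, idx)
        assert res.loss_x == pytest.approx(2 * math.log(0.5), rel=1e-12)
        assert res.loss_c == pytest.approx(2 * math.log(1 / 3), rel=1e-12)

    def test_hand_computed_batch_of_two(self):
        """real (0.8, 0.6), fake-detected (0.7, 0.9):
        mean(ln .8, ln .6) + mean(ln .7, ln .9) ~ -0.5980."""
        real = np.array([0.8, 0.6])
        fake = np.array([0.7, 0.9])
        cls = _uniform_class(2, 2)
        idx = np.zeros(2, dtype=int)
        res = gan_losses(real, fake, cls, idx, cls, idx)
        expected = np.mean(np.log(real)) + np.mean(np.log(fake))
        assert res.loss_x == pytest.approx(expected, abs=1e-12)
        assert res.loss_x == pytest.approx(-0.59801, abs=5e-5)

    def test_matches_independent_log_sum_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            nr, nf, C = rng.integers(1, 9, 3)
            p_rr = rng.uniform(1e-4, 1, nr)
            p_ff = rng.uniform(1e-4, 1, nf)
            rc = rng.dirichlet(np.ones(C), nr)
            fc = rng.dirichlet(np.ones(C), nf)
            ri = rng.integers(0, C, nr)
            fi = rng.integers(0, C, nf)
            res = gan_losses(p_rr, p_ff, rc, ri, fc, fi)
            lx = sum(math.log(v) for v in p_rr) / nr + sum(math.log(v) for v in p_ff) / nf
            lc = sum(math.log(rc[i, ri[i]]) for i in range(nr)) / nr
            lc += sum(math.log(max(fc[i, fi[i]], 1e-7)) for i in range(nf)) / nf
            assert res.loss_x == pytest.approx(lx, rel=1e-10)
            assert res.loss_c == pytest.approx(lc, rel=1e-10)
            assert res.loss_x <= 0 and res.loss_c <= 0

    def test_empty_batch_rejected(self):
        cls = _uniform_class(2, 1)
        with pytest.raises(ValueError, match="empty"):
            gan_losses(np.array([]), np.array([0.5]), cls, [0], cls, [0])


def _gaussian_fixture(n=200, p=2, seed=0, labels=("A",)):
    rng = np.random.default_rng(seed)
    per = n // len(labels)
    values = rng.normal(3.0, 1.5, size=(p, per * len(labels)))
    ids = [f"s{j}" for j in range(values.shape[1])]
    y = LabelVector(ids, [l for l in labels for _ in range(per)])
    return ExpressionMatrix([f"g{i}" for i in range(p)], ids, values), y


class TestTrainGan:
    def test_smoke_one_epoch(self):
        X, y = _gaussian_fixture(n=20)
        model = train_gan(X, y, GanConfig(epochs=1, hidden_sizes=(4,), seed=0))
        assert len(model.loss_history) == 1
        assert model.gene_ids == X.gene_ids

    def test_single_class_moment_matching(self):
        """Generated mean within 0.25 within-class SD per gene (3-seed median)."""
        X, y = _gaussian_fixture(n=200, seed=1)
        real_mean = X.values.mean(axis=1)
        real_sd = X.values.std(axis=1, ddof=1)
        worst = []
        for seed in range(3):
            model = train_gan(X, y, GanConfig(epochs=2000, seed=seed))
            batch = generate(model, "A", 400, seed=9)
            dev = np.abs(batch.values.mean(axis=0) - real_mean) / real_sd
            worst.append(dev.max())
        assert np.median(worst) < 0.25

    def test_two_seeds_differ_but_both_valid(self):
        X, y = _gaussian_fixture(n=100, seed=2)
        m1 = train_gan(X, y, GanConfig(epochs=300, seed=0))
        m2 = train_gan(X, y, GanConfig(epochs=300, seed=1))
        assert not all(
            np.array_equal(a, b) for a, b in zip(m1.gen_params, m2.gen_params)
        )

    def test_deterministic_given_seed(self):
        X, y = _gaussian_fixture(n=60, seed=3)
        m1 = train_gan(X, y, GanConfig(epochs=100, seed=7))
        m2 = train_gan(X, y, GanConfig(epochs=100, seed=7))
        for a, b in zip(m1.gen_params, m2.gen_params):
            np.testing.assert_array_equal(a, b)
        assert m1.loss_history == m2.loss_history

    def test_class_with_one_sample_rejected(self):
        X, _ = _gaussian_fixture(n=5, labels=("A",))
        y = LabelVector(X.sample_ids, ["A", "A", "A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            train_gan(X, y, GanConfig(epochs=1))

    def test_discriminator_alone_improves_on_separable_data(self):
        """With the generator frozen, discriminator ascends Loss_x on
        linearly separable real/fake clouds (non-decreasing over 5-epoch
        windows)."""
        from panelboost.gan import _Adam, _d_update, gan_losses as gl

        rng = np.random.default_rng(5)
        X, y = _gaussian_fixture(n=40, seed=4)
        model = train_gan(X, y, GanConfig(epochs=1, hidden_sizes=(16,), seed=0))
        x_real = rng.normal(+2.0, 0.5, size=(40, 2))
        x_fake = rng.normal(-2.0, 0.5, size=(40, 2))
        yidx = np.zeros(40, dtype=int)
        opt = _Adam(model.trunk_params + model.src_params + model.cls_params, 1e-3)
        losses = []
        for _ in range(60):
            _d_update(model, opt, x_real, yidx, x_fake, yidx)
            p_rr, pc_r = model.discriminate(x_real)
            p_rf, pc_f = model.discriminate(x_fake)
            losses.append(gl(p_rr, 1 - p_rf, pc_r, yidx, pc_f, yidx).loss_x)
        window = [np.mean(losses[i : i + 5]) for i in range(0, 60, 5)]
        assert all(b >= a - 1e-9 for a, b in zip(window, window[1:]))


class TestGenerate:
    def _model(self, seed=0, **kw):
        X, y = _gaussian_fixture(n=60, seed=6, labels=("A", "B"))
        kw.setdefault("epochs", 50)
        return train_gan(X, y, GanConfig(seed=seed, **kw))

    def test_n_zero_gives_empty_batch(self):
        batch = generate(self._model(), "A", 0)
        assert batch.values.shape == (0, 2) and batch.sample_ids == []

    def test_shape_and_synthetic_flags(self):
        model = self._model()
        batch = generate(model, "B", 50, seed=1)
        assert batch.values.shape == (50, 2)
        assert batch.origin == "synthetic"
        assert all(s.startswith("synthetic:") for s in batch.sample_ids)
        assert batch.labels == ["B"] * 50

    def test_deterministic_given_seed(self):
        model = self._model()
        a = generate(model, "A", 10, seed=3)
        b = generate(model, "A", 10, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unseen_class_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            generate(self._model(), "Z", 5)

    def test_filter_threshold_on_uninformative_discriminator(self):
        """A class head near chance (two classes) accepts ~half the draws at
        threshold 0.5 and nearly none at 0.9 -> short output with warning."""
        model = self._model(epochs=1, hidden_sizes=(4,))
        # force an exactly uniform class head: zero weights, zero bias
        for p in model.cls_params:
            p[...] = 0.0
        model.cfg.filter_threshold = 0.9
        with pytest.warns(ShortGenerationWarning):
            batch = generate(model, "A", 30, seed=2)
        assert batch.short and batch.values.shape[0] == 0
        model.cfg.filter_threshold = 0.5
        ok = generate(model, "A", 30, seed=2)
        assert not ok.short and ok.values.shape[0] == 30


def test_forward_backward_gradient_check():
    """Manual backprop matches numerical gradients on a small network."""
    from panelboost.gan import _backward

    rng = np.random.default_rng(8)
    params = _init_params([3, 5, 2], rng)
    x = rng.standard_normal((4, 3))
    target = rng.standard_normal((4, 2))

    def loss(ps):
        out, _ = _forward(ps, x, act_last=False)
        return 0.5 * np.sum((out - target) ** 2)

    out, caches = _forward(params, x, act_last=False)
    grads, dx = _backward(params, caches, out - target, act_last=False)
    eps = 1e-6
    for k, p in enumerate(params):
        it = np.nditer(p, flags=["multi_index"])
        for _ in range(min(p.size, 5)):
            ix = it.multi_index
            orig = p[ix]
            p[ix] = orig + eps
            up = loss(params)
            p[ix] = orig - eps
            down = loss(params)
            p[ix] = orig
            num = (up - down) / (2 * eps)
            assert grads[k][ix] == pytest.approx(num, rel=1e-4, abs=1e-7)
            next(it, None)
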
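"""Class-conditional GAN for augmenting small expression cohorts.

The generator maps (one-hot class c, noise z) to an expression vector over
the selected gene panel; the discriminator has two heads, one scoring
real-vs-synthetic origin and one predicting the class.  Both losses follow
the auxiliary-classifier construction:

    Loss_x = E[log P(source=real | X_real)] + E[log P(source=fake | X_fake)]
    Loss_c = E[log P(class=c | X_real)]     + E[log P(class=c | X_fake)]

The discriminator ascends Loss_x + Loss_c.  Two generator objectives are
available: ``ac_gan_standard`` (default) ascends
log P(source=real | fake) + log P(class=intended | fake), the usual
auxiliary-classifier generator; ``paper_literal`` descends Loss_x + Loss_c
directly, which fools the source head but pushes fakes *away* from their
intended class — kept selectable for fidelity experiments.

Networks are small dense MLPs written directly in numpy with manual
backpropagation and Adam, sized for ~10-gene panels and ~10-sample folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, LabelVector

__all__ = [
    "GanConfig",
    "GanLosses",
    "GanModel",
    "SyntheticBatch",
    "ShortGenerationWarning",
    "gan_losses",
    "train_gan",
    "generate",
]

EPS = 1e-7
LEAK = 0.2


class ShortGenerationWarning(UserWarning):
    """Discriminator-confidence filtering exhausted its retry budget."""


@dataclass
class GanConfig:
    noise_dim: int = 8
    hidden_sizes: tuple[int, ...] = (32, 32)
    epochs: int = 8000
    batch_size: int | None = None  # None = full training fold
    learning_rate: float = 5e-4
    d_steps_per_g_step: int = 2
    #: instance-noise scale: Gaussian noise of this sd (annealed linearly to
    #: zero over the first 80% of epochs) is added to the discriminator's
    #: inputs; stabilises the adversarial game on 10-sample folds
    instance_noise: float = 1.0
    #: exponential-moving-average decay for generator weights; sampling uses
    #: the averaged generator, which damps the oscillation of the
    #: adversarial game around its equilibrium.  0 disables averaging.
    ema_decay: float = 0.999
    generator_objective: str = "ac_gan_standard"
    filter_threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_dim < 1 or self.epochs < 1:
            raise ValueError("noise_dim and epochs must be >= 1")
        if self.generator_objective not in ("ac_gan_standard", "paper_literal"):
            raise ValueError(f"unknown generator objective {self.generator_objective!r}")
        if self.filter_threshold is not None and not (0.0 <= self.filter_threshold <= 1.0):
            raise ValueError("filter_threshold must be in [0, 1]")


@dataclass
class GanLosses:
    """Batch-mean log-likelihood terms, both <= 0 (0 only at perfect confidence)."""

    loss_x: float
    loss_c: float


def gan_losses(
    p_real_on_real: np.ndarray,
    p_fake_on_fake: np.ndarray,
    real_class_probs: np.ndarray,
    real_classes: np.ndarray,
    fake_class_probs: np.ndarray,
    fake_classes: np.ndarray,
) -> GanLosses:
    """Evaluate the source and class log-likelihood losses on one batch.

    ``p_real_on_real`` is P(source=real) on the real batch and
    ``p_fake_on_fake`` is P(source=fake) on the synthetic batch; the class
    arrays hold per-sample class distributions with their true (real) or
    intended (fake) class indices.  Probabilities are clamped at 1e-7
    before the log; no sign flips are hidden inside.
    """
    p_rr = np.asarray(p_real_on_real, dtype=float)
    p_ff = np.asarray(p_fake_on_fake, dtype=float)
    if p_rr.size == 0 or p_ff.size == 0:
        raise ValueError("empty batch")
    rc = np.asarray(real_class_probs, dtype=float)
    fc = np.asarray(fake_class_probs, dtype=float)
    ri = np.asarray(real_classes, dtype=int)
    fi = np.asarray(fake_classes, dtype=int)
    if rc.shape[0] != ri.shape[0] or fc.shape[0] != fi.shape[0]:
        raise ValueError("class probabilities and class indices disagree in length")

    def _mlog(p: np.ndarray) -> float:
        return float(np.mean(np.log(np.clip(p, EPS, 1.0))))

    loss_x = _mlog(p_rr) + _mlog(p_ff)
    loss_c = _mlog(rc[np.arange(len(ri)), ri]) + _mlog(fc[np.arange(len(fi)), fi])
    return GanLosses(loss_x=loss_x, loss_c=loss_c)


# ---------------------------------------------------------------------------
# minimal dense network machinery (manual gradients)


def _init_params(sizes: list[int], rng: np.random.Generator) -> list[np.ndarray]:
    """He-style initialisation; parameters stored flat as [W0, b0, W1, b1, ...]."""
    params: list[np.ndarray] = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        params.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        params.append(np.zeros(fan_out))
    return params


def _forward(
    params: list[np.ndarray], x: np.ndarray, act_last: bool
) -> tuple[np.ndarray, list]:
    """Forward pass with leaky-rectifier hidden units; caches for backward."""
    caches = []
    h = x
    n_layers = len(params) // 2
    for i in range(n_layers):
        W, b = params[2 * i], params[2 * i + 1]
        z = h @ W + b
        if i < n_layers - 1 or act_last:
            a = np.where(z > 0, z, LEAK * z)
        else:
            a = z
        caches.append((h, z))
        h = a
    return h, caches


def _backward(
    params: list[np.ndarray], caches: list, dout: np.ndarray, act_last: bool
) -> tuple[list[np.ndarray], np.ndarray]:
    """Gradients w.r.t. parameters and the network input."""
    grads = [np.zeros_like(p) for p in params]
    n_layers = len(params) // 2
    d = dout
    for i in reversed(range(n_layers)):
        h, z = caches[i]
        if i < n_layers - 1 or act_last:
            d = d * np.where(z > 0, 1.0, LEAK)
        W = params[2 * i]
        grads[2 * i] = h.T @ d
        grads[2 * i + 1] = d.sum(axis=0)
        d = d @ W.T
    return grads, d


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------


@dataclass
class GanModel:
    """Trained generator/discriminator pair over a gene panel."""

    gene_ids: list[str]
    class_order: list[str]
    seen_classes: list[str]
    cfg: GanConfig
    gen_params: list[np.ndarray]
    trunk_params: list[np.ndarray]
    src_params: list[np.ndarray]
    cls_params: list[np.ndarray]
    feature_center: np.ndarray = field(default=None)  # per-gene mean on train
    feature_scale: np.ndarray = field(default=None)  # per-gene sd on train
    loss_history: list[tuple[float, float]] = field(default_factory=list)

    def _onehot(self, labels: list[str] | np.ndarray) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.class_order)}
        idx = [pos[l] for l in labels]
        out = np.zeros((len(idx), len(self.class_order)))
        out[np.arange(len(idx)), idx] = 1.0
        return out

    def generator_forward(self, onehot: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Standardized-scale expression vectors for (class, noise) inputs."""
        x, _ = _forward(self.gen_params, np.hstack([onehot, z]), act_last=False)
        return x

    def discriminate(self, x_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(P(source=real), class distribution) for standardized inputs."""
        h, _ = _forward(self.trunk_params, x_std, act_last=True)
        s, _ = _forward(self.src_params, h, act_last=False)
        c, _ = _forward(self.cls_params, h, act_last=False)
        return _sigmoid(s[:, 0]), _softmax(c)

    def to_original_scale(self, x_std: np.ndarray) -> np.ndarray:
        return x_std * self.feature_scale + self.feature_center

    def to_standardized(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feature_center) / self.feature_scale


@dataclass
class SyntheticBatch:
    """Generated expression vectors; every sample carries a synthetic-origin flag."""

    gene_ids: list[str]
    sample_ids: list[str]
    labels: list[str]
    values: np.ndarray  # n x p, original expression scale
    origin: str = "synthetic"
    short: bool = False


def _d_update(
    model: GanModel,
    opt: _Adam,
    x_real: np.ndarray,
    y_real_idx: np.ndarray,
    x_fake: np.ndarray,
    y_fake_idx: np.ndarray,
) -> None:
    """One discriminator ascent step on Loss_x + Loss_c (descends the negative)."""
    d_params = model.trunk_params + model.src_params + model.cls_params
    nt = len(model.trunk_params)
    ns = len(model.src_params)
    C = len(model.class_order)
    n_r, n_f = x_real.shape[0], x_fake.shape[0]

    grads_total = [np.zeros_like(p) for p in d_params]
    for x, y_idx, is_real, n in (
        (x_real, y_real_idx, True, n_r),
        (x_fake, y_fake_idx, False, n_f),
    ):
        h, tcache = _forward(model.trunk_params, x, act_last=True)
        s, scache = _forward(model.src_params, h, act_last=False)
        c, ccache = _forward(model.cls_params, h, act_last=False)
        p_src = _sigmoid(s[:, 0])
        p_cls = _softmax(c)
        # source: minimize -log sigma on real, -log(1-sigma) on fake
        ds = ((p_src - 1.0) if is_real else p_src)[:, None] / n
        # class: minimize -log p_target on both batches
        dc = p_cls.copy()
        dc[np.arange(n), y_idx] -= 1.0
        dc /= n
        g_src, dh_s = _backward(model.src_params, scache, ds, act_last=False)
        g_cls, dh_c = _backward(model.cls_params, ccache, dc, act_last=False)
        g_trunk, _ = _backward(model.trunk_params, tcache, dh_s + dh_c, act_last=True)
        for acc, g in zip(grads_total, g_trunk + g_src + g_cls):
            acc += g
    opt.step(d_params, grads_total)


def _g_update(
    model: GanModel,
    opt: _Adam,
    onehot: np.ndarray,
    z: np.ndarray,
    y_idx: np.ndarray,
    objective: str,
) -> None:
    """One generator step; gradient flows through the frozen discriminator."""
    n = onehot.shape[0]
    C = len(model.class_order)
    gin = np.hstack([onehot, z])
    x_fake, gcache = _forward(model.gen_params, gin, act_last=False)
    h, tcache = _forward(model.trunk_params, x_fake, act_last=True)
    s, scache = _forward(model.src_params, h, act_last=False)
    c, ccache = _forward(model.cls_params, h, act_last=False)
    p_src = _sigmoid(s[:, 0])
    p_cls = _softmax(c)

    if objective == "ac_gan_standard":
        # ascend log sigma(s) + log p_intended  (descend the negatives)
        ds = (p_src - 1.0)[:, None] / n
        dc = p_cls.copy()
        dc[np.arange(n), y_idx] -= 1.0
        dc /= n
    else:  # paper_literal: descend log(1 - sigma(s)) + log p_intended
        ds = (-p_src)[:, None] / n
        dc = -p_cls.copy()
        dc[np.arange(n), y_idx] += 1.0
        dc /= n

    _, dh_s = _backward(model.src_params, scache, ds, act_last=False)
    _, dh_c = _backward(model.cls_params, ccache, dc, act_last=False)
    _, dx = _backward(model.trunk_params, tcache, dh_s + dh_c, act_last=True)
    g_gen, _ = _backward(model.gen_params, gcache, dx, act_last=False)
    opt.step(model.gen_params, g_gen)


def train_gan(
    X_train: ExpressionMatrix,
    y_train: LabelVector,
    cfg: GanConfig,
) -> GanModel:
    """Train the class-conditional GAN on one training fold.

    Features are standardized to zero mean / unit variance (per gene, on the
    training fold) before training; the scaling is stored on the model and
    inverted at generation time.  Deterministic given cfg.seed.
    """
    counts = y_train.class_counts()
    absent = [c for c, k in counts.items() if k == 0]
    if absent:
        raise ValueError(f"classes absent from training fold: {absent}")
    small = [c for c, k in counts.items() if k < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 training samples: {small}")

    rng = np.random.default_rng(cfg.seed)
    p = X_train.n_genes
    C = len(y_train.class_order)
    center = X_train.values.mean(axis=1)
    scale = X_train.values.std(axis=1, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)

    hidden = list(cfg.hidden_sizes)
    model = GanModel(
        gene_ids=list(X_train.gene_ids),
        class_order=list(y_train.class_order),
        seen_classes=[c for c in y_train.class_order if counts[c] > 0],
        cfg=cfg,
        gen_params=_init_params([C + cfg.noise_dim] + hidden + [p], rng),
        trunk_params=_init_params([p] + hidden, rng),
        src_params=_init_params([hidden[-1], 1], rng),
        cls_params=_init_params([hidden[-1], C], rng),
        feature_center=center,
        feature_scale=scale,
    )

    x_all = model.to_standardized(X_train.samples_view())
    y_all = y_train.codes()
    n = x_all.shape[0]
    batch = n if cfg.batch_size is None else min(cfg.batch_size, n)

    d_opt = _Adam(model.trunk_params + model.src_params + model.cls_params, cfg.learning_rate)
    g_opt = _Adam(model.gen_params, cfg.learning_rate)

    anneal_until = max(1, int(0.8 * cfg.epochs))
    ema_params: list[np.ndarray] | None = None
    for epoch in range(cfg.epochs):
        idx = rng.permutation(n)[:batch] if batch < n else np.arange(n)
        x_real, y_real = x_all[idx], y_all[idx]
        sigma = cfg.instance_noise * max(0.0, 1.0 - epoch / anneal_until)
        for _ in range(cfg.d_steps_per_g_step):
            # intended classes mirror the real batch's class composition
            y_fake = y_real
            z = rng.standard_normal((len(y_fake), cfg.noise_dim))
            onehot = np.eye(C)[y_fake]
            x_fake = model.generator_forward(onehot, z)
            xr, xf = x_real, x_fake
            if sigma > 0:  # annealed instance noise into the discriminator
                xr = xr + sigma * rng.standard_normal(xr.shape)
                xf = xf + sigma * rng.standard_normal(xf.shape)
            _d_update(model, d_opt, xr, y_real, xf, y_fake)
        y_fake = y_real
        z = rng.standard_normal((len(y_fake), cfg.noise_dim))
        onehot = np.eye(C)[y_fake]
        _g_update(model, g_opt, onehot, z, y_fake, cfg.generator_objective)
        if cfg.ema_decay > 0:
            if ema_params is None:
                ema_params = [p.copy() for p in model.gen_params]
            else:
                for e, p_ in zip(ema_params, model.gen_params):
                    e *= cfg.ema_decay
                    e += (1.0 - cfg.ema_decay) * p_

        # epoch diagnostics on the current batch
        p_rr, pc_r = model.discriminate(x_real)
        x_fake = model.generator_forward(onehot, z)
        p_rf, pc_f = model.discriminate(x_fake)
        losses = gan_losses(p_rr, 1.0 - p_rf, pc_r, y_real, pc_f, y_fake)
        model.loss_history.append((losses.loss_x, losses.loss_c))

    if ema_params is not None:
        model.gen_params = ema_params
    return model


MAX_FILTER_ROUNDS = 20


def generate(
    model: GanModel,
    class_label: str,
    n: int,
    seed: int = 0,
) -> SyntheticBatch:
    """Sample ``n`` labeled synthetic expression vectors for one class.

    Output is on the original expression scale.  With
    cfg.filter_threshold set, candidates whose discriminator class
    probability for ``class_label`` falls below the threshold are rejected
    and resampled for up to a bounded number of rounds; a short batch with
    a warning is returned if the budget runs out.
    """
    if class_label not in model.seen_classes:
        raise ValueError(
            f"class {class_label!r} was not present in the GAN training fold"
        )
    if n < 0:
        raise ValueError("n must be >= 0")

    rng = np.random.default_rng(seed)
    C = len(model.class_order)
    cls_idx = model.class_order.index(class_label)
    threshold = model.cfg.filter_threshold

    accepted: list[np.ndarray] = []
    rounds = 0
    need = n
    while need > 0 and rounds < MAX_FILTER_ROUNDS:
        z = rng.standard_normal((need, model.cfg.noise_dim))
        onehot = np.zeros((need, C))
        onehot[:, cls_idx] = 1.0
        x_std = model.generator_forward(onehot, z)
        if threshold is None:
            accepted.append(x_std)
            need = 0
            break
        _, p_cls = model.discriminate(x_std)
        keep = p_cls[:, cls_idx] >= threshold
        if keep.any():
            accepted.append(x_std[keep])
        need = n - sum(a.shape[0] for a in accepted)
        rounds += 1

    x_std = np.vstack(accepted) if accepted else np.empty((0, len(model.gene_ids)))
    x_std = x_std[:n]
    short = x_std.shape[0] < n
    if short:
        warnings.warn(
            f"discriminator filter accepted only {x_std.shape[0]}/{n} samples "
            f"for class {class_label!r} after {MAX_FILTER_ROUNDS} rounds",
            ShortGenerationWarning,
            stacklevel=2,
        )
    values = model.to_original_scale(x_std)
    m = values.shape[0]
    sample_ids = [f"synthetic:{class_label}:{seed}:{i}" for i in range(m)]
    return SyntheticBatch(
        gene_ids=list(model.gene_ids),
        sample_ids=sample_ids,
        labels=[class_label] * m,
        values=values,
        short=short,
    )
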
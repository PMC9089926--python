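"""Perceptual component: a two-RBM Deep Belief Network with a mixed
unsupervised/reinforcement learning rule on its top layer.

Both RBMs are built from Bernoulli-logistic stochastic units. A unit j
with activation potential p_j = Σ_i w_ji v_i (+ bias, if enabled) fires
with probability σ(p_j) = 1 / (1 + exp(−p_j)). Weights are bidirectional:
the same matrix drives the upward (visible→hidden) and downward
(hidden→visible) passes.

The first RBM (retina → H1) is pretrained offline with Contrastive
Divergence (CD-1):

    Δw_ij = ε (⟨v_i h_j⟩_data − ⟨v_i h_j⟩_model)

where the data term is the product of the input and the hidden
activation it evokes, and the model term comes from one
reconstruct-and-reactivate Gibbs cycle.

The second RBM (H1 → H2) learns online during the task with a convex
mixture of CD and REINFORCE, weighted by λ:

    Δw_ij = λ · ε (⟨v_i h_j⟩_data − ⟨v_i h_j⟩_model)
          + (1−λ) · α (r − r̄)(y_j − σ(p_j)) x_i

λ = 1 is pure unsupervised learning, λ = 0 pure reinforcement learning.
The REINFORCE term reuses the sampled hidden activation y and firing
probabilities of the trial's action-selection pass, so the same
behavioural episode drives both terms.

Sampling convention: every sampler can consume either a numpy Generator
or a pre-drawn uniform vector. The uniform-consumption order is fixed
(data hidden, then reconstruction visible, then model hidden), which
makes whole training runs bit-reproducible and lets a fast inlined
kernel be checked against these reference functions on identical
random streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "RbmLayer",
    "RbmDelta",
    "Dbn",
    "LearnConfig",
    "CdStats",
    "unit_potentials",
    "sample_bernoulli",
    "cd1_statistics",
    "cd_update",
    "mixed_update",
    "dbn_encode",
    "dbn_reconstruct",
    "pretrain_rbm1",
]


@dataclass
class RbmLayer:
    """One RBM: bidirectional weights plus optional visible/hidden biases.

    ``W`` has shape (hidden, visible); ``W[j, i]`` is w_ji. When
    ``use_bias`` is False the bias vectors are kept at zero and never
    updated.
    """

    W: np.ndarray
    b_vis: np.ndarray
    b_hid: np.ndarray
    use_bias: bool = True

    @property
    def visible_size(self) -> int:
        return self.W.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.W.shape[0]

    @classmethod
    def init(
        cls,
        visible_size: int,
        hidden_size: int,
        rng: np.random.Generator,
        scale: float = 0.01,
        use_bias: bool = True,
    ) -> "RbmLayer":
        """Small zero-mean Gaussian weight init; biases start at zero."""
        W = rng.normal(0.0, scale, size=(hidden_size, visible_size))
        return cls(
            W=W,
            b_vis=np.zeros(visible_size),
            b_hid=np.zeros(hidden_size),
            use_bias=use_bias,
        )

    def copy(self) -> "RbmLayer":
        return RbmLayer(self.W.copy(), self.b_vis.copy(), self.b_hid.copy(), self.use_bias)


@dataclass
class RbmDelta:
    """A weight/bias update for one RBM; bias deltas are zero if bias is off."""

    dW: np.ndarray
    db_vis: np.ndarray
    db_hid: np.ndarray

    def apply_to(self, layer: RbmLayer) -> None:
        layer.W += self.dW
        if layer.use_bias:
            layer.b_vis += self.db_vis
            layer.b_hid += self.db_hid

    def __mul__(self, c: float) -> "RbmDelta":
        return RbmDelta(self.dW * c, self.db_vis * c, self.db_hid * c)

    __rmul__ = __mul__

    def __add__(self, other: "RbmDelta") -> "RbmDelta":
        return RbmDelta(
            self.dW + other.dW, self.db_vis + other.db_vis, self.db_hid + other.db_hid
        )


@dataclass
class Dbn:
    """Two stacked RBMs: retina → H1 (offline CD) → H2 (online mixed rule)."""

    rbm1: RbmLayer
    rbm2: RbmLayer
    rbm1_pretrained: bool = False

    def __post_init__(self) -> None:
        if self.rbm2.visible_size != self.rbm1.hidden_size:
            raise ValueError(
                f"rbm2 visible size {self.rbm2.visible_size} must equal "
                f"rbm1 hidden size {self.rbm1.hidden_size}"
            )


@dataclass
class LearnConfig:
    """Learning-rule parameters for the top RBM's mixed update.

    lambda_mix : λ, convex weight of the CD term (1 = pure UL, 0 = pure RL).
    eps : ε, CD learning rate.
    alpha : α, REINFORCE learning rate.
    cd_k : number of Gibbs reconstruction cycles (the model uses 1).
    rl_factor : form of the REINFORCE eligibility factor for these hidden
        units: ``"potential"`` uses (y_j − p_j) with the raw activation
        potential, ``"sigmoid"`` uses (y_j − σ(p_j)). The raw-potential
        form self-limits the potentials near the sigmoid's stochastic
        range, so the units keep exploring indefinitely; the σ form is
        the textbook Bernoulli policy gradient but lets units saturate
        and freeze.
    """

    lambda_mix: float
    eps: float = 0.02
    alpha: float = 0.01
    cd_k: int = 1
    rl_factor: str = "sigmoid"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError(f"lambda_mix must lie in [0, 1], got {self.lambda_mix}")
        if self.eps <= 0 or self.alpha <= 0:
            raise ValueError("learning rates must be positive")
        if self.cd_k < 1:
            raise ValueError("cd_k must be a positive integer")
        if self.rl_factor not in ("potential", "sigmoid"):
            raise ValueError(f"rl_factor must be 'potential' or 'sigmoid', got {self.rl_factor!r}")


@dataclass
class CdStats:
    """Correlation products and activations of one CD cycle."""

    pos: np.ndarray  # outer(h_data, v_data), shape (hidden, visible)
    neg: np.ndarray  # outer(h_model, v_model)
    h_data: np.ndarray
    v_model: np.ndarray
    h_model: np.ndarray
    p_h_data: np.ndarray = field(default=None, repr=False)
    p_v_model: np.ndarray = field(default=None, repr=False)


def unit_potentials(layer: RbmLayer, v: np.ndarray, direction: str = "up") -> np.ndarray:
    """Activation potentials p = W·v (up) or Wᵀ·h (down), plus bias if enabled."""
    v = np.asarray(v, dtype=np.float64)
    if direction == "up":
        if v.shape[-1] != layer.visible_size:
            raise ValueError(f"expected visible vector of length {layer.visible_size}")
        p = layer.W @ v
        if layer.use_bias:
            p = p + layer.b_hid
        return p
    if direction == "down":
        if v.shape[-1] != layer.hidden_size:
            raise ValueError(f"expected hidden vector of length {layer.hidden_size}")
        p = layer.W.T @ v
        if layer.use_bias:
            p = p + layer.b_vis
        return p
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def sample_bernoulli(
    potentials: np.ndarray, rng: np.random.Generator | np.ndarray
) -> np.ndarray:
    """Sample Bernoulli-logistic units: unit j is 1 with probability σ(p_j).

    ``rng`` may be a Generator (fresh uniforms are drawn) or an array of
    uniforms in [0, 1) of matching length (for replayable streams).
    """
    p = expit(np.asarray(potentials, dtype=np.float64))
    u = rng.random(p.shape) if isinstance(rng, np.random.Generator) else np.asarray(rng)
    return (u < p).astype(np.float64)


def cd1_statistics(
    layer: RbmLayer,
    v_data: np.ndarray,
    rng: np.random.Generator | np.ndarray,
    k: int = 1,
) -> CdStats:
    """One CD-k cycle from a visible data vector; returns both correlation products.

    Data pass: sample h from v_data. Then k reconstruction cycles, each
    sampling a visible reconstruction from the current hidden sample and a
    new hidden sample from it. Sampled (not mean-field) activations are
    used in both products. Uniform-consumption order: h_data, then per
    cycle (v_model, h_model).
    """
    v_data = np.asarray(v_data, dtype=np.float64)
    H, V = layer.hidden_size, layer.visible_size
    if isinstance(rng, np.random.Generator):
        u = rng.random(H + k * (V + H))
    else:
        u = np.asarray(rng)
    p_h_data = expit(unit_potentials(layer, v_data, "up"))
    h = (u[:H] < p_h_data).astype(np.float64)
    h_data = h
    off = H
    p_v = None
    for _ in range(k):
        p_v = expit(unit_potentials(layer, h, "down"))
        v_model = (u[off : off + V] < p_v).astype(np.float64)
        off += V
        p_h = expit(unit_potentials(layer, v_model, "up"))
        h = (u[off : off + H] < p_h).astype(np.float64)
        off += H
    h_model = h
    return CdStats(
        pos=np.outer(h_data, v_data),
        neg=np.outer(h_model, v_model),
        h_data=h_data,
        v_model=v_model,
        h_model=h_model,
        p_h_data=p_h_data,
        p_v_model=p_v,
    )


def _cd_delta_from_stats(layer: RbmLayer, v_data: np.ndarray, stats: CdStats, eps: float) -> RbmDelta:
    dW = eps * (stats.pos - stats.neg)
    if layer.use_bias:
        db_vis = eps * (v_data - stats.v_model)
        db_hid = eps * (stats.h_data - stats.h_model)
    else:
        db_vis = np.zeros(layer.visible_size)
        db_hid = np.zeros(layer.hidden_size)
    return RbmDelta(dW, db_vis, db_hid)


def cd_update(
    layer: RbmLayer,
    v_data: np.ndarray,
    eps: float,
    rng: np.random.Generator | np.ndarray,
    k: int = 1,
    apply: bool = False,
) -> RbmDelta:
    """Single-sample CD update Δw = ε(pos − neg); optionally applied in place."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    v_data = np.asarray(v_data, dtype=np.float64)
    stats = cd1_statistics(layer, v_data, rng, k=k)
    delta = _cd_delta_from_stats(layer, v_data, stats, eps)
    if apply:
        delta.apply_to(layer)
    return delta


def mixed_update(
    layer: RbmLayer,
    v_data: np.ndarray,
    e: float,
    y: np.ndarray,
    potentials: np.ndarray,
    cfg: LearnConfig,
    rng: np.random.Generator | np.ndarray,
    apply: bool = False,
) -> RbmDelta:
    """Convex CD/REINFORCE mixture for the top RBM.

    Parameters
    ----------
    v_data : sampled hidden activation of the lower RBM (this layer's input x).
    e : reward prediction error r − r̄ from the critic.
    y : the sampled hidden activation used for this trial's action selection;
        it doubles as the CD data-phase hidden sample, so no fresh data-phase
        sample is drawn.
    potentials : activation potentials of that same pass (pre-sigmoid).
    rng : Generator or uniform vector of length visible + hidden
        (reconstruction then model hidden).

    Returns Δw = λ·ε(pos − neg) + (1−λ)·α·e·outer(y − σ(p), x).
    """
    lam = cfg.lambda_mix
    v_data = np.asarray(v_data, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    H, V = layer.hidden_size, layer.visible_size
    if isinstance(rng, np.random.Generator):
        u = rng.random(V + H)
    else:
        u = np.asarray(rng)

    # CD term, reusing y as the data-phase hidden sample
    p_v = expit(unit_potentials(layer, y, "down"))
    v_model = (u[:V] < p_v).astype(np.float64)
    p_h = expit(unit_potentials(layer, v_model, "up"))
    h_model = (u[V : V + H] < p_h).astype(np.float64)
    stats = CdStats(
        pos=np.outer(y, v_data),
        neg=np.outer(h_model, v_model),
        h_data=y,
        v_model=v_model,
        h_model=h_model,
    )
    cd_delta = _cd_delta_from_stats(layer, v_data, stats, cfg.eps)

    # REINFORCE term on the same episode's activations
    potentials = np.asarray(potentials, dtype=np.float64)
    p_factor = potentials if cfg.rl_factor == "potential" else expit(potentials)
    rl_dW = cfg.alpha * e * np.outer(y - p_factor, v_data)
    rl_db_hid = (
        cfg.alpha * e * (y - p_factor) if layer.use_bias else np.zeros(H)
    )
    rl_delta = RbmDelta(rl_dW, np.zeros(V), rl_db_hid)

    delta = lam * cd_delta + (1.0 - lam) * rl_delta
    if apply:
        delta.apply_to(layer)
    return delta


def dbn_encode(
    dbn: Dbn,
    retina: np.ndarray,
    mode: str = "sample",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Encode a retina vector to the top hidden layer.

    ``sample`` draws binary activations layer by layer; ``meanfield``
    propagates firing probabilities deterministically.
    """
    retina = np.asarray(retina, dtype=np.float64)
    if mode == "sample":
        if rng is None:
            raise ValueError("sample mode requires an rng")
        h1 = sample_bernoulli(unit_potentials(dbn.rbm1, retina, "up"), rng)
        return sample_bernoulli(unit_potentials(dbn.rbm2, h1, "up"), rng)
    if mode == "meanfield":
        p1 = expit(unit_potentials(dbn.rbm1, retina, "up"))
        return expit(unit_potentials(dbn.rbm2, p1, "up"))
    raise ValueError(f"mode must be 'sample' or 'meanfield', got {mode!r}")


def dbn_reconstruct(dbn: Dbn, retina: np.ndarray) -> np.ndarray:
    """Deterministic mean-field reconstruction of the retina through the DBN.

    Probabilities are propagated up to the top layer and back down; the
    result is a visible probability vector in [0, 1]^2352.
    """
    retina = np.asarray(retina, dtype=np.float64)
    p1 = expit(unit_potentials(dbn.rbm1, retina, "up"))
    p2 = expit(unit_potentials(dbn.rbm2, p1, "up"))
    p1_down = expit(unit_potentials(dbn.rbm2, p2, "down"))
    return expit(unit_potentials(dbn.rbm1, p1_down, "down"))


def reconstruct_batch(dbn: Dbn, retinas: np.ndarray) -> np.ndarray:
    """Mean-field reconstructions for a (n, visible) matrix of retinas."""
    retinas = np.asarray(retinas, dtype=np.float64)
    b1h = dbn.rbm1.b_hid if dbn.rbm1.use_bias else 0.0
    b1v = dbn.rbm1.b_vis if dbn.rbm1.use_bias else 0.0
    b2h = dbn.rbm2.b_hid if dbn.rbm2.use_bias else 0.0
    b2v = dbn.rbm2.b_vis if dbn.rbm2.use_bias else 0.0
    p1 = expit(retinas @ dbn.rbm1.W.T + b1h)
    p2 = expit(p1 @ dbn.rbm2.W.T + b2h)
    p1_down = expit(p2 @ dbn.rbm2.W + b2v)
    return expit(p1_down @ dbn.rbm1.W + b1v)


def pretrain_rbm1(
    rbm1: RbmLayer,
    retinas: np.ndarray,
    epochs: int,
    eps: float,
    rng: np.random.Generator,
    engine: str = "numba",
) -> list[float]:
    """Offline CD-1 pretraining of the first RBM on the stimulus set.

    Per-sample updates over shuffled epochs. Returns a per-epoch trace of
    the mean squared reconstruction error (input vs the mean-field
    reconstruction probability of the CD cycle), which is monitored but
    never used for learning. Marks no layer as pretrained by itself —
    the caller flags the DBN.

    Each epoch draws a permutation and one uniform block from ``rng``;
    the default inlined kernel and the ``numpy`` reference path consume
    the identical stream, so both yield the same weights.
    """
    from . import _kernel

    retinas = np.ascontiguousarray(retinas, dtype=np.float64)
    n = retinas.shape[0]
    H, V = rbm1.hidden_size, rbm1.visible_size
    nu = _kernel.n_uniforms_cd(V, H)
    trace: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        U = rng.random((n, nu))
        if engine == "numba":
            err = _kernel.pretrain_epoch_kernel(
                rbm1.W, rbm1.b_vis, rbm1.b_hid, rbm1.use_bias,
                retinas, order.astype(np.int64), U, eps,
            )
        elif engine == "numpy":
            err = 0.0
            for t, i in enumerate(order):
                v = retinas[i]
                # cd1_statistics consumes uniforms as h_data | v_model | h_model
                stats = cd1_statistics(rbm1, v, U[t])
                _cd_delta_from_stats(rbm1, v, stats, eps).apply_to(rbm1)
                err += float(np.mean((v - stats.p_v_model) ** 2))
            err /= n
        else:
            raise ValueError(f"unknown engine {engine!r}")
        trace.append(float(err))
    return trace
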
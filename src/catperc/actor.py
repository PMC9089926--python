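"""Motor component: a single-layer perceptron of Bernoulli-logistic units
trained with REINFORCE.

The actor reads the DBN's top hidden activation x and emits a binary
action vector y, each bit drawn independently with probability
σ(potential). Learning follows the likelihood-ratio policy gradient
with the critic's prediction as baseline:

    Δw_ji = α (r − r̄)(y_j − σ(p_j)) x_i

which ascends expected reward: action bits that fired more than their
current probability are reinforced when the outcome beats the
prediction, and suppressed when it falls short.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["ActorState", "ActorDelta", "act", "reinforce_update"]


@dataclass
class ActorState:
    """Actor weights: W has shape (action_len, input_size); optional bias."""

    W: np.ndarray
    b: np.ndarray
    use_bias: bool = True

    @property
    def input_size(self) -> int:
        return self.W.shape[1]

    @property
    def action_len(self) -> int:
        return self.W.shape[0]

    @classmethod
    def init(
        cls,
        input_size: int,
        action_len: int,
        rng: np.random.Generator,
        scale: float = 0.01,
        use_bias: bool = True,
    ) -> "ActorState":
        W = rng.normal(0.0, scale, size=(action_len, input_size))
        return cls(W=W, b=np.zeros(action_len), use_bias=use_bias)

    def copy(self) -> "ActorState":
        return ActorState(self.W.copy(), self.b.copy(), self.use_bias)


@dataclass
class ActorDelta:
    dW: np.ndarray
    db: np.ndarray

    def apply_to(self, actor: ActorState) -> None:
        actor.W += self.dW
        if actor.use_bias:
            actor.b += self.db


def act(
    actor: ActorState,
    x: np.ndarray,
    rng: np.random.Generator | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a binary action from the current policy.

    Returns ``(y, p_fire)``: the sampled action bits and their firing
    probabilities σ(W·x + b), kept for the learning step. ``rng`` may be
    a Generator or a pre-drawn uniform vector of length action_len.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != actor.input_size:
        raise ValueError(f"expected input of length {actor.input_size}, got {x.shape[-1]}")
    pot = actor.W @ x
    if actor.use_bias:
        pot = pot + actor.b
    p_fire = expit(pot)
    u = rng.random(p_fire.shape) if isinstance(rng, np.random.Generator) else np.asarray(rng)
    y = (u < p_fire).astype(np.float64)
    return y, p_fire


def reinforce_update(
    actor: ActorState,
    x: np.ndarray,
    y: np.ndarray,
    p_fire: np.ndarray,
    r: float,
    r_bar: float,
    alpha: float,
    apply: bool = False,
) -> ActorDelta:
    """REINFORCE step Δw = α(r − r̄)·outer(y − p_fire, x).

    Zero when the outcome matches the critic's prediction (r == r̄);
    linear in α. Optionally applied in place.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    p_fire = np.asarray(p_fire, dtype=np.float64)
    surprise = alpha * (r - r_bar)
    dW = surprise * np.outer(y - p_fire, x)
    db = surprise * (y - p_fire) if actor.use_bias else np.zeros(actor.action_len)
    delta = ActorDelta(dW, db)
    if apply:
        delta.apply_to(actor)
    return delta
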
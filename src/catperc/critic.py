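"""Motivational component: reward scaling, reward prediction, prediction error.

Three sub-modules mirror the critic of an actor-critic architecture:

* the *motivator* rescales the environment's raw L1 distance into a
  reward signal r ∈ [0, 1] via the unique affine map with r = 1 for a
  perfect action and r = 0 for its full complement:
  r = 1 − distance / action_len;
* the *predictor*, a small multi-layer perceptron (sigmoid hidden layer,
  single linear output unit), estimates the expected reward r̄ from the
  DBN's top hidden activation;
* the *prediction error* is the surprise e = r − r̄, broadcast as the
  learning signal to the actor, the top perceptual layer and the
  predictor itself.

The predictor is trained per trial by one gradient step on ½e²
(LMS with backprop through the hidden layer), using the same top-layer
activation that drove action selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "CriticState",
    "scale_reward",
    "predict_reward",
    "prediction_error",
    "train_predictor",
]


@dataclass
class CriticState:
    """Predictor MLP weights plus the last trial's (r, r̄, e) for logging.

    ``W1`` (hidden, input) and ``b1`` feed the sigmoid hidden layer;
    ``w2`` (hidden,) and ``b2`` the linear output unit.
    """

    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float = 0.0
    last_r: float = np.nan
    last_r_bar: float = np.nan
    last_e: float = np.nan

    @property
    def input_size(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    @classmethod
    def init(
        cls,
        input_size: int,
        hidden_size: int,
        rng: np.random.Generator,
        scale: float = 0.01,
        init_r_bar: float = 0.0,
    ) -> "CriticState":
        """``init_r_bar`` sets the output bias, i.e. the initial reward
        expectation. An optimistic value (near 1) makes early surprise
        negative, which keeps the actor exploring until outcomes match
        the expectation."""
        return cls(
            W1=rng.normal(0.0, scale, size=(hidden_size, input_size)),
            b1=np.zeros(hidden_size),
            w2=rng.normal(0.0, scale, size=hidden_size),
            b2=float(init_r_bar),
        )

    def copy(self) -> "CriticState":
        return CriticState(
            self.W1.copy(), self.b1.copy(), self.w2.copy(), self.b2,
            self.last_r, self.last_r_bar, self.last_e,
        )


def scale_reward(distance: int, action_len: int) -> float:
    """Affine reward scaling r = 1 − distance / action_len.

    r = 1 iff the action equals the ideal vector, r = 0 iff it is the
    full complement; order-reversing in the distance.
    """
    if not 0 <= distance <= action_len:
        raise ValueError(f"distance {distance} outside [0, {action_len}]")
    return 1.0 - distance / action_len


def predict_reward(critic: CriticState, x: np.ndarray) -> float:
    """Deterministic forward pass: r̄ = w2·σ(W1·x + b1) + b2."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != critic.input_size:
        raise ValueError(f"expected input of length {critic.input_size}, got {x.shape[-1]}")
    h = expit(critic.W1 @ x + critic.b1)
    return float(critic.w2 @ h + critic.b2)


def prediction_error(r: float, r_bar: float) -> float:
    """Surprise e = r − r̄ (exact subtraction)."""
    return r - r_bar


def train_predictor(critic: CriticState, x: np.ndarray, e: float, alpha: float) -> None:
    """One gradient-descent step on ½e² with e as the output-layer error.

    Updates the predictor in place. The hidden-layer error uses the
    pre-update output weights (standard backprop); a zero e leaves the
    weights unchanged, and the first-step delta is linear in alpha.
    """
    x = np.asarray(x, dtype=np.float64)
    h = expit(critic.W1 @ x + critic.b1)
    delta_h = e * critic.w2 * h * (1.0 - h)
    critic.w2 += alpha * e * h
    critic.b2 += alpha * e
    critic.W1 += alpha * np.outer(delta_h, x)
    critic.b1 += alpha * delta_h
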
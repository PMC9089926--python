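"""Sorting-task environment: rule, ideal action vectors, trial feedback.

Before a run the environment fixes a sorting rule — colour, shape or
size — and draws four "ideal" binary action vectors, one per attribute
value of the rule's category. Every stimulus is then owned by exactly
one ideal vector (16 stimuli each). During the task the environment
scores an emitted action by its L1 distance from the ideal vector of
the current stimulus; the critic later rescales that distance into a
reward in [0, 1].

Ideal vectors are drawn with a minimum pairwise Hamming separation so
that no two categories share near-identical targets, which would make
the reward signal uninformative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stimuli import COLOURS, SHAPES, SIZES, Stimulus

__all__ = ["RULES", "TaskSpec", "TrialOutcome", "make_task", "raw_distance", "epoch_schedule"]

RULES = ("colour", "shape", "size")

_RULE_AXIS = {"colour": 0, "shape": 1, "size": 2}
_RULE_VALUES = {"colour": COLOURS, "shape": SHAPES, "size": SIZES}


@dataclass(frozen=True)
class TaskSpec:
    """A fixed sorting task: rule, four ideal actions, stimulus→category map.

    Attributes
    ----------
    rule : str
        Sorting attribute, one of ``colour``, ``shape``, ``size``.
    action_len : int
        Length of the binary action vectors.
    ideal_actions : ndarray, shape (4, action_len)
        Ideal binary vector for each of the four attribute values of the
        rule's category, in canonical attribute order.
    category_of : ndarray, shape (64,)
        Category index (0..3) of each stimulus in canonical dataset order.
    seed : int
        Seed the ideal vectors were drawn with.
    """

    rule: str
    action_len: int
    ideal_actions: np.ndarray = field(repr=False)
    category_of: np.ndarray = field(repr=False)
    seed: int = 0

    def ideal_for(self, stimulus_index: int) -> np.ndarray:
        """Ideal action vector y* for the stimulus at a canonical index."""
        return self.ideal_actions[self.category_of[stimulus_index]]

    def category_of_stimulus(self, stimulus: Stimulus) -> int:
        return stimulus.triple.indices[_RULE_AXIS[self.rule]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rule": self.rule,
            "action_len": self.action_len,
            "seed": self.seed,
            "ideal_actions": self.ideal_actions.astype(int).tolist(),
            "values": list(_RULE_VALUES[self.rule]),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TaskSpec":
        payload = json.loads(Path(path).read_text())
        ideal = np.asarray(payload["ideal_actions"], dtype=np.float64)
        return cls(
            rule=payload["rule"],
            action_len=payload["action_len"],
            ideal_actions=ideal,
            category_of=_category_map(payload["rule"]),
            seed=payload["seed"],
        )


@dataclass(frozen=True)
class TrialOutcome:
    """Environment feedback for one trial: L1 distance and its raw value."""

    distance: int
    action_len: int


def _category_map(rule: str) -> np.ndarray:
    """Category index of each of the 64 stimuli in canonical order.

    Canonical dataset order is colour-major, then shape, then size, so the
    attribute indices of stimulus i are (i // 16, (i // 4) % 4, i % 4).
    """
    idx = np.arange(64)
    axes = np.stack([idx // 16, (idx // 4) % 4, idx % 4])
    cats = axes[_RULE_AXIS[rule]]
    cats.flags.writeable = False
    return cats


def make_task(rule: str, action_len: int = 10, rng_seed: int = 0, max_tries: int = 1000) -> TaskSpec:
    """Draw a TaskSpec: four distinct random binary ideal vectors.

    The four vectors are redrawn until every pair is at Hamming distance
    at least ``max(2, action_len // 4)``. Regeneration with the same seed
    is identical.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    if action_len < 4:
        raise ValueError("action_len must be at least 4")
    min_dist = max(2, action_len // 4)
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_tries):
        vecs = (rng.random((4, action_len)) < 0.5).astype(np.float64)
        dists = [
            np.abs(vecs[a] - vecs[b]).sum() for a in range(4) for b in range(a + 1, 4)
        ]
        if min(dists) >= min_dist:
            vecs.flags.writeable = False
            return TaskSpec(
                rule=rule,
                action_len=action_len,
                ideal_actions=vecs,
                category_of=_category_map(rule),
                seed=rng_seed,
            )
    raise RuntimeError(
        f"could not draw 4 ideal vectors with pairwise Hamming distance >= {min_dist} "
        f"in {max_tries} tries; try a larger action_len"
    )


def raw_distance(y_star: np.ndarray, y: np.ndarray) -> int:
    """L1 norm of y* − y; the Hamming distance for binary vectors."""
    y_star = np.asarray(y_star)
    y = np.asarray(y)
    if y_star.shape != y.shape:
        raise ValueError(f"length mismatch: {y_star.shape} vs {y.shape}")
    return int(np.abs(y_star - y).sum())


def epoch_schedule(rng: np.random.Generator, n_stimuli: int = 64) -> np.ndarray:
    """Random presentation order for one epoch: a permutation of 0..n−1."""
    return rng.permutation(n_stimuli)
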
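"""Experiment orchestration: pretraining, trial phases, epochs, sweeps.

A run follows the task protocol: RBM-1 is pretrained offline on the 64
stimuli, then the model loops over epochs. Each epoch presents every
stimulus exactly once in random order, and each trial runs four phases:

1. perceive — sampled bottom-up encode of the retina to the top layer;
2. act — the actor emits a binary action vector;
3. feedback — the environment scores the action (L1 distance → reward);
4. learn — prediction error e = r − r̄ drives the mixed CD/REINFORCE
   update of the top RBM, the actor's REINFORCE step, and one predictor
   gradient step. RBM-1 stays frozen.

Final performance is the maximum over epochs of the 100-epoch moving
average of per-epoch mean reward (configurable to a plain final-window
mean).

Seeding: a run is a pure function of (config, seeds). The task seed
draws the ideal vectors, the weight seed drives initialisation and
pretraining, and the trial seed drives all within-task stochasticity.
Two engines share one random layout: a fast inlined kernel (default)
and a pure-numpy reference path built from the module-level operations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _kernel
from .actor import ActorState, act, reinforce_update
from .critic import CriticState, predict_reward, prediction_error, scale_reward, train_predictor
from .perceptual import (
    Dbn,
    LearnConfig,
    RbmLayer,
    mixed_update,
    pretrain_rbm1,
    sample_bernoulli,
    unit_potentials,
)
from .stimuli import RETINA_SIZE, Stimulus, dataset_retinas, generate_dataset
from .task import TaskSpec, epoch_schedule, make_task, raw_distance

__all__ = [
    "LAMBDA_LEVELS",
    "RunConfig",
    "ModelState",
    "TrialRecord",
    "RunLog",
    "build_model",
    "pretrain_for_config",
    "run_trial",
    "run_experiment",
    "sweep",
    "summarise",
    "save_checkpoint",
    "load_checkpoint",
]

# Mapping of condition labels to the CD mixing weight λ:
# L0 = pure UL ... L4 = pure RL.
LAMBDA_LEVELS = {"L0": 1.0, "L1": 0.1, "L2": 0.01, "L3": 0.001, "L4": 0.0}


@dataclass
class RunConfig:
    """Full configuration of one run; a run is reproducible from this alone."""

    rule: str = "colour"
    lambda_level: str | None = "L0"
    lambda_mix: float | None = None  # overrides lambda_level if set
    h1_size: int = 200
    h2_size: int = 10
    action_len: int = 10
    epochs: int = 15000
    eps: float = 0.02            # CD learning rate of the RBM-2 mixed rule
    rl_factor: str = "sigmoid"   # RBM-2 REINFORCE eligibility: "sigmoid" | "potential"
    h1_mode: str = "sample"      # bottom-up RBM-1 pass during trials: "sample" | "meanfield"
    alpha: float = 0.1           # REINFORCE learning rate (actor)
    actor_decay: float = 0.0     # per-trial actor weight decay (0 = pure Eq-4 REINFORCE)
    alpha_rbm2: float | None = 0.01    # RL rate of the RBM-2 mixed rule; None -> alpha
    alpha_critic: float | None = 0.0003  # predictor learning rate; None -> alpha
    critic_hidden: int = 50
    critic_init_r_bar: float = 0.0  # initial reward expectation (1 = optimistic start)
    pretrain_epochs: int = 300
    pretrain_eps: float = 0.01
    init_scale: float = 0.01
    rbm1_bias: bool = True
    rbm2_bias: bool = False
    actor_bias: bool = True
    task_seed: int = 0
    weight_seed: int = 0
    trial_seed: int = 0
    perf_window: int = 100
    perf_mode: str = "max_moving_avg"  # or "final_window"
    record_trials: bool = False
    engine: str = "numba"  # or "numpy" (reference path)

    @property
    def lam(self) -> float:
        if self.lambda_mix is not None:
            return float(self.lambda_mix)
        if self.lambda_level not in LAMBDA_LEVELS:
            raise ValueError(
                f"unknown lambda_level {self.lambda_level!r}; expected one of "
                f"{sorted(LAMBDA_LEVELS)} or an explicit lambda_mix"
            )
        return LAMBDA_LEVELS[self.lambda_level]

    @property
    def level_index(self) -> int | None:
        """0..4 for the named conditions (index grows with RL contribution)."""
        if self.lambda_level in LAMBDA_LEVELS:
            return list(LAMBDA_LEVELS).index(self.lambda_level)
        return None

    def learn_config(self) -> LearnConfig:
        return LearnConfig(
            lambda_mix=self.lam, eps=self.eps, alpha=self.alpha_r2,
            rl_factor=self.rl_factor,
        )

    @property
    def alpha_r2(self) -> float:
        return self.alpha if self.alpha_rbm2 is None else self.alpha_rbm2

    @property
    def alpha_c(self) -> float:
        return self.alpha if self.alpha_critic is None else self.alpha_critic


@dataclass
class ModelState:
    """All trainable components of the model."""

    dbn: Dbn
    actor: ActorState
    critic: CriticState

    def copy(self) -> "ModelState":
        return ModelState(
            dbn=Dbn(self.dbn.rbm1.copy(), self.dbn.rbm2.copy(), self.dbn.rbm1_pretrained),
            actor=self.actor.copy(),
            critic=self.critic.copy(),
        )


@dataclass
class TrialRecord:
    epoch: int
    stimulus_index: int
    action: np.ndarray
    distance: int
    r: float
    r_bar: float
    e: float


@dataclass
class RunLog:
    """Per-epoch reward trace, final performance and the trained model."""

    config: RunConfig
    task: TaskSpec
    epoch_rewards: np.ndarray
    epoch_mean_abs_e: np.ndarray
    final_performance: float
    state: ModelState
    pretrain_trace: list[float] = field(default_factory=list)
    trials: list[TrialRecord] = field(default_factory=list)


def _seed_streams(weight_seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent streams for (RBM-1 init + pretraining) and the rest.

    Splitting them lets a pretrained RBM-1 be cached and reused across
    conditions without changing the other components' initial weights.
    """
    ss = np.random.SeedSequence(weight_seed)
    child1, child2 = ss.spawn(2)
    return np.random.default_rng(child1), np.random.default_rng(child2)


def pretrain_for_config(
    cfg: RunConfig, retinas: np.ndarray | None = None
) -> tuple[RbmLayer, list[float]]:
    """Initialise and CD-pretrain RBM-1 as run_experiment would.

    The result depends only on (weight_seed, h1_size, pretrain_epochs,
    pretrain_eps, rbm1_bias, init_scale), so it can be cached and shared
    across λ levels, rules and top-layer sizes.
    """
    if retinas is None:
        retinas = dataset_retinas(generate_dataset())
    rng1, _ = _seed_streams(cfg.weight_seed)
    rbm1 = RbmLayer.init(
        RETINA_SIZE, cfg.h1_size, rng1, scale=cfg.init_scale, use_bias=cfg.rbm1_bias
    )
    trace = pretrain_rbm1(rbm1, retinas, cfg.pretrain_epochs, cfg.pretrain_eps, rng1)
    return rbm1, trace


def build_model(
    cfg: RunConfig,
    retinas: np.ndarray | None = None,
    pretrained_rbm1: RbmLayer | None = None,
) -> tuple[ModelState, list[float]]:
    """Assemble the full model, pretraining RBM-1 unless one is supplied."""
    if pretrained_rbm1 is None:
        rbm1, trace = pretrain_for_config(cfg, retinas)
    else:
        if pretrained_rbm1.hidden_size != cfg.h1_size:
            raise ValueError(
                f"pretrained RBM-1 has {pretrained_rbm1.hidden_size} hidden units, "
                f"config wants {cfg.h1_size}"
            )
        rbm1, trace = pretrained_rbm1.copy(), []
    _, rng2 = _seed_streams(cfg.weight_seed)
    rbm2 = RbmLayer.init(
        cfg.h1_size, cfg.h2_size, rng2, scale=cfg.init_scale, use_bias=cfg.rbm2_bias
    )
    actor = ActorState.init(
        cfg.h2_size, cfg.action_len, rng2, scale=cfg.init_scale, use_bias=cfg.actor_bias
    )
    critic = CriticState.init(
        cfg.h2_size, cfg.critic_hidden, rng2,
        scale=cfg.init_scale, init_r_bar=cfg.critic_init_r_bar,
    )
    dbn = Dbn(rbm1, rbm2, rbm1_pretrained=True)
    return ModelState(dbn, actor, critic), trace


def run_trial(
    state: ModelState,
    stimulus: Stimulus,
    task: TaskSpec,
    cfg: RunConfig,
    rng: np.random.Generator | np.ndarray,
    epoch: int = 0,
    stimulus_index: int = -1,
) -> TrialRecord:
    """Execute one trial's four phases, updating the model in place.

    ``rng`` may be a Generator or a pre-drawn uniform vector of length
    ``n_uniforms(H1, H2, action_len)`` laid out as in the kernel.
    """
    if not state.dbn.rbm1_pretrained:
        raise RuntimeError("RBM-1 must be pretrained before running trials")
    H1 = state.dbn.rbm1.hidden_size
    H2 = state.dbn.rbm2.hidden_size
    A = state.actor.action_len
    nU = _kernel.n_uniforms(H1, H2, A)
    u = rng.random(nU) if isinstance(rng, np.random.Generator) else np.asarray(rng)

    # phase 1: sampled encode
    h1 = sample_bernoulli(unit_potentials(state.dbn.rbm1, stimulus.retina, "up"), u[:H1])
    pot2 = unit_potentials(state.dbn.rbm2, h1, "up")
    h2 = sample_bernoulli(pot2, u[H1 : H1 + H2])

    # phase 2: act
    y, p_fire = act(state.actor, h2, u[H1 + H2 : H1 + H2 + A])

    # phase 3: environment feedback
    cat = task.category_of_stimulus(stimulus)
    y_star = task.ideal_actions[cat]
    d = raw_distance(y_star, y)
    r = scale_reward(d, A)

    # phase 4: learning
    r_bar = predict_reward(state.critic, h2)
    e = prediction_error(r, r_bar)
    mixed_update(
        state.dbn.rbm2, h1, e, h2, pot2, cfg.learn_config(),
        u[H1 + H2 + A :], apply=True,
    )
    actor_delta = reinforce_update(state.actor, h2, y, p_fire, r, r_bar, cfg.alpha)
    if cfg.actor_decay:
        state.actor.W *= 1.0 - cfg.actor_decay
        if state.actor.use_bias:
            state.actor.b *= 1.0 - cfg.actor_decay
    actor_delta.apply_to(state.actor)
    train_predictor(state.critic, h2, e, cfg.alpha_c)
    state.critic.last_r, state.critic.last_r_bar, state.critic.last_e = r, r_bar, e

    return TrialRecord(
        epoch=epoch, stimulus_index=stimulus_index, action=y,
        distance=d, r=r, r_bar=r_bar, e=e,
    )


def _final_performance(epoch_rewards: np.ndarray, cfg: RunConfig) -> float:
    w = min(cfg.perf_window, len(epoch_rewards))
    if w == 0:
        return float("nan")
    if cfg.perf_mode == "final_window":
        return float(epoch_rewards[-w:].mean())
    ma = np.convolve(epoch_rewards, np.ones(w) / w, mode="valid")
    return float(ma.max())


def run_experiment(
    cfg: RunConfig,
    dataset: list[Stimulus] | None = None,
    pretrained_rbm1: RbmLayer | None = None,
) -> RunLog:
    """Run the full protocol: pretrain, then epochs × 64 trials."""
    if dataset is None:
        dataset = generate_dataset()
    retinas = dataset_retinas(dataset)
    n_stim = len(dataset)
    task = make_task(cfg.rule, cfg.action_len, cfg.task_seed)
    state, pre_trace = build_model(cfg, retinas, pretrained_rbm1)

    H1, H2, A = cfg.h1_size, cfg.h2_size, cfg.action_len
    nU = _kernel.n_uniforms(H1, H2, A)
    rng = np.random.default_rng(cfg.trial_seed)

    epoch_rewards = np.empty(cfg.epochs)
    epoch_abs_e = np.empty(cfg.epochs)
    trials: list[TrialRecord] = []

    if cfg.engine == "numba":
        rbm1, rbm2 = state.dbn.rbm1, state.dbn.rbm2
        b1h = rbm1.b_hid if rbm1.use_bias else np.zeros(H1)
        p1 = expit(retinas @ rbm1.W.T + b1h)
        r_buf = np.empty(n_stim)
        e_buf = np.empty(n_stim)
        bc2_arr = np.array([state.critic.b2])
        cats = task.category_of.astype(np.int64)
        ystars = np.ascontiguousarray(task.ideal_actions, dtype=np.float64)
        for ep in range(cfg.epochs):
            schedule = epoch_schedule(rng, n_stim).astype(np.int64)
            U = rng.random((n_stim, nU))
            _kernel.epoch_kernel(
                p1, schedule, U,
                rbm2.W, rbm2.b_vis, rbm2.b_hid, rbm2.use_bias,
                state.actor.W, state.actor.b, state.actor.use_bias,
                state.critic.W1, state.critic.b1, state.critic.w2, bc2_arr,
                cats, ystars,
                cfg.lam, cfg.eps, cfg.alpha, cfg.alpha_r2, cfg.alpha_c,
                cfg.actor_decay,
                cfg.rl_factor == "potential", cfg.h1_mode == "meanfield",
                r_buf, e_buf,
            )
            epoch_rewards[ep] = r_buf.mean()
            epoch_abs_e[ep] = np.abs(e_buf).mean()
        state.critic.b2 = float(bc2_arr[0])
    elif cfg.engine == "numpy":
        for ep in range(cfg.epochs):
            schedule = epoch_schedule(rng, n_stim)
            U = rng.random((n_stim, nU))
            rs = np.empty(n_stim)
            es = np.empty(n_stim)
            for t, s in enumerate(schedule):
                rec = run_trial(
                    state, dataset[s], task, cfg, U[t], epoch=ep, stimulus_index=int(s)
                )
                rs[t] = rec.r
                es[t] = rec.e
                if cfg.record_trials:
                    trials.append(rec)
            epoch_rewards[ep] = rs.mean()
            epoch_abs_e[ep] = np.abs(es).mean()
    else:
        raise ValueError(f"unknown engine {cfg.engine!r}")

    return RunLog(
        config=cfg,
        task=task,
        epoch_rewards=epoch_rewards,
        epoch_mean_abs_e=epoch_abs_e,
        final_performance=_final_performance(epoch_rewards, cfg),
        state=state,
        pretrain_trace=pre_trace,
        trials=trials,
    )


def sweep(
    configs: list[RunConfig],
    replicates: int = 1,
    seed_offsets: tuple[int, int] = (1000, 2000),
    dataset: list[Stimulus] | None = None,
    pretrain_cache: dict | None = None,
) -> tuple[list[RunLog], pd.DataFrame]:
    """Run a grid of configs with replicate seeds; return logs + summary.

    Replicate k of a config shifts its weight and trial seeds by
    k·offsets. Pretrained RBM-1 layers are cached by their defining
    parameters and shared across conditions.
    """
    if dataset is None:
        dataset = generate_dataset()
    retinas = dataset_retinas(dataset)
    cache = {} if pretrain_cache is None else pretrain_cache
    logs: list[RunLog] = []
    for base in configs:
        for k in range(replicates):
            cfg = RunConfig(**{**asdict(base)})
            cfg.weight_seed = base.weight_seed + k * seed_offsets[0]
            cfg.trial_seed = base.trial_seed + k * seed_offsets[1]
            key = (
                cfg.weight_seed, cfg.h1_size, cfg.pretrain_epochs,
                cfg.pretrain_eps, cfg.rbm1_bias, cfg.init_scale,
            )
            if key not in cache:
                cache[key] = pretrain_for_config(cfg, retinas)[0]
            logs.append(run_experiment(cfg, dataset, pretrained_rbm1=cache[key]))
    return logs, summarise(logs)


def summarise(logs: list[RunLog]) -> pd.DataFrame:
    """Mean ± SD of final performance per (h2_size, rule, λ level)."""
    rows = [
        {
            "h2_size": log.config.h2_size,
            "rule": log.config.rule,
            "lambda_level": log.config.lambda_level,
            "lambda": log.config.lam,
            "weight_seed": log.config.weight_seed,
            "trial_seed": log.config.trial_seed,
            "final_performance": log.final_performance,
        }
        for log in logs
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["h2_size", "rule", "lambda_level"], sort=False)["final_performance"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def save_checkpoint(log: RunLog, path: str | Path) -> None:
    """Serialise a run (weights, config, reward trace, task) to one NPZ."""
    state, cfg = log.state, log.config
    np.savez(
        Path(path),
        W1=state.dbn.rbm1.W, b1v=state.dbn.rbm1.b_vis, b1h=state.dbn.rbm1.b_hid,
        W2=state.dbn.rbm2.W, b2v=state.dbn.rbm2.b_vis, b2h=state.dbn.rbm2.b_hid,
        Wa=state.actor.W, ba=state.actor.b,
        Wc1=state.critic.W1, bc1=state.critic.b1,
        wc2=state.critic.w2, bc2=np.array([state.critic.b2]),
        epoch_rewards=log.epoch_rewards,
        epoch_mean_abs_e=log.epoch_mean_abs_e,
        ideal_actions=log.task.ideal_actions,
        config_json=np.frombuffer(json.dumps(asdict(cfg)).encode(), dtype=np.uint8),
    )


def load_checkpoint(path: str | Path) -> RunLog:
    """Load a checkpoint saved by :func:`save_checkpoint`."""
    with np.load(Path(path)) as z:
        cfg = RunConfig(**json.loads(bytes(z["config_json"]).decode()))
        rbm1 = RbmLayer(z["W1"].copy(), z["b1v"].copy(), z["b1h"].copy(), cfg.rbm1_bias)
        rbm2 = RbmLayer(z["W2"].copy(), z["b2v"].copy(), z["b2h"].copy(), cfg.rbm2_bias)
        actor = ActorState(z["Wa"].copy(), z["ba"].copy(), cfg.actor_bias)
        critic = CriticState(
            z["Wc1"].copy(), z["bc1"].copy(), z["wc2"].copy(), float(z["bc2"][0])
        )
        task = make_task(cfg.rule, cfg.action_len, cfg.task_seed)
        if not np.array_equal(task.ideal_actions, z["ideal_actions"]):
            raise ValueError("checkpoint task does not match its seed regeneration")
        epoch_rewards = z["epoch_rewards"].copy()
        epoch_abs_e = z["epoch_mean_abs_e"].copy()
    state = ModelState(Dbn(rbm1, rbm2, rbm1_pretrained=True), actor, critic)
    return RunLog(
        config=cfg,
        task=task,
        epoch_rewards=epoch_rewards,
        epoch_mean_abs_e=epoch_abs_e,
        final_performance=_final_performance(epoch_rewards, cfg),
        state=state,
    )
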
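# Methods

## Model

The agent is a system-level actor-critic whose perceptual front end is a
generative Deep Belief Network (DBN) of two Restricted Boltzmann
Machines (RBMs) with Bernoulli-logistic stochastic units: a unit with
activation potential p = Σᵢ w·vᵢ (plus bias where enabled) fires with
probability σ(p). Weights are bidirectional; the same matrix serves
recognition (up) and generation (down).

**RBM-1** (2,352-pixel retina → H1 = 200) is pretrained offline by
per-sample Contrastive Divergence (CD-1) over shuffled epochs of the
64-stimulus set, with sampled activations in both the data and model
phases and visible/hidden biases enabled (the black background makes
the inputs sparse; biases let the generative pass represent it without
dedicating weights). During the task RBM-1 is frozen.

**RBM-2** (H1 → H2 ∈ {10, 50}) learns online. Each trial's
action-selection pass samples h1 from the retina and h2 from h1; the
weight update is the convex mixture

Δw = λ·ε(⟨v h⟩_data − ⟨v h⟩_model) + (1−λ)·α₂·e·(y − σ(p))·x,

where the data-phase hidden activation of the CD term and the
eligibility y of the REINFORCE term are the *same* sampled h2 of the
behavioural episode, x = h1, and e is the critic's prediction error.
λ ∈ {1, 0.1, 0.01, 0.001, 0} defines conditions L0–L4.

**Actor**: a single-layer perceptron of Bernoulli-logistic units maps
h2 to a 10-bit action, trained by REINFORCE with the critic's
prediction as baseline. **Critic**: reward is the affine rescaling
r = 1 − d/10 of the L1 distance d between action and the ideal vector
of the stimulus's category; an MLP (H2 → 50 sigmoid → 1 linear)
predicts r̄ from h2 and is trained one LMS/backprop step per trial on
e = r − r̄.

**Environment**: a sorting rule (colour, shape or size) partitions the
64 stimuli into four categories of 16; each category owns a random
binary ideal vector (pairwise Hamming separation ≥ 2 enforced, so the
reward remains informative). Every epoch presents each stimulus once in
random order.

## Stimuli

64 images: 4 colours (pure saturated red, green, blue, yellow) × 4
shapes (square, circle, upward isosceles triangle, 3:1 bar) × 4 sizes
spanning ~25–85 % of the 28-px frame, hard-edged and centred on a black
background, so every retina entry is exactly 0 or 1. Within each shape
the four size levels give strictly decreasing pixel counts, and colour
dominates the pixel count overall — many pixels encode colour, few
differentiate equally-coloured shapes, which is what makes colour the
"easy" attribute for unsupervised learning. The renderer is a pure
function; the synthetic set has no jitter, occlusion, lighting or
pose variation, so conclusions about real-image robustness are outside
what the tests can show.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| ε | 0.02 | CD rate of the online mixed rule |
| α (actor) | 0.1 | REINFORCE rate of the motor layer |
| α₂ | 0.01 | REINFORCE rate inside the mixed rule |
| α_c | 3·10⁻⁴ | predictor (critic) learning rate |
| H1 / H2 | 200 / {10, 50} | hidden sizes |
| action length | 10 | bits per action vector |
| pretraining | 300 epochs, ε = 0.01 | offline CD-1 of RBM-1 |
| init | 𝒩(0, 0.01) | all weight matrices |
| epochs | 15,000 (full), 10,000 (acceptance), 1,000–10,000 (tests) | 64 trials each |

Final performance is the maximum over epochs of the 100-epoch moving
average of per-epoch mean reward (a final-window mean is available via
`perf_mode`).

The learning rates were fixed by a reduced random search over the
published conditions, mirroring how the original study selected its
configurations by a large random grid search. The decisive and least
obvious choice is the **slow critic**: because the predictor conditions
on the top hidden activation itself, it acts as an action-dependent
baseline for the representation's policy gradient — a fast predictor
asymptotically cancels exactly the reward covariance that the mixed
rule needs, and the RL pathway goes inert (we verified with an
oracle-representation control that the actor/critic loop itself is
sound). With α_c ≈ 3·10⁻⁴ the cancellation is slow enough for
reward to shape the representation. The actor's faster α makes the
pure-UL condition exploit its quickly-formed code early, reproducing
the published early-phase ordering of the learning curves.

Options retained from the investigation, all off by default:
`rl_factor="potential"` (the raw-potential eligibility variant of the
mixed rule — it self-limits potentials at the fixed point p = σ(p) and
learns poorly, but is kept for study), `h1_mode="meanfield"`,
`actor_decay`, `critic_init_r_bar` (optimistic start), RBM-2 biases.

## Analyses

Representations are the mean-field reconstructions of the 64 retinas
through the trained DBN (probabilities propagated up to h2 and back).
They are centred and projected onto the first two principal components
(sign-fixed so the largest-magnitude loading is positive), clustered by
K-means with K = 4 (k-means++, 10 restarts, fixed seed), and compared
with attribute partitions by Hungarian-matched accuracy (primary) and
adjusted Rand index. Information loss is the mean squared error between
retina and reconstruction; its relation to the RL contribution is the
Pearson correlation of level index (0–4) with error across a sweep.

## Numerical and design notes

- Bernoulli sampling uses the convention P(h = 1) = σ(p) (h = 1 iff
  u < σ(p)); sigmoids are computed in the numerically stable split
  form.
- Every sampler can consume a pre-drawn uniform vector with a fixed
  consumption order (h1 | h2 | action | CD reconstruction | CD model
  hidden per trial), so runs are bit-reproducible from (config, seeds)
  and the fast numba kernel is testable against the pure-numpy
  reference path on identical random streams.
- The CD and REINFORCE pieces of the mixed update are computed from the
  same pre-update weights and activations, so the convex-combination
  identity holds to machine precision for any λ.
- K-means on 64 identical points degenerates gracefully (empty
  clusters are reported, radius 0); PCA raises on zero-variance input.
- The ideal-vector draw retries up to 1,000 times to meet the Hamming
  separation and then fails with advice to enlarge the action length.

## Known limitations

- With λ = 0.01 and 50 top units under the colour rule, runs can
  converge to a deterministic sub-optimal attractor in which yellow —
  whose retina is the union of the red and green channels and whose
  first-layer code correlates ~0.5 with both — keeps a compromise
  action a few bits from its ideal vector. Saturated Bernoulli policy
  units have zero REINFORCE gradient, so nothing unfreezes the
  commitment once the critic has learned to expect it. This caps that
  condition near 0.92–0.95 rather than the published 0.98 and leaves
  the moderate mixture level tied with, rather than above, pure UL
  there; the corresponding acceptance check is asserted at the
  published band and currently fails.
- Scaled-down runs (10,000 epochs, 3 seeds) carry seed-to-seed spread
  of a few hundredths in final performance; bands in the tests are the
  published means ± 2 SD.
- The shape rule's early learning phase is dominated by the
  best-reply-to-colour ceiling, which depends on the drawn ideal
  vectors; early-phase comparisons are therefore made on the
  three-rule average, as in the published level-averaged curves.
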
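"""Inlined one-epoch training kernel (numba).

The trial loop is the hot path of a run: tens of thousands of epochs of
64 trials, each touching only small matrices. This kernel replays the
exact per-trial uniform-consumption layout of the reference functions in
``perceptual``/``actor``/``critic``:

    [0, H1)                     sample h1 from the cached RBM-1 probabilities
    [H1, H1+H2)                 sample the top activation h2
    [H1+H2, H1+H2+A)            sample the action bits y
    [H1+H2+A, 2H1+H2+A)         sample the CD reconstruction v'
    [2H1+H2+A, 2H1+2H2+A)       sample the CD model hidden h'

Uniform blocks are drawn outside the kernel from a numpy Generator, so a
run is bit-reproducible from its seeds and the kernel can be checked
against the pure-numpy ``run_trial`` path on identical random streams.
RBM-1 is frozen during the task, which is why its per-stimulus firing
probabilities can be cached.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["n_uniforms", "n_uniforms_cd", "epoch_kernel", "pretrain_epoch_kernel"]


def n_uniforms(h1_size: int, h2_size: int, action_len: int) -> int:
    """Uniform draws consumed per trial."""
    return 2 * h1_size + 2 * h2_size + action_len


def n_uniforms_cd(visible_size: int, hidden_size: int) -> int:
    """Uniform draws consumed per CD-1 sample (h_data, v_model, h_model)."""
    return 2 * hidden_size + visible_size


@njit(cache=False)
def _sigmoid(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    z = np.exp(x)
    return z / (1.0 + z)


@njit(cache=False)
def pretrain_epoch_kernel(
    W, bv, bh, use_bias,
    retinas,     # (n, V) binary data
    order,       # (n,) shuffled sample order
    U,           # (n, 2H+V) uniforms: h_data | v_model | h_model
    eps,
):
    """One epoch of per-sample CD-1 on an RBM, updating weights in place.

    Returns the epoch-mean squared error between each input and the
    mean-field reconstruction probability of its CD cycle.
    """
    H, V = W.shape
    n = order.shape[0]
    h = np.empty(H)
    hm = np.empty(H)
    vm = np.empty(V)
    vacc = np.empty(V)
    err = 0.0
    for t in range(n):
        s = order[t]
        u = U[t]
        v = retinas[s]
        # data pass (inputs are binary and sparse: skip zero pixels)
        for j in range(H):
            acc = bh[j] if use_bias else 0.0
            for i in range(V):
                if v[i] != 0.0:
                    acc += W[j, i] * v[i]
            h[j] = 1.0 if u[j] < _sigmoid(acc) else 0.0
        # reconstruction; accumulate row-wise so memory access stays contiguous
        for i in range(V):
            vacc[i] = bv[i] if use_bias else 0.0
        for j in range(H):
            if h[j] == 1.0:
                for i in range(V):
                    vacc[i] += W[j, i]
        serr = 0.0
        for i in range(V):
            pv = _sigmoid(vacc[i])
            serr += (v[i] - pv) ** 2
            vm[i] = 1.0 if u[H + i] < pv else 0.0
        err += serr / V
        # model pass
        for j in range(H):
            acc = bh[j] if use_bias else 0.0
            for i in range(V):
                acc += W[j, i] * vm[i]
            hm[j] = 1.0 if u[H + V + j] < _sigmoid(acc) else 0.0
        # CD update
        for j in range(H):
            for i in range(V):
                W[j, i] += eps * (h[j] * v[i] - hm[j] * vm[i])
        if use_bias:
            for i in range(V):
                bv[i] += eps * (v[i] - vm[i])
            for j in range(H):
                bh[j] += eps * (h[j] - hm[j])
    return err / n


@njit(cache=False)
def epoch_kernel(
    p1,          # (n_stim, H1) cached RBM-1 hidden firing probabilities
    schedule,    # (n_stim,) stimulus presentation order
    U,           # (n_stim, nU) uniforms
    W2, b2v, b2h, rbm2_bias,
    Wa, ba, actor_bias,
    Wc1, bc1, wc2, bc2,          # bc2: 1-element array
    cats,        # (n_stim,) category index per stimulus
    ystars,      # (4, A) ideal action vectors
    lam, eps, alpha, alpha_r2, alpha_c, actor_decay,
    rl_factor_potential, h1_meanfield,
    rewards_out, e_out,          # (n_stim,) per-trial reward and surprise
):
    """Run one epoch of trials, updating all weights in place.

    ``rl_factor_potential`` selects the RBM-2 REINFORCE eligibility
    factor: (y − potential) if true, (y − σ(potential)) otherwise.
    ``h1_meanfield`` propagates RBM-1 firing probabilities instead of
    sampling the first hidden layer.
    """
    H2, H1 = W2.shape
    A = Wa.shape[0]
    Hc = Wc1.shape[0]
    n = schedule.shape[0]

    h1 = np.empty(H1)
    h2 = np.empty(H2)
    p2 = np.empty(H2)
    pot2 = np.empty(H2)
    pa = np.empty(A)
    y = np.empty(A)
    hc = np.empty(Hc)
    vp = np.empty(H1)
    hp = np.empty(H2)

    for t in range(n):
        s = schedule[t]
        u = U[t]

        # phase 1: bottom-up encode (RBM-1 probabilities are cached)
        if h1_meanfield:
            for i in range(H1):
                h1[i] = p1[s, i]
        else:
            for i in range(H1):
                h1[i] = 1.0 if u[i] < p1[s, i] else 0.0
        off = H1
        for j in range(H2):
            acc = b2h[j] if rbm2_bias else 0.0
            for i in range(H1):
                acc += W2[j, i] * h1[i]
            pot2[j] = acc
            pj = _sigmoid(acc)
            p2[j] = pj
            h2[j] = 1.0 if u[off + j] < pj else 0.0
        off += H2

        # phase 2: action selection
        for j in range(A):
            acc = ba[j] if actor_bias else 0.0
            for i in range(H2):
                acc += Wa[j, i] * h2[i]
            pa[j] = _sigmoid(acc)
            y[j] = 1.0 if u[off + j] < pa[j] else 0.0
        off += A

        # phase 3: environment feedback and reward scaling
        c = cats[s]
        d = 0.0
        for j in range(A):
            d += abs(ystars[c, j] - y[j])
        r = 1.0 - d / A

        # critic forward pass and surprise
        for k in range(Hc):
            acc = bc1[k]
            for i in range(H2):
                acc += Wc1[k, i] * h2[i]
            hc[k] = _sigmoid(acc)
        rbar = bc2[0]
        for k in range(Hc):
            rbar += wc2[k] * hc[k]
        e = r - rbar

        # phase 4a: CD passes on pre-update weights (only needed if λ > 0)
        if lam > 0.0:
            for i in range(H1):
                acc = b2v[i] if rbm2_bias else 0.0
                for j in range(H2):
                    acc += W2[j, i] * h2[j]
                pv = _sigmoid(acc)
                vp[i] = 1.0 if u[off + i] < pv else 0.0
            for j in range(H2):
                acc = b2h[j] if rbm2_bias else 0.0
                for i in range(H1):
                    acc += W2[j, i] * vp[i]
                ph = _sigmoid(acc)
                hp[j] = 1.0 if u[off + H1 + j] < ph else 0.0

        # phase 4b: mixed CD/REINFORCE update of RBM-2
        ce = lam * eps
        ca = (1.0 - lam) * alpha_r2 * e
        for j in range(H2):
            factor = pot2[j] if rl_factor_potential else p2[j]
            rl_j = ca * (h2[j] - factor)
            for i in range(H1):
                dw = rl_j * h1[i]
                if lam > 0.0:
                    dw += ce * (h2[j] * h1[i] - hp[j] * vp[i])
                W2[j, i] += dw
        if rbm2_bias:
            if lam > 0.0:
                for i in range(H1):
                    b2v[i] += ce * (h1[i] - vp[i])
            for j in range(H2):
                factor = pot2[j] if rl_factor_potential else p2[j]
                db = ca * (h2[j] - factor)
                if lam > 0.0:
                    db += ce * (h2[j] - hp[j])
                b2h[j] += db

        # phase 4c: REINFORCE on the actor (with optional weight decay that
        # bounds the potentials and so keeps the policy softly stochastic)
        sa = alpha * e
        keep = 1.0 - actor_decay
        for j in range(A):
            diff = sa * (y[j] - pa[j])
            for i in range(H2):
                Wa[j, i] = keep * Wa[j, i] + diff * h2[i]
            if actor_bias:
                ba[j] = keep * ba[j] + diff

        # phase 4d: one LMS/backprop step on the predictor
        for k in range(Hc):
            dh = e * wc2[k] * hc[k] * (1.0 - hc[k])
            for i in range(H2):
                Wc1[k, i] += alpha_c * dh * h2[i]
            bc1[k] += alpha_c * dh
        for k in range(Hc):
            wc2[k] += alpha_c * e * hc[k]
        bc2[0] += alpha_c * e

        rewards_out[t] = r
        e_out[t] = e
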
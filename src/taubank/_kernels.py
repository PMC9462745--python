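"""Numba-compiled inner loops for episode simulation and training.

The public modules (:mod:`taubank.agent`, :mod:`taubank.learning`) carry
readable numpy reference implementations of the same arithmetic; these
kernels exist because training runs ~10^5 episodes of up to 200 steps each
and the metrics need millions of evaluated steps.  Tests assert that kernel
and reference implementations agree.

Conventions inside kernels: action rows 0=left, 1=wait, 2=right; emitted
action codes -1/0/+1 (timeout = 0 with steps == n_steps_max).  All
randomness comes from numba's per-thread numpy RNG, seeded explicitly at
kernel entry, so every kernel call is a pure function of its arguments.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "policy_terms",
    "train_episodes",
    "eval_episodes",
    "ou_threshold_curve",
    "ou_run",
    "ddm_first_passage",
]


@njit(cache=True)
def policy_terms(theta_s, theta_c, b, y_s, y_c):
    """Signal parts, clock parts (with bias) and softmax probabilities.

    Returns (sigma_s, sigma_c, p) each of shape (3,); row 1 (wait) uses
    |y_s| as its signal feature.
    """
    n = y_s.shape[0]
    sigma_s = np.zeros(3)
    sigma_c = np.zeros(3)
    for a in range(3):
        acc_s = 0.0
        acc_c = b[a]
        for i in range(n):
            ys = y_s[i]
            if a == 1:
                ys = abs(ys)
            acc_s += theta_s[a, i] * ys
            acc_c += theta_c[a, i] * y_c[i]
        sigma_s[a] = acc_s
        sigma_c[a] = acc_c
    m = sigma_s[0] + sigma_c[0]
    for a in range(1, 3):
        tot = sigma_s[a] + sigma_c[a]
        if tot > m:
            m = tot
    p = np.empty(3)
    z = 0.0
    for a in range(3):
        p[a] = np.exp(sigma_s[a] + sigma_c[a] - m)
        z += p[a]
    for a in range(3):
        p[a] /= z
    return sigma_s, sigma_c, p


@njit(cache=True)
def _sample_action(p):
    u = np.random.random()
    if u < p[0]:
        return 0
    if u < p[0] + p[1]:
        return 1
    return 2


@njit(cache=True)
def train_episodes(
    theta_s,
    theta_c,
    b,
    w_s,
    w_c,
    b_v,
    decay,
    gain,
    mus,
    s_std,
    sigma_I,
    n_steps_max,
    lr_a,
    lr_c,
    lam_a,
    lam_c,
    gamma,
    clock_trainable,
    critic_abs,
    seed,
):
    """Actor-critic TD(lambda) over a block of episodes.

    Within an episode the parameters are held fixed; per-step TD errors
    multiply the eligibility traces into update accumulators that are
    applied at episode end.  (With lambda_actor = 1 this makes the actor
    update an exact REINFORCE estimate with the critic as baseline.)
    Parameters are updated in place; ``b_v`` is a length-1 array (critic
    bias).  Returns per-episode (rewards, steps, actions) with actions in
    {-1, 0, +1}.
    """
    np.random.seed(seed)
    n = decay.shape[0]
    n_ep = mus.shape[0]
    rewards = np.zeros(n_ep)
    steps = np.zeros(n_ep, dtype=np.int64)
    actions = np.zeros(n_ep, dtype=np.int64)

    e_ts = np.zeros((3, n))
    e_tc = np.zeros((3, n))
    e_b = np.zeros(3)
    e_ws = np.zeros(n)
    e_wc = np.zeros(n)
    d_ts = np.zeros((3, n))
    d_tc = np.zeros((3, n))
    d_b = np.zeros(3)
    d_ws = np.zeros(n)
    d_wc = np.zeros(n)

    xs = np.zeros(n)
    xc = np.zeros(n)
    y_s = np.zeros(n)
    y_c = np.zeros(n)
    g = np.zeros(3)

    for ep in range(n_ep):
        mu = mus[ep]
        for i in range(n):
            xs[i] = 0.0
            xc[i] = 0.0
        for a in range(3):
            e_b[a] = 0.0
            d_b[a] = 0.0
            for i in range(n):
                e_ts[a, i] = 0.0
                e_tc[a, i] = 0.0
                d_ts[a, i] = 0.0
                d_tc[a, i] = 0.0
        for i in range(n):
            e_ws[i] = 0.0
            e_wc[i] = 0.0
            d_ws[i] = 0.0
            d_wc[i] = 0.0
        e_bv = 0.0
        d_bv = 0.0
        prev_V = 0.0
        has_prev = False

        for k in range(1, n_steps_max + 1):
            s = mu + s_std * np.random.normal()
            for i in range(n):
                xs[i] = xs[i] * decay[i] + gain[i] * s
                xc[i] = xc[i] * decay[i] + gain[i]
                y_s[i] = xs[i] + sigma_I * np.random.normal()
                y_c[i] = xc[i] + sigma_I * np.random.normal()

            sigma_s, sigma_c, p = policy_terms(theta_s, theta_c, b, y_s, y_c)
            V = b_v[0]
            for i in range(n):
                fs = abs(y_s[i]) if critic_abs else y_s[i]
                V += w_s[i] * fs + w_c[i] * y_c[i]

            if has_prev:
                # TD error for the previous (non-terminal, zero-reward) step
                delta = gamma * V - prev_V
                da = lr_a * delta
                dc = lr_c * delta
                for a in range(3):
                    d_b[a] += da * e_b[a]
                    for i in range(n):
                        d_ts[a, i] += da * e_ts[a, i]
                        d_tc[a, i] += da * e_tc[a, i]
                d_bv += dc * e_bv
                for i in range(n):
                    d_ws[i] += dc * e_ws[i]
                    d_wc[i] += dc * e_wc[i]

            act = _sample_action(p)
            terminal = (act != 1) or (k == n_steps_max)

            # accumulate eligibility traces with this step's gradients
            gl_a = gamma * lam_a
            gl_c = gamma * lam_c
            for a in range(3):
                g[a] = -p[a]
            g[act] += 1.0
            for a in range(3):
                e_b[a] = gl_a * e_b[a] + g[a]
                for i in range(n):
                    ys = y_s[i]
                    if a == 1:
                        ys = abs(ys)
                    e_ts[a, i] = gl_a * e_ts[a, i] + g[a] * ys
                    if clock_trainable:
                        e_tc[a, i] = gl_a * e_tc[a, i] + g[a] * y_c[i]
            e_bv = gl_c * e_bv + 1.0
            for i in range(n):
                fs = abs(y_s[i]) if critic_abs else y_s[i]
                e_ws[i] = gl_c * e_ws[i] + fs
                e_wc[i] = gl_c * e_wc[i] + y_c[i]

            if terminal:
                r = 0.0
                if act == 0 and mu < 0.0:
                    r = 1.0
                elif act == 2 and mu > 0.0:
                    r = 1.0
                delta = r - V
                da = lr_a * delta
                dc = lr_c * delta
                for a in range(3):
                    d_b[a] += da * e_b[a]
                    for i in range(n):
                        d_ts[a, i] += da * e_ts[a, i]
                        d_tc[a, i] += da * e_tc[a, i]
                d_bv += dc * e_bv
                for i in range(n):
                    d_ws[i] += dc * e_ws[i]
                    d_wc[i] += dc * e_wc[i]
                # apply the episode's accumulated updates
                for a in range(3):
                    b[a] += d_b[a]
                    for i in range(n):
                        theta_s[a, i] += d_ts[a, i]
                        theta_c[a, i] += d_tc[a, i]
                b_v[0] += d_bv
                for i in range(n):
                    w_s[i] += d_ws[i]
                    w_c[i] += d_wc[i]
                rewards[ep] = r
                steps[ep] = k
                actions[ep] = act - 1
                break
            prev_V = V
    return rewards, steps, actions


@njit(cache=True)
def eval_episodes(
    theta_s,
    theta_c,
    b,
    decay,
    gain,
    mus,
    s_std,
    sigma_I,
    n_steps_max,
    seed,
    record,
    dsr_out,
    dss_out,
):
    """Run frozen-policy episodes; optionally record per-step propensities.

    When ``record`` is true, ``dsr_out``/``dss_out`` must be (n_ep,
    n_steps_max) float32 arrays; entries beyond the decision step are left
    untouched (caller pre-fills with NaN).  Returns (rewards, steps,
    actions).
    """
    np.random.seed(seed)
    n = decay.shape[0]
    n_ep = mus.shape[0]
    rewards = np.zeros(n_ep)
    steps = np.zeros(n_ep, dtype=np.int64)
    actions = np.zeros(n_ep, dtype=np.int64)
    xs = np.zeros(n)
    xc = np.zeros(n)
    y_s = np.zeros(n)
    y_c = np.zeros(n)

    for ep in range(n_ep):
        mu = mus[ep]
        for i in range(n):
            xs[i] = 0.0
            xc[i] = 0.0
        for k in range(1, n_steps_max + 1):
            s = mu + s_std * np.random.normal()
            for i in range(n):
                xs[i] = xs[i] * decay[i] + gain[i] * s
                xc[i] = xc[i] * decay[i] + gain[i]
                y_s[i] = xs[i] + sigma_I * np.random.normal()
                y_c[i] = xc[i] + sigma_I * np.random.normal()
            sigma_s, sigma_c, p = policy_terms(theta_s, theta_c, b, y_s, y_c)
            if record:
                dsr_out[ep, k - 1] = np.float32(
                    (sigma_s[2] + sigma_c[2]) - (sigma_s[1] + sigma_c[1])
                )
                dss_out[ep, k - 1] = np.float32(sigma_s[2] - sigma_s[1])
            act = _sample_action(p)
            if act != 1 or k == n_steps_max:
                r = 0.0
                if act == 0 and mu < 0.0:
                    r = 1.0
                elif act == 2 and mu > 0.0:
                    r = 1.0
                rewards[ep] = r
                steps[ep] = k
                actions[ep] = act - 1
                break
    return rewards, steps, actions


@njit(cache=True)
def ou_threshold_curve(
    mus, decay, gain, s_std, sigma_eff, n_steps_max, thetas, seed
):
    """Accuracy of the thresholded single integrator per candidate threshold.

    Common random numbers: each episode's noisy integrator trajectory is
    simulated once and scanned for the first crossing of every candidate
    +-theta.  Returns the fraction of correct decisions per candidate
    (timeouts count as incorrect).
    """
    np.random.seed(seed)
    n_ep = mus.shape[0]
    n_cand = thetas.shape[0]
    correct = np.zeros(n_cand)
    y = np.zeros(n_steps_max)
    d = decay[0]
    gn = gain[0]
    for ep in range(n_ep):
        mu = mus[ep]
        x = 0.0
        for k in range(n_steps_max):
            s = mu + s_std * np.random.normal()
            x = x * d + gn * s
            y[k] = x + sigma_eff * np.random.normal()
        for c in range(n_cand):
            th = thetas[c]
            for k in range(n_steps_max):
                if y[k] >= th:
                    if mu > 0.0:
                        correct[c] += 1.0
                    break
                elif y[k] <= -th:
                    if mu < 0.0:
                        correct[c] += 1.0
                    break
    return correct / n_ep


@njit(cache=True)
def ou_run(
    mus, decay, gain, s_std, sigma_eff, n_steps_max, theta, seed, record, y_out
):
    """Batch run of the thresholded integrator at one threshold.

    With ``record`` true the noisy integrator value (the model's decision
    variable, the analogue of dSigma_right) is written per step into
    ``y_out`` (n_ep, n_steps_max; caller pre-fills with NaN).  Returns
    (rewards, steps, actions) in the same format as :func:`eval_episodes`.
    """
    np.random.seed(seed)
    n_ep = mus.shape[0]
    rewards = np.zeros(n_ep)
    steps = np.zeros(n_ep, dtype=np.int64)
    actions = np.zeros(n_ep, dtype=np.int64)
    d = decay[0]
    gn = gain[0]
    for ep in range(n_ep):
        mu = mus[ep]
        x = 0.0
        act = 0
        k_end = n_steps_max
        for k in range(1, n_steps_max + 1):
            s = mu + s_std * np.random.normal()
            x = x * d + gn * s
            y = x + sigma_eff * np.random.normal()
            if record:
                y_out[ep, k - 1] = np.float32(y)
            if y >= theta:
                act = 1
                k_end = k
                break
            elif y <= -theta:
                act = -1
                k_end = k
                break
        steps[ep] = k_end
        actions[ep] = act
        if act == 1 and mu > 0.0:
            rewards[ep] = 1.0
        elif act == -1 and mu < 0.0:
            rewards[ep] = 1.0
    return rewards, steps, actions


@njit(cache=True)
def ddm_first_passage(n, mu, sigma, theta, dt, max_steps, seed):
    """First-passage times of pure drift-diffusion between +-theta.

    ``dX = mu dt + sigma dW``; Euler steps of size ``dt``.  Returns (times,
    signs); sign 0 marks paths that never crossed within ``max_steps``.
    """
    np.random.seed(seed)
    times = np.zeros(n)
    signs = np.zeros(n, dtype=np.int64)
    sq = sigma * np.sqrt(dt)
    for ep in range(n):
        x = 0.0
        for k in range(1, max_steps + 1):
            x += mu * dt + sq * np.random.normal()
            if x >= theta:
                times[ep] = k * dt
                signs[ep] = 1
                break
            elif x <= -theta:
                times[ep] = k * dt
                signs[ep] = -1
                break
    return times, signs
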
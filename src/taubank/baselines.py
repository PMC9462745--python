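"""Comparative decision models and closed-form references.

* Thresholded single leaky integrator (Ornstein-Uhlenbeck decision process):
  one signal integrator of time constant tau decides when its noisy value
  first crosses +-Theta; Theta is optimised by grid search with common
  random numbers.
* Intrinsic-noise rescaling: a single integrator compared against the
  multi-integrator agent receives read-out noise reduced by
  ``alpha_I = max|theta*| / sqrt(sum theta*^2)`` so that its effective noise
  matches what the agent achieves by averaging many noisy integrators.
* Fixed-t observer: the ideal decider forced to answer at time t with the
  sign of the summed signal; its accuracy has the closed form
  ``1/2 + arctan(sigma_mu sqrt(t) / sigma) / pi`` under mu ~ N(0, sigma_mu^2).
* Experimental psychometric reference, a fit to monkey random-dot data:
  ``1 - 0.5 exp[-(c / 7.97)^1.62]``.
* Drift-diffusion CV law: for the pure (no-leak) drift-diffusion model the
  response-time coefficient of variation varies with coherence as
  ``((100 - c) / c^2)^(1/4)`` — the analytic foil to the scalar property.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .integrators import IntegratorBank, make_grid
from .task import COHERENCE_SCALE, LEFT, RIGHT, WAIT, Episode, Outcome, TaskParams

__all__ = [
    "ThresholdModel",
    "ou_decide",
    "ou_run_batch",
    "optimize_threshold",
    "alpha_rescale",
    "fixed_t_accuracy",
    "psychometric_reference",
    "ddm_cv",
    "ddm_reference_threshold",
    "ddm_first_passage",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class ThresholdModel:
    """Single leaky integrator with symmetric decision thresholds."""

    tau: float
    theta: float
    sigma_I_eff: float = 0.02

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


def ou_decide(
    model: ThresholdModel,
    episode: Episode,
    params: TaskParams,
    rng: np.random.Generator,
) -> Outcome:
    """Run the thresholded integrator on one episode's sample path.

    'right' at the first step where the noisy integrator value reaches
    ``+theta``, 'left' at ``-theta``; timeout if neither within t_max.
    """
    bank = IntegratorBank(make_grid(1, model.tau, model.tau), params.dt)
    for k, s in enumerate(episode.samples, start=1):
        bank.step(float(s))
        y = bank.observe(model.sigma_I_eff, rng).y_signal[0]
        if y >= model.theta:
            return Outcome(
                action=RIGHT,
                decision_time=k * params.dt,
                reward=1.0 if episode.mu > 0 else 0.0,
                correct=episode.mu > 0 if episode.mu != 0 else None,
                mu=episode.mu,
            )
        if y <= -model.theta:
            return Outcome(
                action=LEFT,
                decision_time=k * params.dt,
                reward=1.0 if episode.mu < 0 else 0.0,
                correct=episode.mu < 0 if episode.mu != 0 else None,
                mu=episode.mu,
            )
    return Outcome(
        action=WAIT,
        decision_time=params.t_max,
        reward=0.0,
        correct=None,
        mu=episode.mu,
    )


def ou_run_batch(
    model: ThresholdModel,
    task: TaskParams,
    mus: np.ndarray,
    seed: int,
    record_traces: bool = False,
    coherence: Optional[float] = None,
):
    """Batch simulation of the thresholded integrator.

    Returns an :class:`~taubank.simulate.EvalBatch`; with
    ``record_traces=True`` the per-step noisy integrator value (the model's
    decision variable, playing the role dSigma_right has in the agent) is
    stored in both trace slots so the decision-aligned analyses apply
    unchanged.
    """
    from .simulate import EvalBatch

    mus = np.ascontiguousarray(mus, dtype=float)
    decay = np.exp(-task.dt / np.array([model.tau]))
    gain = 1.0 - decay
    if record_traces:
        y_out = np.full((mus.size, task.n_steps), np.nan, dtype=np.float32)
    else:
        y_out = np.zeros((1, 1), dtype=np.float32)
    rewards, steps, actions = _kernels.ou_run(
        mus,
        decay,
        gain,
        task.sample_std,
        model.sigma_I_eff,
        task.n_steps,
        model.theta,
        int(seed) % _SEED_MOD,
        record_traces,
        y_out,
    )
    return EvalBatch(
        mus=mus,
        actions=actions,
        steps=steps,
        rewards=rewards,
        dt=task.dt,
        n_steps_max=task.n_steps,
        coherence=coherence,
        dsr=y_out if record_traces else None,
        dss=y_out if record_traces else None,
    )


def ou_evaluate_coherences(
    model: ThresholdModel,
    task: TaskParams,
    coherences,
    n_per: int,
    seed: int,
    record_traces: bool = True,
):
    """Fixed-coherence evaluation of the thresholded integrator (random
    direction per episode), mirroring
    :func:`taubank.simulate.evaluate_coherences`."""
    from .simulate import _child_seeds
    from .task import coherence_to_mu

    seeds = _child_seeds(seed, 2 * len(coherences))
    out = {}
    for j, c in enumerate(coherences):
        rng = np.random.default_rng(seeds[2 * j])
        signs = rng.choice([-1.0, 1.0], size=n_per)
        mus = signs * coherence_to_mu(c)
        out[float(c)] = ou_run_batch(
            model, task, mus, seeds[2 * j + 1], record_traces, coherence=float(c)
        )
    return out


def optimize_threshold(
    tau: float,
    task: TaskParams,
    thresholds: Optional[np.ndarray] = None,
    n_episodes: int = 20_000,
    seed: int = 0,
    sigma_I_eff: Optional[float] = None,
) -> Tuple[ThresholdModel, pd.DataFrame]:
    """Grid-search the decision threshold maximising accuracy.

    Common random numbers: every candidate threshold is scored on the same
    episodes and the same integrator noise, so the accuracy-vs-Theta curve
    is smooth up to shared Monte-Carlo noise.  Ties break toward the
    smallest Theta.  Returns the optimised model and the full curve.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 51)
    thresholds = np.ascontiguousarray(thresholds, dtype=float)
    if thresholds.size < 2:
        raise ValueError("need a grid of candidate thresholds")
    sig = task.sigma_I if sigma_I_eff is None else float(sigma_I_eff)
    ss = np.random.SeedSequence(seed)
    mu_rng = np.random.default_rng(ss.spawn(1)[0])
    mus = mu_rng.normal(0.0, task.sigma_mu, size=n_episodes)
    kern_seed = int(ss.generate_state(1, dtype=np.uint64)[0]) % _SEED_MOD
    decay = np.exp(-task.dt / np.array([float(tau)]))
    gain = 1.0 - decay
    acc = _kernels.ou_threshold_curve(
        mus, decay, gain, task.sample_std, sig, task.n_steps, thresholds, kern_seed
    )
    best = int(np.argmax(acc))  # first max == smallest Theta among ties
    curve = pd.DataFrame({"theta": thresholds, "accuracy": acc})
    return ThresholdModel(tau=float(tau), theta=float(thresholds[best]), sigma_I_eff=sig), curve


def alpha_rescale(theta_star: np.ndarray) -> float:
    """Noise rescaling factor for single-integrator comparisons.

    ``alpha_I = max_tau |theta*| / sqrt(sum_tau theta*^2)``, computed from
    the trained 'right' signal weights.  Equals 1 when a single weight is
    nonzero and reaches its floor ``1/sqrt(n_tau)`` for equal weights — the
    read-out noise of an equally weighted average of n_tau independently
    noisy integrators.
    """
    w = np.asarray(theta_star, dtype=float)
    norm = float(np.sqrt(np.sum(w * w)))
    if norm == 0.0:
        raise ValueError("alpha rescaling undefined for all-zero weights")
    return float(np.max(np.abs(w)) / norm)


def fixed_t_accuracy(t, sigma_mu: float = 0.25, sigma: float = 0.18):
    """Accuracy of the ideal observer forced to decide at time ``t``.

    The sign of the summed signal at time t is correct with probability
    ``Phi(|mu| sqrt(t) / sigma)``; averaging over mu ~ N(0, sigma_mu^2)
    gives ``1/2 + arctan(sigma_mu sqrt(t) / sigma) / pi`` (exact identity
    E[Phi(a|Z|)] = 1/2 + arctan(a)/pi).  Monotone in t, 1/2 at t = 0, -> 1
    as t -> infinity.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = 0.5 + np.arctan(sigma_mu * np.sqrt(t) / sigma) / np.pi
    return float(out) if out.ndim == 0 else out


def psychometric_reference(coherence):
    """Psychometric curve fitted to experimental random-dot data.

    ``1 - 0.5 exp[-(c / 7.97)^1.62]`` with c the coherence percentage.
    """
    c = np.asarray(coherence, dtype=float)
    if np.any(c < 0):
        raise ValueError("coherence must be non-negative")
    out = 1.0 - 0.5 * np.exp(-((c / 7.97) ** 1.62))
    return float(out) if out.ndim == 0 else out


def ddm_cv(coherence):
    """Response-time CV of the pure drift-diffusion model vs coherence.

    ``CV(c) = ((100 - c) / c^2)^(1/4)``: strictly decreasing, 0 at c = 100
    and diverging at c -> 0 — the DDM violates the scalar property.  The
    absolute normalisation corresponds to the decision threshold
    ``ddm_reference_threshold``; the coherence dependence is general.
    """
    c = np.asarray(coherence, dtype=float)
    if np.any(c <= 0) or np.any(c > 100):
        raise ValueError("coherence must lie in (0, 100] percent")
    out = ((100.0 - c) / (c * c)) ** 0.25
    return float(out) if out.ndim == 0 else out


def ddm_reference_threshold(sigma: float = 0.18) -> float:
    """Threshold at which the CV law holds with unit prefactor.

    For drift ``mu = k c / sqrt(100 - c)`` (k = 0.216) and diffusion sigma,
    the (single-boundary) first-passage CV is ``sigma / sqrt(Theta mu)``;
    it equals ``((100 - c)/c^2)^(1/4)`` exactly when ``Theta = sigma^2/k``.
    """
    return sigma * sigma / COHERENCE_SCALE


def ddm_first_passage(
    mu: float,
    theta: float,
    n: int,
    seed: int,
    sigma: float = 0.18,
    dt: float = 1e-4,
    t_cap: float = 200.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate pure drift-diffusion first passages between ``+-theta``.

    The no-leak limit of the integrator models; fine default dt keeps the
    boundary-crossing discretisation bias well below Monte-Carlo error.
    Returns (times, signs); sign 0 marks paths that never crossed within
    ``t_cap`` seconds.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    return _kernels.ddm_first_passage(
        int(n),
        float(mu),
        float(sigma),
        float(theta),
        float(dt),
        int(round(t_cap / dt)),
        int(seed) % _SEED_MOD,
    )
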
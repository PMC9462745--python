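"""Frozen-policy episode simulation and batch containers.

Everything downstream of training (metrics, figures, acceptance checks)
consumes :class:`EvalBatch` objects produced here: per-episode outcomes plus,
optionally, the per-step decision propensities ``dSigma_right`` and
``dSigma^s`` needed for decision-aligned averaging and boundary read-outs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .agent import AgentParams
from .task import RIGHT, TaskParams, coherence_to_mu

__all__ = ["EvalBatch", "run_batch", "evaluate_random", "evaluate_coherences"]

_SEED_MOD = 2**31 - 1


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit kernel seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % _SEED_MOD for s in ss.generate_state(n, dtype=np.uint64)]


@dataclass
class EvalBatch:
    """Outcomes (and optional per-step traces) of a batch of episodes."""

    mus: np.ndarray  # (n_ep,) true signal means
    actions: np.ndarray  # (n_ep,) in {-1, 0, +1}; 0 == timeout
    steps: np.ndarray  # (n_ep,) decision step (1-based); n_steps for timeouts
    rewards: np.ndarray  # (n_ep,) 0/1
    dt: float
    n_steps_max: int
    coherence: Optional[float] = None  # set when generated at fixed coherence
    dsr: Optional[np.ndarray] = None  # (n_ep, n_steps_max) float32, NaN-padded
    dss: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return int(self.mus.size)

    @property
    def decided(self) -> np.ndarray:
        return self.actions != 0

    @property
    def decision_times(self) -> np.ndarray:
        """Seconds from onset; equals t_max for timeouts."""
        return self.steps * self.dt

    @property
    def correct(self) -> np.ndarray:
        """Correct mask over decided episodes with mu != 0 (others False)."""
        return (self.rewards == 1.0) & self.decided

    @property
    def timeout_fraction(self) -> float:
        return float(np.mean(~self.decided))

    def accuracy(self, decided_only: bool = True) -> float:
        """Fraction of correct choices.

        The headline performance measure: among episodes that ended in an
        actual left/right choice and have a defined correct side (mu != 0).
        Late responses are not choices; they are tracked separately as
        ``timeout_fraction``.  With ``decided_only=False`` timeouts count
        as errors and the value equals the mean reward (the quantity the
        agent maximises).
        """
        defined = self.mus != 0.0
        if decided_only:
            defined &= self.decided
        if not defined.any():
            raise ValueError("accuracy undefined: no qualifying episodes")
        return float(self.rewards[defined].mean())

    def mean_rt(self, decided_only: bool = True) -> float:
        t = self.decision_times
        if decided_only:
            t = t[self.decided]
        return float(t.mean())

    def outcomes_frame(self) -> pd.DataFrame:
        """Outcome log with the columns of the on-disk CSV format."""
        return pd.DataFrame(
            {
                "mu": self.mus,
                "coherence": np.full(self.n, np.nan)
                if self.coherence is None
                else np.full(self.n, self.coherence),
                "action": self.actions,
                "decision_time": self.decision_times,
                "reward": self.rewards,
            }
        ).rename_axis("episode_id")


def run_batch(
    params: AgentParams,
    task: TaskParams,
    mus: np.ndarray,
    seed: int,
    record_traces: bool = False,
    sigma_I: Optional[float] = None,
    coherence: Optional[float] = None,
) -> EvalBatch:
    """Simulate one batch of episodes under a frozen policy."""
    mus = np.ascontiguousarray(mus, dtype=float)
    decay = np.exp(-task.dt / params.taus)
    gain = 1.0 - decay
    n_steps = task.n_steps
    if record_traces:
        dsr = np.full((mus.size, n_steps), np.nan, dtype=np.float32)
        dss = np.full((mus.size, n_steps), np.nan, dtype=np.float32)
    else:
        dsr = np.zeros((1, 1), dtype=np.float32)
        dss = np.zeros((1, 1), dtype=np.float32)
    rewards, steps, actions = _kernels.eval_episodes(
        params.theta_s,
        params.theta_c,
        params.b,
        decay,
        gain,
        mus,
        task.sample_std,
        task.sigma_I if sigma_I is None else float(sigma_I),
        n_steps,
        int(seed) % _SEED_MOD,
        record_traces,
        dsr,
        dss,
    )
    return EvalBatch(
        mus=mus,
        actions=actions,
        steps=steps,
        rewards=rewards,
        dt=task.dt,
        n_steps_max=n_steps,
        coherence=coherence,
        dsr=dsr if record_traces else None,
        dss=dss if record_traces else None,
    )


def evaluate_random(
    params: AgentParams,
    task: TaskParams,
    n: int,
    seed: int,
    record_traces: bool = False,
    sigma_I: Optional[float] = None,
) -> EvalBatch:
    """Evaluate on fresh episodes drawn from the training distribution
    ``mu ~ N(0, sigma_mu^2)``."""
    mu_seed, kern_seed = _child_seeds(seed, 2)
    rng = np.random.default_rng(mu_seed)
    mus = rng.normal(0.0, task.sigma_mu, size=n)
    return run_batch(params, task, mus, kern_seed, record_traces, sigma_I)


def evaluate_coherences(
    params: AgentParams,
    task: TaskParams,
    coherences: Sequence[float],
    n_per: int,
    seed: int,
    record_traces: bool = True,
    sigma_I: Optional[float] = None,
) -> Dict[float, EvalBatch]:
    """Evaluate at fixed coherences with random left/right direction.

    Each batch uses ``|mu| = coherence_to_mu(c)`` with the sign drawn
    uniformly, mirroring the experimental protocol of interleaved motion
    directions.  At 0% coherence mu is exactly 0.
    """
    seeds = _child_seeds(seed, 2 * len(coherences))
    out: Dict[float, EvalBatch] = {}
    for j, c in enumerate(coherences):
        rng = np.random.default_rng(seeds[2 * j])
        signs = rng.choice([-1.0, 1.0], size=n_per)
        mus = signs * coherence_to_mu(c)
        out[float(c)] = run_batch(
            params, task, mus, seeds[2 * j + 1], record_traces, sigma_I,
            coherence=float(c),
        )
    return out


def right_aligned_mask(batch: EvalBatch) -> np.ndarray:
    """Episodes entering decision-aligned 'right' averages.

    Correct 'right' decisions; at exactly zero coherence there is no correct
    side, so episodes whose *choice* was 'right' stand in (the standard
    choice-conditioned convention at 0%).
    """
    chose_right = (batch.actions == RIGHT) & batch.decided
    if batch.coherence == 0.0 or np.all(batch.mus == 0.0):
        return chose_right
    return chose_right & (batch.rewards == 1.0)
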
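"""Actor-critic training with eligibility traces.

The actor (softmax over the six weighted sums) and a linear critic are
trained by TD(lambda) with eligibility traces.  The critic reads the same
noisy read-out the actor sees::

    V = sum_tau w_s[tau] f(y^s_tau) + sum_tau w_c[tau] y^c_tau + b_v

where the signal feature ``f`` is the signed value by default (the critic
then converges to an almost time-only baseline, since the expected reward
is symmetric in the signal's sign); ``critic_abs_signal=True`` selects
``f = |.|`` instead, making V track momentary evidence strength.

Per step, the TD error ``delta = r + gamma V(t+1) - V(t)`` (with V(t+1) = 0
at episode end) multiplies eligibility traces ``e <- gamma lambda e + grad``
of the actor's ``grad log p(action)`` and the critic's ``grad V``.  Within
an episode the parameters are frozen and the per-step updates accumulate;
they are applied at episode end, and traces reset at episode start.  With
``lambda_actor = 1`` the actor update is then an exact REINFORCE estimate
with the critic as a baseline; the default ``lambda = 0.6`` trades a little
bootstrap bias for much lower variance.

Training checkpoints every ``checkpoint_every`` episodes: held-out accuracy
(frozen seed, comparable across checkpoints), signal neutrality and the
scalar property over the six standard coherences, plus behavioural
statistics of the preceding training window.  Training stops at
``n_episodes_max``; the returned parameters are the checkpoint snapshot
where signal neutrality peaked among checkpoints at or above the accuracy
floor — the halting rule under which the signatures are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels, metrics
from .agent import AgentParams
from .integrators import NoisyReadout, TimescaleGrid, make_grid
from .simulate import evaluate_coherences, evaluate_random
from .task import TaskParams

__all__ = [
    "CriticParams",
    "TrainingConfig",
    "TrainingResult",
    "critic_value",
    "critic_grad",
    "td_step",
    "trace_update",
    "train",
]

_SEED_MOD = 2**31 - 1


@dataclass
class CriticParams:
    """Linear value-function weights (signal magnitudes, clock, bias)."""

    w_s: np.ndarray
    w_c: np.ndarray
    b_v: float = 0.0

    @classmethod
    def zeros(cls, n_tau: int) -> "CriticParams":
        return cls(w_s=np.zeros(n_tau), w_c=np.zeros(n_tau), b_v=0.0)

    def copy(self) -> "CriticParams":
        return CriticParams(self.w_s.copy(), self.w_c.copy(), float(self.b_v))

    def to_dict(self) -> dict:
        return {"w_s": self.w_s.tolist(), "w_c": self.w_c.tolist(), "b_v": self.b_v}

    @classmethod
    def from_dict(cls, d: dict) -> "CriticParams":
        return cls(
            w_s=np.asarray(d["w_s"], dtype=float),
            w_c=np.asarray(d["w_c"], dtype=float),
            b_v=float(d["b_v"]),
        )


def critic_value(
    readout: NoisyReadout, critic: CriticParams, abs_signal: bool = False
) -> float:
    """Value estimate ``V`` for one read-out (reference implementation)."""
    f = np.abs(readout.y_signal) if abs_signal else readout.y_signal
    return float(critic.w_s @ f + critic.w_c @ readout.y_clock + critic.b_v)


def critic_grad(
    readout: NoisyReadout, abs_signal: bool = False
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Gradient of ``V`` w.r.t. (w_s, w_c, b_v) — it is linear, so the
    gradient is just the feature vector."""
    f = np.abs(readout.y_signal) if abs_signal else readout.y_signal.copy()
    return f, readout.y_clock.copy(), 1.0


def td_step(
    prev_V: float,
    next_V: float,
    reward: float,
    terminal: bool,
    gamma: float,
) -> float:
    """TD error ``delta = r + gamma * next_V * (1 - terminal) - prev_V``."""
    return reward + gamma * next_V * (0.0 if terminal else 1.0) - prev_V


def trace_update(trace: np.ndarray, grad: np.ndarray, gamma: float, lam: float):
    """Eligibility-trace accumulation ``e <- gamma * lambda * e + grad``.

    With lambda = 0 this reduces to the instantaneous gradient (one-step
    actor-critic).
    """
    return gamma * lam * np.asarray(trace) + np.asarray(grad)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the training run.

    Learning rates and trace constants are package defaults chosen so that
    the default task is learned to the accuracy floor within ~1e5 episodes;
    gamma = 1 because episodes are short and reward is terminal-only.
    ``b_wait_init`` sets the initial waiting propensity: with the default
    8.0 the untrained agent waits long (many early episodes end in late
    responses), so the slow integrators are exercised from the start —
    initialisations that act early steer learning into an impatient local
    optimum of short, fluctuation-driven decisions.
    """

    lr_actor: float = 8e-3
    lr_critic: float = 2e-3
    lambda_actor: float = 0.6
    lambda_critic: float = 0.6
    gamma: float = 1.0
    b_wait_init: float = 8.0
    n_episodes_max: int = 150_000
    checkpoint_every: int = 2_000
    eval_episodes: int = 2_000
    coherence_episodes: int = 2_000
    coherences: Sequence[float] = metrics.STANDARD_COHERENCES
    accuracy_floor: float = 0.81
    theta_bound: float = 50.0
    critic_abs_signal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr_actor, self.lr_critic) <= 0:
            raise ValueError("learning rates must be positive")
        for lam in (self.lambda_actor, self.lambda_critic):
            if not 0.0 <= lam <= 1.0:
                raise ValueError("lambda must lie in [0, 1]")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")


@dataclass
class TrainingResult:
    """Trained parameters, the checkpoint trace, and halting information."""

    params: AgentParams  # snapshot at the halting checkpoint
    critic: CriticParams
    trace: pd.DataFrame  # one row per checkpoint
    snapshots: List[Tuple[AgentParams, CriticParams]]
    halt_index: int  # row index of the halting checkpoint
    halt_episode: int  # episode count at the halting checkpoint
    final_params: AgentParams  # snapshot at n_episodes_max
    final_critic: CriticParams
    variant: str
    config: TrainingConfig

    @property
    def halt_accuracy(self) -> float:
        return float(self.trace["eval_accuracy"].iloc[self.halt_index])


def _check_finite(params: AgentParams, critic: CriticParams, bound: float, ep: int):
    arrays = [params.theta_s, params.theta_c, params.b, critic.w_s, critic.w_c]
    if not all(np.all(np.isfinite(a)) for a in arrays) or not np.isfinite(critic.b_v):
        raise FloatingPointError(f"non-finite parameters after {ep} episodes")
    mean_abs = float(np.mean(np.abs(np.concatenate([a.ravel() for a in arrays]))))
    if mean_abs > bound:
        raise FloatingPointError(
            f"divergence guard: mean |theta| = {mean_abs:.2f} exceeds bound "
            f"{bound} after {ep} episodes"
        )


def train(
    task: TaskParams,
    grid: Optional[TimescaleGrid] = None,
    config: TrainingConfig = TrainingConfig(),
    variant: str = "full",
    tau: Optional[float] = None,
    sigma_I_scale: float = 1.0,
) -> TrainingResult:
    """Train an agent on the task and return the halting-point snapshot.

    ``variant`` selects the model: ``"full"`` (multi-timescale signal and
    clock banks), ``"single_tau"`` (one time constant ``tau`` for both
    banks; 9 parameters), or ``"no_clock"`` (multi-timescale signal bank,
    clock weights frozen at 0).  ``sigma_I_scale`` rescales the intrinsic
    read-out noise (used to equalise total noise when comparing single- and
    multi-integrator models).
    """
    if variant == "single_tau":
        if tau is None:
            raise ValueError("single_tau variant needs a tau")
        grid = make_grid(1, tau, tau)
    elif grid is None:
        grid = make_grid()
    elif variant not in ("full", "no_clock"):
        raise ValueError(f"unknown variant {variant!r}")
    clock_trainable = variant != "no_clock"

    params = AgentParams.zeros(grid, b_wait=config.b_wait_init)
    critic = CriticParams.zeros(grid.n_tau)
    b_v = np.array([critic.b_v])
    decay = grid.decay(task.dt)
    gain = 1.0 - decay
    sigma_I = task.sigma_I * sigma_I_scale

    ss = np.random.SeedSequence(config.seed)
    mu_rng = np.random.default_rng(ss.spawn(1)[0])
    # frozen held-out evaluation seeds: identical episodes at every checkpoint
    eval_seed_acc, eval_seed_coh = (
        int(s) % _SEED_MOD for s in ss.generate_state(2, dtype=np.uint64)
    )
    n_blocks = int(np.ceil(config.n_episodes_max / config.checkpoint_every))
    block_seeds = [
        int(s) % _SEED_MOD
        for s in np.random.SeedSequence((config.seed, 1)).generate_state(
            n_blocks, dtype=np.uint64
        )
    ]

    rows = []
    snapshots: List[Tuple[AgentParams, CriticParams]] = []
    episodes_done = 0
    for blk in range(n_blocks):
        n_ep = min(config.checkpoint_every, config.n_episodes_max - episodes_done)
        mus = mu_rng.normal(0.0, task.sigma_mu, size=n_ep)
        rewards, steps, actions = _kernels.train_episodes(
            params.theta_s,
            params.theta_c,
            params.b,
            critic.w_s,
            critic.w_c,
            b_v,
            decay,
            gain,
            mus,
            task.sample_std,
            sigma_I,
            task.n_steps,
            config.lr_actor,
            config.lr_critic,
            config.lambda_actor,
            config.lambda_critic,
            config.gamma,
            clock_trainable,
            config.critic_abs_signal,
            block_seeds[blk],
        )
        episodes_done += n_ep
        critic.b_v = float(b_v[0])
        _check_finite(params, critic, config.theta_bound, episodes_done)

        # held-out diagnostics (frozen seeds -> comparable across checkpoints)
        acc_batch = evaluate_random(
            params, task, config.eval_episodes, eval_seed_acc, sigma_I=sigma_I
        )
        coh = evaluate_coherences(
            params,
            task,
            config.coherences,
            config.coherence_episodes,
            eval_seed_coh,
            record_traces=True,
            sigma_I=sigma_I,
        )
        try:
            sn = metrics.signal_neutrality(
                metrics.build_aligned_curves(coh, warn=False)
            )
        except ValueError:
            sn = np.nan
        try:
            sp = metrics.scalar_property(
                {c: b.decision_times[b.decided] for c, b in coh.items()}
            )
        except ValueError:
            sp = np.nan
        decided = actions != 0
        row = {
            "episode": episodes_done,
            "train_reward": float(rewards.mean()),
            "train_mean_rt": float(steps[decided].mean() * task.dt)
            if decided.any()
            else np.nan,
            "train_late_fraction": float(np.mean(~decided)),
            "eval_accuracy": acc_batch.accuracy(),
            "eval_mean_rt": acc_batch.mean_rt(),
            "eval_late_fraction": acc_batch.timeout_fraction,
            "signal_neutrality": sn,
            "scalar_property": sp,
        }
        for c, bt in coh.items():
            row[f"acc_c{c:g}"] = bt.accuracy() if c != 0.0 else np.nan
            dec = bt.decided
            row[f"rt_c{c:g}"] = (
                float(bt.decision_times[dec].mean()) if dec.any() else np.nan
            )
        rows.append(row)
        snapshots.append((params.copy(), critic.copy()))

    trace = pd.DataFrame(rows)
    halt_index = _select_halt(trace, config.accuracy_floor)
    halt_params, halt_critic = snapshots[halt_index]
    return TrainingResult(
        params=halt_params,
        critic=halt_critic,
        trace=trace,
        snapshots=snapshots,
        halt_index=halt_index,
        halt_episode=int(trace["episode"].iloc[halt_index]),
        final_params=params.copy(),
        final_critic=critic.copy(),
        variant=variant,
        config=config,
    )


def _select_halt(trace: pd.DataFrame, accuracy_floor: float) -> int:
    """Checkpoint with peak signal neutrality among those at/above the
    accuracy floor; falls back to the most accurate checkpoint if the floor
    is never reached."""
    ok = trace["eval_accuracy"] >= accuracy_floor
    sn = trace["signal_neutrality"]
    if ok.any() and sn[ok].notna().any():
        return int(sn.where(ok).idxmax())
    return int(trace["eval_accuracy"].idxmax())
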
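"""Shared fixtures: trained artifacts reused across the suite.

Training is the expensive step, so trained agents are session-scoped and
shared.  Seed 0 runs the full default configuration (fine checkpointing);
seeds 1-4 use coarser checkpoint cadence and smaller per-checkpoint
evaluation batches — same learning trajectory per episode count, cheaper
diagnostics.  Comparison models (single-timescale agent, clockless agent,
thresholded integrators) are trained/optimised per seed with the intrinsic
noise rescaling computed from that seed's trained weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pytest

from taubank import baselines
from taubank.integrators import make_grid
from taubank.learning import TrainingConfig, TrainingResult, train
from taubank.task import TaskParams

warnings.filterwarnings("ignore", message=".*curve omitted.*")

#: Seeds of the independent trainings used by the model-comparison tests.
COMPARISON_SEEDS = (0, 1, 2, 3, 4)

#: Example time constant for the single-timescale comparison models (s).
SINGLE_TAU = 2.0


@pytest.fixture(scope="session")
def task() -> TaskParams:
    return TaskParams()


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def default_run(task, grid) -> TrainingResult:
    """Full default-configuration training (seed 0, fine checkpointing)."""
    return train(task, grid, TrainingConfig(seed=0))


def _desk_config(seed: int) -> TrainingConfig:
    # identical learning trajectory per episode; coarser/cheaper diagnostics
    return TrainingConfig(
        seed=seed,
        checkpoint_every=15_000,
        eval_episodes=2_000,
        coherence_episodes=500,
    )


@dataclass
class SeedArtifacts:
    """All trained/optimised models for one training seed."""

    seed: int
    full: TrainingResult
    single_tau: TrainingResult
    no_clock: TrainingResult
    alpha: float
    ou_models: Dict[float, baselines.ThresholdModel]  # grid tau -> model
    ou_tau2: baselines.ThresholdModel  # the example tau = 2 s integrator


@pytest.fixture(scope="session")
def seed_artifacts(task, grid, default_run) -> List[SeedArtifacts]:
    """Matched artifacts for the five comparison seeds."""
    out = []
    for seed in COMPARISON_SEEDS:
        full = default_run if seed == 0 else train(task, grid, _desk_config(seed))
        alpha = baselines.alpha_rescale(full.params.theta_s[2])
        cfg = _desk_config(seed)
        single = train(
            task, None, cfg, variant="single_tau", tau=SINGLE_TAU,
            sigma_I_scale=alpha,
        )
        noclock = train(task, grid, cfg, variant="no_clock")
        ou_models = {}
        for tau in list(grid.taus) + [SINGLE_TAU]:
            m, _ = baselines.optimize_threshold(
                float(tau),
                task,
                n_episodes=6_000,
                seed=100 + seed,
                sigma_I_eff=alpha * task.sigma_I,
            )
            ou_models[float(tau)] = m
        ou_tau2 = ou_models.pop(SINGLE_TAU)
        out.append(
            SeedArtifacts(
                seed=seed,
                full=full,
                single_tau=single,
                no_clock=noclock,
                alpha=alpha,
                ou_models=ou_models,
                ou_tau2=ou_tau2,
            )
        )
    return out


@pytest.fixture(scope="session")
def long_run(task, grid) -> TrainingResult:
    """Extended training (1e6 episodes) for the late-refinement check."""
    cfg = TrainingConfig(
        seed=0,
        n_episodes_max=1_000_000,
        checkpoint_every=100_000,
        eval_episodes=4_000,
        coherence_episodes=300,
    )
    return train(task, grid, cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
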
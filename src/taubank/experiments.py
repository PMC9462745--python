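"""Experiment drivers: full runs, robustness sweeps, frozen fixtures.

:func:`run_experiment` executes the train -> evaluate -> metrics pipeline of
one configuration and writes a self-contained artifact directory (manifest
with config hash and seeds, parameter snapshots, checkpoint trace, outcome
logs, metrics).  Re-running the same configuration reproduces every output
byte-identically.

Sweeps retrain from scratch for every grid value (episode deadline ``t_max``
or intrinsic noise ``sigma_I``), which is how robustness of the
multi-timescale strategy is assessed.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__, metrics
from .agent import AgentParams
from .config import RunConfig
from .integrators import make_grid
from .learning import CriticParams, TrainingConfig, TrainingResult, train
from .simulate import evaluate_coherences, evaluate_random
from .task import TaskParams, coherence_to_mu

__all__ = ["run_experiment", "sweep", "make_fixtures"]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def run_experiment(
    config: RunConfig,
    outdir: Union[str, Path],
    overwrite: bool = True,
) -> dict:
    """Run one configuration end to end and write its artifact directory.

    Returns the metrics dictionary.  With ``overwrite=False`` an existing
    completed run (manifest present) raises instead of being clobbered.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"completed run already at {outdir}")
    outdir.mkdir(parents=True, exist_ok=True)

    exp = config.experiment
    result = train(
        config.task,
        config.grid(),
        config.training,
        variant=exp.get("variant", "full"),
        tau=exp.get("tau"),
        sigma_I_scale=exp.get("sigma_I_scale", 1.0),
    )

    ev = config.evaluation
    acc_batch = evaluate_random(
        result.params, config.task, int(ev["n_episodes"]), int(ev["seed"])
    )
    coh = evaluate_coherences(
        result.params,
        config.task,
        config.training.coherences,
        int(ev["coherence_episodes"]),
        int(ev["seed"]) + 1,
        record_traces=True,
    )
    curves = metrics.build_aligned_curves(coh, warn=False)
    strip = metrics.boundary_strip(coh, result.params)
    perf = metrics.performance_curves(coh)
    try:
        sn = metrics.signal_neutrality(curves)
    except ValueError:  # undertrained/short runs may not define 2 curves
        sn = float("nan")
    try:
        sp = metrics.scalar_property(
            {c: b.decision_times[b.decided] for c, b in coh.items()}
        )
    except ValueError:
        sp = float("nan")
    out_metrics = {
        "accuracy": acc_batch.accuracy(),
        "mean_rt": acc_batch.mean_rt(),
        "late_fraction": acc_batch.timeout_fraction,
        "signal_neutrality": sn,
        "scalar_property": sp,
        "halt_episode": result.halt_episode,
        "halt_accuracy": result.halt_accuracy,
    }

    # artifact files
    result.params.save(outdir / "params.json")
    _write_json(outdir / "critic.json", result.critic.to_dict())
    result.trace.to_csv(outdir / "trace.csv", index=False)
    _write_json(outdir / "metrics.json", out_metrics)
    acc_batch.outcomes_frame().to_csv(outdir / "outcomes.csv")
    perf.to_csv(outdir / "performance.csv")
    curve_frame = pd.DataFrame({"lag": curves.lags})
    for c in sorted(curves.curves):
        curve_frame[f"dsr_c{c:g}"] = curves.curves[c]
    curve_frame.to_csv(outdir / "curves.csv", index=False)
    pd.DataFrame(
        {"t": strip.t, "lo": strip.lo, "hi": strip.hi, "ds_c": strip.ds_c}
    ).to_csv(outdir / "boundary.csv", index=False)
    _write_json(
        manifest_path,
        {
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "package_version": __version__,
            "variant": result.variant,
            "halt_episode": result.halt_episode,
        },
    )
    return out_metrics


def sweep(
    config: RunConfig,
    variable: str,
    values: Sequence[float],
    outdir: Union[str, Path],
    repetitions: int = 1,
) -> pd.DataFrame:
    """Robustness sweep: retrain from scratch for each value of ``variable``.

    ``variable`` is ``"t_max"`` or ``"sigma_I"``; each cell's accuracy is
    evaluated on fresh episodes with that cell's own task parameters.
    """
    if variable not in ("t_max", "sigma_I"):
        raise ValueError("sweep variable must be 't_max' or 'sigma_I'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in values:
        for rep in range(repetitions):
            task = replace(config.task, **{variable: float(v)})
            training = replace(config.training, seed=config.training.seed + rep)
            cell = RunConfig(
                task=task,
                integrators=config.integrators,
                training=training,
                evaluation=config.evaluation,
                experiment=config.experiment,
            )
            m = run_experiment(cell, outdir / f"{variable}_{v:g}_rep{rep}")
            rows.append({variable: float(v), "repetition": rep, **m})
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "sweep.csv", index=False)
    return frame


def make_fixtures(seed: int = 0, outdir: Optional[Union[str, Path]] = None) -> dict:
    """Small frozen datasets for fast testing and demos.

    (a) a 50-episode outcome log from a hand-set agent, (b) a tiny trained
    snapshot from a 2,000-episode run, (c) a table of closed-form reference
    values.  Regeneration under the same seed is identical.
    """
    task = TaskParams()
    grid = make_grid()
    # (a) hand-set agent: antisymmetric signal weights at mid taus, mild urgency
    params = AgentParams.zeros(grid, b_wait=3.0)
    params.theta_s[2] = np.exp(-0.5 * (np.log(grid.taus / 1.0)) ** 2) * 4.0
    params.theta_s[0] = -params.theta_s[2]
    params.theta_c[1] = np.linspace(1.0, -1.0, grid.n_tau)
    batch = evaluate_random(params, task, 50, seed)
    log = batch.outcomes_frame()

    # (b) tiny trained snapshot (well short of convergence, by construction)
    cfg = TrainingConfig(
        n_episodes_max=2_000,
        checkpoint_every=1_000,
        eval_episodes=200,
        coherence_episodes=100,
        seed=seed,
    )
    trained = train(task, grid, cfg)

    # (c) closed-form reference table
    from . import baselines

    closed_form = {
        "coherence_to_mu_51.2": coherence_to_mu(51.2),
        "coherence_to_mu_12.8": coherence_to_mu(12.8),
        "fixed_t_accuracy_2s": baselines.fixed_t_accuracy(2.0),
        "psychometric_7.97": baselines.psychometric_reference(7.97),
        "ddm_cv_50": baselines.ddm_cv(50.0),
        "grid_ratio": float(grid.taus[1] / grid.taus[0]),
    }
    fixtures = {
        "episode_log": log,
        "handset_params": params,
        "trained_params": trained.params,
        "trained_critic": trained.critic,
        "closed_form": closed_form,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        log.to_csv(outdir / "episode_log.csv")
        params.save(outdir / "handset_params.json")
        trained.params.save(outdir / "trained_params.json")
        _write_json(outdir / "trained_critic.json", trained.critic.to_dict())
        _write_json(outdir / "closed_form.json", closed_form)
    return fixtures
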
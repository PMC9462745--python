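"""The three signatures of the multi-timescale strategy.

Trains the full agent plus its two ablations (single time constant; no
clock) at a reduced episode budget, then measures:

* signal neutrality — decision-aligned propensity curves collapse across
  coherences,
* the scalar property — response-time CV nearly constant across coherences,
* collapsing boundaries — the clock-driven part of the decision propensity
  rises, peaks around 200 ms and then decays, acting as a moving threshold.

Takes a few minutes; the test suite runs the same comparisons over five
seeds at the full default budget.
"""

import warnings

warnings.filterwarnings("ignore", message=".*curve omitted.*")

import numpy as np

from taubank import baselines, metrics
from taubank.agent import delta_sigma_clock
from taubank.integrators import make_grid
from taubank.learning import TrainingConfig, train
from taubank.simulate import evaluate_coherences
from taubank.task import TaskParams

task = TaskParams()
grid = make_grid()
cfg = TrainingConfig(
    n_episodes_max=90_000,
    checkpoint_every=15_000,
    eval_episodes=1_500,
    coherence_episodes=500,
    seed=1,
)

print("training full agent...")
full = train(task, grid, cfg)
alpha = baselines.alpha_rescale(full.params.theta_s[2])
print(f"  intrinsic-noise rescale for single-integrator comparisons: "
      f"alpha_I = {alpha:.2f}")
print("training single-timescale agent (tau = 2 s)...")
single = train(task, None, cfg, variant="single_tau", tau=2.0, sigma_I_scale=alpha)
print("training clockless agent...")
noclock = train(task, grid, cfg, variant="no_clock")

C = metrics.STANDARD_COHERENCES
evals = {
    "full agent": evaluate_coherences(full.params, task, C, 1500, 42),
    "single-tau": evaluate_coherences(
        single.params, task, C, 1500, 42, sigma_I=alpha * task.sigma_I
    ),
    "no clock": evaluate_coherences(noclock.params, task, C, 1500, 42),
}

print("\nmodel         signal neutrality   CV range across coherences")
for name, coh in evals.items():
    sn = metrics.signal_neutrality(metrics.build_aligned_curves(coh, warn=False))
    cvr = metrics.cv_range(coh)
    print(f"  {name:12s}    {sn:6.2f}            {cvr:.3f}")
print("(higher neutrality = tighter collapse; smaller CV range = closer to")
print(" Weber's law. Both favour the multi-timescale agent.)")

t = np.arange(1, task.n_steps + 1) * task.dt
print("\neffective moving threshold dSigma^c(t):")
for name, params in (("full agent", full.params), ("single-tau", single.params),
                     ("no clock", noclock.params)):
    dsc = delta_sigma_clock(params, t)
    peak = t[int(np.argmax(dsc))]
    print(f"  {name:12s} start {dsc[0]:6.2f}  peak {dsc.max():6.2f} at "
          f"{peak:.2f} s  end {dsc[-1]:6.2f}")
print("(the full agent's threshold rises then collapses — the optimal shape")
print(" under a response deadline; the ablations can only decay or stay flat)")
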
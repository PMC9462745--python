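"""Closed-form reference curves of the decision task.

Evaluates the analytic quantities the simulations are checked against: the
coherence <-> signal-mean map, the ideal fixed-time observer's accuracy, the
experimental psychometric reference, and the drift-diffusion response-time
CV law.  No training involved; runs in well under a second.
"""

import numpy as np

from taubank import baselines
from taubank.task import coherence_to_mu, mu_to_coherence

print("coherence -> signal mean |mu| = 0.216 c / sqrt(100 - c):")
for c in (3.2, 6.4, 12.8, 25.6, 51.2):
    mu = coherence_to_mu(c)
    print(f"  {c:5.1f}%  ->  |mu| = {mu:.3f}   (round trip: {mu_to_coherence(mu):.1f}%)")

print("\nideal observer forced to answer at time t (sign of summed signal):")
for t in (0.25, 0.5, 1.0, 2.0):
    print(f"  t = {t:4.2f} s  ->  fraction correct {baselines.fixed_t_accuracy(t):.3f}")
print("  (the task caps episodes at 2 s, so ~0.85 bounds any decider)")

print("\nexperimental psychometric reference 1 - 0.5 exp[-(c/7.97)^1.62]:")
for c in (3.2, 12.8, 51.2):
    print(f"  {c:5.1f}%  ->  {baselines.psychometric_reference(c):.3f}")

print("\ndrift-diffusion CV law ((100 - c)/c^2)^(1/4) — NOT constant in c,")
print("which is why a plain drift-diffusion model violates the scalar property:")
for c in (3.2, 12.8, 51.2):
    print(f"  {c:5.1f}%  ->  CV = {baselines.ddm_cv(c):.3f}")
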
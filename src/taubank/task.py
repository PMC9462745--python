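"""Two-alternative forced-choice task with a scalar noisy signal.

The environment abstracts a random-dot motion discrimination experiment as a
one-dimensional Gaussian signal: every ``dt`` seconds the subject observes a
sample ``s ~ N(mu, (sigma/sqrt(dt))^2)`` and must eventually report the sign
of ``mu`` ("left" for negative, "right" for positive) or wait for another
sample.  An episode lasts at most ``t_max`` seconds; a "wait" emitted on the
last step ends the episode with no reward (a *late response*).  The mean
``mu`` is redrawn at the start of every episode from ``N(0, sigma_mu^2)``, so
the agent experiences a broad distribution of signal-to-noise ratios.

The noise amplitude ``sigma`` is expressed in units of ``s^-1/2`` (white-noise
convention): the per-sample standard deviation is ``sigma / sqrt(dt)``, so the
information gained about the sign of ``mu`` by summing samples up to time
``t`` depends on ``t`` only, not on the discretisation step.

Difficulty is interchangeably expressed as ``|mu|`` or as a motion-coherence
percentage ``c`` via ``|mu| = 0.216 c / sqrt(100 - c)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LEFT",
    "WAIT",
    "RIGHT",
    "COHERENCE_SCALE",
    "TaskParams",
    "Episode",
    "Outcome",
    "coherence_to_mu",
    "mu_to_coherence",
    "generate_episode",
    "sample_mu",
    "score_outcome",
]

# Action encoding used in all public APIs and logs.  A "wait" emitted on the
# final step of an episode is a timeout; timeouts are therefore logged with
# action == WAIT and decision_time == t_max.
LEFT: int = -1
WAIT: int = 0
RIGHT: int = 1

#: Proportionality constant between coherence (percent) and signal mean.
COHERENCE_SCALE: float = 0.216


@dataclass(frozen=True)
class TaskParams:
    """Environment constants, all in seconds / dimensionless units.

    Parameters
    ----------
    dt : float
        Sampling step of the signal (s).
    t_max : float
        Maximum episode duration (s).  Rounded to a multiple of ``dt``
        (with a warning) if it is not one already.
    sigma : float
        Signal noise scale in ``s^-1/2``; the per-sample standard deviation
        is ``sigma / sqrt(dt)``.
    sigma_mu : float
        Standard deviation of the per-episode mean ``mu``.
    sigma_I : float
        Intrinsic read-out noise added to every integrator value observed by
        the actor and the critic (see :mod:`taubank.integrators`).
    """

    dt: float = 0.01
    t_max: float = 2.0
    sigma: float = 0.18
    sigma_mu: float = 0.25
    sigma_I: float = 0.02

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.t_max < self.dt:
            raise ValueError(f"t_max ({self.t_max}) must be >= dt ({self.dt})")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.sigma_mu < 0 or self.sigma_I < 0:
            raise ValueError("sigma_mu and sigma_I must be non-negative")
        n = self.t_max / self.dt
        if abs(n - round(n)) > 1e-9:
            rounded = round(n) * self.dt
            warnings.warn(
                f"t_max={self.t_max} is not an integer multiple of dt={self.dt}; "
                f"rounding to {rounded}",
                stacklevel=2,
            )
            object.__setattr__(self, "t_max", rounded)

    @property
    def n_steps(self) -> int:
        """Number of signal samples per episode, ``round(t_max / dt)``."""
        return int(round(self.t_max / self.dt))

    @property
    def sample_std(self) -> float:
        """Per-sample standard deviation of the signal, ``sigma / sqrt(dt)``."""
        return self.sigma / np.sqrt(self.dt)


@dataclass
class Episode:
    """One realisation of the task signal."""

    mu: float
    samples: np.ndarray
    coherence_label: Optional[float] = None


@dataclass
class Outcome:
    """Terminal record of one episode."""

    action: int  # LEFT, WAIT (timeout) or RIGHT
    decision_time: float  # seconds from onset; t_max for timeouts
    reward: float
    correct: Optional[bool] = None  # None for timeouts and for mu == 0
    mu: float = 0.0
    coherence: Optional[float] = field(default=None)


def coherence_to_mu(coherence) -> float | np.ndarray:
    """Magnitude of the signal mean for a coherence percentage in [0, 100).

    ``|mu| = 0.216 c / sqrt(100 - c)``; monotone increasing, 0 at c = 0 and
    diverging as c -> 100 (a fully coherent stimulus has no diffusion noise
    relative to drift).
    """
    c = np.asarray(coherence, dtype=float)
    if np.any(c < 0) or np.any(c >= 100):
        raise ValueError("coherence must lie in [0, 100) percent")
    out = COHERENCE_SCALE * c / np.sqrt(100.0 - c)
    return float(out) if np.isscalar(coherence) else out


def mu_to_coherence(mu_magnitude) -> float | np.ndarray:
    """Inverse of :func:`coherence_to_mu` on [0, 100).

    Solving ``mu^2 (100 - c) = k^2 c^2`` for ``c >= 0`` gives the closed form
    ``c = (-mu^2 + sqrt(mu^4 + 400 k^2 mu^2)) / (2 k^2)`` with ``k = 0.216``.
    """
    m = np.asarray(mu_magnitude, dtype=float)
    if np.any(m < 0):
        raise ValueError("mu magnitude must be non-negative")
    k2 = COHERENCE_SCALE**2
    m2 = m * m
    c = (-m2 + np.sqrt(m2 * m2 + 400.0 * k2 * m2)) / (2.0 * k2)
    return float(c) if np.isscalar(mu_magnitude) else c


def sample_mu(sigma_mu: float, rng: np.random.Generator) -> float:
    """Draw a per-episode signal mean ``mu ~ N(0, sigma_mu^2)``."""
    if sigma_mu < 0:
        raise ValueError("sigma_mu must be non-negative")
    return float(rng.normal(0.0, sigma_mu))


def generate_episode(
    params: TaskParams,
    mu: float,
    rng: np.random.Generator,
    coherence_label: Optional[float] = None,
) -> Episode:
    """Generate the full sample path of one episode.

    Samples are i.i.d. ``N(mu, (sigma/sqrt(dt))^2)``, one per step; step ``k``
    (1-based) covers time ``t = k * dt``.
    """
    samples = rng.normal(mu, params.sample_std, size=params.n_steps)
    if coherence_label is not None:
        expected = coherence_to_mu(coherence_label)
        if abs(abs(mu) - expected) > 1e-9 * max(1.0, expected):
            raise ValueError(
                f"|mu|={abs(mu)} does not match coherence {coherence_label}% "
                f"(expected {expected})"
            )
    return Episode(mu=mu, samples=samples, coherence_label=coherence_label)


def score_outcome(action: int, mu: float) -> float:
    """Reward rule: 1 iff the chosen side matches the sign of ``mu``.

    Timeouts (``action == WAIT``) are never rewarded; ``mu == 0`` episodes
    (exactly-zero coherence) yield 0 for any action — there is no correct
    side.
    """
    if action not in (LEFT, WAIT, RIGHT):
        raise ValueError(f"unknown action {action!r}")
    if action == WAIT or mu == 0.0:
        return 0.0
    return 1.0 if (action > 0) == (mu > 0) else 0.0
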
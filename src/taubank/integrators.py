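"""Banks of leaky integrators over a grid of timescales.

Two banks share a single grid of time constants ``tau``: the *signal* bank
low-pass filters the task signal ``s(t)``, the *clock* bank integrates a
constant input of 1 and therefore traces ``1 - exp(-t/tau)`` — a population
code for elapsed time.  Both banks reset to zero at episode onset.

The discrete update is the exact (zero-order-hold) solution of the
continuous leak equation ``tau dx/dt = -(x - input)`` over one step::

    x <- x * exp(-dt/tau) + (1 - exp(-dt/tau)) * input

so the clock trace equals its closed form to machine precision; a forward
Euler step at dt/tau = 0.1 would already deviate by ~0.5%.

What the decision stage sees is not the latent state but a noisy read-out:
fresh i.i.d. ``N(0, sigma_I^2)`` is added per timescale, per bank, per step,
modelling instantaneous-rate fluctuations of a biological implementation.
The noise does not accumulate into the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["TimescaleGrid", "BankState", "NoisyReadout", "make_grid", "IntegratorBank"]


@dataclass(frozen=True)
class TimescaleGrid:
    """Ordered grid of integration time constants (seconds)."""

    taus: np.ndarray
    spacing: Literal["log", "linear"] = "log"

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        object.__setattr__(self, "taus", taus)
        if np.any(taus <= 0):
            raise ValueError("all time constants must be positive")
        if taus.size > 1 and np.any(np.diff(taus) <= 0):
            raise ValueError("time constants must be strictly increasing")

    @property
    def n_tau(self) -> int:
        return int(self.taus.size)

    def decay(self, dt: float) -> np.ndarray:
        """Per-step decay factors ``exp(-dt/tau)``."""
        return np.exp(-dt / self.taus)


def make_grid(
    n_tau: int = 10,
    tau_min: float = 0.1,
    tau_max: float = 10.0,
    spacing: Literal["log", "linear"] = "log",
) -> TimescaleGrid:
    """Build a timescale grid.

    With log spacing, consecutive time constants have a fixed ratio
    ``alpha = (tau_max/tau_min)^(1/(n_tau-1))`` — for the default 10 taus
    between 0.1 s and 10 s, ``alpha = 100^(1/9) ~= 1.668``.
    """
    if n_tau < 1:
        raise ValueError("n_tau must be >= 1")
    if tau_min <= 0 or tau_max <= 0:
        raise ValueError("time constants must be positive")
    if tau_min > tau_max:
        raise ValueError("tau_min must be <= tau_max")
    if n_tau == 1:
        taus = np.array([tau_min], dtype=float)
    elif spacing == "log":
        taus = np.geomspace(tau_min, tau_max, n_tau)
    elif spacing == "linear":
        taus = np.linspace(tau_min, tau_max, n_tau)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return TimescaleGrid(taus=taus, spacing=spacing)


@dataclass
class BankState:
    """Current values of the signal and clock banks."""

    x_signal: np.ndarray
    x_clock: np.ndarray
    elapsed: float = 0.0


@dataclass
class NoisyReadout:
    """One noisy observation of the bank state (what actor and critic see)."""

    y_signal: np.ndarray
    y_clock: np.ndarray


class IntegratorBank:
    """Stateful pair of signal and clock integrator banks on a shared grid."""

    def __init__(self, grid: TimescaleGrid, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.grid = grid
        self.dt = float(dt)
        self._decay = grid.decay(dt)
        self._gain = 1.0 - self._decay
        self.state = BankState(
            x_signal=np.zeros(grid.n_tau),
            x_clock=np.zeros(grid.n_tau),
        )

    def reset(self) -> None:
        """Zero both banks and the elapsed-time counter (episode onset)."""
        self.state.x_signal[:] = 0.0
        self.state.x_clock[:] = 0.0
        self.state.elapsed = 0.0

    def step(self, s_t: float) -> BankState:
        """Advance both banks by one step given the signal sample ``s_t``."""
        st = self.state
        st.x_signal *= self._decay
        st.x_signal += self._gain * s_t
        st.x_clock *= self._decay
        st.x_clock += self._gain
        st.elapsed += self.dt
        return st

    def observe(self, sigma_I: float, rng: np.random.Generator) -> NoisyReadout:
        """Noisy read-out of the current state; does not modify the state.

        A single read-out per step is shared by the actor and the critic.
        """
        if sigma_I < 0:
            raise ValueError("sigma_I must be non-negative")
        n = self.grid.n_tau
        if sigma_I == 0.0:
            return NoisyReadout(
                y_signal=self.state.x_signal.copy(),
                y_clock=self.state.x_clock.copy(),
            )
        noise = rng.normal(0.0, sigma_I, size=2 * n)
        return NoisyReadout(
            y_signal=self.state.x_signal + noise[:n],
            y_clock=self.state.x_clock + noise[n:],
        )

    def clock_closed_form(self, t) -> np.ndarray:
        """Noise-free clock values ``1 - exp(-t/tau)`` at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        return 1.0 - np.exp(-t[..., None] / self.grid.taus)
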
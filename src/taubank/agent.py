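"""Softmax decision layer reading the integrator banks.

At every step the actor forms six weighted sums of the noisy read-outs — a
signal part and a clock part for each of the three options left / wait /
right::

    Sigma^s_right = sum_tau theta^s[right, tau] * y^s_tau
    Sigma^s_left  = sum_tau theta^s[left,  tau] * y^s_tau
    Sigma^s_wait  = sum_tau theta^s[wait,  tau] * |y^s_tau|
    Sigma^c_a     = sum_tau theta^c[a, tau] * y^c_tau + b_a

The absolute value in the wait sum makes a signal and its mirror image
equally effective at deferring the decision.  The three totals
``Sigma_a = Sigma^s_a + Sigma^c_a`` pass through a softmax to give action
probabilities; the episode ends when left or right is sampled.

Analyses work with the decision propensities

    dSigma_right = Sigma_right - Sigma_wait
                 = dSigma^s - dSigma^c,

where ``dSigma^s = Sigma^s_right - Sigma^s_wait`` depends on the signal and
``dSigma^c = Sigma^c_wait - Sigma^c_right`` depends on elapsed time only:
``dSigma^c(t)`` is the agent's *effective moving decision threshold*.

Parameter arrays are indexed by action row 0=left, 1=wait, 2=right;
public logs use the integer encoding left=-1, wait=0, right=+1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .integrators import NoisyReadout, TimescaleGrid

__all__ = [
    "A_LEFT",
    "A_WAIT",
    "A_RIGHT",
    "AgentParams",
    "PolicyOutput",
    "action_sums",
    "softmax_policy",
    "act",
    "log_policy_grad",
    "restrict_to_single_tau",
    "strip_clock",
    "delta_sigma_clock",
]

# Row indices of the parameter arrays (not the public action encoding).
A_LEFT, A_WAIT, A_RIGHT = 0, 1, 2

#: Map from row index to the public action encoding {-1, 0, +1}.
ROW_TO_ACTION = np.array([-1, 0, 1])


@dataclass
class AgentParams:
    """Actor parameters: 6 x n_tau weights and 3 biases.

    ``theta_s[a, i]`` weights the signal integrator with time constant
    ``taus[i]`` toward action row ``a``; ``theta_c`` the clock integrators;
    ``b`` the per-action biases.  The parameterisation is redundant under a
    common shift of the biases (softmax shift invariance); no canonical form
    is enforced.
    """

    theta_s: np.ndarray  # (3, n_tau)
    theta_c: np.ndarray  # (3, n_tau)
    b: np.ndarray  # (3,)
    taus: np.ndarray  # (n_tau,)

    def __post_init__(self) -> None:
        self.theta_s = np.asarray(self.theta_s, dtype=float)
        self.theta_c = np.asarray(self.theta_c, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)
        n = self.taus.size
        if self.theta_s.shape != (3, n) or self.theta_c.shape != (3, n):
            raise ValueError(
                f"weight shapes {self.theta_s.shape}/{self.theta_c.shape} "
                f"inconsistent with {n} time constants"
            )
        if self.b.shape != (3,):
            raise ValueError("b must have shape (3,)")

    @property
    def n_tau(self) -> int:
        return int(self.taus.size)

    @property
    def n_params(self) -> int:
        return 6 * self.n_tau + 3

    @classmethod
    def zeros(cls, grid: TimescaleGrid, b_wait: float = 0.0) -> "AgentParams":
        n = grid.n_tau
        b = np.zeros(3)
        b[A_WAIT] = b_wait
        return cls(
            theta_s=np.zeros((3, n)),
            theta_c=np.zeros((3, n)),
            b=b,
            taus=grid.taus.copy(),
        )

    def copy(self) -> "AgentParams":
        return AgentParams(
            theta_s=self.theta_s.copy(),
            theta_c=self.theta_c.copy(),
            b=self.b.copy(),
            taus=self.taus.copy(),
        )

    # -- serialisation: flat key/value JSON with the explicit tau grid --
    def to_dict(self) -> dict:
        return {
            "taus": self.taus.tolist(),
            "theta_s": {
                name: self.theta_s[row].tolist()
                for name, row in (("left", A_LEFT), ("wait", A_WAIT), ("right", A_RIGHT))
            },
            "theta_c": {
                name: self.theta_c[row].tolist()
                for name, row in (("left", A_LEFT), ("wait", A_WAIT), ("right", A_RIGHT))
            },
            "b": {"left": self.b[A_LEFT], "wait": self.b[A_WAIT], "right": self.b[A_RIGHT]},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        taus = np.asarray(d["taus"], dtype=float)
        theta_s = np.array([d["theta_s"][k] for k in ("left", "wait", "right")])
        theta_c = np.array([d["theta_c"][k] for k in ("left", "wait", "right")])
        b = np.array([d["b"][k] for k in ("left", "wait", "right")], dtype=float)
        return cls(theta_s=theta_s, theta_c=theta_c, b=b, taus=taus)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "AgentParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PolicyOutput:
    """Per-step sums, probabilities and propensity decompositions."""

    sigma_s: np.ndarray  # (3,) signal parts (wait uses |y|)
    sigma_c: np.ndarray  # (3,) clock parts incl. bias
    sigma: np.ndarray  # (3,) totals
    p: np.ndarray  # (3,) action probabilities
    dsr: float  # dSigma_right = Sigma_right - Sigma_wait
    dsl: float  # dSigma_left  = Sigma_left  - Sigma_wait
    ds_s: float  # dSigma^s = Sigma^s_right - Sigma^s_wait
    ds_c: float  # dSigma^c = Sigma^c_wait - Sigma^c_right


def action_sums(readout: NoisyReadout, params: AgentParams) -> PolicyOutput:
    """Compute the six weighted sums and derived quantities for one read-out."""
    y_s = np.asarray(readout.y_signal, dtype=float)
    y_c = np.asarray(readout.y_clock, dtype=float)
    if y_s.shape != (params.n_tau,) or y_c.shape != (params.n_tau,):
        raise ValueError(
            f"read-out shapes {y_s.shape}/{y_c.shape} inconsistent with "
            f"agent of {params.n_tau} time constants"
        )
    abs_y = np.abs(y_s)
    sigma_s = np.array(
        [
            params.theta_s[A_LEFT] @ y_s,
            params.theta_s[A_WAIT] @ abs_y,
            params.theta_s[A_RIGHT] @ y_s,
        ]
    )
    sigma_c = params.theta_c @ y_c + params.b
    sigma = sigma_s + sigma_c
    p = softmax_policy(sigma)
    dsr = sigma[A_RIGHT] - sigma[A_WAIT]
    dsl = sigma[A_LEFT] - sigma[A_WAIT]
    ds_s = sigma_s[A_RIGHT] - sigma_s[A_WAIT]
    ds_c = sigma_c[A_WAIT] - sigma_c[A_RIGHT]
    return PolicyOutput(
        sigma_s=sigma_s, sigma_c=sigma_c, sigma=sigma, p=p,
        dsr=float(dsr), dsl=float(dsl), ds_s=float(ds_s), ds_c=float(ds_c),
    )


def softmax_policy(sums: np.ndarray) -> np.ndarray:
    """Overflow-safe softmax over the three action sums."""
    sums = np.asarray(sums, dtype=float)
    if not np.all(np.isfinite(sums)):
        raise FloatingPointError(f"non-finite action sums {sums}")
    z = sums - sums.max()
    e = np.exp(z)
    return e / e.sum()


def act(p: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an action from the probability triple; returns -1 / 0 / +1."""
    row = int(rng.choice(3, p=p))
    return int(ROW_TO_ACTION[row])


def log_policy_grad(
    readout: NoisyReadout, params: AgentParams, action_row: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradient of ``log p(action)`` w.r.t. (theta_s, theta_c, b).

    For the softmax, ``d log p(a) / d Sigma_b = 1{a==b} - p_b``; the chain
    rule through the sums gives the per-parameter gradients (the wait row
    sees ``|y^s|``).
    """
    out = action_sums(readout, params)
    g_sigma = -out.p.copy()
    g_sigma[action_row] += 1.0
    y_s = np.asarray(readout.y_signal, dtype=float)
    y_c = np.asarray(readout.y_clock, dtype=float)
    feats = np.vstack([y_s, np.abs(y_s), y_s])  # per-row signal features
    g_theta_s = g_sigma[:, None] * feats
    g_theta_c = g_sigma[:, None] * y_c[None, :]
    return g_theta_s, g_theta_c, g_sigma


def restrict_to_single_tau(params_template: AgentParams, tau: float) -> AgentParams:
    """A 9-parameter agent (one time constant per bank).

    Comparative model: same architecture but every sum over tau reduces to a
    single term — 6 weights + 3 biases.  Biases are inherited from the
    template; weights start at the template's values at the nearest tau if
    the template has one, else zero.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    taus = np.array([float(tau)])
    if params_template.n_tau == 1:
        i = 0
    else:
        i = int(np.argmin(np.abs(params_template.taus - tau)))
    return AgentParams(
        theta_s=params_template.theta_s[:, [i]].copy()
        if np.isclose(params_template.taus[i], tau)
        else np.zeros((3, 1)),
        theta_c=params_template.theta_c[:, [i]].copy()
        if np.isclose(params_template.taus[i], tau)
        else np.zeros((3, 1)),
        b=params_template.b.copy(),
        taus=taus,
    )


def strip_clock(params: AgentParams) -> AgentParams:
    """Comparative model without temporal information: all clock weights 0.

    Biases are retained, so ``dSigma^c(t)`` collapses to the constant
    ``b_wait - b_right``; the signal pathway is untouched.
    """
    out = params.copy()
    out.theta_c[:] = 0.0
    return out


def delta_sigma_clock(params: AgentParams, t: np.ndarray) -> np.ndarray:
    """Noise-free effective moving threshold ``dSigma^c(t)``.

    ``dSigma^c(t) = sum_tau (theta^c_wait - theta^c_right)(1 - e^(-t/tau))
    + b_wait - b_right``; deterministic because the clock input is constant.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    xc = 1.0 - np.exp(-t[:, None] / params.taus[None, :])
    w = params.theta_c[A_WAIT] - params.theta_c[A_RIGHT]
    return xc @ w + (params.b[A_WAIT] - params.b[A_RIGHT])
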
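"""Operational measures of the decision signatures.

Three behavioural/neural signatures are quantified from evaluation batches:

* **Signal neutrality** — collapse of decision-aligned ``dSigma_right``
  averages across coherences in the final hundreds of ms before the
  decision.  Curves for the six standard coherences are jointly min-max
  rescaled to [0, 1]; at each pre-decision lag the maximum pairwise distance
  among the curves defined there is taken, distances are averaged over lags,
  and the measure is the inverse of that mean.
* **Scalar property** (Weber's law for response times) — constancy of the
  coefficient of variation of response times across difficulty; measured as
  the inverse of the CV range over the six coherences.
* **Collapsing boundaries** — the time-only part of the decision propensity,
  ``dSigma^c(t)``, acts as an effective moving threshold; the strip of
  ``dSigma^s`` values at decision time tracks it.

Degenerate inverses (zero distance / zero CV range) are capped at a
configurable finite value so training traces stay plottable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agent import AgentParams, delta_sigma_clock
from .simulate import EvalBatch, right_aligned_mask

__all__ = [
    "STANDARD_COHERENCES",
    "AlignedCurveSet",
    "BoundaryStrip",
    "build_aligned_curves",
    "signal_neutrality",
    "cv",
    "scalar_property",
    "gamma_fit",
    "performance_curves",
    "boundary_strip",
]

#: The six evaluation coherences (percent) used throughout.
STANDARD_COHERENCES: tuple = (0.0, 3.2, 6.4, 12.8, 25.6, 51.2)

#: Finite stand-in for an infinite inverse measure (perfect collapse).
DEGENERACY_CAP: float = 1e6


@dataclass
class AlignedCurveSet:
    """Mean decision-aligned curves per coherence.

    ``lags`` runs from ``-window`` to 0 (decision instant) in steps of dt;
    each curve is defined on the trailing part of that grid where its
    per-lag sample count stays at or above ``min_count`` (NaN elsewhere).
    """

    lags: np.ndarray  # (L,) seconds, negative to 0
    curves: Dict[float, np.ndarray]  # coherence -> (L,) mean dsr, NaN-padded
    counts: Dict[float, np.ndarray]  # coherence -> (L,) sample counts
    min_count: int

    def defined(self, c: float) -> np.ndarray:
        return ~np.isnan(self.curves[c])


def build_aligned_curves(
    batches: Mapping[float, EvalBatch],
    window: float = 0.6,
    min_count: int = 100,
    warn: bool = True,
) -> AlignedCurveSet:
    """Average ``dSigma_right`` aligned to decision time, per coherence.

    Episodes entering each average are the correct 'right' decisions (the
    'right' choices at 0% coherence, where no correct side exists).  The lag
    axis is decision-relative: lag 0 is the step at which the decision was
    sampled.  A coherence's curve is truncated (from the early end) where
    fewer than ``min_count`` episodes are long enough to contribute; a
    coherence with no qualifying episode at all is omitted with a warning.
    """
    first = next(iter(batches.values()))
    dt = first.dt
    n_lags = int(round(window / dt)) + 1
    lags = -dt * np.arange(n_lags)[::-1]
    curves: Dict[float, np.ndarray] = {}
    counts: Dict[float, np.ndarray] = {}
    for c, batch in batches.items():
        if batch.dsr is None:
            raise ValueError("batch lacks per-step traces; run with record_traces=True")
        mask = right_aligned_mask(batch)
        if not mask.any():
            if warn:
                warnings.warn(
                    f"no qualifying episodes at coherence {c}%; curve omitted"
                )
            continue
        steps = batch.steps[mask]
        dsr = batch.dsr[mask]
        mean = np.full(n_lags, np.nan)
        cnt = np.zeros(n_lags, dtype=int)
        for j in range(n_lags):
            back = n_lags - 1 - j  # steps before decision
            ok = steps > back  # episode long enough to have this lag
            cnt[j] = int(ok.sum())
            if cnt[j] > 0:
                idx = steps[ok] - 1 - back
                mean[j] = float(dsr[ok, idx].mean())
        mean[cnt < min_count] = np.nan
        if np.all(np.isnan(mean)):
            if warn:
                warnings.warn(
                    f"coherence {c}%: fewer than {min_count} episodes at every "
                    "lag; curve omitted"
                )
            continue
        curves[float(c)] = mean
        counts[float(c)] = cnt
    return AlignedCurveSet(lags=lags, curves=curves, counts=counts, min_count=min_count)


def signal_neutrality(
    curve_set: AlignedCurveSet, cap: float = DEGENERACY_CAP
) -> float:
    """Inverse mean maximal pairwise distance of jointly rescaled curves.

    All curves are rescaled together so the global minimum maps to 0 and the
    global maximum to 1; lags where fewer than two curves are defined are
    excluded from the average.  Identical curves give distance 0 and return
    the cap.
    """
    if len(curve_set.curves) < 2:
        raise ValueError("signal neutrality needs at least two curves")
    stack = np.vstack([curve_set.curves[c] for c in sorted(curve_set.curves)])
    lo = np.nanmin(stack)
    hi = np.nanmax(stack)
    span = hi - lo
    if span < 1e-12:
        return cap
    scaled = (stack - lo) / span
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN lag columns
        per_lag = np.nanmax(scaled, axis=0) - np.nanmin(scaled, axis=0)
    n_defined = np.sum(~np.isnan(scaled), axis=0)
    per_lag = per_lag[n_defined >= 2]
    if per_lag.size == 0:
        raise ValueError("no lag has two or more defined curves")
    mean_dist = float(per_lag.mean())
    if mean_dist < 1e-9:
        return cap
    return 1.0 / mean_dist


def cv(rts: np.ndarray) -> float:
    """Coefficient of variation (unbiased std / mean) of response times."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        raise ValueError("CV needs at least two response times")
    m = rts.mean()
    if m <= 0:
        raise ValueError("CV needs a positive mean response time")
    return float(rts.std(ddof=1) / m)


def scalar_property(
    rts_by_coherence: Mapping[float, np.ndarray], cap: float = DEGENERACY_CAP
) -> float:
    """Inverse of the CV range across coherences (higher = more scalar)."""
    cvs = []
    for c, rts in rts_by_coherence.items():
        rts = np.asarray(rts, dtype=float)
        if rts.size >= 2 and rts.mean() > 0:
            cvs.append(cv(rts))
    if len(cvs) < 2:
        raise ValueError("scalar property needs valid CVs at >= 2 coherences")
    rng = max(cvs) - min(cvs)
    if rng < 1e-9:
        return cap
    return 1.0 / rng


def cv_range(batches: Mapping[float, EvalBatch]) -> float:
    """CV range of decided-episode response times across coherences."""
    cvs = []
    for c, b in batches.items():
        rts = b.decision_times[b.decided]
        if rts.size >= 2:
            cvs.append(cv(rts))
    if len(cvs) < 2:
        raise ValueError("need valid CVs at >= 2 coherences")
    return float(max(cvs) - min(cvs))


def gamma_fit(rts: np.ndarray) -> dict:
    """Maximum-likelihood Gamma fit of a response-time sample.

    Location is fixed at 0.  Returns shape ``k``, scale, the fitted mean
    ``k * scale``, the fitted CV ``1/sqrt(k)``, and a callable density
    rescaled to unit mean (time axis divided by the fitted mean), which is
    how distribution-shape invariance is displayed.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 50:
        raise ValueError("gamma fit needs at least 50 response times")
    if np.any(rts <= 0):
        raise ValueError("response times must be positive")
    shape, _, scale = stats.gamma.fit(rts, floc=0)
    mean = shape * scale
    unit_scale = scale / mean

    def unit_mean_pdf(x):
        return stats.gamma.pdf(x, shape, loc=0, scale=unit_scale)

    return {
        "shape": float(shape),
        "scale": float(scale),
        "mean": float(mean),
        "cv": float(1.0 / np.sqrt(shape)),
        "unit_mean_pdf": unit_mean_pdf,
    }


def performance_curves(batches: Mapping[float, EvalBatch]) -> pd.DataFrame:
    """Accuracy and mean response time per coherence, with standard errors.

    Accuracy is NaN at 0% coherence (no correct side); response times are
    over decided episodes.
    """
    rows = []
    for c in sorted(batches):
        b = batches[c]
        rts = b.decision_times[b.decided]
        if c == 0.0 or np.all(b.mus == 0.0):
            acc, acc_se = np.nan, np.nan
        else:
            acc = b.accuracy()
            acc_se = float(np.sqrt(acc * (1 - acc) / b.n))
        rows.append(
            {
                "coherence": c,
                "n": b.n,
                "n_decided": int(b.decided.sum()),
                "accuracy": acc,
                "accuracy_se": acc_se,
                "mean_rt": float(rts.mean()) if rts.size else np.nan,
                "rt_se": float(rts.std(ddof=1) / np.sqrt(rts.size))
                if rts.size > 1
                else np.nan,
                "cv_rt": cv(rts) if rts.size > 1 else np.nan,
                "timeout_fraction": b.timeout_fraction,
            }
        )
    return pd.DataFrame(rows).set_index("coherence")


@dataclass
class BoundaryStrip:
    """Envelope of decision-time ``dSigma^s`` values vs the clock threshold.

    ``lo``/``hi`` bound the central 80% (10th-90th percentile) of
    ``dSigma^s`` at decision among correct 'right' decisions, per time bin;
    bins with fewer than ``min_decisions`` decisions are NaN.  ``ds_c`` is
    the deterministic moving threshold on the same grid.
    """

    t: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    mid: np.ndarray
    counts: np.ndarray
    ds_c: np.ndarray
    min_decisions: int


def boundary_strip(
    batches: Mapping[float, EvalBatch] | EvalBatch,
    params: AgentParams,
    quantile: float = 0.80,
    bin_width: Optional[float] = None,
    min_decisions: int = 20,
) -> BoundaryStrip:
    """Extract the effective decision boundary from episode traces.

    Pools correct 'right' decisions over the given batches; per time bin the
    central-``quantile`` interval of ``dSigma^s`` at the decision step is
    computed, paired with the noise-free ``dSigma^c(t)`` curve.
    """
    if isinstance(batches, EvalBatch):
        batches = {-1.0: batches}
    first = next(iter(batches.values()))
    dt = first.dt
    if bin_width is None:
        bin_width = dt
    steps_per_bin = max(1, int(round(bin_width / dt)))
    n_bins = int(np.ceil(first.n_steps_max / steps_per_bin))

    vals: list[np.ndarray] = [np.empty(0)] * 0
    all_vals = []
    all_bins = []
    for b in batches.values():
        if b.dss is None:
            raise ValueError("batch lacks per-step traces; run with record_traces=True")
        mask = right_aligned_mask(b)
        steps = b.steps[mask]
        ds_at_dec = b.dss[mask, steps - 1]
        all_vals.append(ds_at_dec)
        all_bins.append((steps - 1) // steps_per_bin)
    v = np.concatenate(all_vals) if all_vals else np.empty(0)
    k = np.concatenate(all_bins) if all_bins else np.empty(0, dtype=int)

    q_lo = (1.0 - quantile) / 2.0
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for j in range(n_bins):
        sel = v[k == j]
        counts[j] = sel.size
        if sel.size >= min_decisions:
            lo[j] = np.quantile(sel, q_lo)
            hi[j] = np.quantile(sel, 1.0 - q_lo)
    t = (np.arange(n_bins) * steps_per_bin + (steps_per_bin + 1) / 2.0) * dt
    ds_c = delta_sigma_clock(params, t)
    return BoundaryStrip(
        t=t,
        lo=lo,
        hi=hi,
        mid=0.5 * (lo + hi),
        counts=counts,
        ds_c=ds_c,
        min_decisions=min_decisions,
    )
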
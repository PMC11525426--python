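"""Moment estimates, convergence series, and evidence diagnostics."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .exceptions import EmptySampleError, ParameterError
from .samples import BFSampleSet

__all__ = [
    "MomentReport",
    "cumulative_mean",
    "raw_moment",
    "second_moment_from_mean_var",
    "universal_bound_table",
    "weight_of_evidence_summary",
]


def _values(sample) -> np.ndarray:
    vals = sample.values if isinstance(sample, BFSampleSet) else np.asarray(sample, dtype=float)
    if vals.size == 0:
        raise EmptySampleError("empty Bayes factor sample")
    return vals


def cumulative_mean(values) -> np.ndarray:
    """Running mean; element t is the mean of the first t values."""
    vals = _values(values)
    return np.cumsum(vals) / np.arange(1, vals.size + 1)


@dataclass(frozen=True)
class MomentReport:
    """A raw-moment estimate with its Monte-Carlo standard error."""

    order: int
    estimate: float
    mc_se: float
    m_used: int

    def to_dict(self) -> dict:
        return {"order": self.order, "estimate": self.estimate, "mc_se": self.mc_se, "m_used": self.m_used}


def raw_moment(values, order: int) -> MomentReport:
    """Estimate E[BF^order] (moment about the origin) from a sample."""
    if order < 1:
        raise ParameterError(f"moment order must be >= 1, got {order}")
    vals = _values(values)
    powered = vals**order
    m = vals.size
    se = float(powered.std(ddof=1) / math.sqrt(m)) if m > 1 else float("nan")
    return MomentReport(order=order, estimate=float(powered.mean()), mc_se=se, m_used=m)


def second_moment_from_mean_var(mean: float, variance: float) -> float:
    """E[BF^2] = VAR[BF] + E[BF]^2."""
    if variance < 0:
        raise ParameterError(f"variance must be nonnegative, got {variance}")
    return variance + mean**2


def universal_bound_table(sample, alphas) -> list[dict]:
    """Empirical check of P(BF_false >= 1/alpha) <= alpha.

    For a sample of Bayes factors favoring the false hypothesis, Turing's
    identity plus Markov's inequality bound the chance of misleading
    evidence of strength 1/alpha by alpha (e.g. a Bayes factor of 100 in
    favor of the false hypothesis occurs with probability at most 1%).
    Violations within binomial sampling fluctuation are reported, not
    raised.
    """
    vals = _values(sample)
    rows = []
    for alpha in alphas:
        if not (0.0 < alpha <= 1.0):
            raise ParameterError(f"alpha must lie in (0, 1], got {alpha}")
        frac = float(np.mean(vals >= 1.0 / alpha))
        rows.append(
            {
                "alpha": float(alpha),
                "threshold": 1.0 / alpha,
                "empirical_fraction": frac,
                "bound_satisfied": bool(frac <= alpha),
            }
        )
    return rows


def weight_of_evidence_summary(sample) -> dict:
    """Mean and spread of the log Bayes factor, plus raw-value skewness.

    The log Bayes factor (the weight of evidence) is additive and symmetric
    — log(10) and log(1/10) average to zero — and is expected to be roughly
    normal where the Bayes factor itself is roughly log-normal, so the raw
    skewness doubles as a heavy-tail diagnostic.
    """
    vals = _values(sample)
    logs = np.log(vals)
    if vals.size > 1 and np.ptp(vals) > 0:
        skew = float(_stats.skew(vals))
    else:
        skew = 0.0  # constant sample: no tail to speak of
    return {
        "mean_log_bf": float(logs.mean()),
        "sd_log_bf": float(logs.std(ddof=1)) if vals.size > 1 else 0.0,
        "skewness_bf": skew,
    }
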
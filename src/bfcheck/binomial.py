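"""Binomial hypothesis tests with point, beta, and truncated-beta priors.

Every quantity here is available in closed form: marginal likelihoods are
(truncated) beta-binomial probabilities, Bayes factors are ratios of those,
and raw moments of the Bayes factor under either hypothesis can be obtained
by exact enumeration over the n+1 possible success counts.  The enumeration
is the oracle against which the simulation-based check engine is verified.

Two moment identities drive the package.  With ``H_t`` the true and ``H_f``
the false hypothesis of a pair sharing the same support,

* Turing: ``E[BF_ft | H_t] = 1`` — the expected Bayes factor in favor of the
  false hypothesis equals one, and
* Good:   ``E[BF_12^k | H_1] = E[BF_12^{k+1} | H_2]`` for raw moments of any
  order, of which Turing's identity is the ``k = 0`` special case.

Both are finite sums here, so they hold to machine precision and expose any
error in a marginal-likelihood formula immediately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, betaln, gammaln, logsumexp, xlog1py, xlogy
from scipy.stats import beta as _beta_dist

from .exceptions import (
    CapabilityError,
    ImpossibleOutcomeError,
    ParameterError,
    SupportWarning,
    UndefinedBayesFactorError,
)

#: Hard cap on the trial count for exact moment enumeration.  Everything is
#: computed in log space, so the limit is about enumeration cost, not
#: overflow; it comfortably covers every setting used in practice.
ENUMERATION_CAP = 10_000

__all__ = [
    "ENUMERATION_CAP",
    "BinomialPointHypothesis",
    "BinomialBetaHypothesis",
    "BinomialOutcome",
    "SupportReport",
    "binom_marginal",
    "binom_bf",
    "simulate_binomial",
    "exact_bf_moment",
    "support_overlap_check",
    "log_marginal_table",
]


def _beta_interval_mass(a, b, lower: float, upper: float) -> np.ndarray:
    """Beta(a, b) probability of [lower, upper], differencing whichever tail
    of the regularized incomplete beta is small (I_x(a,b) = 1 - I_{1-x}(b,a))
    to avoid catastrophic cancellation for intervals deep in a tail."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    left = betainc(a, b, lower) if lower > 0.0 else np.zeros(np.broadcast(a, b).shape)
    direct = betainc(a, b, upper) - left
    flipped = betainc(b, a, 1.0 - lower) - betainc(b, a, 1.0 - upper)
    return np.where(left > 0.5, flipped, direct)


@dataclass(frozen=True)
class BinomialOutcome:
    """An observed binomial experiment: ``k`` successes in ``n`` trials."""

    n: int
    k: int

    def __post_init__(self) -> None:
        if self.n < 0 or not (0 <= self.k <= self.n):
            raise ParameterError(
                f"invalid outcome: need 0 <= k <= n, got n={self.n}, k={self.k}"
            )


@dataclass(frozen=True)
class BinomialPointHypothesis:
    """A simple hypothesis fixing the success probability at ``theta0``."""

    label: str
    theta0: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta0 <= 1.0):
            raise ParameterError(f"theta0 must lie in [0, 1], got {self.theta0}")

    def log_pmf(self, n: int, k) -> np.ndarray:
        """Log marginal probability of ``k`` successes in ``n`` trials.

        Uses the ``0**0 = 1`` convention so that degenerate point
        hypotheses at theta0 in {0, 1} are well defined.
        """
        k = np.asarray(k, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (
                gammaln(n + 1)
                - gammaln(k + 1)
                - gammaln(n - k + 1)
                + xlogy(k, self.theta0)
                + xlog1py(n - k, -self.theta0)
            )
        return out

    def sample_theta(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.theta0)


@dataclass(frozen=True)
class BinomialBetaHypothesis:
    """A composite hypothesis with a (possibly truncated) Beta(a, b) prior.

    ``lower``/``upper`` restrict the prior to an interval, which is how
    directional hypotheses such as ``theta > 1/2`` (a Uniform(0.5, 1) prior)
    are expressed.  The defaults ``lower=0, upper=1`` give the untruncated
    beta prior.
    """

    label: str
    a: float
    b: float
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ParameterError(f"beta shapes must be positive, got a={self.a}, b={self.b}")
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ParameterError(
                f"need 0 <= lower < upper <= 1, got [{self.lower}, {self.upper}]"
            )
        if self._prior_mass() <= 0.0:
            raise ParameterError("truncation interval carries zero prior mass")

    def _prior_mass(self) -> float:
        return float(_beta_interval_mass(self.a, self.b, self.lower, self.upper))

    @property
    def truncated(self) -> bool:
        return self.lower > 0.0 or self.upper < 1.0

    def log_pmf(self, n: int, k) -> np.ndarray:
        """Log (truncated) beta-binomial marginal probability of ``k``."""
        k = np.asarray(k, dtype=float)
        out = (
            gammaln(n + 1)
            - gammaln(k + 1)
            - gammaln(n - k + 1)
            + betaln(k + self.a, n - k + self.b)
            - betaln(self.a, self.b)
        )
        if self.truncated:
            post_mass = _beta_interval_mass(k + self.a, n - k + self.b, self.lower, self.upper)
            with np.errstate(divide="ignore"):
                out = out + np.log(post_mass) - np.log(self._prior_mass())
        return out

    def sample_theta(self, rng: np.random.Generator, size: int) -> np.ndarray:
        # Inverse-CDF sampling restricted to [lower, upper]: exact and
        # rejection-free even for narrow truncation intervals.
        c_lo = _beta_dist.cdf(self.lower, self.a, self.b)
        c_hi = _beta_dist.cdf(self.upper, self.a, self.b)
        u = rng.uniform(c_lo, c_hi, size)
        return _beta_dist.ppf(u, self.a, self.b)


BinomialHypothesis = BinomialPointHypothesis | BinomialBetaHypothesis


def log_marginal_table(hyp: BinomialHypothesis, n: int) -> np.ndarray:
    """Log marginal probabilities of every outcome ``k = 0..n`` under ``hyp``."""
    if n < 0:
        raise ParameterError(f"trial count must be nonnegative, got {n}")
    return np.atleast_1d(hyp.log_pmf(n, np.arange(n + 1)))


def binom_marginal(hyp: BinomialHypothesis, outcome: BinomialOutcome) -> float:
    """Marginal likelihood p(k | hyp) for a single observed outcome."""
    return float(np.exp(hyp.log_pmf(outcome.n, outcome.k)))


def binom_bf(
    numerator_hyp: BinomialHypothesis,
    denominator_hyp: BinomialHypothesis,
    outcome: BinomialOutcome,
) -> float:
    """Bayes factor ``p(k | numerator) / p(k | denominator)``.

    Raises :class:`UndefinedBayesFactorError` when only the denominator
    marginal is zero, and :class:`ImpossibleOutcomeError` when both are.
    """
    ln = float(numerator_hyp.log_pmf(outcome.n, outcome.k))
    ld = float(denominator_hyp.log_pmf(outcome.n, outcome.k))
    if np.isneginf(ld):
        if np.isneginf(ln):
            raise ImpossibleOutcomeError(
                f"outcome k={outcome.k} has zero probability under both hypotheses"
            )
        raise UndefinedBayesFactorError(
            f"denominator marginal is zero at k={outcome.k} while the numerator is positive"
        )
    return float(np.exp(ln - ld))


def simulate_binomial(
    hyp: BinomialHypothesis, n: int, m: int, seed: int
) -> np.ndarray:
    """Prior-predictive draws: m success counts from ``hyp`` at trial count n.

    For each replicate theta is drawn from the hypothesis prior (a point
    hypothesis contributes its fixed theta0), then ``k ~ Binomial(n, theta)``.
    Deterministic given ``seed``.
    """
    if m < 1:
        raise ParameterError(f"replicate count must be >= 1, got {m}")
    if n < 0:
        raise ParameterError(f"trial count must be nonnegative, got {n}")
    rng = np.random.default_rng(seed)
    theta = hyp.sample_theta(rng, m)
    return rng.binomial(n, theta)


def exact_bf_moment(
    numerator_hyp: BinomialHypothesis,
    denominator_hyp: BinomialHypothesis,
    true_hyp: BinomialHypothesis,
    n: int,
    order: int,
) -> float:
    """Exact raw moment of the Bayes factor by enumeration over ``k = 0..n``.

    Returns ``sum_k [p(k|num)/p(k|den)]^order * p(k|true)``.  Outcomes with
    zero probability under the true hypothesis contribute nothing; when such
    an outcome has positive probability under the rival hypothesis a
    :class:`SupportWarning` is emitted, because the moment identities are
    then not guaranteed (the "universal generalization" exception).
    """
    if order < 0:
        raise ParameterError(f"moment order must be nonnegative, got {order}")
    if n > ENUMERATION_CAP:
        raise CapabilityError(
            f"exact enumeration capped at n={ENUMERATION_CAP}, got n={n}"
        )
    if true_hyp not in (numerator_hyp, denominator_hyp):
        raise ParameterError("true_hyp must be one of the two compared hypotheses")

    l_num = log_marginal_table(numerator_hyp, n)
    l_den = log_marginal_table(denominator_hyp, n)
    l_true = l_num if true_hyp == numerator_hyp else l_den
    l_rival = l_den if true_hyp == numerator_hyp else l_num

    mass = ~np.isneginf(l_true)
    skipped_with_rival_mass = (~mass) & ~np.isneginf(l_rival)
    if np.any(skipped_with_rival_mass):
        ks = np.flatnonzero(skipped_with_rival_mass).tolist()
        warnings.warn(
            f"outcomes k={ks} have zero probability under the true hypothesis "
            "but positive probability under its rival; the moment identities "
            "do not apply to this pair",
            SupportWarning,
            stacklevel=2,
        )
    terms = order * (l_num[mass] - l_den[mass]) + l_true[mass]
    return float(np.exp(logsumexp(terms)))


@dataclass(frozen=True)
class SupportReport:
    """Outcome-level support comparison between two hypotheses."""

    n: int
    label_a: str
    label_b: str
    zero_in_a_positive_in_b: tuple[int, ...]
    zero_in_b_positive_in_a: tuple[int, ...]

    @property
    def passed(self) -> bool:
        return not self.zero_in_a_positive_in_b and not self.zero_in_b_positive_in_a


def support_overlap_check(
    hyp_a: BinomialHypothesis, hyp_b: BinomialHypothesis, n: int
) -> SupportReport:
    """List the outcomes where one hypothesis assigns zero probability while
    the other assigns positive probability.

    The moment identities require both hypotheses to spread mass over the
    same sample space; the check engine refuses Turing-identity guarantees
    when this report fails.
    """
    la = log_marginal_table(hyp_a, n)
    lb = log_marginal_table(hyp_b, n)
    a_zero = np.isneginf(la)
    b_zero = np.isneginf(lb)
    return SupportReport(
        n=n,
        label_a=hyp_a.label,
        label_b=hyp_b.label,
        zero_in_a_positive_in_b=tuple(np.flatnonzero(a_zero & ~b_zero).tolist()),
        zero_in_b_positive_in_a=tuple(np.flatnonzero(b_zero & ~a_zero).tolist()),
    )
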
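"""The six-step Turing-Good validation workflow.

Given a pair of rival models — each able to simulate prior-predictive
datasets and to score any dataset with a Bayes factor — the engine:

1. optionally computes the observed-data Bayes factor,
2. simulates m datasets under the *general* (more complex) model and
   averages the Bayes factor in favor of the *specific* model, which by
   Turing's identity must be close to 1,
3. optionally simulates m datasets under the specific model and compares
   the mean Bayes factor there with the second raw moment from step 2
   (Good's identity),
4. attaches cumulative-mean series, a universal-bound table and a
   weight-of-evidence summary.

Generating under the general model is the recommended direction: under a
point (specific) hypothesis, rare outcomes carry extreme Bayes factors in
favor of the false general model, and the running mean can take an
impractically long time to settle at 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np

from .diagnostics import (
    MomentReport,
    cumulative_mean,
    raw_moment,
    universal_bound_table,
    weight_of_evidence_summary,
)
from .exceptions import (
    BayesFactorFailureError,
    ContractError,
    EmptySampleError,
    ParameterError,
    SupportViolationError,
    UndefinedBayesFactorError,
)
from .samples import UNDEFINED, BFSampleSet, recode_undefined

__all__ = [
    "ModelPair",
    "Theorem1Report",
    "Theorem2Report",
    "CheckReport",
    "run_bf_batch",
    "theorem1_check",
    "theorem2_check",
    "run_full_check",
    "split_seed",
]

#: Value skewness above which the Monte-Carlo standard error itself is
#: considered unstable and a heavy-tail caution is attached to verdicts.
HEAVY_TAIL_SKEWNESS = 10.0


def split_seed(seed: int, n: int) -> list[int]:
    """Deterministically derive n independent sub-seeds (< 2**31) from one
    master seed, so that separate simulation batches are independent yet
    reproducible."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass
class ModelPair:
    """Two rival models wired up for the check engine.

    ``bf_specific_over_general`` maps one dataset to a positive Bayes factor
    favoring the specific model; it may raise
    :class:`UndefinedBayesFactorError` or :class:`BayesFactorFailureError`.
    ``sampler_specific`` / ``sampler_general`` map ``(m, seed)`` to m
    datasets of the shape the Bayes factor procedure accepts.  An optional
    vectorized ``bf_batch`` hook (datasets -> array; NaN = failed,
    inf or nonpositive = undefined) accelerates large batches.
    """

    specific_label: str
    general_label: str
    bf_specific_over_general: Callable[[Any], float]
    sampler_specific: Callable[[int, int], Sequence]
    sampler_general: Callable[[int, int], Sequence]
    support_ok: Optional[bool] = None
    bf_batch: Optional[Callable[[Sequence], np.ndarray]] = None

    def labels(self) -> tuple[str, str]:
        return (self.specific_label, self.general_label)

    def sampler(self, label: str) -> Callable[[int, int], Sequence]:
        if label == self.specific_label:
            return self.sampler_specific
        if label == self.general_label:
            return self.sampler_general
        raise ParameterError(f"unknown model label {label!r}; expected one of {self.labels()}")


def run_bf_batch(
    pair: ModelPair,
    generate_under: str,
    favor: str,
    m: int,
    seed: int,
    recode_policy: str = "recode_max_plus_one",
) -> BFSampleSet:
    """Simulate m datasets, score each with the pair's Bayes factor oriented
    to favor ``favor``, apply the recode policy, and return the sample set.

    Reversing ``favor`` inverts every value exactly.  Failed evaluations are
    excluded and counted; undefined (1/0) values go through the recode
    policy.  Deterministic given ``seed``.
    """
    if m < 2:
        raise ParameterError(f"need m >= 2 replicates, got {m}")
    if favor not in pair.labels():
        raise ParameterError(f"unknown favor label {favor!r}; expected one of {pair.labels()}")
    datasets = pair.sampler(generate_under)(m, seed)
    flip = favor == pair.general_label

    raw: list = []  # float | UNDEFINED, failures excluded
    records: list[dict] = []
    failed = 0
    if pair.bf_batch is not None:
        vals = np.asarray(pair.bf_batch(datasets), dtype=float)
        if vals.shape != (m,):
            raise ContractError("bf_batch must return one value per dataset")
        with np.errstate(divide="ignore"):
            oriented = np.where(np.isnan(vals), np.nan, 1.0 / vals if flip else vals)
        for i, v in enumerate(oriented):
            if np.isnan(v):
                failed += 1
                records.append({"replicate": i, "bf": float("nan"), "was_undefined": False, "was_failed": True})
            elif not np.isfinite(v) or v <= 0.0:
                raw.append(UNDEFINED)
                records.append({"replicate": i, "bf": float("nan"), "was_undefined": True, "was_failed": False})
            else:
                raw.append(float(v))
                records.append({"replicate": i, "bf": float(v), "was_undefined": False, "was_failed": False})
    else:
        for i, ds in enumerate(datasets):
            try:
                v = float(pair.bf_specific_over_general(ds))
                if flip:
                    if v == 0.0:
                        raise UndefinedBayesFactorError("reciprocal of a zero Bayes factor")
                    v = 1.0 / v
                if not (np.isfinite(v) and v > 0.0):
                    raise UndefinedBayesFactorError(f"non-finite or nonpositive Bayes factor {v}")
                raw.append(v)
                records.append({"replicate": i, "bf": v, "was_undefined": False, "was_failed": False})
            except UndefinedBayesFactorError:
                raw.append(UNDEFINED)
                records.append({"replicate": i, "bf": float("nan"), "was_undefined": True, "was_failed": False})
            except BayesFactorFailureError:
                failed += 1
                records.append({"replicate": i, "bf": float("nan"), "was_undefined": False, "was_failed": True})
            except Exception as exc:
                raise ContractError(f"Bayes factor procedure broke its contract at replicate {i}: {exc}") from exc

    n_undef = sum(1 for v in raw if v is UNDEFINED)
    if raw and n_undef == len(raw):
        raise EmptySampleError("every replicate produced an undefined Bayes factor")
    values = recode_undefined(raw, recode_policy)
    if values.size == 0:
        raise EmptySampleError("no usable Bayes factor values were produced")
    # write recoded values back into the per-replicate records
    if recode_policy == "recode_max_plus_one" and n_undef:
        fill = float(values.max())
        for rec in records:
            if rec["was_undefined"]:
                rec["bf"] = fill
    return BFSampleSet(
        values=values,
        undefined_count=n_undef,
        failed_count=failed,
        direction=favor,
        generated_under=generate_under,
        seed=seed,
        recode_policy=recode_policy,
        records=records,
    )


@dataclass(frozen=True)
class Theorem1Report:
    """Verdict on Turing's identity: is the mean Bayes factor in favor of
    the false (non-generating) hypothesis compatible with 1?"""

    mean: float
    mc_se: float
    m_used: int
    tolerance_multiplier: float
    verdict: bool
    heavy_tail_caution: bool
    skewness: float

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "mc_se": self.mc_se,
            "m_used": self.m_used,
            "tolerance_multiplier": self.tolerance_multiplier,
            "verdict": "pass" if self.verdict else "fail",
            "heavy_tail_caution": self.heavy_tail_caution,
            "skewness": self.skewness,
        }


def theorem1_check(
    sample: BFSampleSet,
    tolerance_multiplier: float = 3.0,
    support_ok: Optional[bool] = None,
    allow_support_violation: bool = False,
) -> Theorem1Report:
    """Check ``|mean - 1| <= tolerance_multiplier * mc_se`` on a sample of
    Bayes factors favoring the hypothesis the data were *not* generated
    under.

    A heavy-tail caution is attached when the value skewness exceeds
    ``HEAVY_TAIL_SKEWNESS``: the standard error estimate is then itself
    unstable and a pass/fail verdict should be read with care.
    """
    if sample.direction == sample.generated_under:
        raise ContractError(
            "Turing's identity applies to the Bayes factor favoring the "
            f"non-generating hypothesis, but this sample favors {sample.direction!r} "
            f"and was generated under it"
        )
    if support_ok is False and not allow_support_violation:
        raise SupportViolationError(
            "the hypotheses do not share a common support; the expected Bayes "
            "factor in favor of the false hypothesis need not be 1"
        )
    mom = raw_moment(sample, 1)
    woe = weight_of_evidence_summary(sample)
    skew = woe["skewness_bf"]
    verdict = abs(mom.estimate - 1.0) <= tolerance_multiplier * mom.mc_se
    return Theorem1Report(
        mean=mom.estimate,
        mc_se=mom.mc_se,
        m_used=mom.m_used,
        tolerance_multiplier=tolerance_multiplier,
        verdict=bool(verdict),
        heavy_tail_caution=bool(skew > HEAVY_TAIL_SKEWNESS),
        skewness=skew,
    )


@dataclass(frozen=True)
class Theorem2Report:
    """Verdict on Good's identity at adjacent orders: the order-k raw moment
    under the specific-true condition against the order-(k+1) raw moment
    under the general-true condition."""

    order_low: int
    moment_specific_true: MomentReport
    moment_general_true: MomentReport
    relative_difference: float
    combined_mc_se: float
    tolerance_multiplier: float
    verdict: bool

    def to_dict(self) -> dict:
        return {
            "order_low": self.order_low,
            "moment_specific_true": self.moment_specific_true.to_dict(),
            "moment_general_true": self.moment_general_true.to_dict(),
            "relative_difference": self.relative_difference,
            "combined_mc_se": self.combined_mc_se,
            "tolerance_multiplier": self.tolerance_multiplier,
            "verdict": "pass" if self.verdict else "fail",
        }


def theorem2_check(
    sample_specific_true: BFSampleSet,
    sample_general_true: BFSampleSet,
    order_low: int = 1,
    tolerance_multiplier: float = 3.0,
) -> Theorem2Report:
    """Compare E[BF^k | specific true] with E[BF^{k+1} | general true].

    Both samples must favor the specific hypothesis and come from different
    generating hypotheses.  The verdict passes when the two estimates agree
    within ``tolerance_multiplier`` root-sum-square Monte-Carlo standard
    errors.
    """
    if sample_specific_true.direction != sample_general_true.direction:
        raise ContractError("both samples must favor the same (specific) hypothesis")
    if sample_specific_true.generated_under == sample_general_true.generated_under:
        raise ContractError("the two samples must be generated under different hypotheses")
    if sample_specific_true.generated_under != sample_specific_true.direction:
        raise ContractError(
            "sample_specific_true must be generated under the hypothesis it favors"
        )
    if order_low < 1:
        raise ParameterError(f"order_low must be >= 1, got {order_low}")
    lo = raw_moment(sample_specific_true, order_low)
    hi = raw_moment(sample_general_true, order_low + 1)
    diff = abs(lo.estimate - hi.estimate)
    combined = math.hypot(lo.mc_se, hi.mc_se)
    center = 0.5 * (lo.estimate + hi.estimate)
    return Theorem2Report(
        order_low=order_low,
        moment_specific_true=lo,
        moment_general_true=hi,
        relative_difference=float(diff / center) if center else 0.0,
        combined_mc_se=combined,
        tolerance_multiplier=tolerance_multiplier,
        verdict=bool(diff <= tolerance_multiplier * combined),
    )


@dataclass
class CheckReport:
    """Full six-step workflow output."""

    specific_label: str
    general_label: str
    m: int
    seed: int
    observed_bf: Optional[float]
    theorem1: Theorem1Report
    theorem2: Optional[Theorem2Report]
    cumulative_means: np.ndarray
    universal_bound: list[dict]
    woe: dict
    sample_general_true: BFSampleSet = field(repr=False)
    sample_specific_true: Optional[BFSampleSet] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        def _counts(s: Optional[BFSampleSet]) -> Optional[dict]:
            if s is None:
                return None
            return {
                "generated_under": s.generated_under,
                "direction": s.direction,
                "m_used": s.m_used,
                "undefined_count": s.undefined_count,
                "failed_count": s.failed_count,
                "seed": s.seed,
                "recode_policy": s.recode_policy,
            }

        return {
            "specific_label": self.specific_label,
            "general_label": self.general_label,
            "m": self.m,
            "seed": self.seed,
            "observed_bf": self.observed_bf,
            "theorem1": self.theorem1.to_dict(),
            "theorem2": self.theorem2.to_dict() if self.theorem2 else None,
            "universal_bound": self.universal_bound,
            "woe": self.woe,
            "batches": {
                "general_true": _counts(self.sample_general_true),
                "specific_true": _counts(self.sample_specific_true),
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def run_full_check(
    pair: ModelPair,
    observed_data=None,
    m: int = 10_000,
    seed: Optional[int] = None,
    recode_policy: str = "recode_max_plus_one",
    tolerance_multiplier: float = 3.0,
    run_theorem2: bool = True,
    alphas: Sequence[float] = (0.2, 0.1, 0.05, 0.01),
    allow_support_violation: bool = False,
) -> CheckReport:
    """Run the full validation workflow on a model pair.

    Data are generated under the general model and the Bayes factor is
    oriented in favor of the specific model (the robust direction for
    Turing's identity); the optional reverse batch feeds Good's identity at
    orders 1 vs 2.  Refuses pairs with a known support violation unless
    explicitly overridden.  Byte-identical reports under a fixed seed.
    """
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    if pair.support_ok is False and not allow_support_violation:
        raise SupportViolationError(
            f"the pair ({pair.specific_label!r} vs {pair.general_label!r}) does not "
            "share a common sample-space support: outcomes that are plausible under "
            "one hypothesis carry zero probability under the other, so the expected "
            "Bayes factor in favor of the false hypothesis is not 1.  Pass "
            "allow_support_violation=True to proceed without the Turing guarantee."
        )
    seeds = split_seed(seed, 2)
    observed_bf = None
    if observed_data is not None:
        observed_bf = float(pair.bf_specific_over_general(observed_data))

    sample_general = run_bf_batch(
        pair, generate_under=pair.general_label, favor=pair.specific_label,
        m=m, seed=seeds[0], recode_policy=recode_policy,
    )
    t1 = theorem1_check(
        sample_general,
        tolerance_multiplier=tolerance_multiplier,
        support_ok=pair.support_ok,
        allow_support_violation=allow_support_violation,
    )
    sample_specific = None
    t2 = None
    if run_theorem2:
        sample_specific = run_bf_batch(
            pair, generate_under=pair.specific_label, favor=pair.specific_label,
            m=m, seed=seeds[1], recode_policy=recode_policy,
        )
        t2 = theorem2_check(
            sample_specific, sample_general, order_low=1,
            tolerance_multiplier=tolerance_multiplier,
        )
    return CheckReport(
        specific_label=pair.specific_label,
        general_label=pair.general_label,
        m=m,
        seed=seed,
        observed_bf=observed_bf,
        theorem1=t1,
        theorem2=t2,
        cumulative_means=cumulative_mean(sample_general.values),
        universal_bound=universal_bound_table(sample_general, alphas),
        woe=weight_of_evidence_summary(sample_general),
        sample_general_true=sample_general,
        sample_specific_true=sample_specific,
    )
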
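"""Tests for the check engine: batch orientation and bookkeeping, undefined
recoding, moment estimates, theorem verdicts, diagnostics, and the full
six-step workflow."""

import math

import numpy as np
import pytest

from bfcheck import (
    UNDEFINED,
    BinomialBetaHypothesis,
    BinomialPointHypothesis,
    binomial_pair,
    cumulative_mean,
    exact_bf_moment,
    raw_moment,
    recode_undefined,
    run_bf_batch,
    run_full_check,
    second_moment_from_mean_var,
    theorem1_check,
    theorem2_check,
    universal_bound_table,
    weight_of_evidence_summary,
)
from bfcheck.engine import split_seed
from bfcheck.exceptions import (
    ContractError,
    EmptySampleError,
    ParameterError,
    SupportViolationError,
)
from bfcheck.samples import BFSampleSet


def _sample(values, direction="H0", generated_under="H1", **kw):
    return BFSampleSet(
        values=np.asarray(values, dtype=float),
        undefined_count=kw.pop("undefined_count", 0),
        failed_count=kw.pop("failed_count", 0),
        direction=direction,
        generated_under=generated_under,
        seed=0,
        **kw,
    )


class TestRecode:
    def test_max_plus_one_rule(self):
        out = recode_undefined([2.0, UNDEFINED, 5.0])
        np.testing.assert_allclose(out, [2.0, 6.0, 5.0])

    def test_no_undefined_passthrough(self):
        np.testing.assert_allclose(recode_undefined([2.0, 5.0]), [2.0, 5.0])

    def test_drop_policy_and_empty_error(self):
        assert recode_undefined([UNDEFINED, None], policy="drop").size == 0
        with pytest.raises(EmptySampleError):
            recode_undefined([UNDEFINED, UNDEFINED])
        with pytest.raises(EmptySampleError):
            recode_undefined([1.0, UNDEFINED], policy="fail")
        with pytest.raises(ParameterError):
            recode_undefined([1.0], policy="nope")


class TestMoments:
    def test_cumulative_mean(self):
        np.testing.assert_allclose(cumulative_mean([1.0, 3.0]), [1.0, 2.0])
        np.testing.assert_allclose(cumulative_mean(np.full(10, 2.5)), np.full(10, 2.5))
        with pytest.raises(EmptySampleError):
            cumulative_mean([])

    def test_cumulative_mean_final_element_is_the_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.exponential(size=1000)
        assert cumulative_mean(vals)[-1] == pytest.approx(raw_moment(vals, 1).estimate)

    def test_raw_moment_values(self):
        assert raw_moment([1.0, 2.0, 3.0], 1).estimate == pytest.approx(2.0)
        assert raw_moment([1.0, 2.0, 3.0], 2).estimate == pytest.approx(14 / 3)
        # asymmetry of the Bayes factor scale: mean of 1/10 and 10 is 5.05
        assert raw_moment([0.1, 10.0], 1).estimate == pytest.approx(5.05)
        with pytest.raises(ParameterError):
            raw_moment([1.0], 0)

    def test_second_moment_identity(self):
        assert second_moment_from_mean_var(5.05, 24.5025) == pytest.approx(50.005)
        assert second_moment_from_mean_var(0.0, 0.0) == 0.0
        with pytest.raises(ParameterError):
            second_moment_from_mean_var(1.0, -0.1)
        rng = np.random.default_rng(2)
        vals = rng.lognormal(size=500)
        assert second_moment_from_mean_var(vals.mean(), vals.var()) == pytest.approx(
            (vals**2).mean()
        )


class TestDiagnostics:
    def test_universal_bound_rows(self):
        rows = universal_bound_table(_sample([0.5, 0.9, 1.0]), [0.5, 0.1, 1.0])
        assert [r["empirical_fraction"] for r in rows] == [0.0, 0.0, pytest.approx(1 / 3)]
        assert all(r["bound_satisfied"] for r in rows)
        with pytest.raises(ParameterError):
            universal_bound_table(_sample([1.0, 1.0]), [0.0])

    def test_weight_of_evidence(self):
        woe = weight_of_evidence_summary(_sample([0.1, 10.0]))
        assert woe["mean_log_bf"] == pytest.approx(0.0, abs=1e-12)
        assert weight_of_evidence_summary(_sample([10.0]))["mean_log_bf"] == pytest.approx(
            math.log(10.0)
        )

    def test_expected_weight_of_evidence_favoring_truth_nonnegative(self):
        """Generated under H1 and favoring H1, the mean log Bayes factor is
        nonnegative up to Monte-Carlo error."""
        pair = binomial_pair(n=100)
        s = run_bf_batch(pair, generate_under="H1", favor="H1", m=10_000, seed=31)
        woe = weight_of_evidence_summary(s)
        logs = np.log(s.values)
        assert woe["mean_log_bf"] >= -4 * logs.std(ddof=1) / math.sqrt(logs.size)


class TestBatch:
    def test_reproducible_and_reciprocal_orientation(self):
        pair = binomial_pair(n=10)
        a = run_bf_batch(pair, "H1", "H0", m=2, seed=9)
        b = run_bf_batch(pair, "H1", "H0", m=2, seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.m_used == 2
        inv = run_bf_batch(pair, "H1", "H1", m=2, seed=9)
        np.testing.assert_allclose(inv.values, 1.0 / a.values, rtol=1e-14)

    def test_scalar_and_batch_paths_agree(self):
        pair = binomial_pair(n=6)
        fast = run_bf_batch(pair, "H1", "H0", m=200, seed=3)
        pair_slow = binomial_pair(n=6)
        pair_slow.bf_batch = None
        slow = run_bf_batch(pair_slow, "H1", "H0", m=200, seed=3)
        np.testing.assert_allclose(fast.values, slow.values, rtol=1e-12)

    def test_batch_moment_matches_enumeration_oracle(self, h0, h1):
        """Simulated raw moments converge to the exact enumeration within
        4 Monte-Carlo standard errors."""
        n, m = 10, 50_000
        pair = binomial_pair(h0, h1, n=n)
        s = run_bf_batch(pair, "H1", "H0", m=m, seed=17)
        for order in (1, 2):
            got = raw_moment(s, order)
            exact = exact_bf_moment(h0, h1, h1, n, order)
            assert abs(got.estimate - exact) <= 4 * got.mc_se

    def test_m_too_small_rejected(self):
        with pytest.raises(ParameterError):
            run_bf_batch(binomial_pair(n=5), "H1", "H0", m=1, seed=0)


class TestTheoremChecks:
    def test_theorem1_trivial_pass_and_orientation_guard(self):
        ok = theorem1_check(_sample([1.0, 1.0], direction="H0", generated_under="H1"))
        assert ok.verdict and ok.mc_se == 0.0
        with pytest.raises(ContractError):
            theorem1_check(_sample([1.0, 1.0], direction="H1", generated_under="H1"))
        with pytest.raises(SupportViolationError):
            theorem1_check(
                _sample([1.0, 1.0], direction="H0", generated_under="H1"), support_ok=False
            )

    def test_theorem2_degenerate_pass_and_guards(self):
        spec = _sample([1.0, 1.0, 1.0], direction="H0", generated_under="H0")
        gen = _sample([1.0, 1.0, 1.0], direction="H0", generated_under="H1")
        rep = theorem2_check(spec, gen)
        assert rep.verdict and rep.relative_difference == 0.0
        with pytest.raises(ContractError):
            theorem2_check(gen, spec)  # specific-true sample generated under H1
        with pytest.raises(ContractError):
            theorem2_check(spec, _sample([1.0], direction="H1", generated_under="H1"))

    def test_theorem1_binomial_mean_near_one(self):
        pair = binomial_pair(n=10)
        s = run_bf_batch(pair, "H1", "H0", m=50_000, seed=23)
        rep = theorem1_check(s, support_ok=True)
        assert rep.verdict
        assert rep.mean == pytest.approx(1.0, abs=4 * rep.mc_se)


class TestFullCheck:
    def test_binomial_workflow_passes_and_reproduces(self):
        pair = binomial_pair(n=10)
        rep1 = run_full_check(pair, observed_data=7, m=5000, seed=101)
        rep2 = run_full_check(pair, observed_data=7, m=5000, seed=101)
        assert rep1.to_json() == rep2.to_json()
        assert rep1.theorem1.verdict
        # BF01 at n=10, k=7: C(10,7) 0.5^10 / (1/11)
        assert rep1.observed_bf == pytest.approx(120 / 1024 * 11, rel=1e-12)
        assert rep1.cumulative_means[-1] == pytest.approx(rep1.theorem1.mean)
        assert len(rep1.universal_bound) == 4

    def test_support_violation_refused(self):
        bad = binomial_pair(
            BinomialPointHypothesis("Hall", 1.0), BinomialBetaHypothesis("H1", 1, 1), n=2
        )
        with pytest.raises(SupportViolationError):
            run_full_check(bad, m=100, seed=1)
        # and enumeration shows why: the moment identity fails for this pair
        with pytest.warns(Warning):
            val = exact_bf_moment(
                BinomialBetaHypothesis("H1", 1, 1),
                BinomialPointHypothesis("Hall", 1.0),
                BinomialPointHypothesis("Hall", 1.0),
                2,
                1,
            )
        assert val == pytest.approx(1 / 3)

    def test_split_seed_stable_and_bounded(self):
        a = split_seed(123, 4)
        assert a == split_seed(123, 4)
        assert all(0 <= s < 2**31 for s in a)
        assert len(set(a)) == 4


def _bin_hyps():
    return (BinomialPointHypothesis("H0", 0.5), BinomialBetaHypothesis("H1", 1, 1))
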
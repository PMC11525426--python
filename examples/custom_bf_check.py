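"""Wire a user-supplied Bayes factor procedure into the check engine.

Any procedure that maps a dataset to a Bayes factor can be validated: the
engine only needs the two prior-predictive samplers and the BF callable.
Here a deliberately buggy implementation (a marginal likelihood off by a
factor depending on the data) is put next to the correct one — the check
catches the bug immediately.
"""

from scipy.stats import binom

from bfcheck import ModelPair, run_bf_batch, simulate_binomial, theorem1_check
from bfcheck import BinomialBetaHypothesis, BinomialPointHypothesis

n = 10
h0 = BinomialPointHypothesis("H0", 0.5)
h1 = BinomialBetaHypothesis("H1", 1, 1)


def bf01_correct(k: int) -> float:
    # p(k | theta=1/2) / p(k | uniform prior); the latter is 1/(n+1)
    return binom.pmf(k, n, 0.5) * (n + 1)


def bf01_buggy(k: int) -> float:
    # classic slip: forgot the binomial coefficient in the null marginal
    return 0.5**n * (n + 1)


def make_pair(bf) -> ModelPair:
    return ModelPair(
        specific_label="H0",
        general_label="H1",
        bf_specific_over_general=bf,
        sampler_specific=lambda m, seed: simulate_binomial(h0, n, m, seed),
        sampler_general=lambda m, seed: simulate_binomial(h1, n, m, seed),
        support_ok=True,
    )


for name, bf in (("correct", bf01_correct), ("buggy", bf01_buggy)):
    sample = run_bf_batch(make_pair(bf), "H1", "H0", m=20_000, seed=5)
    rep = theorem1_check(sample, support_ok=True)
    print(f"{name:>7}: mean BF01 = {rep.mean:.4f} +- {rep.mc_se:.4f} -> "
          f"{'pass' if rep.verdict else 'FAIL'}")
# the buggy mean lands far from 1: the procedure is not a Bayes factor for
# the model pair it claims to compare
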
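import numpy as np
import pytest

from bfcheck import (
    AnovaData,
    AnovaGenConfig,
    BinomialBetaHypothesis,
    BinomialPointHypothesis,
)


@pytest.fixture
def h0():
    return BinomialPointHypothesis("H0", 0.5)


@pytest.fixture
def h1():
    return BinomialBetaHypothesis("H1", 1.0, 1.0)


@pytest.fixture
def hr():
    """Directional hypothesis theta > 1/2 as a truncated uniform prior."""
    return BinomialBetaHypothesis("Hr", 1.0, 1.0, 0.5, 1.0)


@pytest.fixture
def toy_anova():
    """Small fixed two-group dataset (N=6) for oracle comparisons."""
    y = np.array([0.3, -0.1, 0.8, 1.2, 1.9, 1.1])
    group = np.array(["a", "a", "a", "b", "b", "b"])
    return AnovaData(y, group)


@pytest.fixture
def toy_anova_j3():
    """Fixed three-group dataset (N=12) with visible group separation."""
    rng = np.random.default_rng(2024)
    group = np.repeat(["a", "b", "c"], 4)
    means = {"a": 0.0, "b": 0.7, "c": -0.4}
    y = np.array([means[g] for g in group]) + 0.6 * rng.standard_normal(12)
    return AnovaData(y, group)


@pytest.fixture
def gen_cfg():
    """Generation settings: 3 groups of 50, sigma2 = 0.5, medium-scale effects."""
    return AnovaGenConfig(J=3, per_group_n=50, sigma2=0.5, r_gen=0.5, seed=1234)
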
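"""Built-in model pairs wiring the binomial and ANOVA models into the engine."""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import anova, binomial
from .engine import ModelPair

__all__ = ["binomial_pair", "anova_pair", "default_binomial_hypotheses"]


def default_binomial_hypotheses() -> tuple[binomial.BinomialPointHypothesis, binomial.BinomialBetaHypothesis]:
    """The canonical pair: a point null at 1/2 vs a uniform alternative."""
    return (
        binomial.BinomialPointHypothesis("H0", 0.5),
        binomial.BinomialBetaHypothesis("H1", 1.0, 1.0),
    )


def binomial_pair(
    specific_hyp: Optional[binomial.BinomialHypothesis] = None,
    general_hyp: Optional[binomial.BinomialHypothesis] = None,
    n: int = 10,
) -> ModelPair:
    """A :class:`ModelPair` for a binomial test at fixed trial count ``n``.

    Datasets are success counts.  The Bayes factor is closed-form, so the
    batch path is a table lookup over the n+1 possible outcomes.
    """
    if specific_hyp is None or general_hyp is None:
        d_spec, d_gen = default_binomial_hypotheses()
        specific_hyp = specific_hyp or d_spec
        general_hyp = general_hyp or d_gen

    support = binomial.support_overlap_check(specific_hyp, general_hyp, n)
    log_spec = binomial.log_marginal_table(specific_hyp, n)
    log_gen = binomial.log_marginal_table(general_hyp, n)
    with np.errstate(invalid="ignore"):
        bf_table = np.exp(log_spec - log_gen)  # inf where general mass is 0
    bf_table[np.isneginf(log_spec) & np.isneginf(log_gen)] = np.nan

    def bf(k) -> float:
        return binomial.binom_bf(specific_hyp, general_hyp, binomial.BinomialOutcome(n, int(k)))

    def bf_batch(ks) -> np.ndarray:
        return bf_table[np.asarray(ks, dtype=int)]

    def sampler(hyp):
        def _sample(m: int, seed: int):
            return binomial.simulate_binomial(hyp, n, m, seed)

        return _sample

    return ModelPair(
        specific_label=specific_hyp.label,
        general_label=general_hyp.label,
        bf_specific_over_general=bf,
        sampler_specific=sampler(specific_hyp),
        sampler_general=sampler(general_hyp),
        support_ok=support.passed,
        bf_batch=bf_batch,
    )


def anova_pair(
    gen_cfg: Optional[anova.AnovaGenConfig] = None,
    analysis_prior: "anova.JZSPrior | float | str" = "medium",
    specific_label: str = "H0",
    general_label: str = "H1",
) -> ModelPair:
    """A :class:`ModelPair` for the one-way ANOVA test.

    The specific model is the null (all group means equal); the general
    model draws contrasts from the g-scaled effect prior with scale
    ``gen_cfg.r_gen``.  ``analysis_prior`` sets the scale used when
    *computing* the Bayes factor — deliberately misspecifying it against
    ``r_gen`` is how a broken calculation is emulated.
    """
    cfg = gen_cfg if gen_cfg is not None else anova.AnovaGenConfig()
    prior = analysis_prior if isinstance(analysis_prior, anova.JZSPrior) else anova.JZSPrior.from_scale(analysis_prior)

    # BF01 is computed on the log scale and floored at exp(-700): an
    # H1-generated dataset with an enormous effect has a genuinely tiny but
    # positive BF01, which must not underflow to zero (zero would read as an
    # undefined 1/0 Bayes factor and get recoded, biasing the moments).
    _LOG_FLOOR = -700.0

    def bf01(data: anova.AnovaData) -> float:
        return float(np.exp(max(-anova.log_jzs_bf10(data, prior), _LOG_FLOOR)))

    def bf01_batch(datasets) -> np.ndarray:
        log_bf10 = anova.log_jzs_bf10_batch(datasets, prior)
        return np.exp(np.maximum(-log_bf10, _LOG_FLOOR))

    def sampler_h0(m: int, seed: int):
        return anova.simulate_anova_h0(anova.make_gen_config(cfg, seed), m)

    def sampler_h1(m: int, seed: int):
        return anova.simulate_anova_h1(anova.make_gen_config(cfg, seed), m)

    return ModelPair(
        specific_label=specific_label,
        general_label=general_label,
        bf_specific_over_general=bf01,
        sampler_specific=sampler_h0,
        sampler_general=sampler_h1,
        support_ok=True,  # both models share the full Gaussian sample space
        bf_batch=bf01_batch,
    )
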
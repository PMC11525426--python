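"""Exception and warning types shared across the package."""


class ParameterError(ValueError):
    """A hypothesis, prior, or configuration parameter is invalid."""


class DegenerateDataError(ValueError):
    """The data admit no Bayes factor (e.g. constant response, single group)."""


class CapabilityError(ValueError):
    """The request exceeds a documented implementation limit."""


class UndefinedBayesFactorError(ArithmeticError):
    """The Bayes factor is undefined: the denominator marginal is zero while
    the numerator marginal is positive (a 1/0 situation).

    Distinct from :class:`ParameterError`; the hypotheses themselves are
    valid, the observed outcome simply has no probability under one of them.
    """


class ImpossibleOutcomeError(ArithmeticError):
    """Both hypotheses assign zero probability to the observed outcome."""


class BayesFactorFailureError(RuntimeError):
    """A numerical Bayes factor evaluation failed (e.g. quadrature did not
    converge).  Failed evaluations are excluded and counted, never recoded."""


class EmptySampleError(ValueError):
    """No usable Bayes factor values remain in a sample."""


class ContractError(ValueError):
    """A check was invoked with the wrong orientation or generation labels."""


class SupportViolationError(ValueError):
    """The two hypotheses do not share a common sample-space support, so the
    Turing-Good moment identities are not guaranteed to hold."""


class SupportWarning(UserWarning):
    """Outcomes carrying zero probability under the true hypothesis but
    positive probability under its rival were skipped during enumeration."""
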
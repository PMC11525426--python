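"""Bookkeeping for batches of simulated Bayes factors.

A batch can contain three kinds of replicates: finite positive values,
*undefined* values (a 1/0 Bayes factor, typically from a degenerate
posterior quantity), and *failed* evaluations (numerical breakdown).
Undefined values are handled by an explicit recode policy; failed
evaluations are always excluded and counted, never recoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptySampleError, ParameterError

__all__ = ["UNDEFINED", "BFSampleSet", "RECODE_POLICIES", "recode_undefined"]


class _Undefined:
    """Sentinel marking an undefined (1/0) Bayes factor value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"


UNDEFINED = _Undefined()

RECODE_POLICIES = ("recode_max_plus_one", "drop", "fail")


def recode_undefined(raw_values, policy: str = "recode_max_plus_one") -> np.ndarray:
    """Resolve undefined markers in a sequence of Bayes factor values.

    ``recode_max_plus_one`` replaces each undefined value with one plus the
    highest observed finite value — the workaround used when a posterior
    quantity saturates and the Bayes factor comes out as 1/0.  ``drop``
    removes them; ``fail`` raises as soon as one is present.  Entries may be
    positive floats, ``UNDEFINED``, or None (treated as undefined).
    """
    if policy not in RECODE_POLICIES:
        raise ParameterError(f"unknown recode policy {policy!r}; choose from {RECODE_POLICIES}")
    finite = [float(v) for v in raw_values if v is not UNDEFINED and v is not None]
    n_undef = len(raw_values) - len(finite)
    if policy == "fail" and n_undef:
        raise EmptySampleError(f"{n_undef} undefined Bayes factor value(s) with policy 'fail'")
    if policy == "drop" or n_undef == 0:
        return np.asarray(finite, dtype=float)
    if not finite:
        raise EmptySampleError("all Bayes factor values are undefined; nothing to recode against")
    fill = max(finite) + 1.0
    return np.asarray(
        [fill if (v is UNDEFINED or v is None) else float(v) for v in raw_values], dtype=float
    )


@dataclass
class BFSampleSet:
    """m Bayes factors from one simulation condition.

    ``values`` holds the retained (possibly recoded) positive values.
    Under the ``recode_max_plus_one`` policy the undefined replicates are
    recoded *into* ``values``, so ``len(values) + failed_count`` accounts
    for all attempted replicates; under ``drop`` it is
    ``len(values) + undefined_count + failed_count``.
    """

    values: np.ndarray
    undefined_count: int
    failed_count: int
    direction: str  # label of the hypothesis the values favor
    generated_under: str  # label of the hypothesis the data were drawn from
    seed: int
    recode_policy: str = "recode_max_plus_one"
    records: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values) & (self.values > 0)):
            raise ParameterError("retained Bayes factor values must be finite and positive")

    @property
    def m_used(self) -> int:
        return int(self.values.size)

    def attempted(self) -> int:
        base = self.m_used + self.failed_count
        if self.recode_policy == "drop":
            base += self.undefined_count
        return base
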
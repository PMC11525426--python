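"""Run configuration: schema, validation, and (de)serialization.

A run is described by a small YAML or JSON document, e.g.::

    model_family: binomial
    n: 10
    m: 1000
    seed: 42
    null_hypothesis: {type: point, theta0: 0.5, label: H0}
    alt_hypothesis:  {type: beta, a: 1, b: 1, label: H1}

or, for the ANOVA family::

    model_family: anova
    m: 5000
    anova: {J: 3, per_group_n: 50, sigma2: 0.5, r_gen: 0.5}
    analysis_scale: medium

Unknown keys are rejected by name; omitted keys get documented defaults
(point null at 1/2 vs uniform alternative, recode_max_plus_one, 3-sigma
tolerance).  A missing seed is drawn once and stored, so every run is
reproducible from its configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import anova, binomial
from .engine import ModelPair
from .exceptions import ParameterError
from .pairs import anova_pair, binomial_pair, default_binomial_hypotheses
from .samples import RECODE_POLICIES

__all__ = ["RunConfig", "load_config", "write_config", "build_pair"]

_TOP_KEYS = {
    "model_family", "m", "seed", "recode_policy", "tolerance_multiplier",
    "theorem2", "alphas", "out_dir", "n", "null_hypothesis", "alt_hypothesis",
    "anova", "analysis_scale",
}
_HYP_KEYS = {"type", "label", "theta0", "a", "b", "lower", "upper"}
_ANOVA_KEYS = {"J", "per_group_n", "sigma2", "alpha0", "r_gen", "scale_effects_by_sigma2"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ParameterError(f"unknown key(s) {sorted(unknown)} in {where}")


def _hyp_from_dict(d: dict, default_label: str) -> binomial.BinomialHypothesis:
    _check_keys(d, _HYP_KEYS, f"hypothesis {d.get('label', default_label)!r}")
    kind = d.get("type")
    label = d.get("label", default_label)
    if kind == "point":
        return binomial.BinomialPointHypothesis(label, float(d["theta0"]))
    if kind == "beta":
        return binomial.BinomialBetaHypothesis(
            label, float(d["a"]), float(d["b"]),
            float(d.get("lower", 0.0)), float(d.get("upper", 1.0)),
        )
    raise ParameterError(f"hypothesis 'type' must be 'point' or 'beta', got {kind!r}")


def _hyp_to_dict(h: binomial.BinomialHypothesis) -> dict:
    if isinstance(h, binomial.BinomialPointHypothesis):
        return {"type": "point", "label": h.label, "theta0": h.theta0}
    return {"type": "beta", "label": h.label, "a": h.a, "b": h.b, "lower": h.lower, "upper": h.upper}


@dataclass
class RunConfig:
    """Fully validated settings for one check run."""

    model_family: str = "binomial"
    m: int = 1000
    seed: Optional[int] = None
    recode_policy: str = "recode_max_plus_one"
    tolerance_multiplier: float = 3.0
    theorem2: bool = True
    alphas: list = field(default_factory=lambda: [0.2, 0.1, 0.05, 0.01])
    out_dir: str = "bfcheck_out"
    # binomial family
    n: int = 10
    null_hypothesis: Optional[binomial.BinomialHypothesis] = None
    alt_hypothesis: Optional[binomial.BinomialHypothesis] = None
    # anova family
    anova_cfg: Optional[anova.AnovaGenConfig] = None
    analysis_scale: "float | str" = "medium"

    def __post_init__(self) -> None:
        if self.model_family not in ("binomial", "anova"):
            raise ParameterError(
                f"model_family must be 'binomial' or 'anova', got {self.model_family!r} "
                "(custom pairs are constructed directly in Python)"
            )
        if self.m < 2:
            raise ParameterError(f"m must be >= 2, got {self.m}")
        if self.recode_policy not in RECODE_POLICIES:
            raise ParameterError(f"recode_policy must be one of {RECODE_POLICIES}")
        if self.tolerance_multiplier <= 0:
            raise ParameterError("tolerance_multiplier must be positive")
        if self.n < 0:
            raise ParameterError(f"n must be nonnegative, got {self.n}")
        if self.seed is None:
            self.seed = int(np.random.SeedSequence().entropy % (2**31))
        if self.model_family == "binomial":
            d_null, d_alt = default_binomial_hypotheses()
            self.null_hypothesis = self.null_hypothesis or d_null
            self.alt_hypothesis = self.alt_hypothesis or d_alt
        else:
            self.anova_cfg = self.anova_cfg or anova.AnovaGenConfig(seed=self.seed)
            anova.JZSPrior.from_scale(self.analysis_scale)  # validate early

    def to_dict(self) -> dict:
        out = {
            "model_family": self.model_family,
            "m": self.m,
            "seed": self.seed,
            "recode_policy": self.recode_policy,
            "tolerance_multiplier": self.tolerance_multiplier,
            "theorem2": self.theorem2,
            "alphas": list(self.alphas),
            "out_dir": self.out_dir,
        }
        if self.model_family == "binomial":
            out["n"] = self.n
            out["null_hypothesis"] = _hyp_to_dict(self.null_hypothesis)
            out["alt_hypothesis"] = _hyp_to_dict(self.alt_hypothesis)
        else:
            out["anova"] = asdict(self.anova_cfg)
            out["analysis_scale"] = self.analysis_scale
        return out


def _from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ParameterError("configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "run configuration")
    kwargs: dict = {}
    for key in ("model_family", "m", "seed", "recode_policy", "tolerance_multiplier",
                "theorem2", "out_dir", "n", "analysis_scale"):
        if key in raw:
            kwargs[key] = raw[key]
    if "alphas" in raw:
        kwargs["alphas"] = [float(a) for a in raw["alphas"]]
    if "null_hypothesis" in raw:
        kwargs["null_hypothesis"] = _hyp_from_dict(raw["null_hypothesis"], "H0")
    if "alt_hypothesis" in raw:
        kwargs["alt_hypothesis"] = _hyp_from_dict(raw["alt_hypothesis"], "H1")
    if "anova" in raw:
        _check_keys(raw["anova"], _ANOVA_KEYS | {"seed"}, "'anova' section")
        kwargs["anova_cfg"] = anova.AnovaGenConfig(**raw["anova"])
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a run configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    elif path.suffix == ".json":
        raw = json.loads(text)
    else:
        raise ParameterError(f"unsupported config extension {path.suffix!r} (use .yaml/.yml/.json)")
    return _from_dict(raw)


def write_config(cfg: RunConfig, path) -> None:
    """Serialize a configuration; load_config(path) round-trips it."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        raise ParameterError(f"unsupported config extension {path.suffix!r} (use .yaml/.yml/.json)")


def build_pair(cfg: RunConfig) -> ModelPair:
    """Construct the ModelPair a configuration describes."""
    if cfg.model_family == "binomial":
        return binomial_pair(cfg.null_hypothesis, cfg.alt_hypothesis, n=cfg.n)
    return anova_pair(cfg.anova_cfg, analysis_prior=cfg.analysis_scale)
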
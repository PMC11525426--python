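"""Writers for check reports and Bayes factor draw tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import CheckReport
from .exceptions import ParameterError
from .samples import BFSampleSet

__all__ = ["write_report", "bf_draws_frame", "validate_report_dict"]

#: Minimal structural schema for report.json; docs/report_schema.json in the
#: repository mirrors this for external consumers.
REPORT_SCHEMA = {
    "specific_label": str,
    "general_label": str,
    "m": int,
    "seed": int,
    "observed_bf": (float, int, type(None)),
    "theorem1": dict,
    "theorem2": (dict, type(None)),
    "universal_bound": list,
    "woe": dict,
    "batches": dict,
}


def validate_report_dict(d: dict) -> None:
    """Raise ParameterError when a serialized report is malformed."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in d:
            raise ParameterError(f"report is missing key {key!r}")
        if not isinstance(d[key], typ):
            raise ParameterError(f"report key {key!r} has type {type(d[key]).__name__}")
    for key in ("mean", "mc_se", "verdict"):
        if key not in d["theorem1"]:
            raise ParameterError(f"theorem1 block missing {key!r}")


def bf_draws_frame(*samples: BFSampleSet) -> pd.DataFrame:
    """Per-replicate draw table with undefined/failed flags for one or more
    batches."""
    frames = []
    for s in samples:
        if s is None:
            continue
        if not s.records:
            raise ParameterError("sample carries no per-replicate records")
        df = pd.DataFrame(s.records)
        df.insert(1, "generated_under", s.generated_under)
        df.insert(2, "favor", s.direction)
        frames.append(df)
    if not frames:
        raise ParameterError("no samples to write")
    return pd.concat(frames, ignore_index=True)[
        ["replicate", "generated_under", "favor", "bf", "was_undefined", "was_failed"]
    ]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(report: CheckReport, directory) -> list[dict]:
    """Write report.json, bf_draws.csv and cumulative_mean.csv.

    Returns (and also writes, as manifest.json) a manifest listing each file
    with its SHA-256 checksum; re-running the same configuration and seed
    reproduces the checksums bit for bit.  Floats are serialized with full
    round-trip precision.
    """
    if not directory or not str(directory).strip():
        raise ParameterError("output directory path must be non-empty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    report_path = directory / "report.json"
    payload = report.to_dict()
    validate_report_dict(payload)
    report_path.write_text(json.dumps(payload, indent=2) + "\n")

    draws_path = directory / "bf_draws.csv"
    bf_draws_frame(report.sample_general_true, report.sample_specific_true).to_csv(
        draws_path, index=False, float_format="%.17g"
    )

    cm_path = directory / "cumulative_mean.csv"
    cm = np.asarray(report.cumulative_means)
    pd.DataFrame({"m": np.arange(1, cm.size + 1), "cumulative_mean_bf": cm}).to_csv(
        cm_path, index=False, float_format="%.17g"
    )

    manifest = [
        {"file": p.name, "sha256": _sha256(p)} for p in (report_path, draws_path, cm_path)
    ]
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
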
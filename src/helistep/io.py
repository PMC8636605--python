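"""File formats and configuration.

Trace TSV: ``#``-prefixed ``key\tvalue`` metadata header lines
(force_pN, atp_uM, sample_rate_hz, id, seed) followed by two tab-separated
columns ``time_s`` and ``position_bp`` ('.' decimal point).  Step and dwell
tables round-trip as plain TSV; results are JSON; analysis configuration is
YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_steps",
    "write_steps",
    "write_summary",
    "AnalysisConfig",
    "load_config",
]

_FLOAT_FMT = "%.17g"


def write_trace(path, trace: Trace, seed: int | None = None) -> None:
    """Write a trace as metadata-headed TSV (lossless float round trip)."""
    lines = [
        f"# force_pN\t{trace.force:.17g}",
        f"# atp_uM\t{trace.atp:.17g}",
        f"# sample_rate_hz\t{trace.sample_rate:.17g}",
        f"# id\t{trace.id}",
    ]
    if seed is not None:
        lines.append(f"# seed\t{int(seed)}")
    lines.append("time_s\tposition_bp")
    for t, x in zip(trace.time, trace.position):
        lines.append(f"{t:.17g}\t{x:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path) -> Trace:
    """Read a trace TSV written by :func:`write_trace` (CRLF tolerated)."""
    meta = {}
    with open(path, "r", newline=None) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
        else:
            body_start = i
            break
    header = lines[body_start].split("\t")
    required = {"time_s", "position_bp"}
    if not required <= set(header):
        missing = required - set(header)
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    ti = header.index("time_s")
    pi = header.index("position_bp")
    time, pos = [], []
    for line in lines[body_start + 1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        time.append(float(parts[ti]))
        pos.append(float(parts[pi]))
    return Trace(
        time=np.asarray(time),
        position=np.asarray(pos),
        force=float(meta.get("force_pN", np.nan)),
        atp=float(meta.get("atp_uM", np.nan)),
        sample_rate=float(meta.get("sample_rate_hz", 0) or 0)
        or _infer_rate(np.asarray(time)),
        id=meta.get("id", Path(path).stem),
    )


def _infer_rate(time: np.ndarray) -> float:
    if time.size < 2:
        return 1.0
    return 1.0 / float(np.median(np.diff(time)))


def write_steps(path, steps: pd.DataFrame) -> None:
    steps.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_steps(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "s" not in df.columns:
        raise ValueError("missing required column(s): ['s']")
    return df


def write_summary(path, summary: dict, config: dict | None = None) -> None:
    """Write a results JSON with package version and config hash embedded."""
    from . import __version__

    payload = dict(summary)
    payload["_version"] = __version__
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str)
        payload["_config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


@dataclass
class AnalysisConfig:
    """Validated pipeline configuration (see ``run_pipeline``)."""

    out_dir: str = "results"
    seed: int = 0
    traces: list = field(default_factory=list)  # input TSV paths
    simulate: dict | None = None  # generator block (atp_list, n_traces, ...)
    sensitivity: float = 3.0
    min_step: float = 0.5
    boxcar_window: int = 35
    n_boot: int = 10_000
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 25 <= self.boxcar_window <= 45:
            raise ValueError("boxcar_window must lie in [25, 45]")
        if self.min_step < 0:
            raise ValueError("min_step must be non-negative")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if not self.traces and not self.simulate:
            raise ValueError("config must list traces or a simulate block")
        for p in self.traces:
            if not Path(p).exists():
                raise FileNotFoundError(f"trace file not found: {p}")

    def as_dict(self) -> dict:
        return {
            "out_dir": self.out_dir, "seed": self.seed,
            "traces": list(self.traces), "simulate": self.simulate,
            "sensitivity": self.sensitivity, "min_step": self.min_step,
            "boxcar_window": self.boxcar_window, "n_boot": self.n_boot,
            "extra": self.extra,
        }


def load_config(path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {k: raw.pop(k) for k in list(raw)
             if k in AnalysisConfig.__dataclass_fields__}
    cfg = AnalysisConfig(**known)
    cfg.extra.update(raw)
    cfg.validate()
    return cfg
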
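"""Plain-text serialization of traces and event tables.

Traces travel as a two-column TSV (``time_s``, ``current_pA``, header row)
plus a JSON sidecar (same stem, ``.json``) holding the sampling rate,
holding potential and any simulation metadata.  Event tables are CSV.
No binary formats are used.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .channel_sim import Trace
from .exceptions import InputError

FORMAT_VERSION = 1

__all__ = ["write_trace", "read_trace", "sidecar_path", "FORMAT_VERSION"]


def sidecar_path(trace_path: str | Path) -> Path:
    return Path(trace_path).with_suffix(".json")


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Write ``path`` (TSV) and its JSON sidecar; returns the sidecar path."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.time_s, "current_pA": trace.current_pA}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = {
        "format_version": FORMAT_VERSION,
        "sampling_rate_Hz": trace.sampling_rate_Hz,
        "holding_potential_mV": trace.holding_potential_mV,
        "n_samples": trace.n_samples,
        "metadata": _jsonable(trace.metadata),
    }
    side = sidecar_path(path)
    side.write_text(json.dumps(meta, indent=2))
    return side


def read_trace(path: str | Path) -> Trace:
    """Read a TSV trace; uses the JSON sidecar when present, otherwise
    infers the sampling rate from the time column."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"trace file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if not {"time_s", "current_pA"}.issubset(df.columns):
        raise InputError(f"{path}: expected columns time_s, current_pA")
    side = sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        fs = float(meta["sampling_rate_Hz"])
        holding = float(meta.get("holding_potential_mV", 0.0))
        metadata = meta.get("metadata", {})
    else:
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise InputError(f"{path}: cannot infer sampling rate from one sample")
        fs = 1.0 / float(np.median(np.diff(t)))
        holding, metadata = 0.0, {}
    return Trace(
        sampling_rate_Hz=fs,
        holding_potential_mV=holding,
        current_pA=df["current_pA"].to_numpy(float),
        metadata=metadata,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
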
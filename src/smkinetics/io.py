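"""Delimited-text table schemas and JSON result documents.

Tables are UTF-8 delimited text with a header row and '.' decimals:

* dwell tables    — columns ``molecule_id, condition, dwell_s``
* trace tables    — columns ``trace_id, frame, intensity``
* decay tables    — columns ``time_min, target_signal, reference_signal``

Result documents are JSON with every numeric value twice: a ``summary`` block
rounded to 6 significant digits for reading, and a ``machine`` block at full
precision for downstream code.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .models import DecaySeries, DwellDataset, ObservationWindow, TraceSet

__all__ = [
    "read_dwell_table",
    "write_dwell_table",
    "read_trace_table",
    "write_trace_table",
    "read_decay_table",
    "write_decay_table",
    "write_result_document",
    "read_result_document",
]

_DWELL_COLS = ["molecule_id", "condition", "dwell_s"]
_TRACE_COLS = ["trace_id", "frame", "intensity"]
_DECAY_COLS = ["time_min", "target_signal", "reference_signal"]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def write_dwell_table(data: DwellDataset, path, sep: str = "\t") -> None:
    mol = data.molecule_id if data.molecule_id is not None else np.arange(data.n)
    df = pd.DataFrame(
        {"molecule_id": mol, "condition": data.condition, "dwell_s": data.durations}
    )
    df.to_csv(path, sep=sep, index=False)


def read_dwell_table(
    path, window: ObservationWindow, condition: str | None = None, sep: str = "\t"
) -> DwellDataset | dict[str, DwellDataset]:
    """Read a dwell table; returns one dataset, or a dict keyed by condition
    when the file mixes conditions and none is requested."""
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, _DWELL_COLS, path)
    if condition is not None:
        df = df[df["condition"] == condition]
        if df.empty:
            raise ValueError(f"{path}: no rows for condition {condition!r}")

    def build(sub: pd.DataFrame, label: str) -> DwellDataset:
        return DwellDataset(
            durations=sub["dwell_s"].to_numpy(float),
            condition=label,
            window=window,
            molecule_id=sub["molecule_id"].to_numpy(),
        )

    labels = df["condition"].unique()
    if condition is not None or len(labels) == 1:
        return build(df, condition or str(labels[0]))
    return {str(c): build(df[df["condition"] == c], str(c)) for c in labels}


def write_trace_table(traces: TraceSet, path, sep: str = "\t") -> None:
    frames = []
    for trace_id, arr in traces.traces.items():
        frames.append(
            pd.DataFrame(
                {"trace_id": trace_id, "frame": np.arange(arr.size), "intensity": arr}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_trace_table(path, frame_interval: float, sep: str = "\t") -> TraceSet:
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, _TRACE_COLS, path)
    traces: dict[str, np.ndarray] = {}
    for trace_id, sub in df.groupby("trace_id", sort=False):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy(int)
        if not np.array_equal(frames, np.arange(frames.size)):
            raise ValueError(f"{path}: trace {trace_id!r} frames not contiguous from 0")
        traces[str(trace_id)] = sub["intensity"].to_numpy(float)
    return TraceSet(traces=traces, frame_interval=frame_interval)


def write_decay_table(series: DecaySeries, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "time_min": series.times,
            "target_signal": series.target_signal,
            "reference_signal": series.reference_signal,
        }
    ).to_csv(path, sep=sep, index=False)


def read_decay_table(path, label: str = "", sep: str = "\t") -> DecaySeries:
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, _DECAY_COLS, path)
    return DecaySeries(
        times=df["time_min"].to_numpy(float),
        target_signal=df["target_signal"].to_numpy(float),
        reference_signal=df["reference_signal"].to_numpy(float),
        label=label or str(path),
    )


# ---------------------------------------------------------------------------
# result documents


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def _summarize(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _summarize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_summarize(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _summarize(obj.tolist())
    return obj


def _machine(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _machine(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_machine(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _machine(obj.tolist())
    return obj


def write_result_document(content: dict, path, provenance: dict | None = None) -> None:
    """Serialize a result dict with 6-significant-digit summary + full precision."""
    doc = {
        "summary": _summarize(content),
        "machine": _machine(content),
    }
    if provenance is not None:
        doc["provenance"] = _machine(provenance)
    Path(path).write_text(json.dumps(doc, indent=2, allow_nan=True) + "\n")


def read_result_document(path) -> dict:
    return json.loads(Path(path).read_text())
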
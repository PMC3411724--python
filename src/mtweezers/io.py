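"""Trace and configuration file I/O.

Traces travel as plain delimited text (CSV) with a commented header that
names the units — universal and diff-able.  Required columns are
``t, x, y, z, bead_id`` (seconds and micrometres).  Large files are
parsed in chunks so memory stays bounded by the chunk size during
reading.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import pandas as pd
import yaml

from .dynamics import Trace
from .magnetostatics import BeadModel, MagnetAssembly

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "write_traces",
    "read_traces",
    "iter_trace_chunks",
    "load_config",
    "save_config",
]

REQUIRED_COLUMNS = ("t", "x", "y", "z", "bead_id")
_HEADER = "# mtweezers trace: t (s), x (um), y (um), z (um), bead_id\n"


class SchemaError(ValueError):
    """A trace file does not conform to the required column schema."""


def write_traces(traces: Trace | list[Trace] | pd.DataFrame, path) -> Path:
    """Write one or several traces to a delimited text file.

    Values round-trip losslessly at full double precision
    (``repr``-style formatting).  Returns the path written.
    """
    path = Path(path)
    if isinstance(traces, Trace):
        frames = [traces.data]
    elif isinstance(traces, pd.DataFrame):
        frames = [traces]
    else:
        frames = [t.data for t in traces]
    data = pd.concat(frames, ignore_index=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise SchemaError(f"trace is missing required column(s): {', '.join(missing)}")
    with open(path, "w") as fh:
        fh.write(_HEADER)
        data.to_csv(fh, index=False, float_format="%.17g")
    return path


def _validate_columns(columns) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in columns]
    if missing:
        raise SchemaError(f"trace file is missing required column(s): {', '.join(missing)}")


def iter_trace_chunks(path, chunksize: int = 100_000) -> Iterator[pd.DataFrame]:
    """Stream a trace file in chunks of ``chunksize`` rows."""
    first = True
    with pd.read_csv(path, comment="#", chunksize=chunksize) as reader:
        for chunk in reader:
            if first:
                _validate_columns(chunk.columns)
                first = False
            yield chunk


def read_traces(path, frame_rate_hz: float | None = None) -> Trace:
    """Read a trace file, validating the column schema.

    The frame rate, if not given, is inferred from the median time step
    of the first bead.
    """
    chunks = list(iter_trace_chunks(path))
    data = pd.concat(chunks, ignore_index=True)
    data[["t", "x", "y", "z"]] = data[["t", "x", "y", "z"]].astype(float)
    if frame_rate_hz is None:
        first = data[data["bead_id"] == data["bead_id"].iloc[0]]
        dt = first["t"].diff().median()
        frame_rate_hz = 1.0 / float(dt) if dt and dt > 0 else 1.0
    if data["bead_id"].nunique() > 1:
        # multiple beads: times must be strictly increasing per bead
        for _, sub in data.groupby("bead_id"):
            Trace(sub.reset_index(drop=True), frame_rate_hz)
        return _MultiTrace(data, frame_rate_hz)
    return Trace(data, frame_rate_hz)


class _MultiTrace(Trace):
    """Trace containing several beads; time ordering holds per bead."""

    def __post_init__(self) -> None:  # per-bead validation done by the reader
        pass

    def per_bead(self) -> dict[int, Trace]:
        return {
            int(bid): Trace(sub.reset_index(drop=True), self.frame_rate_hz)
            for bid, sub in self.data.groupby("bead_id")
        }


def save_config(obj, path) -> Path:
    """Serialize a configuration dataclass (or dict of them) to YAML."""
    from dataclasses import asdict, is_dataclass

    def plain(o):
        if is_dataclass(o):
            return {k: plain(v) for k, v in asdict(o).items()}
        if isinstance(o, dict):
            return {k: plain(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [plain(v) for v in o]
        return o

    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(plain(obj), fh, sort_keys=False)
    return path


def load_config(path, cls):
    """Load a YAML mapping into a configuration dataclass ``cls``.

    Nested ``magnet``/``bead`` blocks map onto :class:`MagnetAssembly`
    and :class:`BeadModel` fields where the target class declares them.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    hints = {"assembly": MagnetAssembly, "bead": BeadModel}
    kwargs = {}
    for key, value in raw.items():
        sub = hints.get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = sub(**value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)
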
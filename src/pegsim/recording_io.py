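"""CSV persistence for array recordings.

Dialect: a recording file starts with ``# key: value`` header lines
(sample_rate, seed, protocol hash, ...), then a CSV table with a
``time_s`` column and one column per channel.  Channel metadata
(functionalization, molarity) lives in a sidecar ``channels.csv`` with
columns ``id, functionalization, molarity``.  Round trips are lossless to
1e-12 relative (values are written with 17 significant digits).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .breath_simulator import ArrayRecording, ChannelRecording
from .errors import FormatError

__all__ = ["write_recording", "read_recording"]


def write_recording(
    recording: ArrayRecording,
    path: str | Path,
    channels_path: str | Path | None = "auto",
) -> Path:
    """Write a recording; by default a ``channels.csv`` sidecar is placed
    next to it (pass ``None`` to skip, or an explicit path)."""
    path = Path(path)
    buf = io.StringIO()
    meta = dict(recording.meta)
    meta.setdefault("sample_rate", recording.sample_rate)
    for key, value in meta.items():
        buf.write(f"# {key}: {value}\n")
    frame = pd.DataFrame({"time_s": recording.time})
    for ch in recording.channels:
        frame[ch.id] = ch.trace
    frame.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue())

    if channels_path is not None:
        side = path.parent / "channels.csv" if channels_path == "auto" else Path(channels_path)
        rows = ["id,functionalization,molarity"] + [
            f"{ch.id},{ch.functionalization},{ch.molarity:.17g}" for ch in recording.channels
        ]
        side.write_text("\n".join(rows) + "\n")
    return path


def read_recording(path: str | Path, channels_path: str | Path | None = None) -> ArrayRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` (with row numbers where applicable) for a
    missing time column, non-uniform grid, nonpositive conductances, or a
    missing channels sidecar.
    """
    path = Path(path)
    meta: dict = {}
    lines = path.read_text().splitlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line.lstrip("# ")
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    table = pd.read_csv(io.StringIO("\n".join(lines[n_header:])))
    if "time_s" not in table.columns:
        raise FormatError(f"{path}: missing 'time_s' column")
    time = table["time_s"].to_numpy(float)
    if len(time) < 2:
        raise FormatError(f"{path}: need at least 2 rows")
    dt = np.diff(time)
    bad = np.nonzero(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-12) | (dt <= 0))[0]
    if bad.size:
        raise FormatError(f"{path}: non-uniform time grid at data row {int(bad[0]) + 2}")

    side = Path(channels_path) if channels_path else path.parent / "channels.csv"
    if not side.exists():
        raise FormatError(f"missing channel metadata file {side}")
    chmeta = pd.read_csv(side).set_index("id")

    channels = []
    for col in table.columns:
        if col == "time_s":
            continue
        values = table[col].to_numpy(float)
        nonpos = np.nonzero(values <= 0)[0]
        if nonpos.size:
            raise FormatError(
                f"{path}: nonpositive conductance in {col} at data row {int(nonpos[0]) + 2}"
            )
        if col not in chmeta.index:
            raise FormatError(f"{side}: no metadata for channel {col!r}")
        channels.append(
            ChannelRecording(
                id=col,
                functionalization=str(chmeta.loc[col, "functionalization"]),
                molarity=float(chmeta.loc[col, "molarity"]),
                trace=values,
            )
        )
    if not channels:
        raise FormatError(f"{path}: no channel columns")

    sample_rate = float(meta.pop("sample_rate", 1.0 / dt[0]))
    return ArrayRecording(time=time, channels=channels, sample_rate=sample_rate, meta=meta)
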
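"""The :class:`PulseTrace` container — a uniformly sampled signal with a
frame rate. Every signal-processing stage consumes and produces one.

Samples are stored as a ``(channels, n_samples)`` float array; a
single-channel trace is simply ``channels == 1``.  The RGB channel-mean
traces coming off a webcam front end have three channels; a separated
pulse component has one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError

__all__ = ["PulseTrace", "read_trace_csv", "write_trace_csv"]


@dataclass(frozen=True)
class PulseTrace:
    """A uniformly sampled scalar or multichannel signal.

    Parameters
    ----------
    samples
        Array of shape ``(channels, n)`` or ``(n,)`` (promoted to one
        channel). Arbitrary units.
    fps
        Sampling rate in frames per second; must be positive.
    """

    samples: np.ndarray
    fps: float
    channel_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise InvalidArgumentError(f"samples must be 1-D or 2-D, got ndim={arr.ndim}")
        if arr.shape[1] < 2:
            raise InvalidArgumentError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("trace samples must be finite")
        if not (self.fps > 0):
            raise InvalidArgumentError(f"fps must be positive, got {self.fps}")
        object.__setattr__(self, "samples", arr)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds (n / fps)."""
        return self.n_samples / self.fps

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t_i = i / fps`` in seconds."""
        return np.arange(self.n_samples) / self.fps

    def channel(self, i: int) -> "PulseTrace":
        """Extract one channel as a single-channel trace."""
        return PulseTrace(self.samples[i], self.fps)


def write_trace_csv(trace: PulseTrace, path: str | Path) -> None:
    """Write a trace as CSV with a JSON sidecar recording the frame rate.

    Three channels write ``frame,r,g,b``; one channel writes ``frame,value``.
    The sidecar is ``<path>.meta.json`` with key ``fps``.
    """
    path = Path(path)
    frame = np.arange(trace.n_samples)
    if trace.n_channels == 3:
        cols = {"frame": frame, "r": trace.samples[0], "g": trace.samples[1], "b": trace.samples[2]}
    elif trace.n_channels == 1:
        cols = {"frame": frame, "value": trace.samples[0]}
    else:
        cols = {"frame": frame}
        for i in range(trace.n_channels):
            cols[f"ch{i}"] = trace.samples[i]
    # %.17g guarantees bit-exact float round-trips
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    Path(str(path) + ".meta.json").write_text(json.dumps({"fps": trace.fps}))


def read_trace_csv(path: str | Path, fps: float | None = None) -> PulseTrace:
    """Read a trace written by :func:`write_trace_csv`.

    ``fps`` overrides the sidecar; one of the two must supply a frame rate.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise SchemaError(f"{path}: empty trace file")
    if fps is None:
        sidecar = Path(str(path) + ".meta.json")
        if not sidecar.exists():
            raise SchemaError(f"{path}: no fps given and no sidecar {sidecar.name}")
        fps = float(json.loads(sidecar.read_text())["fps"])
    if "frame" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'frame'")
    value_cols = [c for c in df.columns if c != "frame"]
    if not value_cols:
        raise SchemaError(f"{path}: no value columns found")
    return PulseTrace(df[value_cols].to_numpy(dtype=float).T, fps, tuple(value_cols))
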
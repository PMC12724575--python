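"""Velocity trace container and plain-text trace I/O.

A trace is one player-match instantaneous-velocity series sampled at a
nominal rate (10 Hz for the devices this package targets).  Traces are
stored on disk as two-column CSV (``time_s,velocity_mps``) with a JSON
sidecar carrying player/match/sex metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VelocityTrace",
    "TraceValidationError",
    "TraceParseError",
    "read_trace",
    "write_trace",
]

#: tolerance for matching sample times to the 1/sample_hz lattice (seconds)
TIME_TOL = 1e-9


class TraceValidationError(ValueError):
    """A trace violates its structural invariants."""


class TraceParseError(ValueError):
    """A trace file could not be parsed; message names file and line."""


@dataclass(frozen=True)
class VelocityTrace:
    """One player-match velocity time series.

    Parameters
    ----------
    player_id, match_id : str
        Identifiers carried through to reports.
    sex : str
        Cohort label, ``"male"``, ``"female"`` or ``"other"``.
    sample_hz : float
        Nominal sampling rate in Hz.
    times : ndarray
        Sample times in seconds, strictly increasing.  After cleaning the
        series may contain gaps, but every stamp stays on the original
        1/sample_hz lattice.
    velocities : ndarray
        Instantaneous velocities in m/s, same length as ``times``, all
        finite and non-negative.
    """

    player_id: str
    match_id: str
    sex: str
    sample_hz: float
    times: np.ndarray = field(repr=False)
    velocities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "velocities", v)
        self.validate()

    def validate(self) -> None:
        if self.sex not in ("male", "female", "other"):
            raise TraceValidationError(f"unknown sex label {self.sex!r}")
        if self.sample_hz <= 0:
            raise TraceValidationError("sample_hz must be positive")
        t, v = self.times, self.velocities
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise TraceValidationError("times and velocities must be 1-D and equal length")
        if len(t) == 0:
            raise TraceValidationError("empty trace")
        if not np.all(np.isfinite(v)):
            raise TraceValidationError("velocities must be finite")
        if np.any(v < 0):
            raise TraceValidationError("velocities must be non-negative")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise TraceValidationError("times must be strictly increasing")
        # stamps must sit on the 1/sample_hz lattice (gaps from cleaning allowed)
        step = 1.0 / self.sample_hz
        offsets = (t - t[0]) / step
        if np.any(np.abs(offsets - np.round(offsets)) > TIME_TOL * self.sample_hz):
            raise TraceValidationError("sample times are not on the 1/sample_hz lattice")

    # -- convenience ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        """Effective duration: retained sample count over the sampling rate."""
        return len(self.times) / self.sample_hz

    @property
    def is_uniform(self) -> bool:
        """True when the series has no gaps (constant step 1/sample_hz)."""
        if len(self.times) < 2:
            return True
        step = 1.0 / self.sample_hz
        return bool(np.all(np.abs(np.diff(self.times) - step) <= TIME_TOL))

    def with_samples(self, times: np.ndarray, velocities: np.ndarray) -> "VelocityTrace":
        return replace(self, times=times, velocities=velocities)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "velocity_mps": self.velocities})


def write_trace(trace: VelocityTrace, path: str | Path) -> Path:
    """Write a trace as CSV plus a ``.meta.json`` sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.to_frame().to_csv(path, index=False, float_format="%.6f")
    meta = {
        "player_id": trace.player_id,
        "match_id": trace.match_id,
        "sex": trace.sex,
        "sample_hz": trace.sample_hz,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path, require_uniform: bool = True) -> VelocityTrace:
    """Read a CSV trace (``time_s,velocity_mps``; extra columns ignored).

    Metadata comes from the ``.meta.json`` sidecar when present, otherwise
    from the file name.  Raw files must be uniformly sampled; pass
    ``require_uniform=False`` to re-load already-cleaned traces with gaps.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise TraceParseError(f"{path}: unreadable CSV ({exc})") from exc
    for col in ("time_s", "velocity_mps"):
        if col not in df.columns:
            raise TraceParseError(f"{path}: missing required column {col!r} (line 1)")
    if len(df) == 0:
        raise TraceParseError(f"{path}: no data rows (line 2)")
    for col in ("time_s", "velocity_mps"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2  # +1 header, +1 zero-based
            raise TraceParseError(f"{path}: non-numeric value in {col!r} (line {line})")
        df[col] = coerced
        del bad

    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {"player_id": path.stem, "match_id": path.stem, "sex": "other", "sample_hz": 10.0}

    t = df["time_s"].to_numpy(float)
    hz = float(meta.get("sample_hz", 10.0))
    if require_uniform and len(t) > 1:
        steps = np.diff(t)
        bad = np.abs(steps - 1.0 / hz) > TIME_TOL
        if bad.any():
            line = int(np.argmax(bad)) + 3  # row after the offending step
            raise TraceParseError(f"{path}: non-uniform sampling at line {line}")
    try:
        return VelocityTrace(
            player_id=str(meta.get("player_id", path.stem)),
            match_id=str(meta.get("match_id", path.stem)),
            sex=str(meta.get("sex", "other")),
            sample_hz=hz,
            times=t,
            velocities=df["velocity_mps"].to_numpy(float),
        )
    except TraceValidationError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc
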
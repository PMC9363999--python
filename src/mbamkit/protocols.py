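"""Voltage-clamp command protocols and measurement schedules.

A protocol is an ordered list of segments ``(duration, v_start, v_end)``;
equal start/end voltages give a step, unequal give a linear ramp. Times are
in ms, voltages in mV. The measurement schedule carries the sample times at
which the model output enters the cost function and sensitivity metric.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "VoltageProtocol",
    "MeasurementSchedule",
    "ProtocolError",
    "uniform_schedule",
    "read_protocol_csv",
    "write_protocol_csv",
    "default_mbam_protocol",
]


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    duration: float  # ms
    v_start: float  # mV
    v_end: float  # mV

    def __post_init__(self):
        if not self.duration > 0:
            raise ProtocolError(f"segment duration must be > 0, got {self.duration}")

    @property
    def is_step(self) -> bool:
        return self.v_start == self.v_end


@dataclass(frozen=True)
class VoltageProtocol:
    segments: tuple

    def __post_init__(self):
        if not self.segments:
            raise ProtocolError("protocol must have at least one segment")
        object.__setattr__(
            self, "segments", tuple(s if isinstance(s, Segment) else Segment(*s) for s in self.segments)
        )

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times, prepended with 0."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def voltage_at(self, t: float) -> float:
        """Command voltage at time t (ms).

        Uses the left-closed/right-open convention: at a junction between two
        segments, the later segment's voltage applies. The final endpoint
        ``t == total_duration`` returns the last segment's end voltage.
        """
        T = self.total_duration
        if not (0.0 <= t <= T):
            raise ProtocolError(f"t={t} outside protocol range [0, {T}]")
        b = self.boundaries
        if t == T:
            return float(self.segments[-1].v_end)
        i = int(np.searchsorted(b, t, side="right") - 1)
        seg = self.segments[i]
        if seg.is_step:
            return float(seg.v_start)
        frac = (t - b[i]) / seg.duration
        return float(seg.v_start + frac * (seg.v_end - seg.v_start))

    def voltages(self, times) -> np.ndarray:
        """Vectorised :meth:`voltage_at` over an array of times."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        T = self.total_duration
        if np.any(t < 0) or np.any(t > T):
            raise ProtocolError("times outside protocol range")
        b = self.boundaries
        idx = np.clip(np.searchsorted(b, t, side="right") - 1, 0, len(self.segments) - 1)
        vs = np.array([s.v_start for s in self.segments])
        ve = np.array([s.v_end for s in self.segments])
        dur = np.array([s.duration for s in self.segments])
        frac = (t - b[idx]) / dur[idx]
        return vs[idx] + frac * (ve[idx] - vs[idx])


@dataclass(frozen=True)
class MeasurementSchedule:
    sample_times: tuple  # ms, strictly increasing

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        if t.size == 0:
            raise ProtocolError("schedule must contain at least one sample time")
        if np.any(np.diff(t) <= 0):
            raise ProtocolError("sample times must be strictly increasing")
        object.__setattr__(self, "sample_times", tuple(float(x) for x in t))

    @property
    def count(self) -> int:
        return len(self.sample_times)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.sample_times, dtype=float)


def uniform_schedule(protocol: VoltageProtocol, m: int) -> MeasurementSchedule:
    """M equally spaced sample times spanning ``(0, total_duration]``.

    The first point sits at ``T/M`` and the last at ``T``; t = 0 is excluded
    because the initial condition is known exactly. With a 5000 ms protocol,
    ``m=37`` gives the sparse schedule used for the sensitivity metric and
    ``m=5000`` the 1 ms spacing used for calibration.
    """
    if m < 2:
        raise ProtocolError(f"schedule needs at least 2 points, got {m}")
    T = protocol.total_duration
    times = T * np.arange(1, m + 1) / m
    return MeasurementSchedule(tuple(times))


# ---------------------------------------------------------------------------
# CSV I/O: columns duration_ms, v_start_mV, v_end_mV

_COLUMNS = ["duration_ms", "v_start_mV", "v_end_mV"]


def write_protocol_csv(protocol: VoltageProtocol, path) -> None:
    df = pd.DataFrame(
        [(s.duration, s.v_start, s.v_end) for s in protocol.segments], columns=_COLUMNS
    )
    df.to_csv(path, index=False)


def read_protocol_csv(path) -> VoltageProtocol:
    if isinstance(path, (str,)) or hasattr(path, "read"):
        pass
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ProtocolError(f"cannot read protocol CSV {path!r}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ProtocolError(f"protocol CSV missing columns {missing}")
    segs = []
    for i, row in df.iterrows():
        try:
            segs.append(Segment(float(row[_COLUMNS[0]]), float(row[_COLUMNS[1]]), float(row[_COLUMNS[2]])))
        except (ProtocolError, ValueError) as exc:
            # +2: header line plus 1-based numbering
            raise ProtocolError(f"protocol CSV line {i + 2}: {exc}") from exc
    return VoltageProtocol(tuple(segs))


# ---------------------------------------------------------------------------
# default MBAM protocol

#: A 5000 ms staircase-like step protocol: holding at -80 mV, a brief
#: hyperpolarising dip, an ascending then descending staircase spanning
#: -120..+60 mV, a long depolarisation and a strong repolarising step that
#: elicits a large inward tail current while channels recover from
#: inactivation. Steps only (no ramps) for solver robustness; the exact
#: shape is a documented repository constant, not a reconstruction of any
#: published waveform.
DEFAULT_MBAM_SEGMENTS = (
    (250.0, -80.0, -80.0),
    (200.0, -120.0, -120.0),
    (200.0, -80.0, -80.0),
    (300.0, -40.0, -40.0),
    (300.0, 0.0, 0.0),
    (300.0, 40.0, 40.0),
    (300.0, 60.0, 60.0),
    (300.0, 20.0, 20.0),
    (300.0, -20.0, -20.0),
    (300.0, -60.0, -60.0),
    (450.0, -80.0, -80.0),
    (500.0, 40.0, 40.0),
    (400.0, -120.0, -120.0),
    (400.0, -40.0, -40.0),
    (500.0, -80.0, -80.0),
)


def default_mbam_protocol() -> VoltageProtocol:
    """The package's default 5000 ms staircase-like protocol."""
    return VoltageProtocol(DEFAULT_MBAM_SEGMENTS)
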
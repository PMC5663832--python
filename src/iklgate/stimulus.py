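"""Piecewise-constant voltage-command protocols.

Protocols are ordered lists of (level, duration) segments with optional role
tags (``hold``, ``conditioning``, ``test``).  Segment boundaries are
half-open, [t_start, t_end): the first sample of a step is already at the new
voltage, so "instantaneous" measurements refer to that sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Segment",
    "VoltageProtocol",
    "make_step_protocol",
    "make_activation_family",
    "make_tail_protocol",
]


@dataclass(frozen=True)
class Segment:
    level: float          # mV
    duration: float       # ms
    role: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"segment duration must be positive, got {self.duration!r}")
        if not np.isfinite(self.level):
            raise ValueError("segment level must be finite")


@dataclass(frozen=True)
class VoltageProtocol:
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("protocol needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def boundaries(self) -> np.ndarray:
        """Cumulative segment start/end times, length n_segments + 1."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def segment_by_role(self, role: str) -> tuple[int, Segment]:
        for i, s in enumerate(self.segments):
            if s.role == role:
                return i, s
        raise ValueError(f"protocol has no segment with role {role!r}")

    def segment_sample_counts(self, dt: float) -> list[int]:
        """Samples per segment at step ``dt``; durations must be multiples of dt."""
        counts = []
        for s in self.segments:
            n = s.duration / dt
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise ValueError(
                    f"segment duration {s.duration} ms is not an integer "
                    f"multiple of dt = {dt} ms"
                )
            counts.append(int(round(n)))
        return counts

    def sample_voltages(self, dt: float) -> np.ndarray:
        """Command voltage on the grid t_k = k*dt, k = 0 .. total/dt - 1."""
        counts = self.segment_sample_counts(dt)
        return np.concatenate(
            [np.full(n, s.level) for n, s in zip(counts, self.segments)]
        )

    # --- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            [
                {"level_mV": s.level, "duration_ms": s.duration, "role": s.role}
                for s in self.segments
            ]
        )

    @classmethod
    def from_json(cls, text: str) -> "VoltageProtocol":
        items = json.loads(text)
        return cls(
            tuple(
                Segment(float(d["level_mV"]), float(d["duration_ms"]), d.get("role"))
                for d in items
            )
        )


def make_step_protocol(
    v_hold: float, hold_ms: float, v_step: float, step_ms: float
) -> VoltageProtocol:
    """Hold then a single test step."""
    return VoltageProtocol(
        (Segment(v_hold, hold_ms, "hold"), Segment(v_step, step_ms, "test"))
    )


def make_activation_family(
    v_hold: float,
    v_first: float,
    v_last: float,
    increment: float,
    step_ms: float,
    hold_ms: float = 1000.0,
) -> list[VoltageProtocol]:
    """One step protocol per test voltage, v_first .. v_last by ``increment``."""
    if increment == 0:
        raise ValueError("increment must be nonzero")
    span = v_last - v_first
    n = span / increment
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"range {v_first}..{v_last} mV is not divisible by {increment} mV"
        )
    n = int(round(n))
    if n < 0:
        raise ValueError("v_last lies opposite to the increment direction")
    levels = [v_first + k * increment for k in range(n + 1)]
    return [make_step_protocol(v_hold, hold_ms, lv, step_ms) for lv in levels]


def make_tail_protocol(
    v_hold: float,
    v_cond: float,
    cond_ms: float,
    v_test: float,
    test_ms: float = 1000.0,
    hold_ms: float = 1000.0,
) -> VoltageProtocol:
    """Hold / conditioning / test three-segment protocol for tail currents."""
    return VoltageProtocol(
        (
            Segment(v_hold, hold_ms, "hold"),
            Segment(v_cond, cond_ms, "conditioning"),
            Segment(v_test, test_ms, "test"),
        )
    )
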
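"""Macroscopic currents, state-occupancy time courses and tail measurements.

The macroscopic current (arbitrary units) is the open-channel fraction times
the driving force,

    I(t) = g_norm * P_open(t) * (V(t) - v_rev),

with the occupancy vector integrated by forward Euler through the voltage
protocol.  Unless an explicit initial distribution is supplied, the
simulation starts at the steady state of the first (holding) segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gating import (
    N_STATES,
    OPEN_MASK,
    GatingScheme,
    SimulationSettings,
    build_generator,
    propagator_matrix,
    steady_state,
)
from .stimulus import VoltageProtocol

__all__ = [
    "CurrentTrace",
    "TailMeasurement",
    "simulate_current",
    "occupancy_timecourse",
    "measure_instantaneous_tail",
    "activation_curve",
]


@dataclass
class CurrentTrace:
    """Uniformly sampled time / command-voltage / current series.

    ``occupancies`` (n_samples x 10, state order C0..C4, O0..O4) is attached
    when the simulation recorded it.  ``meta`` carries provenance (protocol,
    parameters, seeds, distortions).
    """

    time: np.ndarray          # ms
    voltage: np.ndarray       # mV (command)
    current: np.ndarray       # a.u.
    occupancies: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        n = self.time.size
        if self.voltage.size != n or self.current.size != n:
            raise ValueError("time, voltage and current must have equal length")
        if n >= 2:
            dts = np.diff(self.time)
            if np.any(dts <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time grid must be uniform")
        if self.occupancies is not None:
            self.occupancies = np.asarray(self.occupancies, dtype=float)
            if self.occupancies.shape != (n, N_STATES):
                raise ValueError("occupancies must be n_samples x 10")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else np.nan

    def slice(self, t0: float, t1: float) -> "CurrentTrace":
        """Samples with t0 <= t < t1 (half-open, like protocol segments)."""
        m = (self.time >= t0 - 1e-12) & (self.time < t1 - 1e-12)
        return CurrentTrace(
            self.time[m],
            self.voltage[m],
            self.current[m],
            None if self.occupancies is None else self.occupancies[m],
            dict(self.meta),
        )


@dataclass(frozen=True)
class TailMeasurement:
    """Instantaneous tail amplitude after one conditioning step."""

    v_cond: float             # mV, possibly R_s-corrected
    amplitude: float          # a.u.

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude):
            raise ValueError("tail amplitude must be finite")


def simulate_current(
    protocol: VoltageProtocol,
    scheme: GatingScheme,
    settings: SimulationSettings | None = None,
    record_occupancies: bool = True,
    initial: np.ndarray | None = None,
) -> CurrentTrace:
    """Integrate the gating model through ``protocol`` and return the current.

    Sample k lies at t = k*dt; the occupancy at a sample is the state reached
    after integrating up to that time, so the first sample of a step pairs
    the pre-step occupancy with the new driving force (the instantaneous
    current convention).
    """
    settings = settings or SimulationSettings()
    dt = settings.dt
    counts = protocol.segment_sample_counts(dt)
    n_total = int(sum(counts))

    p = steady_state(scheme, protocol.segments[0].level) if initial is None \
        else np.asarray(initial, dtype=float).copy()
    if p.shape != (N_STATES,):
        raise ValueError("initial distribution must have 10 entries")

    occ = np.empty((n_total, N_STATES))
    volt = np.empty(n_total)
    renorm = settings.renormalize_each_step
    k = 0
    for seg, n in zip(protocol.segments, counts):
        step = propagator_matrix(build_generator(scheme, seg.level), dt)
        for _ in range(n):
            occ[k] = p
            volt[k] = seg.level
            p = p @ step
            if renorm:
                p = p / p.sum()
            k += 1

    time = np.arange(n_total) * dt
    p_open = occ[:, OPEN_MASK].sum(axis=1)
    current = settings.g_norm * p_open * (volt - settings.v_rev)
    meta = {
        "protocol": [
            {"level_mV": s.level, "duration_ms": s.duration, "role": s.role}
            for s in protocol.segments
        ],
        "params": scheme.params.to_dict(),
        "dt": dt,
        "v_rev": settings.v_rev,
        "g_norm": settings.g_norm,
    }
    return CurrentTrace(
        time, volt, current,
        occ if record_occupancies else None,
        meta,
    )


def occupancy_timecourse(trace: CurrentTrace) -> np.ndarray:
    """Per-state occupancies as percentages (n_samples x 10, rows sum to 100)."""
    if trace.occupancies is None:
        raise ValueError("trace carries no occupancies")
    return trace.occupancies * 100.0


def _test_onset_index(trace: CurrentTrace, protocol: VoltageProtocol) -> int:
    idx, _ = protocol.segment_by_role("test")
    t_start = protocol.boundaries()[idx]
    return int(round(t_start / trace.dt))


def measure_instantaneous_tail(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    window_ms: float = 0.0,
) -> TailMeasurement:
    """Instantaneous current at the onset of the test segment.

    For noise-free traces the amplitude is the first sample of the test
    segment; a positive ``window_ms`` takes the median over that initial
    window instead (robust choice for noisy fixtures).
    """
    k0 = _test_onset_index(trace, protocol)
    if window_ms > 0:
        k1 = min(trace.time.size, k0 + max(1, int(round(window_ms / trace.dt))))
        amp = float(np.median(trace.current[k0:k1]))
    else:
        amp = float(trace.current[k0])
    _, cond = protocol.segment_by_role("conditioning")
    return TailMeasurement(v_cond=cond.level, amplitude=amp)


def activation_curve(
    protocols: Sequence[VoltageProtocol],
    scheme: GatingScheme,
    settings: SimulationSettings | None = None,
    rs: float = 0.0,
    current_scale: float = 1.0,
    window_ms: float = 0.0,
) -> list[TailMeasurement]:
    """Normalized tail-current activation curve from a conditioning family.

    Each protocol is simulated, the instantaneous tail is measured at the
    common test potential, amplitudes are min/max normalized to [0, 1], and
    when ``rs`` (MOhm) is positive the conditioning voltages are corrected
    for the ohmic drop of the instantaneous tail current (``current_scale``
    converts a.u. to nA).
    """
    from .fitting import rs_correct  # local import to avoid a cycle

    if len(protocols) < 4:
        raise ValueError("need at least 4 conditioning levels to define a curve")
    test_levels = {p.segment_by_role("test")[1].level for p in protocols}
    if len(test_levels) != 1:
        raise ValueError("all protocols must share the same test potential")

    raw = [
        measure_instantaneous_tail(
            simulate_current(p, scheme, settings, record_occupancies=False),
            p,
            window_ms=window_ms,
        )
        for p in protocols
    ]
    amps = np.array([m.amplitude for m in raw])
    span = amps.max() - amps.min()
    if span <= 0:
        raise ValueError("tail amplitudes are constant; cannot normalize")
    normalized = (amps - amps.min()) / span

    out = []
    for m, a in zip(raw, normalized):
        v = m.v_cond
        if rs > 0:
            v = rs_correct(m.v_cond, m.amplitude * current_scale, rs).v_corrected
        out.append(TailMeasurement(v_cond=v, amplitude=float(a)))
    return out
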
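"""Plain-text readers/writers for traces, parameters and fit results.

Traces are tab-separated text with a one-line header (``time_ms  v_mV  i_au``
plus optional occupancy columns ``c0..c4 o0..o4``) and a JSON sidecar
``<file>.json`` carrying provenance (protocol, parameters, dt, seeds).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .currents import CurrentTrace
from .gating import N_STATES, STATE_LABELS, RateParameters, SimulationSettings

__all__ = ["write_trace", "read_trace", "write_params", "read_params"]

_OCC_COLUMNS = [s.lower() for s in STATE_LABELS]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    """Write a trace as TSV plus a ``<path>.json`` provenance sidecar."""
    path = Path(path)
    cols = [trace.time, trace.voltage, trace.current]
    header = ["time_ms", "v_mV", "i_au"]
    if trace.occupancies is not None:
        cols.extend(trace.occupancies.T)
        header.extend(_OCC_COLUMNS)
    data = np.column_stack(cols)
    np.savetxt(path, data, fmt="%.17g", delimiter="\t",
               header="\t".join(header), comments="")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(_jsonable(trace.meta), indent=1))


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a trace written by :func:`write_trace` (lossless round-trip)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    expected_min = ["time_ms", "v_mV", "i_au"]
    if header[:3] != expected_min:
        raise ValueError(
            f"{path}:1: malformed header {header[:3]!r}, expected {expected_min}"
        )
    has_occ = len(header) > 3
    if has_occ and header[3:] != _OCC_COLUMNS:
        raise ValueError(f"{path}:1: unexpected occupancy columns {header[3:]!r}")

    data = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
    if data.shape[1] != len(header):
        raise ValueError(f"{path}: column count does not match header")
    time = data[:, 0]
    dts = np.diff(time)
    if time.size >= 2:
        bad = np.nonzero(~np.isclose(dts, dts[0], rtol=1e-9, atol=1e-12))[0]
        if dts[0] <= 0 or bad.size:
            line = (bad[0] + 3) if bad.size else 2  # +1 header, +1 one-based
            raise ValueError(f"{path}:{line}: non-uniform or non-increasing time grid")

    meta = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    occ = data[:, 3:3 + N_STATES] if has_occ else None
    return CurrentTrace(time, data[:, 1], data[:, 2], occ, meta)


def write_params(
    params: RateParameters,
    settings: SimulationSettings | None,
    path: str | Path,
) -> None:
    """Flat JSON key-value parameter file."""
    d = params.to_dict()
    if settings is not None:
        d.update(dt=settings.dt, v_rev=settings.v_rev, g_norm=settings.g_norm)
    Path(path).write_text(json.dumps(d, indent=1))


def read_params(path: str | Path) -> tuple[RateParameters, SimulationSettings]:
    d = json.loads(Path(path).read_text())
    known = {"alpha0", "beta0", "k_alpha", "k_beta", "a", "b", "c_on", "c_off",
             "variant", "multiplicity", "dt", "v_rev", "g_norm",
             "renormalize_each_step"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown parameter keys {sorted(unknown)}")
    settings = SimulationSettings(
        dt=d.pop("dt", 0.1),
        v_rev=d.pop("v_rev", -76.0),
        g_norm=d.pop("g_norm", 1.0),
        renormalize_each_step=d.pop("renormalize_each_step", True),
    )
    return RateParameters.from_dict(d), settings
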
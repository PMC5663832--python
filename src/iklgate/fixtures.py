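"""Synthetic voltage-clamp fixtures: noise, series resistance, calyx cleft.

These generators stand in for recorded data.  They add, on top of the clean
model current, the main artifacts of whole-cell recordings from type I hair
cells still partly enveloped by their afferent calyx:

* additive Gaussian instrumentation noise;
* the ohmic voltage error over the residual series resistance R_s, which
  makes the membrane see less than the command voltage whenever current
  flows;
* K+ accumulation in the residual synaptic cleft, modelled as a single
  well-mixed compartment with first-order clearance and a Nernstian
  reversal potential, which produces the characteristic outward-current
  relaxation during depolarizing steps and the depolarizing shift of the
  tail-current reversal afterwards.

The cleft model is deliberately minimal and entirely synthetic: it
reproduces the phenomenology qualitatively and is not a quantitative model
of calyx geometry or clearance.  All generators are deterministic given
their settings (and seed, where noise is involved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .currents import CurrentTrace, simulate_current
from .gating import (
    N_STATES,
    OPEN_MASK,
    GatingScheme,
    SimulationSettings,
    generator_parts,
    propagator_matrix,
    steady_state,
)
from .stimulus import VoltageProtocol

__all__ = [
    "NoiseSettings",
    "CleftSettings",
    "nernst_potential",
    "generate_noisy_trace",
    "generate_calyx_trace",
    "generate_rs_trace",
]

GAS_CONSTANT = 8.314462618       # J / (mol K)
FARADAY = 96485.33212            # C / mol

#: mM per (nA * ms / fL): 1e-9 A * 1e-3 s / F, per 1e-15 L, in mmol/L.
_NA_MS_PER_FL_TO_MM = 1e-12 / FARADAY / 1e-15 * 1e3


@dataclass(frozen=True)
class NoiseSettings:
    """Additive white Gaussian noise of SD ``sigma`` (a.u.) per sample."""

    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class CleftSettings:
    """Single-compartment residual-cleft model.

    Defaults are illustrative: they make a 1-s strong depolarizing step
    shift the K+ reversal potential by roughly +40 mV, with tail currents
    re-equilibrating within a few milliseconds of clearance time.
    """

    cleft_volume: float = 11.0      # fL
    clearance_tau: float = 5.0      # ms; np.inf disables clearance
    k_bath: float = 5.8             # mM
    k_in: float = 131.0             # mM
    temperature: float = 24.0       # degrees C
    current_scale: float = 0.1      # nA per a.u.

    def __post_init__(self) -> None:
        for name in ("cleft_volume", "clearance_tau", "k_bath", "k_in",
                     "current_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def nernst_potential(k_out: float, k_in: float, temperature: float = 24.0) -> float:
    """Nernst equilibrium potential for K+ in mV.

    With physiological concentrations (5.8 mM outside, 131 mM inside) at
    24 C this evaluates to about -80 mV.
    """
    if k_out <= 0 or k_in <= 0:
        raise ValueError("concentrations must be positive")
    rt_over_f = GAS_CONSTANT * (temperature + 273.15) / FARADAY * 1e3  # mV
    return float(rt_over_f * np.log(k_out / k_in))


def generate_noisy_trace(
    protocol: VoltageProtocol,
    scheme: GatingScheme,
    settings: SimulationSettings | None = None,
    noise: NoiseSettings = NoiseSettings(),
) -> CurrentTrace:
    """Clean simulated current plus i.i.d. Gaussian noise (seeded)."""
    trace = simulate_current(protocol, scheme, settings)
    rng = np.random.default_rng(noise.seed)
    trace.current = trace.current + rng.normal(0.0, noise.sigma, trace.current.size)
    trace.meta["noise"] = {"sigma": noise.sigma, "seed": noise.seed}
    return trace


def generate_calyx_trace(
    protocol: VoltageProtocol,
    scheme: GatingScheme,
    settings: SimulationSettings | None = None,
    cleft: CleftSettings = CleftSettings(),
) -> CurrentTrace:
    """Current distorted by K+ accumulation in a residual-cleft compartment.

    The cleft concentration follows

        d[K]/dt = I * current_scale / (F * volume) - ([K] - k_bath) / tau,

    integrated with an exponential update (exact for a sample-constant
    current), and the reversal potential at each sample is the clean
    ``v_rev`` shifted by the Nernstian displacement
    nernst([K]) - nernst(k_bath).  As clearance_tau -> 0 the trace
    converges to the clean trace.
    """
    settings = settings or SimulationSettings()
    trace = simulate_current(protocol, scheme, settings)
    occ = trace.occupancies
    p_open = occ[:, OPEN_MASK].sum(axis=1)

    dt = settings.dt
    tau = cleft.clearance_tau
    k = cleft.k_bath
    shift0 = nernst_potential(cleft.k_bath, cleft.k_in, cleft.temperature)
    influx_per_nA = _NA_MS_PER_FL_TO_MM / cleft.cleft_volume  # mM per nA*ms
    decay = np.exp(-dt / tau) if np.isfinite(tau) else 1.0

    current = np.empty_like(trace.current)
    k_series = np.empty_like(trace.current)
    for i in range(current.size):
        v_rev_i = settings.v_rev + (
            nernst_potential(k, cleft.k_in, cleft.temperature) - shift0
        )
        current[i] = settings.g_norm * p_open[i] * (trace.voltage[i] - v_rev_i)
        k_series[i] = k
        influx = current[i] * cleft.current_scale * influx_per_nA  # mM/ms
        if np.isfinite(tau):
            target = cleft.k_bath + influx * tau
            k = target + (k - target) * decay
        else:
            k = k + influx * dt
        if k <= 0:
            raise ValueError(
                "cleft [K+] driven non-positive; cleft parameters unphysical"
            )

    trace.current = current
    trace.meta["cleft"] = {
        "cleft_volume_fL": cleft.cleft_volume,
        "clearance_tau_ms": cleft.clearance_tau,
        "k_bath_mM": cleft.k_bath,
        "k_in_mM": cleft.k_in,
        "temperature_C": cleft.temperature,
        "current_scale_nA_per_au": cleft.current_scale,
    }
    trace.meta["cleft_k_final_mM"] = float(k)
    return trace


def generate_rs_trace(
    protocol: VoltageProtocol,
    scheme: GatingScheme,
    settings: SimulationSettings | None = None,
    rs: float = 3.0,
    current_scale: float = 0.05,
) -> CurrentTrace:
    """Current recorded through a residual series resistance ``rs`` (MOhm).

    At each sample the membrane voltage satisfies the ohmic balance
    V_m = V_cmd - I * rs (with I = g * P_open * (V_m - v_rev) converted to
    nA by ``current_scale``); because the current is linear in V_m the
    balance is solved in closed form, and gating is integrated at V_m.
    The meta field ``max_v_drop_mV`` reports max |I * rs| for comparison
    with the 6 mV discard rule.
    """
    settings = settings or SimulationSettings()
    if rs < 0:
        raise ValueError("rs must be non-negative")
    dt = settings.dt
    volt_cmd = protocol.sample_voltages(dt)
    n = volt_cmd.size
    qc, qa, qb = generator_parts(scheme)
    params = scheme.params
    eye = np.eye(N_STATES)

    p = steady_state(scheme, protocol.segments[0].level)
    occ = np.empty((n, N_STATES))
    current = np.empty(n)
    v_mem = np.empty(n)
    rs_scale = rs * current_scale  # mV per a.u.
    for i in range(n):
        occ[i] = p
        po = float(p[OPEN_MASK].sum())
        g_po = settings.g_norm * po
        denom = 1.0 + g_po * rs_scale
        if denom <= 0:
            raise RuntimeError("series-resistance balance has no solution")
        vm = (volt_cmd[i] + g_po * rs_scale * settings.v_rev) / denom
        v_mem[i] = vm
        current[i] = g_po * (vm - settings.v_rev)
        alpha = params.alpha0 * np.exp(vm / params.k_alpha)
        beta = params.beta0 * np.exp(-vm / params.k_beta)
        q = qc + alpha * qa + beta * qb
        p = p @ propagator_matrix(q, dt)
        if settings.renormalize_each_step:
            p = p / p.sum()

    time = np.arange(n) * dt
    trace = CurrentTrace(time, volt_cmd, current, occ, {
        "protocol": [
            {"level_mV": s.level, "duration_ms": s.duration, "role": s.role}
            for s in protocol.segments
        ],
        "params": params.to_dict(),
        "dt": dt,
        "v_rev": settings.v_rev,
        "g_norm": settings.g_norm,
        "rs_MOhm": rs,
        "current_scale_nA_per_au": current_scale,
        "max_v_drop_mV": float(np.max(np.abs(current * rs_scale))),
    })
    return trace
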
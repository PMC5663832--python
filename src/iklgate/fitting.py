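"""Fitting functions for activation onset, steady-state activation and decay.

Three functional forms are used to characterize I_K,L:

* onset of activation — a two-component function in which a slow
  mono-exponential term is gated by the fast sigmoid,

      I(t) = A [ A1*(1 - exp(-t/tau_f))^n
               + A2*(1 - exp(-t/tau_s)) (1 - exp(-t/tau_f))^n ] + C,

  with A1 + A2 = 1 (relative component amplitudes), a fast and a slow time
  constant tau_f < tau_s, and an exponential power n setting the sigmoidal
  lag;

* steady-state activation — a Boltzmann curve
  I(V) = I_max + (I_min - I_max) / (1 + exp((V - V_half)/S));

* deactivation — a sum of one or two decaying exponentials plus offset.

All fits are unweighted least squares (scipy.optimize.least_squares) with
standard deviations from the linearized covariance at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .currents import CurrentTrace, TailMeasurement

__all__ = [
    "OnsetFitParams",
    "OnsetFitResult",
    "BoltzmannFitResult",
    "ExpDecayFitResult",
    "RsCorrection",
    "eval_onset",
    "fit_onset",
    "eval_boltzmann",
    "fit_boltzmann",
    "fit_deactivation",
    "rs_correct",
]

ONSET_PARAM_NAMES = ("A", "a2_bar", "tau_f", "tau_s", "n", "c")

#: Ohmic drop above which a recording would be discarded (mV).
RS_DISCARD_MV = 6.0


@dataclass(frozen=True)
class OnsetFitParams:
    """Parameters of the activation-onset function.

    ``a2_bar`` is the relative amplitude of the slow component
    (A2/(A1 + A2)); the fast relative amplitude is 1 - a2_bar by
    construction.
    """

    A: float                # overall steady-state amplitude (a.u.)
    a2_bar: float           # relative slow amplitude, 0..1
    tau_f: float            # ms
    tau_s: float            # ms
    n: float                # exponential power
    c: float = 0.0          # offset (a.u.)

    def __post_init__(self) -> None:
        if not 0.0 <= self.a2_bar <= 1.0:
            raise ValueError("a2_bar must lie in [0, 1]")
        if self.tau_f <= 0 or self.tau_s <= 0:
            raise ValueError("time constants must be positive")
        if self.n <= 0:
            raise ValueError("n must be positive")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ONSET_PARAM_NAMES}


@dataclass(frozen=True)
class OnsetFitResult:
    params: OnsetFitParams
    sd: dict[str, float]          # per free parameter; fixed params absent
    rss: float
    window: tuple[float, float]   # fitted time range (ms, trace coordinates)
    degenerate: bool = False


@dataclass(frozen=True)
class BoltzmannFitResult:
    i_min: float
    i_max: float
    v_half: float                 # mV
    s: float                      # mV per e-fold
    sd: dict[str, float] = field(default_factory=dict)
    rss: float = np.nan

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("S must be positive")
        if self.i_max <= self.i_min:
            raise ValueError("I_max must exceed I_min")


@dataclass(frozen=True)
class ExpDecayFitResult:
    components: tuple[tuple[float, float], ...]   # (amplitude, tau), tau ascending
    offset: float
    rss: float

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class RsCorrection:
    v_corrected: float
    v_drop: float
    discard: bool


# --------------------------------------------------------------------------
# onset of activation
# --------------------------------------------------------------------------

def eval_onset(t: np.ndarray | float, p: OnsetFitParams) -> np.ndarray | float:
    """Evaluate the activation-onset function at times ``t`` (ms, >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    fast = 1.0 - np.exp(-t / p.tau_f)
    slow = 1.0 - np.exp(-t / p.tau_s)
    y = p.A * ((1.0 - p.a2_bar) * fast ** p.n + p.a2_bar * slow * fast ** p.n) + p.c
    return y if y.ndim else float(y)


def _onset_initial_guess(t: np.ndarray, y: np.ndarray) -> OnsetFitParams:
    c0 = float(y[0])
    a0 = float(y[-1] - y[0])
    span = a0 if a0 != 0 else 1.0
    rise = (y - y[0]) / span
    # tau_f from the 10-90% rise time (2.2 tau for a single exponential)
    idx10 = np.nonzero(rise >= 0.1)[0]
    idx90 = np.nonzero(rise >= 0.9)[0]
    if idx10.size and idx90.size and t[idx90[0]] > t[idx10[0]]:
        tau_f0 = (t[idx90[0]] - t[idx10[0]]) / 2.2
    else:
        tau_f0 = (t[-1] - t[0]) / 10.0
    tau_f0 = max(tau_f0, t[1] - t[0])
    return OnsetFitParams(A=a0 if a0 != 0 else 1.0, a2_bar=0.6,
                          tau_f=tau_f0, tau_s=10.0 * tau_f0, n=2.0, c=c0)


def _covariance(res, n_free: int) -> np.ndarray | None:
    m = res.fun.size
    if m <= n_free:
        return None
    rss = float(res.fun @ res.fun)
    j = res.jac
    try:
        cov = np.linalg.inv(j.T @ j) * rss / (m - n_free)
    except np.linalg.LinAlgError:
        return None
    return cov


def fit_onset(
    trace: CurrentTrace,
    window: tuple[float, float] | None = None,
    init: OnsetFitParams | None = None,
    fixed: dict[str, float] | None = None,
    max_points: int = 4000,
) -> OnsetFitResult:
    """Least-squares fit of the onset function to a depolarizing step.

    ``window`` is a (t0, t1) range in trace time; by default the test
    segment (from the protocol stored in ``trace.meta``) or, absent that,
    the whole trace is fitted, with time re-zeroed at the window start.
    Parameters listed in ``fixed`` (name -> value) are held constant and
    get no standard deviation.  The ordering tau_f < tau_s is enforced by
    fitting tau_s as tau_f + delta with delta > 0.
    """
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(ONSET_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown fixed parameters {sorted(unknown)}")

    t0, t1 = _resolve_window(trace, window)
    m = (trace.time >= t0 - 1e-12) & (trace.time <= t1 + 1e-12)
    t = trace.time[m] - trace.time[m][0]
    y = trace.current[m]
    if t.size < 50:
        raise ValueError(f"fit window holds only {t.size} samples (< 50)")
    if max_points and t.size > max_points:
        # uniform decimation: keeps the unweighted-LS estimate on a uniform
        # grid while bounding the optimizer cost on long traces
        stride = int(np.ceil(t.size / max_points))
        t, y = t[::stride], y[::stride]

    # degenerate (flat) input: report a zero-amplitude fit
    if np.ptp(y) < 1e-12 * max(1.0, abs(y[0])):
        p = OnsetFitParams(A=0.0 if "A" not in fixed else fixed["A"],
                           a2_bar=0.5, tau_f=1.0, tau_s=2.0, n=1.0,
                           c=float(y[0]))
        return OnsetFitResult(p, {}, 0.0, (t0, t1), degenerate=True)

    p0 = init or _onset_initial_guess(t, y)

    # internal vector: (A, a2_bar, tau_f, delta, n, c), delta = tau_s - tau_f
    full0 = np.array([p0.A, p0.a2_bar, p0.tau_f,
                      max(p0.tau_s - p0.tau_f, 1e-6), p0.n, p0.c])
    lo = np.array([-np.inf, 0.0, 1e-6, 1e-9, 0.5, -np.inf])
    hi = np.array([np.inf, 1.0, np.inf, np.inf, 6.0, np.inf])

    internal_names = ["A", "a2_bar", "tau_f", "delta", "n", "c"]
    fixed_internal: dict[int, float] = {}
    for name, value in fixed.items():
        if name == "tau_s":
            if "tau_f" in fixed:
                fixed_internal[3] = value - fixed["tau_f"]
            else:
                # tau_s pinned while tau_f floats: bound tau_f from above
                hi[2] = value
                fixed_internal[-1] = value  # sentinel handled below
        else:
            fixed_internal[internal_names.index(name)] = value

    tau_s_pinned = fixed_internal.pop(-1, None)
    free_idx = [i for i in range(6) if i not in fixed_internal]
    if tau_s_pinned is not None and 3 in free_idx:
        free_idx.remove(3)

    def expand(theta: np.ndarray) -> np.ndarray:
        full = np.empty(6)
        for i, v in fixed_internal.items():
            full[i] = v
        full[free_idx] = theta
        if tau_s_pinned is not None:
            full[3] = tau_s_pinned - full[2]
        return full

    def unpack(full: np.ndarray) -> OnsetFitParams:
        return OnsetFitParams(A=full[0], a2_bar=min(max(full[1], 0.0), 1.0),
                              tau_f=full[2], tau_s=full[2] + max(full[3], 1e-12),
                              n=full[4], c=full[5])

    def residuals(theta: np.ndarray) -> np.ndarray:
        return eval_onset(t, unpack(expand(theta))) - y

    theta0 = np.clip(full0[free_idx], lo[free_idx], hi[free_idx])
    res = least_squares(residuals, theta0,
                        bounds=(lo[free_idx], hi[free_idx]),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20000)
    if not res.success:
        raise RuntimeError(f"onset fit failed to converge: {res.message}")

    full = expand(res.x)
    params = unpack(full)
    rss = float(res.fun @ res.fun)

    sd: dict[str, float] = {}
    cov = _covariance(res, len(free_idx))
    if cov is not None:
        var = {internal_names[i]: cov[k, k] for k, i in enumerate(free_idx)}
        pos = {internal_names[i]: k for k, i in enumerate(free_idx)}
        for name in ONSET_PARAM_NAMES:
            if name in fixed:
                continue
            if name == "tau_s":
                if tau_s_pinned is not None:
                    continue
                # tau_s = tau_f + delta
                g = np.zeros(len(free_idx))
                if "tau_f" in pos:
                    g[pos["tau_f"]] = 1.0
                if "delta" in pos:
                    g[pos["delta"]] = 1.0
                sd[name] = float(np.sqrt(max(g @ cov @ g, 0.0)))
            elif name in var:
                sd[name] = float(np.sqrt(max(var[name], 0.0)))
    return OnsetFitResult(params, sd, rss, (t0, t1))


def _resolve_window(
    trace: CurrentTrace, window: tuple[float, float] | None
) -> tuple[float, float]:
    if window is not None:
        return float(window[0]), float(window[1])
    segs = trace.meta.get("protocol")
    if segs:
        start = 0.0
        for s in segs:
            if s.get("role") == "test":
                return start, start + s["duration_ms"] - trace.dt
            start += s["duration_ms"]
    return float(trace.time[0]), float(trace.time[-1])


# --------------------------------------------------------------------------
# Boltzmann steady-state activation
# --------------------------------------------------------------------------

def eval_boltzmann(
    v: np.ndarray | float, i_min: float, i_max: float, v_half: float, s: float
) -> np.ndarray | float:
    """Boltzmann curve; rises from i_min to i_max with midpoint v_half."""
    v = np.asarray(v, dtype=float)
    y = i_max + (i_min - i_max) / (1.0 + np.exp((v - v_half) / s))
    return y if y.ndim else float(y)


def fit_boltzmann(
    curve: Sequence[TailMeasurement] | Sequence[tuple[float, float]],
) -> BoltzmannFitResult:
    """Fit a Boltzmann function to (conditioning voltage, amplitude) points."""
    pts = [(m.v_cond, m.amplitude) if isinstance(m, TailMeasurement) else m
           for m in curve]
    if len(pts) < 4:
        raise ValueError("need at least 4 points spanning the transition")
    v = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)

    i_min0, i_max0 = float(y.min()), float(y.max())
    half = (i_min0 + i_max0) / 2.0
    v_half0 = float(v[np.argmin(np.abs(y - half))])
    s_lo, s_hi = 1e-3, 100.0

    def residuals(theta):
        return eval_boltzmann(v, *theta) - y

    res = least_squares(
        residuals,
        np.array([i_min0, i_max0, v_half0, 3.0]),
        bounds=([-np.inf, -np.inf, v.min() - 50.0, s_lo],
                [np.inf, np.inf, v.max() + 50.0, s_hi]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20000,
    )
    if not res.success:
        raise RuntimeError(f"Boltzmann fit failed to converge: {res.message}")
    i_min, i_max, v_half, s = res.x
    if s <= s_lo * 1.01 or s >= s_hi * 0.99:
        raise RuntimeError(f"fitted slope S = {s:.3g} mV is at its bound")
    rss = float(res.fun @ res.fun)
    names = ("i_min", "i_max", "v_half", "s")
    cov = _covariance(res, 4)
    sd = {} if cov is None else {
        nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)
    }
    return BoltzmannFitResult(float(i_min), float(i_max), float(v_half),
                              float(s), sd, rss)


# --------------------------------------------------------------------------
# exponential deactivation
# --------------------------------------------------------------------------

def fit_deactivation(
    trace: CurrentTrace,
    n_components: int = 2,
    window: tuple[float, float] | None = None,
) -> ExpDecayFitResult:
    """Sum-of-exponentials fit of a decaying (repolarization) segment.

    By default the last protocol segment in ``trace.meta`` (or the whole
    trace) is fitted; time is re-zeroed at the window start.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if window is None:
        segs = trace.meta.get("protocol")
        if segs:
            start = sum(s["duration_ms"] for s in segs[:-1])
            window = (start, float(trace.time[-1]))
        else:
            window = (float(trace.time[0]), float(trace.time[-1]))
    m = (trace.time >= window[0] - 1e-12) & (trace.time <= window[1] + 1e-12)
    t = trace.time[m] - trace.time[m][0]
    y = trace.current[m]
    if t.size < 10:
        raise ValueError("decay window too short")

    offset0 = float(y[-1])
    amp0 = float(y[0] - y[-1])
    # crude tau: time at which the decay has completed 1 - 1/e of its span
    span = amp0 if amp0 != 0 else 1.0
    frac = (y - y[-1]) / span
    below = np.nonzero(frac <= np.exp(-1.0))[0]
    tau0 = float(t[below[0]]) if below.size else float(t[-1] / 3.0)
    tau0 = max(tau0, float(t[1] - t[0]))

    if n_components == 1:
        starts = [np.array([amp0, tau0, offset0])]
        lo = [-np.inf, 1e-6, -np.inf]
        hi = [np.inf, np.inf, np.inf]

        def model(theta):
            a, tau, c = theta
            return a * np.exp(-t / tau) + c
    else:
        # multiple tau splits: decays with well-separated components (e.g. a
        # fast closing step plus slow chain unwinding) trap single-start
        # fits in a degenerate equal-tau solution
        starts = [
            np.array([amp0 * f, tau0 * r1, amp0 * (1 - f), tau0 * r2, offset0])
            for (f, r1, r2) in ((0.5, 1 / 3, 3.0), (0.5, 0.02, 1.0),
                                (0.3, 0.005, 1.0), (0.5, 1.0, 5.0))
        ]
        lo = [-np.inf, 1e-6, -np.inf, 1e-6, -np.inf]
        hi = [np.inf, np.inf, np.inf, np.inf, np.inf]

        def model(theta):
            a1, t1, a2, t2, c = theta
            return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + c

    best = None
    failure = None
    for theta0 in starts:
        try:
            res = least_squares(lambda th: model(th) - y, theta0,
                                bounds=(lo, hi),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=20000)
        except Exception as e:  # pragma: no cover - defensive
            failure = e
            continue
        if res.success and (best is None or
                            float(res.fun @ res.fun) < float(best.fun @ best.fun)):
            best = res
    if best is None:
        raise RuntimeError(f"deactivation fit failed to converge: {failure}")
    res = best
    rss = float(res.fun @ res.fun)
    if n_components == 1:
        comps = [(float(res.x[0]), float(res.x[1]))]
        offset = float(res.x[2])
    else:
        comps = [(float(res.x[0]), float(res.x[1])),
                 (float(res.x[2]), float(res.x[3]))]
        offset = float(res.x[4])
    comps.sort(key=lambda c: c[1])
    return ExpDecayFitResult(tuple(comps), offset, rss)


# --------------------------------------------------------------------------
# series-resistance correction
# --------------------------------------------------------------------------

def rs_correct(v_cmd: float, i: float, rs: float) -> RsCorrection:
    """Correct a command voltage for the ohmic drop over the residual R_s.

    ``i`` in nA, ``rs`` in MOhm, so the drop i*rs is in mV.  The ``discard``
    flag marks drops exceeding 6 mV, the acceptance limit for recordings.
    """
    if rs < 0:
        raise ValueError("rs must be non-negative")
    drop = i * rs
    return RsCorrection(
        v_corrected=v_cmd - drop,
        v_drop=drop,
        discard=abs(drop) > RS_DISCARD_MV,
    )
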
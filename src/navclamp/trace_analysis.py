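"""Extraction of biophysical measures from sweep sets.

Implements the measurement chain applied to each recorded cell: peak
currents and densities, peak conductance, Boltzmann fits of the
conductance-voltage and availability curves, exponential fits of the
current decay (fast inactivation), of recovery time courses, and of the
slow-inactivation entry curve.  All fits use trust-region nonlinear least
squares with heuristic initialization and a few perturbed restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .protocol_engine import Sweep, SweepSet

__all__ = [
    "BoltzmannFit",
    "ExpFit",
    "FitError",
    "peak_current",
    "current_density",
    "conductance",
    "fit_boltzmann",
    "fit_decay",
    "fit_recovery",
    "fit_slow_entry",
    "analyze_iv",
    "analyze_ssi",
    "analyze_recovery",
    "analyze_slow_entry",
]

_N_RESTARTS = 3


class FitError(RuntimeError):
    """A curve fit failed to converge; carries the initializations tried."""

    def __init__(self, message: str, attempts: Sequence[Sequence[float]] = ()):
        super().__init__(message)
        self.attempts = [list(a) for a in attempts]


@dataclass
class BoltzmannFit:
    """Fitted sigmoid: scale / (1 + exp(+/-(v12 - V)/k)).

    ``k`` follows the table sign convention: negative for rising
    (activation) curves, positive for falling (availability) curves.
    ``scale`` is the fitted saturation level (normalization constant).
    """

    v12: float
    k: float
    scale: float
    residual_norm: float
    n_points: int
    direction: str = "rising"

    def __call__(self, V):
        V = np.asarray(V, dtype=float)
        x = (self.v12 - V) / abs(self.k)
        if self.direction == "falling":
            x = -x
        return self.scale / (1.0 + np.exp(np.clip(x, -700, 700)))


@dataclass
class ExpFit:
    """Exponential fit result; taus sorted ascending (tau_fast first).

    ``amplitudes`` are the component amplitudes in data units;
    ``fraction_fast`` is A_fast/(A_fast+A_slow) for two components.
    ``offset`` is y0 (slow-entry fits) or the baseline (decay fits).
    """

    n_components: int
    taus: tuple[float, ...]
    amplitudes: tuple[float, ...]
    offset: float
    residual_norm: float

    @property
    def tau(self) -> float:
        return self.taus[0]

    @property
    def tau_fast(self) -> float:
        return self.taus[0]

    @property
    def tau_slow(self) -> float:
        return self.taus[-1]

    @property
    def fraction_fast(self) -> float:
        total = sum(abs(a) for a in self.amplitudes)
        return abs(self.amplitudes[0]) / total if total else float("nan")


def peak_current(sweep: Sweep, window: Optional[tuple[float, float]] = None) -> float:
    """Signed extremum of the recorded step current (inward currents are
    negative).  ``window`` optionally restricts the search (ms)."""
    t, i = sweep.time, sweep.current
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, i = t[mask], i[mask]
    if len(i) == 0:
        raise ValueError("empty peak-search window")
    return float(i[np.argmax(np.abs(i))])


def current_density(peak: float, capacitance: float) -> float:
    """Peak current density, |pA|/pF (magnitude, as reported)."""
    if capacitance <= 0:
        raise ValueError("capacitance must be positive")
    return abs(peak) / capacitance


def conductance(I: float, V: float, E_Na: float) -> float:
    """Chord conductance G = I/(V - E_Na) in nS (pA/mV)."""
    if V == E_Na:
        raise ValueError("V equals the reversal potential; point excluded")
    return I / (V - E_Na)


def _boltz(V, v12, k_abs, scale, sign):
    return scale / (1.0 + np.exp(np.clip(sign * (v12 - V) / k_abs, -700, 700)))


def fit_boltzmann(
    x: Sequence[float],
    y: Sequence[float],
    direction: str = "rising",
    free_scale: bool = True,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a normalized activation or
    availability curve.

    The reported slope factor is negative for rising fits and positive for
    falling fits, matching the convention of the parameter tables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points spanning the transition")
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising' or 'falling'")
    span = float(y.max() - y.min())
    if span < 1e-3:
        raise FitError("no transition in data (flat curve)")
    sign = 1.0 if direction == "rising" else -1.0

    # half-maximum crossing as V1/2 init; k from the 25-75% width
    yn = (y - y.min()) / span
    order = np.argsort(x)
    xs, ys = x[order], yn[order]
    if direction == "falling":
        ys = 1.0 - ys
    v12_0 = float(np.interp(0.5, ys, xs))
    lo, hi = float(np.interp(0.25, ys, xs)), float(np.interp(0.75, ys, xs))
    k0 = max(abs(hi - lo) / 2.2, 0.5)

    rng = np.random.default_rng(0)
    attempts = []
    for trial in range(_N_RESTARTS + 1):
        if trial == 0:
            p0 = [v12_0, k0, max(y.max(), 1e-6)]
        else:
            p0 = [
                v12_0 + rng.normal(0, 5),
                k0 * rng.uniform(0.5, 2.0),
                max(y.max(), 1e-6) * rng.uniform(0.8, 1.2),
            ]
        attempts.append(p0)
        try:
            if free_scale:
                popt, _ = curve_fit(
                    lambda V, v12, k_abs, scale: _boltz(V, v12, k_abs, scale, sign),
                    x, y, p0=p0, maxfev=20000,
                    bounds=([-200, 0.1, 1e-9], [100, 100, np.inf]),
                )
            else:
                popt, _ = curve_fit(
                    lambda V, v12, k_abs: _boltz(V, v12, k_abs, 1.0, sign),
                    x, y, p0=p0[:2], maxfev=20000,
                    bounds=([-200, 0.1], [100, 100]),
                )
                popt = [popt[0], popt[1], 1.0]
        except RuntimeError:
            continue
        resid = y - _boltz(x, popt[0], popt[1], popt[2], sign)
        return BoltzmannFit(
            v12=float(popt[0]),
            k=float(-popt[1] if direction == "rising" else popt[1]),
            scale=float(popt[2]),
            residual_norm=float(np.linalg.norm(resid)),
            n_points=len(x),
            direction=direction,
        )
    raise FitError("Boltzmann fit failed to converge", attempts)


def _fit_exp_sum(
    t: np.ndarray,
    y: np.ndarray,
    n_components: int,
    kind: str,
    tau_inits: Sequence[float],
) -> ExpFit:
    """Shared driver for decay / recovery / entry exponential fits.

    kind: "decay"    y = sum A_i exp(-t/tau_i) + c
          "recovery" y = sum A_i (1 - exp(-t/tau_i))
          "entry"    y = y0 + sum A_i exp(-t/tau_i)
    """
    span = float(np.ptp(y))
    if span <= 0:
        if kind == "entry":
            return ExpFit(n_components, tuple(tau_inits[:n_components]),
                          (0.0,) * n_components, float(y[0]), 0.0)
        raise FitError("no signal to fit (flat trace)")

    def model(tt, *p):
        if kind == "decay":
            c = p[-1]
            out = np.full_like(tt, c)
            for j in range(n_components):
                out = out + p[2 * j] * np.exp(-tt / p[2 * j + 1])
            return out
        if kind == "recovery":
            out = np.zeros_like(tt)
            for j in range(n_components):
                out = out + p[2 * j] * -np.expm1(-tt / p[2 * j + 1])
            return out
        # entry
        out = np.full_like(tt, p[-1])
        for j in range(n_components):
            out = out + p[2 * j] * np.exp(-tt / p[2 * j + 1])
        return out

    amp0 = span if kind != "decay" else float(y[0] - y[-1])
    rng = np.random.default_rng(1)
    attempts = []
    best = None
    for trial in range(_N_RESTARTS + 1):
        factor = 1.0 if trial == 0 else rng.uniform(0.3, 3.0)
        p0: list[float] = []
        for j in range(n_components):
            p0 += [amp0 / n_components, tau_inits[j] * factor]
        if kind in ("decay", "entry"):
            p0.append(float(y[-1]) if kind == "decay" else float(y.min()))
        attempts.append(p0)
        lo = [-np.inf, 1e-6] * n_components
        hi = [np.inf, np.inf] * n_components
        if kind in ("decay", "entry"):
            lo.append(-np.inf)
            hi.append(np.inf)
        try:
            popt, _ = curve_fit(model, t, y, p0=p0, bounds=(lo, hi), maxfev=50000)
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(y - model(t, *popt)))
        if best is None or resid < best[1]:
            best = (popt, resid)
        if resid < 1e-8 * max(1.0, np.linalg.norm(y)):
            break
    if best is None:
        raise FitError(f"{kind} exponential fit failed to converge", attempts)
    popt, resid = best
    pairs = sorted(
        ((float(popt[2 * j + 1]), float(popt[2 * j])) for j in range(n_components)),
        key=lambda p: p[0],
    )
    taus = tuple(p[0] for p in pairs)
    amps = tuple(p[1] for p in pairs)
    offset = float(popt[-1]) if kind in ("decay", "entry") else 0.0
    return ExpFit(n_components, taus, amps, offset, resid)


def fit_decay(
    sweep: Sweep,
    window: Optional[tuple[float, float]] = None,
    n_components: int = 1,
) -> ExpFit:
    """Exponential fit of the current decay after the peak.

    The fit window runs from the first post-peak sample at or below 95% of
    the peak magnitude to the end of the step (or of ``window``), which
    excludes the activation rise.  Currents are peak-normalized
    internally, so the result is invariant to amplitude rescaling.
    """
    t, i = sweep.time, sweep.current
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, i = t[mask], i[mask]
    pk_idx = int(np.argmax(np.abs(i)))
    pk = abs(i[pk_idx])
    if pk == 0:
        raise FitError("zero-amplitude trace")
    after = np.abs(i[pk_idx:]) <= 0.95 * pk
    start = pk_idx + (int(np.argmax(after)) if after.any() else 1)
    tt = t[start:] - t[start]
    yy = np.abs(i[start:]) / pk
    if len(tt) < 4:
        raise FitError("decay window too short to fit")
    tau0 = _tail_tau_init(tt, yy)
    if tt[-1] < 3 * tau0:
        warnings.warn("decay window shorter than ~3 tau; fit may be ill-conditioned",
                      stacklevel=2)
    inits = [tau0] if n_components == 1 else [tau0 / 3, tau0 * 3]
    return _fit_exp_sum(tt, yy, n_components, "decay", inits)


def _tail_tau_init(t: np.ndarray, y: np.ndarray) -> float:
    """Log-linear regression of the (positive) early tail for a tau init."""
    yy = y - min(0.0, float(y.min()))
    pos = yy > 0.05 * yy.max()
    if pos.sum() < 3:
        return max(float(t[-1]) / 3.0, 1e-3)
    slope = np.polyfit(t[pos], np.log(yy[pos]), 1)[0]
    if slope >= 0:
        return max(float(t[-1]) / 3.0, 1e-3)
    return float(-1.0 / slope)


def fit_recovery(
    intervals: Sequence[float],
    fractions: Sequence[float],
    n_components: int = 1,
) -> ExpFit:
    """Fit a recovery time course I/Imax(t) = sum A_i (1 - exp(-t/tau_i)).

    One component for recovery from fast inactivation, two for recovery
    from slow inactivation; the curve passes through zero at t = 0.
    """
    t = np.asarray(intervals, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if np.any(y < -0.05) or np.any(y > 1.2):
        raise ValueError("recovery fractions should lie in [0, 1]")
    # tau inits from geometric spread of the sampled interval range
    span = (float(t[t > 0].min()), float(t.max()))
    if n_components == 1:
        inits = [float(np.interp(0.63, np.clip(y, 0, 1), t))]
    else:
        inits = [np.sqrt(span[0] * span[1]) / 3.0, np.sqrt(span[0] * span[1]) * 3.0]
    return _fit_exp_sum(t, y, n_components, "recovery", inits)


def fit_slow_entry(durations: Sequence[float], fractions: Sequence[float]) -> ExpFit:
    """Fit the slow-inactivation entry curve
    I/Imax(t) = y0 + A_fast exp(-t/tau_fast) + A_slow exp(-t/tau_slow).

    Amplitudes are labelled by the time constant they multiply (A_fast
    with tau_fast); ``offset`` is the residual availability y0.
    """
    t = np.asarray(durations, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if np.log10(t.max() / t[t > 0].min()) < 3:
        warnings.warn("entry durations span fewer than 3 decades; taus may be degenerate",
                      stacklevel=2)
    gm = np.sqrt(float(t[t > 0].min()) * float(t.max()))
    return _fit_exp_sum(t, y, 2, "entry", [gm / 10.0, gm * 10.0])


# ---------------------------------------------------------------------------
# Per-protocol measurement pipelines


def analyze_iv(
    sweeps: SweepSet,
    capacitance: float,
    E_Na: float,
    density_at: float = -10.0,
    exclude_near_rev: float = 10.0,
) -> dict:
    """Measure an I-V run: per-voltage peaks, density at the reference
    voltage, the G-V Boltzmann fit, and the decay fit at the reference
    voltage.

    Conductance points within ``exclude_near_rev`` mV of the reversal
    potential are excluded from the fit (vanishing driving force).
    """
    volts = sweeps.values()
    peaks = np.array([peak_current(s) for s in sweeps.sweeps])
    dens_idx = int(np.argmin(np.abs(volts - density_at)))
    dens = current_density(peaks[dens_idx], capacitance)

    keep = np.abs(volts - E_Na) >= exclude_near_rev
    g = np.array([conductance(p, v, E_Na) for p, v in zip(peaks[keep], volts[keep])])
    gmax = float(np.max(np.abs(g)))
    gv_fit = fit_boltzmann(volts[keep], np.abs(g) / gmax, direction="rising")
    decay = fit_decay(sweeps.sweeps[dens_idx], n_components=1)
    return {
        "voltages": volts,
        "peaks": peaks,
        "density": dens,
        "gv_fit": gv_fit,
        "decay_fit": decay,
        "tau_h": decay.tau,
    }


def analyze_ssi(sweeps: SweepSet) -> dict:
    """Measure a steady-state inactivation run: peak at each prepulse
    normalized to the maximum, fitted with a falling Boltzmann."""
    volts = sweeps.values()
    peaks = np.array([peak_current(s) for s in sweeps.sweeps])
    mags = np.abs(peaks)
    fracs = mags / mags.max()
    fit = fit_boltzmann(volts, fracs, direction="falling")
    return {"voltages": volts, "fractions": fracs, "ssi_fit": fit}


def analyze_recovery(sweeps: SweepSet, n_components: int = 1) -> dict:
    """Measure a recovery run (fast or slow): test-pulse peaks normalized
    to the maximum, fitted with a 1- or 2-component recovery kernel."""
    t = sweeps.values()
    peaks = np.abs([peak_current(s) for s in sweeps.sweeps])
    fracs = peaks / peaks.max()
    fit = fit_recovery(t, fracs, n_components=n_components)
    return {"intervals": t, "fractions": fracs, "recovery_fit": fit}


def analyze_slow_entry(sweeps: SweepSet) -> dict:
    """Measure a slow-entry run: available fraction against conditioning
    duration, fitted with the double-exponential entry kernel."""
    t = sweeps.values()
    peaks = np.abs([peak_current(s) for s in sweeps.sweeps])
    fracs = peaks / peaks.max()
    fit = fit_slow_entry(t, fracs)
    return {"durations": t, "fractions": fracs, "entry_fit": fit}
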
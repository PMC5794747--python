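"""Empirical forward model of macroscopic NaV1.4 gating.

The model is descriptive rather than mechanistic: steady-state activation
and fast-inactivation availability are Boltzmann functions of voltage,
fast-inactivation kinetics are single-exponential with a voltage-dependent
time constant anchored at -10 mV, slow inactivation is represented by the
fitted double-exponential entry/recovery kernels, and every time constant
scales with temperature through an Arrhenius law with a per-variant energy
of activation.  All parameters of a variant live in :class:`VariantParams`
and are shipped as JSON documents for the wild-type and the R1451C/R1451L
channels at 22 and 10 degrees C.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "GAS_CONSTANT_KCAL",
    "VariantParams",
    "GateState",
    "TauHShape",
    "SlowEntryKernel",
    "SlowRecoveryKernel",
    "load_variant",
    "packaged_variants",
    "boltzmann",
    "act_inf",
    "h_inf",
    "tau_h",
    "tau_h_effective",
    "arrhenius_scale",
    "nernst_sodium",
    "simulate_step_current",
    "entry_availability",
    "recovery_fraction",
    "slow_recovery_kernel_for",
    "slow_availability",
]

#: Gas constant in kcal mol^-1 K^-1, the unit the energies of activation use.
GAS_CONSTANT_KCAL = 1.987e-3

#: Reference temperature (degrees C) at which tau_h anchors are specified.
TAU_REFERENCE_TEMP_C = 22.0

_PACKAGED = {
    ("WT", 22.0): "wt_22C.json",
    ("WT", 10.0): "wt_10C.json",
    ("R1451C", 22.0): "r1451c_22C.json",
    ("R1451C", 10.0): "r1451c_10C.json",
    ("R1451L", 22.0): "r1451l_22C.json",
    ("R1451L", 10.0): "r1451l_10C.json",
}


class TauHShape(BaseModel):
    """Voltage dependence of the fast-inactivation entry time constant.

    tau_h(V) = floor + amp * exp(-V / efold), a saturating-decreasing
    function of voltage.  ``amp_ms`` may be omitted, in which case it is
    derived so that tau_h(-10 mV) equals the variant's anchor exactly.
    """

    floor_ms: float = Field(0.2, gt=0)
    amp_ms: Optional[float] = Field(None, gt=0)
    efold_mV: float = Field(15.0, gt=0)


class SlowEntryKernel(BaseModel):
    """Double-exponential entry into slow inactivation.

    avail(t) = y0 + a_fast * exp(-t/tau_fast) + a_slow * exp(-t/tau_slow)
    with a_slow = 1 - y0 - a_fast so that avail(0) = 1.  Amplitudes are
    labelled by the time constant they multiply.
    """

    tau_fast: float = Field(gt=0)
    a_fast: float = Field(ge=0, le=1)
    tau_slow: float = Field(gt=0)
    y0: float = Field(0.25, ge=0, lt=1)

    @property
    def a_slow(self) -> float:
        return 1.0 - self.y0 - self.a_fast


class SlowRecoveryKernel(BaseModel):
    """Double-exponential recovery from slow inactivation.

    frac(t) = a_fast * (1 - exp(-t/tau_fast)) + (1 - a_fast) * (1 - exp(-t/tau_slow))
    """

    tau_fast: float = Field(gt=0)
    a_fast: float = Field(ge=0, le=1)
    tau_slow: float = Field(gt=0)


class VariantParams(BaseModel):
    """Complete empirical parameter set for one channel variant.

    Sign conventions follow the source tables: the activation slope factor
    ``act_k`` is negative, the inactivation slope factor ``inact_k``
    positive.  Internally both are used as positive canonical slopes with
    the direction fixed by the curve (rising activation, falling
    availability).  ``tau_h_anchor`` is the -10 mV fast-inactivation time
    constant at 22 degrees C; other temperatures are reached through the
    Arrhenius law with energy ``Ea``.
    """

    name: str
    temperature: float = Field(description="deg C the set was measured at")
    act_v12: float
    act_k: float
    inact_v12: float
    inact_k: float = Field(gt=0)
    tau_h_anchor: float = Field(gt=0, description="ms at -10 mV, 22 deg C")
    tau_h_shape: TauHShape = TauHShape()
    tau_m: float = Field(0.1, gt=0, description="ms at 22 deg C")
    rec_fast_tau: float = Field(gt=0, description="ms, recovery from fast inactivation")
    slow_entry: SlowEntryKernel
    slow_rec_4s: SlowRecoveryKernel
    slow_rec_30s: SlowRecoveryKernel
    Ea: float = Field(gt=0, description="kcal/mol")
    density: float = Field(gt=0, description="pA/pF peak density at -10 mV")
    pedestal_C: float = Field(0.0, ge=0, lt=1)
    activation_exponent: int = Field(1, ge=1, description="effective gate exponent")

    @model_validator(mode="after")
    def _check_signs(self) -> "VariantParams":
        if self.act_k >= 0:
            raise ValueError("act_k must be negative under the table sign convention")
        if self.slow_entry.a_fast + self.slow_entry.y0 > 1:
            raise ValueError("slow-entry amplitudes exceed unity")
        return self

    @property
    def tau_h_amp(self) -> float:
        """Amplitude of the tau_h(V) shape, derived from the -10 mV anchor."""
        shape = self.tau_h_shape
        if shape.amp_ms is not None:
            return shape.amp_ms
        return (self.tau_h_anchor - shape.floor_ms) * math.exp(-10.0 / shape.efold_mV)


@dataclass
class GateState:
    """Occupancies of the effective gates: activation m, fast availability h,
    slow availability s.  All lie in [0, 1]; open fraction is their product."""

    m: float = 0.0
    h: float = 1.0
    s_avail: float = 1.0

    def __post_init__(self) -> None:
        for label, x in (("m", self.m), ("h", self.h), ("s_avail", self.s_avail)):
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate occupancy {label}={x} outside [0, 1]")

    @property
    def open_fraction(self) -> float:
        return self.m * self.h * self.s_avail


def load_variant(name: str, temperature: float = 22.0) -> VariantParams:
    """Load a packaged variant parameter set (WT/R1451C/R1451L at 22 or 10 C)."""
    key = (name.upper() if name.lower() == "wt" else name, float(temperature))
    try:
        fname = _PACKAGED[key]
    except KeyError:
        raise KeyError(
            f"no packaged parameter set for {name!r} at {temperature} C; "
            f"available: {sorted(_PACKAGED)}"
        ) from None
    text = resources.files("navclamp.data").joinpath(fname).read_text()
    return VariantParams.model_validate(json.loads(text))


def packaged_variants(temperature: float = 22.0) -> dict[str, VariantParams]:
    """All packaged variants at one temperature, keyed by name."""
    return {n: load_variant(n, temperature) for n in ("WT", "R1451C", "R1451L")}


def boltzmann(V, v12: float, k: float, direction: str = "rising"):
    """Canonical Boltzmann curve 1 / (1 + exp((v12 - V)/|k|)).

    ``direction="rising"`` gives the activation form (increasing with V,
    0.5 at v12); ``"falling"`` the availability form.  The magnitude of the
    slope factor is used, so table-convention negative activation slopes
    can be passed directly; the mapping is bijective (reported activation
    k = -|k|, inactivation k = +|k|).
    """
    if k == 0:
        raise ValueError("Boltzmann slope factor k must be nonzero")
    if direction not in ("rising", "falling"):
        raise ValueError(f"direction must be 'rising' or 'falling', got {direction!r}")
    V = np.asarray(V, dtype=float)
    x = (v12 - V) / abs(k)
    if direction == "falling":
        x = -x
    out = 1.0 / (1.0 + np.exp(np.clip(x, -700, 700)))
    return out if out.ndim else float(out)


def act_inf(V, params: VariantParams):
    """Steady-state activation (normalized peak conductance) at voltage V."""
    p = boltzmann(V, params.act_v12, params.act_k, "rising")
    if params.activation_exponent != 1:
        p = np.asarray(p) ** params.activation_exponent
        return p if p.ndim else float(p)
    return p


def h_inf(V, params: VariantParams):
    """Steady-state fast-inactivation availability (falling Boltzmann)."""
    return boltzmann(V, params.inact_v12, params.inact_k, "falling")


def arrhenius_scale(tau_ref: float, T_ref: float, T: float, Ea: float):
    """Scale a time constant from T_ref to T (deg C) with energy Ea (kcal/mol).

    tau(T) = tau_ref * exp((Ea/R) * (1/T_K - 1/T_refK)); cooling slows.
    """
    t_k = float(T) + 273.15
    tref_k = float(T_ref) + 273.15
    return tau_ref * math.exp((Ea / GAS_CONSTANT_KCAL) * (1.0 / t_k - 1.0 / tref_k))


def tau_h(V, T: float, params: VariantParams):
    """Fast-inactivation entry time constant (ms) at voltage V and temperature T.

    Saturating-decreasing in V: floor + amp * exp(-V/efold), anchored so
    that tau_h(-10 mV, 22 C) equals the variant anchor exactly; other
    temperatures via the Arrhenius law.  The shape is calibrated over the
    -50..+30 mV fit range; colder than 5 C or warmer than 35 C is an
    extrapolation and triggers a warning.
    """
    if not 5.0 <= T <= 35.0:
        warnings.warn(
            f"temperature {T} C outside the calibrated 5-35 C range; extrapolating",
            stacklevel=2,
        )
    shape = params.tau_h_shape
    V = np.asarray(V, dtype=float)
    base = shape.floor_ms + params.tau_h_amp * np.exp(-V / shape.efold_mV)
    scaled = base * arrhenius_scale(1.0, TAU_REFERENCE_TEMP_C, T, params.Ea)
    return scaled if scaled.ndim else float(scaled)


def tau_h_effective(V: float, T: float, params: VariantParams) -> float:
    """Relaxation time constant of the h gate at any voltage.

    Entry and recovery rates add (HH alpha+beta form):
    1/tau = w/tau_rec + (1 - w)/tau_entry(V), where the weight w is a
    falling sigmoid at the inactivation midpoint with half the SSI slope
    factor.  The sharpened switch makes the limits exact: at strongly
    depolarized voltages tau equals the entry tau_h, at strongly
    hyperpolarized voltages the measured recovery time constant.

    The entry limb is evaluated no lower than -50 mV (the lower edge of
    the calibrated tau_h range): physically tau_h is bell-shaped and
    turns over below the activation range, whereas the fitted
    saturating-exponential would keep growing.
    """
    hi = boltzmann(V, params.inact_v12, params.inact_k / 2.0, "falling")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        entry = tau_h(max(V, -50.0), T, params)
    rec = arrhenius_scale(params.rec_fast_tau, params.temperature, T, params.Ea)
    return 1.0 / (hi / rec + (1.0 - hi) / entry)


def nernst_sodium(T: float = 22.0, na_out_mM: float = 150.0, na_in_mM: float = 35.0) -> float:
    """Sodium reversal potential (mV) from the recording solutions.

    Nernst: E_Na = (RT/F) ln([Na]o/[Na]i); about +37 mV at 22 C for
    150 mM external / 35 mM internal sodium.
    """
    t_k = T + 273.15
    rt_over_f = 8.31446 * t_k / 96485.33 * 1000.0  # mV
    return rt_over_f * math.log(na_out_mM / na_in_mM)


def simulate_step_current(
    V: float,
    duration: float,
    T: float,
    params: VariantParams,
    gmax: float,
    E_Na: Optional[float] = None,
    initial: Optional[GateState] = None,
    sample_interval: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Macroscopic current (pA) during a voltage step, sampled on a grid.

    The waveform is the empirical description the fitted parameters
    encode: a rise with time constant tau_m to a peak of
    gmax * (V - E_Na) * m_inf(V) * h0 * s0, followed by an exact
    single-exponential decay with time constant tau_h_effective(V, T)
    toward the pedestal-adjusted steady-state availability.  The peak
    falls on a sample so that peak conductance-voltage curves reproduce
    the activation Boltzmann exactly in the noise-free limit.

    Returns (time ms, current pA); time starts at 0 at step onset.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if gmax <= 0:
        raise ValueError("gmax must be positive")
    if E_Na is None:
        E_Na = nernst_sodium(T)
    state = initial or GateState(m=0.0, h=1.0, s_avail=1.0)

    t = np.arange(0.0, duration, sample_interval)
    minf = act_inf(V, params)
    h0, s0 = state.h, state.s_avail
    peak = gmax * (V - E_Na) * minf * h0 * s0
    if peak == 0.0 or h0 == 0.0:
        return t, np.zeros_like(t)

    tau_m = arrhenius_scale(params.tau_m, TAU_REFERENCE_TEMP_C, T, params.Ea)
    tau_dec = tau_h_effective(V, T, params)
    # steady-state availability the decay relaxes to, incl. persistent pedestal
    plateau = params.pedestal_C + (1.0 - params.pedestal_C) * h_inf(V, params)
    c = plateau / h0 if h0 > 0 else 0.0
    c = min(c, 1.0)

    # time-to-peak of the underlying m*h product, snapped to the sample grid
    t_pk = tau_m * math.log1p(tau_dec / tau_m)
    t_pk = max(sample_interval, round(t_pk / sample_interval) * sample_interval)

    envelope = np.empty_like(t)
    rising = t < t_pk
    denom = -math.expm1(-t_pk / tau_m)
    envelope[rising] = -np.expm1(-t[rising] / tau_m) / denom
    td = t[~rising] - t_pk
    envelope[~rising] = c + (1.0 - c) * np.exp(-td / tau_dec)
    return t, peak * envelope


def entry_availability(conditioning_ms, params: VariantParams):
    """Fraction of channels still available after a depolarized conditioning
    pulse, from the double-exponential slow-entry kernel (value 1 at t=0)."""
    k = params.slow_entry
    t = np.asarray(conditioning_ms, dtype=float)
    out = k.y0 + k.a_fast * np.exp(-t / k.tau_fast) + k.a_slow * np.exp(-t / k.tau_slow)
    return out if out.ndim else float(out)


def recovery_fraction(recovery_ms, kernel: SlowRecoveryKernel):
    """Recovered fraction after a recovery interval, double-exponential kernel."""
    t = np.asarray(recovery_ms, dtype=float)
    a_s = 1.0 - kernel.a_fast
    out = kernel.a_fast * -np.expm1(-t / kernel.tau_fast) + a_s * -np.expm1(-t / kernel.tau_slow)
    return out if out.ndim else float(out)


def slow_recovery_kernel_for(conditioning_ms: float, params: VariantParams) -> SlowRecoveryKernel:
    """Recovery kernel for a given conditioning duration.

    The 4-s and 30-s kernels are measured; intermediate durations use
    linear interpolation of the kernel parameters in log conditioning
    time, clamped outside the measured range.
    """
    k4, k30 = params.slow_rec_4s, params.slow_rec_30s
    if conditioning_ms <= 4000.0:
        return k4
    if conditioning_ms >= 30000.0:
        return k30
    w = (math.log(conditioning_ms) - math.log(4000.0)) / (math.log(30000.0) - math.log(4000.0))
    return SlowRecoveryKernel(
        tau_fast=(1 - w) * k4.tau_fast + w * k30.tau_fast,
        a_fast=(1 - w) * k4.a_fast + w * k30.a_fast,
        tau_slow=(1 - w) * k4.tau_slow + w * k30.tau_slow,
    )


def slow_availability(conditioning_ms: float, recovery_ms: float, params: VariantParams) -> float:
    """Available fraction after conditioning and a recovery interval.

    Entry follows the slow-entry kernel; the slow-inactivated pool then
    recovers along the double-exponential kernel selected by the
    conditioning duration.  Bounded to [0, 1].
    """
    if conditioning_ms < 0:
        raise ValueError("conditioning duration must be >= 0")
    if conditioning_ms == 0:
        return 1.0
    avail = entry_availability(conditioning_ms, params)
    kern = slow_recovery_kernel_for(conditioning_ms, params)
    rec = recovery_fraction(recovery_ms, kern)
    return float(np.clip(avail + (1.0 - avail) * rec, 0.0, 1.0))
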
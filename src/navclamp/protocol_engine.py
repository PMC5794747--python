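"""Declarative voltage-clamp protocols and an executor over the gating model.

The five protocols used to characterize the channels are built here as
epoch-structured command-voltage programs: the current-voltage (I-V)
family, steady-state inactivation (SSI), recovery from fast inactivation,
entry into slow inactivation, and recovery from slow inactivation after a
4-s or 30-s conditioning pulse.  ``run`` executes a variant parameter set
over a protocol and yields a deterministic, noise-free ``SweepSet``;
recording noise and cell variability are added downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import gating_model as gm
from .gating_model import GateState, VariantParams

__all__ = [
    "Epoch",
    "VoltageProtocol",
    "Sweep",
    "SweepSet",
    "build_iv",
    "build_ssi",
    "build_recovery_fast",
    "build_slow_entry",
    "build_recovery_slow",
    "standard_protocols",
    "run",
]

#: Default digitization interval, ms (10 kHz).
SAMPLE_INTERVAL_MS = 0.1


@dataclass(frozen=True)
class Epoch:
    """One segment of a command-voltage program.

    Either ``level``/``duration`` are scalars, or exactly one of them is
    swept across sweeps: ``levels`` as an inclusive (start, stop,
    increment) range in mV, ``durations`` as an explicit set in ms.
    ``record`` marks epochs whose current is digitized; ``role`` tags the
    epoch for the executor ("conditioning", "interpulse", "test", ...).
    """

    level: Optional[float] = None
    duration: Optional[float] = None
    levels: Optional[tuple[float, float, float]] = None
    durations: Optional[tuple[float, ...]] = None
    record: bool = False
    role: str = ""

    def __post_init__(self) -> None:
        if (self.level is None) == (self.levels is None):
            raise ValueError("exactly one of level/levels must be set")
        if (self.duration is None) == (self.durations is None):
            raise ValueError("exactly one of duration/durations must be set")
        if self.levels is not None and self.durations is not None:
            raise ValueError("an epoch may vary level or duration, not both")
        if self.levels is not None:
            start, stop, inc = self.levels
            n = (stop - start) / inc
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"increment {inc} does not divide span {stop - start}")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("epoch duration must be positive")
        if self.durations is not None and any(d <= 0 for d in self.durations):
            raise ValueError("epoch durations must be positive")

    @property
    def varied(self) -> bool:
        return self.levels is not None or self.durations is not None

    def values(self) -> np.ndarray:
        """Swept values (levels in mV or durations in ms)."""
        if self.levels is not None:
            start, stop, inc = self.levels
            n = int(round((stop - start) / inc)) + 1
            return start + inc * np.arange(n)
        if self.durations is not None:
            return np.asarray(self.durations, dtype=float)
        raise ValueError("epoch is not varied")


@dataclass(frozen=True)
class VoltageProtocol:
    """An ordered program of epochs plus holding potential.

    ``kind`` selects the executor semantics: "iv", "ssi", "recovery_fast",
    "slow_entry", or "recovery_slow".
    """

    name: str
    kind: str
    holding: float
    epochs: tuple[Epoch, ...]
    inter_sweep_ms: float = 5000.0
    conditioning_ms: Optional[float] = None  # recovery_slow only

    def __post_init__(self) -> None:
        if sum(e.varied for e in self.epochs) != 1:
            raise ValueError("protocol must vary exactly one epoch")

    @property
    def varied_epoch(self) -> Epoch:
        return next(e for e in self.epochs if e.varied)

    @property
    def n_sweeps(self) -> int:
        return len(self.varied_epoch.values())

    def sweep_values(self) -> np.ndarray:
        return self.varied_epoch.values()


@dataclass
class Sweep:
    """Recorded samples of one sweep with the varied epoch value attached."""

    varied: float
    time: np.ndarray  # ms, relative to the start of the recorded window
    current: np.ndarray  # pA


@dataclass
class SweepSet:
    """All sweeps of one protocol run on one cell at one temperature."""

    protocol: VoltageProtocol
    sweeps: list[Sweep]
    sample_interval: float = SAMPLE_INTERVAL_MS
    temperature: float = 22.0
    cell_id: str = ""
    varied_label: str = "value"

    def values(self) -> np.ndarray:
        return np.array([s.varied for s in self.sweeps])

    def currents(self) -> np.ndarray:
        return np.column_stack([s.current for s in self.sweeps])


def _log_spaced(lo: float, hi: float, per_decade: int = 10) -> tuple[float, ...]:
    n = int(round(np.log10(hi / lo) * per_decade)) + 1
    return tuple(np.geomspace(lo, hi, n))


def build_iv(
    start: float = -140.0, stop: float = 60.0, increment: float = 10.0, step_ms: float = 50.0
) -> VoltageProtocol:
    """Current-voltage family: 50-ms steps from -140 to +60 mV in 10-mV
    increments, holding -140 mV (21 sweeps)."""
    return VoltageProtocol(
        name="iv",
        kind="iv",
        holding=-140.0,
        epochs=(Epoch(levels=(start, stop, increment), duration=step_ms, record=True, role="test"),),
    )


def build_ssi() -> VoltageProtocol:
    """Steady-state inactivation: 500-ms prepulse from -140 to -30 mV in
    10-mV increments, then a 10-ms test pulse to -10 mV."""
    return VoltageProtocol(
        name="ssi",
        kind="ssi",
        holding=-140.0,
        epochs=(
            Epoch(levels=(-140.0, -30.0, 10.0), duration=500.0, role="conditioning"),
            Epoch(level=-10.0, duration=10.0, record=True, role="test"),
        ),
    )


def build_recovery_fast(points_per_decade: int = 10) -> VoltageProtocol:
    """Recovery from fast inactivation: 40-ms conditioning at -10 mV from
    holding -140 mV, recovery interval 0.1-4000 ms at holding, 20-ms test
    pulse to -10 mV."""
    return VoltageProtocol(
        name="recovery_fast",
        kind="recovery_fast",
        holding=-140.0,
        epochs=(
            Epoch(level=-10.0, duration=40.0, role="conditioning"),
            Epoch(level=-140.0, durations=_log_spaced(0.1, 4000.0, points_per_decade), role="interval"),
            Epoch(level=-10.0, duration=20.0, record=True, role="test"),
        ),
    )


def build_slow_entry(points_per_decade: int = 10) -> VoltageProtocol:
    """Entry into slow inactivation: conditioning at -10 mV for 1 ms to 30 s
    from holding -120 mV, 20-ms interpulse at -120 mV to clear fast
    inactivation, 5-ms test pulse to -10 mV."""
    return VoltageProtocol(
        name="slow_entry",
        kind="slow_entry",
        holding=-120.0,
        epochs=(
            Epoch(level=-10.0, durations=_log_spaced(1.0, 30000.0, points_per_decade), role="conditioning"),
            Epoch(level=-120.0, duration=20.0, role="interpulse"),
            Epoch(level=-10.0, duration=5.0, record=True, role="test"),
        ),
    )


def build_recovery_slow(conditioning_ms: float = 30000.0, points_per_decade: int = 10) -> VoltageProtocol:
    """Recovery from slow inactivation: 4-s or 30-s conditioning at -10 mV
    from holding -120 mV, recovery interval 0.5 ms to 10 s at holding,
    20-ms test pulse to -10 mV."""
    if conditioning_ms not in (4000.0, 30000.0):
        raise ValueError("conditioning pulse must be 4000 or 30000 ms")
    label = "4s" if conditioning_ms == 4000.0 else "30s"
    return VoltageProtocol(
        name=f"recovery_slow_{label}",
        kind="recovery_slow",
        holding=-120.0,
        conditioning_ms=conditioning_ms,
        epochs=(
            Epoch(level=-10.0, duration=conditioning_ms, role="conditioning"),
            Epoch(level=-120.0, durations=_log_spaced(0.5, 10000.0, points_per_decade), role="interval"),
            Epoch(level=-10.0, duration=20.0, record=True, role="test"),
        ),
    )


def standard_protocols(points_per_decade: int = 10) -> dict[str, VoltageProtocol]:
    """The five protocols of the study, keyed by name."""
    ps = [
        build_iv(),
        build_ssi(),
        build_recovery_fast(points_per_decade),
        build_slow_entry(points_per_decade),
        build_recovery_slow(4000.0, points_per_decade),
        build_recovery_slow(30000.0, points_per_decade),
    ]
    return {p.name: p for p in ps}


def _holding_state(protocol: VoltageProtocol, params: VariantParams) -> GateState:
    """Steady state at the holding potential (full recovery between sweeps)."""
    return GateState(
        m=float(gm.act_inf(protocol.holding, params)),
        h=float(gm.h_inf(protocol.holding, params)),
        s_avail=1.0,
    )


def run(
    params: VariantParams,
    protocol: VoltageProtocol,
    T: float = 22.0,
    gmax: float = 100.0,
    E_Na: Optional[float] = None,
    cell_id: str = "",
    sample_interval: float = SAMPLE_INTERVAL_MS,
) -> SweepSet:
    """Execute a protocol over the gating model: deterministic, noise-free.

    Gate state carries across epochs within a sweep and resets to the
    holding steady state between sweeps.  The fast gates (m, h) relax
    with their voltage-dependent time constants; slow availability is
    driven by the empirical entry/recovery kernels on the protocols that
    engage it (the kernels describe the measured test-pulse fractions, so
    fast-gate recovery during a slow-protocol interval is already folded
    into them).
    """
    if E_Na is None:
        E_Na = gm.nernst_sodium(T)
    sweeps: list[Sweep] = []
    for value in protocol.sweep_values():
        state = _holding_state(protocol, params)
        rec_t: Optional[np.ndarray] = None
        rec_i: Optional[np.ndarray] = None
        for epoch in protocol.epochs:
            level = value if epoch.levels is not None else epoch.level
            dur = value if epoch.durations is not None else epoch.duration
            assert level is not None and dur is not None

            if protocol.kind == "slow_entry" and epoch.role == "conditioning":
                state.s_avail = float(np.clip(gm.entry_availability(dur, params), 0.0, 1.0))
                state.h = float(gm.h_inf(level, params))
                continue
            if protocol.kind == "recovery_slow" and epoch.role == "conditioning":
                # recovery kernel is referenced to zero at interval start
                state.s_avail = 0.0
                state.h = float(gm.h_inf(level, params))
                continue
            if protocol.kind == "recovery_slow" and epoch.role == "interval":
                kern = gm.slow_recovery_kernel_for(protocol.conditioning_ms, params)
                state.s_avail = float(np.clip(gm.recovery_fraction(dur, kern), 0.0, 1.0))
                state.h = 1.0  # fast-gate recovery is part of the empirical kernel
                continue

            if epoch.record:
                t, i = gm.simulate_step_current(
                    level, dur, T, params, gmax, E_Na,
                    initial=GateState(m=state.m, h=state.h, s_avail=state.s_avail),
                    sample_interval=sample_interval,
                )
                rec_t, rec_i = t, i
            # end-of-epoch fast-gate relaxation for state carry-over
            tau = gm.tau_h_effective(level, T, params)
            plateau = params.pedestal_C + (1.0 - params.pedestal_C) * float(gm.h_inf(level, params))
            state.h = float(np.clip(plateau + (state.h - plateau) * np.exp(-dur / tau), 0.0, 1.0))
            state.m = float(gm.act_inf(level, params))
        if rec_t is None:
            raise ValueError(f"protocol {protocol.name} has no recorded epoch")
        sweeps.append(Sweep(varied=float(value), time=rec_t, current=rec_i))

    label = "level_mV" if protocol.varied_epoch.levels is not None else "interval_ms"
    if protocol.kind == "slow_entry":
        label = "conditioning_ms"
    return SweepSet(
        protocol=protocol,
        sweeps=sweeps,
        sample_interval=sample_interval,
        temperature=T,
        cell_id=cell_id,
        varied_label=label,
    )
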
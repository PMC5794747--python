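"""Synthetic cohorts of transfected cells.

Emulates a population of cells heterologously expressing one channel
variant: per-cell membrane capacitance and maximal conductance, small
cell-to-cell jitter of the gating parameters, and additive Gaussian
recording noise.  Every draw is reproducible from an integer seed, and a
cohort written to disk carries a manifest recording every per-cell seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from . import gating_model as gm
from .gating_model import VariantParams
from .protocol_engine import SweepSet, VoltageProtocol, run
from .atf import write_sweepset

__all__ = [
    "CellRecord",
    "CohortConfig",
    "sample_cell",
    "apply_jitter",
    "add_noise",
    "simulate_cell",
    "generate_cohort",
]

#: The per-protocol cell counts of the recorded cohorts (I-V protocol).
DEFAULT_N_CELLS = {"WT": 10, "R1451C": 18, "R1451L": 18}


class CohortConfig(BaseModel):
    """Study-condition defaults for a synthetic cohort.

    Capacitance is lognormal (median 15 pF, sigma 0.3 on the log scale);
    per-cell gating jitter is 1 mV additive on midpoints, 5% on slope
    factors and 10% on time constants; maximal conductance scatters
    lognormally (sigma 0.15) around the value that hits the variant's
    -10 mV density target; recording noise is 10 pA i.i.d. Gaussian.
    """

    n_cells: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_N_CELLS))
    cap_median_pF: float = Field(15.0, gt=0)
    cap_sigma: float = Field(0.3, ge=0)
    v12_jitter_mV: float = Field(1.0, ge=0)
    k_jitter: float = Field(0.05, ge=0)
    tau_jitter: float = Field(0.10, ge=0)
    gmax_jitter: float = Field(0.15, ge=0)
    noise_sigma_pA: float = Field(10.0, ge=0)
    seed: int = 0


@dataclass
class CellRecord:
    """One virtual cell: passive properties, conductance and jitter."""

    id: str
    variant: str
    capacitance: float  # pF
    gmax: float  # nS
    jitter: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if self.capacitance <= 0 or self.gmax <= 0:
            raise ValueError("capacitance and gmax must be positive")
        if any(f <= 0 for k, f in self.jitter.items() if not k.endswith("_mV")):
            raise ValueError("multiplicative jitter factors must be positive")


def apply_jitter(params: VariantParams, jitter: dict[str, float]) -> VariantParams:
    """Variant parameters perturbed by one cell's jitter.

    Midpoints shift additively (``*_mV`` entries); slope factors and all
    time constants scale multiplicatively.
    """
    doc = params.model_dump()
    doc["act_v12"] += jitter.get("act_v12_mV", 0.0)
    doc["inact_v12"] += jitter.get("inact_v12_mV", 0.0)
    doc["act_k"] *= jitter.get("act_k", 1.0)
    doc["inact_k"] *= jitter.get("inact_k", 1.0)
    doc["tau_h_anchor"] *= jitter.get("tau", 1.0)
    doc["rec_fast_tau"] *= jitter.get("tau", 1.0)
    for kernel in ("slow_entry", "slow_rec_4s", "slow_rec_30s"):
        doc[kernel]["tau_fast"] *= jitter.get("tau", 1.0)
        doc[kernel]["tau_slow"] *= jitter.get("tau", 1.0)
    return VariantParams.model_validate(doc)


def _truncated_factor(rng: np.random.Generator, sigma: float) -> float:
    """Multiplicative jitter factor ~ N(1, sigma), truncated positive."""
    if sigma == 0:
        return 1.0
    f = rng.normal(1.0, sigma)
    while f <= 0.1:
        f = rng.normal(1.0, sigma)
    return float(f)


def sample_cell(
    variant: VariantParams,
    config: CohortConfig,
    seed: int,
    index: int = 0,
) -> CellRecord:
    """Draw one cell for a variant, reproducibly from ``seed``.

    The maximal conductance is set so the expected peak current density
    at -10 mV (magnitude of g * (V - E_Na) * m_inf / Cm) equals the
    variant's density target, then scattered by the lognormal gmax
    jitter whose mean is one.
    """
    rng = np.random.default_rng(seed)
    cap = float(config.cap_median_pF * math.exp(rng.normal(0.0, config.cap_sigma)))
    jitter = {
        "act_v12_mV": float(rng.normal(0.0, config.v12_jitter_mV)),
        "inact_v12_mV": float(rng.normal(0.0, config.v12_jitter_mV)),
        "act_k": _truncated_factor(rng, config.k_jitter),
        "inact_k": _truncated_factor(rng, config.k_jitter),
        "tau": _truncated_factor(rng, config.tau_jitter),
    }
    cell_params = apply_jitter(variant, jitter)
    e_na = gm.nernst_sodium(variant.temperature)
    # peak at -10 mV as measured from the -140 mV holding of the I-V family
    drive = (
        abs(-10.0 - e_na)
        * float(gm.act_inf(-10.0, cell_params))
        * float(gm.h_inf(-140.0, cell_params))
    )
    gmax = variant.density * cap / drive
    if config.gmax_jitter > 0:
        # lognormal factor with mean exactly 1
        sig = config.gmax_jitter
        gmax *= float(math.exp(rng.normal(-0.5 * sig * sig, sig)))
    return CellRecord(
        id=f"{variant.name}_{variant.temperature:g}C_{index:03d}",
        variant=variant.name,
        capacitance=cap,
        gmax=gmax,
        jitter=jitter,
        seed=int(seed),
    )


def add_noise(sweeps: SweepSet, sigma: float, seed: int) -> SweepSet:
    """Additive i.i.d. Gaussian sample noise; sigma = 0 returns the input."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0:
        return sweeps
    rng = np.random.default_rng(seed)
    noisy = [
        type(s)(varied=s.varied, time=s.time.copy(), current=s.current + rng.normal(0.0, sigma, s.current.shape))
        for s in sweeps.sweeps
    ]
    return SweepSet(
        protocol=sweeps.protocol,
        sweeps=noisy,
        sample_interval=sweeps.sample_interval,
        temperature=sweeps.temperature,
        cell_id=sweeps.cell_id,
        varied_label=sweeps.varied_label,
    )


def simulate_cell(
    variant: VariantParams,
    cell: CellRecord,
    protocols: Sequence[VoltageProtocol],
    T: Optional[float] = None,
    noise_sigma: float = 0.0,
    noise_seed: int = 0,
) -> dict[str, SweepSet]:
    """Run a cell through a set of protocols, optionally with noise."""
    if T is None:
        T = variant.temperature
    params = apply_jitter(variant, cell.jitter)
    out = {}
    for k, proto in enumerate(protocols):
        ss = run(params, proto, T=T, gmax=cell.gmax, cell_id=cell.id)
        if noise_sigma > 0:
            ss = add_noise(ss, noise_sigma, noise_seed + k)
        out[proto.name] = ss
    return out


def generate_cohort(
    variant: VariantParams,
    protocols: Sequence[VoltageProtocol],
    config: CohortConfig,
    outdir: Path,
    T: Optional[float] = None,
) -> dict:
    """Write a cohort dataset to disk: one sweep file per cell and
    protocol plus a JSON manifest recording every seed.

    Regenerating from the same config produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if T is None:
        T = variant.temperature
    n = config.n_cells.get(variant.name, 8)
    master = np.random.default_rng(config.seed)
    entries = []
    for i in range(n):
        cell_seed = int(master.integers(2**31))
        noise_seed = int(master.integers(2**31))
        cell = sample_cell(variant, config, cell_seed, index=i)
        sets = simulate_cell(
            variant, cell, protocols, T=T,
            noise_sigma=config.noise_sigma_pA, noise_seed=noise_seed,
        )
        files = {}
        for pname, ss in sets.items():
            fname = f"{cell.id}_{pname}.atf"
            write_sweepset(outdir / fname, ss)
            files[pname] = fname
        entries.append(
            {
                "cell_id": cell.id,
                "variant": cell.variant,
                "capacitance_pF": cell.capacitance,
                "gmax_nS": cell.gmax,
                "jitter": cell.jitter,
                "cell_seed": cell_seed,
                "noise_seed": noise_seed,
                "files": files,
            }
        )
    manifest = {
        "variant": variant.name,
        "temperature_C": T,
        "config": json.loads(config.model_dump_json()),
        "params": json.loads(variant.model_dump_json()),
        "cells": entries,
    }
    path = outdir / f"manifest_{variant.name}_{T:g}C.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    manifest["manifest_path"] = str(path)
    return manifest
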
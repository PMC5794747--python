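"""Text sweep-file dialect (ATF-like).

A diff-able, tab-separated exchange format for sweep sets: a small header
(format version, sample interval, protocol name and kind, temperature,
cell id, the varied epoch value of every sweep) followed by a column of
time in ms and one current column per sweep in pA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .protocol_engine import Epoch, Sweep, SweepSet, VoltageProtocol

__all__ = ["write_sweepset", "read_sweepset"]

_VERSION = "navclamp-atf-1"


def write_sweepset(path: Path, sweeps: SweepSet) -> None:
    """Write a sweep set; floats are emitted with repr-level precision so a
    rewrite of the same data is byte-identical."""
    p = sweeps.protocol
    lines = [
        f"version\t{_VERSION}",
        f"protocol\t{p.name}",
        f"kind\t{p.kind}",
        f"holding_mV\t{p.holding:g}",
        f"sample_interval_ms\t{sweeps.sample_interval:g}",
        f"temperature_C\t{sweeps.temperature:g}",
        f"cell_id\t{sweeps.cell_id}",
        f"varied\t{sweeps.varied_label}\t" + "\t".join(repr(s.varied) for s in sweeps.sweeps),
        "data\ttime_ms\t" + "\t".join(f"sweep{i}" for i in range(len(sweeps.sweeps))),
    ]
    t = sweeps.sweeps[0].time
    cols = [t] + [s.current for s in sweeps.sweeps]
    body = "\n".join(
        "\t".join(repr(float(col[j])) for col in cols) for j in range(len(t))
    )
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_sweepset(path: Path) -> SweepSet:
    """Read a sweep set written by :func:`write_sweepset`.

    The protocol is reconstructed as a minimal single-epoch program that
    preserves name, kind, holding level and the varied values; that is
    all downstream analysis needs.
    """
    text = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    varied_label = "value"
    varied_values: list[float] = []
    data_start = None
    for idx, line in enumerate(text):
        parts = line.split("\t")
        if parts[0] == "varied":
            varied_label = parts[1]
            varied_values = [float(x) for x in parts[2:]]
        elif parts[0] == "data":
            data_start = idx + 1
            break
        else:
            header[parts[0]] = parts[1] if len(parts) > 1 else ""
    if data_start is None or not varied_values:
        raise ValueError(f"{path}: not a navclamp sweep file")
    if header.get("version") != _VERSION:
        raise ValueError(f"{path}: unsupported version {header.get('version')!r}")

    rows = np.array([[float(x) for x in line.split("\t")] for line in text[data_start:]])
    t = rows[:, 0]
    duration = float(t[-1] - t[0]) + float(header["sample_interval_ms"])
    kind = header["kind"]
    # minimal reconstructed protocol: the recorded epoch plus varied values
    if varied_label == "level_mV":
        inc = varied_values[1] - varied_values[0] if len(varied_values) > 1 else 10.0
        epoch = Epoch(levels=(varied_values[0], varied_values[-1], inc),
                      duration=duration, record=True, role="test")
    else:
        epoch = Epoch(level=-10.0, durations=tuple(varied_values), record=True, role="test")
    proto = VoltageProtocol(
        name=header["protocol"],
        kind=kind,
        holding=float(header["holding_mV"]),
        epochs=(epoch,),
        conditioning_ms=None,
    )
    sweeps = [
        Sweep(varied=v, time=t.copy(), current=rows[:, j + 1].copy())
        for j, v in enumerate(varied_values)
    ]
    return SweepSet(
        protocol=proto,
        sweeps=sweeps,
        sample_interval=float(header["sample_interval_ms"]),
        temperature=float(header["temperature_C"]),
        cell_id=header.get("cell_id", ""),
        varied_label=varied_label,
    )
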
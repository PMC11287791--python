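"""Containers and file I/O for electrophysiology traces, sweep sets, and event tables.

Units are fixed package-wide: time in ms, current in pA, voltage in mV,
conductance in nS.  With these units conductance times driving force gives
current directly (nS * mV = pA), so the whole pipeline runs without
conversion constants.

Time is sweep-local: each trace starts at ``t0`` (default 0 ms) and the
stimulus of a :class:`SweepSet` occurs at ``stim_time`` within the sweep.
Event latency relative to the stimulus is therefore ``t_detect - stim_time``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "SweepSet",
    "EventTable",
    "read_trace",
    "write_trace",
    "read_sweepset",
    "write_sweepset",
    "read_events",
    "write_events",
]

TraceKind = Literal["current", "voltage"]

#: CSV column headers for event tables (fixed dialect: comma separated,
#: '.' decimal, header row mandatory).
EVENT_COLUMNS = ["sweep_id", "t_detect_ms", "baseline_pA", "amplitude_pA"]

# CSV value-column headers recognized by read_trace; the unit implies the kind.
_UNIT_TO_KIND = {"pA": "current", "mV": "voltage"}
_KIND_TO_UNIT = {v: k for k, v in _UNIT_TO_KIND.items()}


@dataclasses.dataclass
class Trace:
    """A uniformly sampled current (pA) or voltage (mV) time series.

    Parameters
    ----------
    samples : ndarray
        Signal values, pA for ``kind='current'`` and mV for ``kind='voltage'``.
    dt : float
        Sample interval in ms (20 kHz sampling corresponds to dt = 0.05 ms).
    kind : {'current', 'voltage'}
    t0 : float
        Time of the first sample in ms.
    """

    samples: np.ndarray
    dt: float
    kind: TraceKind = "current"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.kind not in ("current", "voltage"):
            raise ValueError(f"kind must be 'current' or 'voltage', got {self.kind!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span of the trace in ms (n * dt)."""
        return self.samples.size * self.dt

    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms; raises if out of range."""
        i = int(round((t_ms - self.t0) / self.dt))
        if not 0 <= i < self.samples.size:
            raise IndexError(f"time {t_ms} ms outside trace span")
        return i


@dataclasses.dataclass
class SweepSet:
    """A collection of equal-length sweeps sharing dt and a stimulus time."""

    sweeps: list[Trace]
    stim_time: float
    stim_meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("SweepSet requires at least one sweep")
        dt0, n0, k0 = self.sweeps[0].dt, len(self.sweeps[0]), self.sweeps[0].kind
        for s in self.sweeps[1:]:
            if s.dt != dt0 or len(s) != n0 or s.kind != k0:
                raise ValueError("all sweeps must share dt, length, and kind")
        span_lo = self.sweeps[0].t0
        span_hi = span_lo + self.sweeps[0].duration
        if not span_lo <= self.stim_time <= span_hi:
            raise ValueError(
                f"stim_time {self.stim_time} ms outside sweep span "
                f"[{span_lo}, {span_hi}] ms"
            )

    def __len__(self) -> int:
        return len(self.sweeps)

    @property
    def dt(self) -> float:
        return self.sweeps[0].dt


class EventTable:
    """Detected synaptic events: (sweep_id, t_detect_ms, baseline_pA, amplitude_pA).

    Amplitudes are strictly negative by construction — events with
    nonnegative amplitudes are removed upstream, and the invariant is
    re-checked here and at write time.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        missing = set(EVENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        df = df[EVENT_COLUMNS].reset_index(drop=True)
        amps = df["amplitude_pA"].to_numpy(dtype=float)
        if amps.size and np.any(amps >= 0):
            raise ValueError("event amplitudes must be strictly negative")
        self.df = df

    @classmethod
    def from_rows(cls, rows) -> "EventTable":
        return cls(pd.DataFrame(rows, columns=EVENT_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        if len(self) == 0:
            return True
        a, b = self.df, other.df
        return bool(
            (a["sweep_id"].to_numpy() == b["sweep_id"].to_numpy()).all()
            and np.allclose(
                a[EVENT_COLUMNS[1:]].to_numpy(float),
                b[EVENT_COLUMNS[1:]].to_numpy(float),
            )
        )


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format from {path}; pass format=")


def read_trace(path, format: str | None = None) -> Trace:
    """Read a single trace from CSV (t_ms, pA|mV) or HDF5.

    The CSV must have a header declaring the time column as ``t_ms`` and the
    value column as the unit (``pA`` or ``mV``), and a uniformly spaced time
    column; HDF5 traces carry ``dt_ms``/``kind``/``t0_ms`` attributes.
    """
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(path)
        if df.shape[1] != 2:
            raise ValueError("trace CSV must have exactly two columns")
        tcol, vcol = df.columns
        if tcol != "t_ms":
            raise ValueError(f"first CSV column must be 't_ms', got {tcol!r}")
        if vcol not in _UNIT_TO_KIND:
            raise ValueError(f"value column must declare units pA or mV, got {vcol!r}")
        t = df[tcol].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError("trace CSV must contain at least two samples")
        steps = np.diff(t)
        dt = float(np.median(steps))
        if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-9 * max(dt, 1.0)):
            raise ValueError("time column is not uniformly spaced")
        return Trace(df[vcol].to_numpy(dtype=float), dt=dt, kind=_UNIT_TO_KIND[vcol], t0=float(t[0]))
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            ds = f["trace"]
            if "dt_ms" not in ds.attrs or "kind" not in ds.attrs:
                raise ValueError("HDF5 trace missing dt_ms/kind attributes")
            return Trace(
                ds[...],
                dt=float(ds.attrs["dt_ms"]),
                kind=str(ds.attrs["kind"]),
                t0=float(ds.attrs.get("t0_ms", 0.0)),
            )
    raise ValueError(f"unknown format {fmt!r}")


def write_trace(trace: Trace, path, format: str | None = None) -> None:
    """Write a trace; HDF5 round-trips bit-exactly, CSV to float-text precision."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        pd.DataFrame(
            {"t_ms": trace.times(), _KIND_TO_UNIT[trace.kind]: trace.samples}
        ).to_csv(path, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("trace", data=trace.samples)
            ds.attrs["dt_ms"] = trace.dt
            ds.attrs["kind"] = trace.kind
            ds.attrs["t0_ms"] = trace.t0
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_sweepset(sweeps: SweepSet, path) -> None:
    """Write a sweep set as /sweeps/{i}/samples with dt/kind/stim-time attrs."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("sweeps")
        grp.attrs["stim_time_ms"] = sweeps.stim_time
        grp.attrs["dt_ms"] = sweeps.dt
        grp.attrs["kind"] = sweeps.sweeps[0].kind
        for key, val in sweeps.stim_meta.items():
            grp.attrs[f"meta_{key}"] = val
        for i, sw in enumerate(sweeps.sweeps):
            g = grp.create_group(str(i))
            ds = g.create_dataset("samples", data=sw.samples)
            ds.attrs["t0_ms"] = sw.t0


def read_sweepset(path) -> SweepSet:
    with h5py.File(path, "r") as f:
        grp = f["sweeps"]
        dt = float(grp.attrs["dt_ms"])
        kind = str(grp.attrs["kind"])
        stim_time = float(grp.attrs["stim_time_ms"])
        meta = {
            k[len("meta_"):]: (v.item() if hasattr(v, "item") else v)
            for k, v in grp.attrs.items()
            if k.startswith("meta_")
        }
        idx = sorted((k for k in grp.keys()), key=int)
        sweeps = [
            Trace(
                grp[k]["samples"][...],
                dt=dt,
                kind=kind,
                t0=float(grp[k]["samples"].attrs.get("t0_ms", 0.0)),
            )
            for k in idx
        ]
    return SweepSet(sweeps, stim_time=stim_time, stim_meta=meta)


def write_events(table: EventTable, path) -> None:
    """Write an event table to CSV with the canonical header, enforcing invariants."""
    # re-validate: the table may have been mutated through .df
    EventTable(table.df)
    table.df.to_csv(path, index=False)


def read_events(path) -> EventTable:
    df = pd.read_csv(path)
    if len(df) == 0:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    return EventTable(df)
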
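"""Core data model: timestamped recordings, epoch schedules, ratio computation, I/O.

Time is in seconds for imaging traces and milliseconds for electrophysiology
recordings; conversions happen only at I/O edges. Epochs are half-open
``[start, end)`` so every sample on a regular grid belongs to exactly one
adjacent epoch. No resampling or interpolation is performed anywhere: the
responder rule downstream counts consecutive *acquired* samples, so analyses
must operate on native timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RatioTrace",
    "Epoch",
    "EpochSchedule",
    "VoltageTrace",
    "CapacitanceRecording",
    "ratio",
    "slice_epoch",
    "read_traces",
    "write_traces",
    "TraceError",
]


class TraceError(ValueError):
    """Raised when a recording violates its structural invariants."""


EpochRole = Literal["baseline", "test", "washout", "positive_control", "preincubation"]


def _as_float_array(x: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise TraceError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class RatioTrace:
    """Per-cell two-channel fluorescence time series.

    chanA/chanB are the 340 nm / 380 nm excitation channels for Fura2 or the
    CFP / YFP emission channels for the FRET cAMP sensor. Backgrounds are
    per-sample (a constant background is the degenerate case) and optional.
    """

    cell_id: str
    time: np.ndarray  # s
    chanA: np.ndarray  # a.u.
    chanB: np.ndarray  # a.u.
    bgA: np.ndarray | None = None
    bgB: np.ndarray | None = None
    modality: Literal["fura2", "fret"] = "fura2"

    def __post_init__(self) -> None:
        t = _as_float_array(self.time, "time")
        a = _as_float_array(self.chanA, "chanA")
        b = _as_float_array(self.chanB, "chanB")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "chanA", a)
        object.__setattr__(self, "chanB", b)
        for name in ("bgA", "bgB"):
            bg = getattr(self, name)
            if bg is not None:
                object.__setattr__(self, name, _as_float_array(bg, name))
        n = len(t)
        for name in ("chanA", "chanB", "bgA", "bgB"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise TraceError(
                    f"cell {self.cell_id!r}: {name} has length {len(v)}, expected {n}"
                )
        if n and np.any(np.diff(t) <= 0):
            raise TraceError(f"cell {self.cell_id!r}: time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class Epoch:
    label: str
    start: float  # inclusive
    end: float  # exclusive
    role: EpochRole = "test"

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise TraceError(f"epoch {self.label!r}: end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


class EpochSchedule:
    """Ordered, non-overlapping labeled half-open intervals for one recording.

    Each test epoch must be preceded by at least 60 s of cumulative
    baseline-role coverage, and exactly one positive-control epoch is required
    unless explicitly waived (``require_positive_control=False``).
    """

    MIN_BASELINE_S = 60.0

    def __init__(
        self,
        epochs: Iterable[Epoch | tuple],
        require_positive_control: bool = True,
    ) -> None:
        eps: list[Epoch] = []
        for e in epochs:
            eps.append(e if isinstance(e, Epoch) else Epoch(*e))
        eps.sort(key=lambda e: e.start)
        for prev, nxt in zip(eps, eps[1:]):
            if nxt.start < prev.end:
                raise TraceError(
                    f"epochs {prev.label!r} and {nxt.label!r} overlap"
                )
        n_pc = sum(1 for e in eps if e.role == "positive_control")
        if require_positive_control and n_pc != 1:
            raise TraceError(
                f"schedule requires exactly one positive_control epoch, found {n_pc}"
            )
        for e in eps:
            if e.role == "test":
                cover = sum(
                    min(b.end, e.start) - b.start
                    for b in eps
                    if b.role == "baseline" and b.start < e.start
                )
                if cover < self.MIN_BASELINE_S:
                    raise TraceError(
                        f"test epoch {e.label!r} preceded by only {cover:g} s of "
                        f"baseline coverage (< {self.MIN_BASELINE_S:g} s)"
                    )
        self.epochs: tuple[Epoch, ...] = tuple(eps)

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]

    def __getitem__(self, label: str) -> Epoch:
        for e in self.epochs:
            if e.label == label:
                return e
        raise KeyError(f"no epoch labeled {label!r}")

    def __contains__(self, label: str) -> bool:
        return any(e.label == label for e in self.epochs)

    def by_role(self, role: EpochRole) -> list[Epoch]:
        return [e for e in self.epochs if e.role == role]

    def to_records(self) -> list[dict]:
        return [
            {"label": e.label, "start": e.start, "end": e.end, "role": e.role}
            for e in self.epochs
        ]

    @classmethod
    def from_records(cls, records: Iterable[dict], **kw) -> "EpochSchedule":
        return cls(
            (Epoch(r["label"], r["start"], r["end"], r.get("role", "test")) for r in records),
            **kw,
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, EpochSchedule) and self.epochs == other.epochs


@dataclass(frozen=True)
class VoltageTrace:
    """Membrane-potential recording with current-step annotations (ms / mV / pA)."""

    cell_id: str
    time: np.ndarray  # ms
    vm: np.ndarray  # mV
    step_annotations: tuple = ()  # (start_ms, end_ms, injected_pA)

    def __post_init__(self) -> None:
        t = _as_float_array(self.time, "time")
        v = _as_float_array(self.vm, "vm")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "vm", v)
        object.__setattr__(self, "step_annotations", tuple(tuple(s) for s in self.step_annotations))
        if len(t) != len(v):
            raise TraceError(f"cell {self.cell_id!r}: time/vm length mismatch")
        if len(t) and np.any(np.diff(t) <= 0):
            raise TraceError(f"cell {self.cell_id!r}: time must be strictly increasing")
        steps = sorted(self.step_annotations)
        for (s0, e0, _), (s1, _e1, _) in zip(steps, steps[1:]):
            if s1 < e0:
                raise TraceError(f"cell {self.cell_id!r}: overlapping current steps")


@dataclass(frozen=True)
class Pulse:
    """One depolarizing pulse of a capacitance protocol."""

    start: float  # ms
    duration: float  # ms (10, 100 or 500 in the standard protocols)
    v_from: float = -70.0  # mV
    v_to: float = 20.0  # mV
    peak_current: float = float("nan")  # pA, inward currents negative

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class CapacitanceRecording:
    """Membrane-capacitance samples in measurement windows plus pulse metadata.

    Cm is measured with a sine + DC technique that is suspended during
    depolarizations, so samples inside pulse intervals are invalid and must be
    absent. ``cm0`` is the initial whole-cell capacitance in pF (cell size).
    """

    cell_id: str
    time: np.ndarray  # ms
    cm: np.ndarray  # fF
    pulses: tuple[Pulse, ...]
    cm0: float  # pF

    def __post_init__(self) -> None:
        t = _as_float_array(self.time, "time")
        c = _as_float_array(self.cm, "cm")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "cm", c)
        object.__setattr__(self, "pulses", tuple(self.pulses))
        if len(t) != len(c):
            raise TraceError(f"cell {self.cell_id!r}: time/cm length mismatch")
        if len(t) and np.any(np.diff(t) <= 0):
            raise TraceError(f"cell {self.cell_id!r}: time must be strictly increasing")
        if not self.cm0 > 0:
            raise TraceError(f"cell {self.cell_id!r}: cm0 must be positive")
        pulses = self.pulses
        for p, q in zip(pulses, pulses[1:]):
            if q.start < p.end:
                raise TraceError(f"cell {self.cell_id!r}: pulses overlap or are unordered")
        for p in pulses:
            inside = (t >= p.start) & (t < p.end)
            if np.any(inside):
                raise TraceError(
                    f"cell {self.cell_id!r}: Cm samples present during pulse at {p.start} ms"
                )


def ratio(trace: RatioTrace) -> np.ndarray:
    """Background-subtracted channel ratio r_t = (A_t - bgA_t) / (B_t - bgB_t).

    Missing backgrounds are treated as zero. The output is aligned to the
    trace's native timestamps. A non-positive denominator anywhere invalidates
    the whole trace (the ratio is undefined there), and the offending sample
    index is reported.
    """
    bgA = trace.bgA if trace.bgA is not None else 0.0
    bgB = trace.bgB if trace.bgB is not None else 0.0
    num = trace.chanA - bgA
    den = trace.chanB - bgB
    bad = np.flatnonzero(den <= 0)
    if bad.size:
        raise TraceError(
            f"cell {trace.cell_id!r}: non-positive denominator at sample index {bad[0]}"
        )
    return num / den


def slice_epoch(
    time: np.ndarray,
    values: np.ndarray,
    schedule: EpochSchedule,
    label: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Samples of ``values`` falling in the half-open epoch ``[start, end)``.

    Raises ``KeyError`` for an unknown label and ``TraceError`` if the epoch
    contains no samples.
    """
    epoch = schedule[label]
    mask = (time >= epoch.start) & (time < epoch.end)
    if not np.any(mask):
        raise TraceError(f"epoch {label!r} [{epoch.start}, {epoch.end}) contains no samples")
    return time[mask], values[mask]


_TRACE_COLUMNS = ["cell_id", "time_s", "chanA", "chanB"]
_BG_COLUMNS = ["bgA", "bgB"]


def write_traces(
    path: str | Path,
    traces: Sequence[RatioTrace],
    schedule: EpochSchedule | None = None,
) -> None:
    """Write a cohort as a long-format CSV with a YAML epoch-schedule sidecar.

    The sidecar is ``<path stem>.epochs.yaml`` next to the CSV. Round-trip
    through :func:`read_traces` is lossless to 1e-9 relative.
    """
    path = Path(path)
    frames = []
    any_bg = any(t.bgA is not None or t.bgB is not None for t in traces)
    for t in traces:
        df = pd.DataFrame(
            {
                "cell_id": t.cell_id,
                "time_s": t.time,
                "chanA": t.chanA,
                "chanB": t.chanB,
            }
        )
        if any_bg:
            df["bgA"] = t.bgA if t.bgA is not None else 0.0
            df["bgB"] = t.bgB if t.bgB is not None else 0.0
        df["modality"] = t.modality
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=_TRACE_COLUMNS + ["modality"]
    )
    out.to_csv(path, index=False, float_format="%.12g")
    if schedule is not None:
        sidecar = path.with_suffix(".epochs.yaml")
        sidecar.write_text(yaml.safe_dump({"epochs": schedule.to_records()}, sort_keys=False))


def read_traces(
    path: str | Path,
    require_positive_control: bool = True,
) -> tuple[list[RatioTrace], EpochSchedule | None]:
    """Read a long-format trace CSV (and its epoch sidecar, if present)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceError(f"{path.name}: missing required column(s) {missing}")
    has_bg = all(c in df.columns for c in _BG_COLUMNS)
    traces = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        t = g["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TraceError(f"{path.name}: non-monotone time for cell {cell_id!r}")
        modality = str(g["modality"].iloc[0]) if "modality" in g.columns else "fura2"
        traces.append(
            RatioTrace(
                cell_id=str(cell_id),
                time=t,
                chanA=g["chanA"].to_numpy(dtype=float),
                chanB=g["chanB"].to_numpy(dtype=float),
                bgA=g["bgA"].to_numpy(dtype=float) if has_bg else None,
                bgB=g["bgB"].to_numpy(dtype=float) if has_bg else None,
                modality=modality,  # type: ignore[arg-type]
            )
        )
    sidecar = path.with_suffix(".epochs.yaml")
    schedule = None
    if sidecar.exists():
        payload = yaml.safe_load(sidecar.read_text())
        schedule = EpochSchedule.from_records(
            payload["epochs"], require_positive_control=require_positive_control
        )
    return traces, schedule
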
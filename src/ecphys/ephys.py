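"""Capacitance-based exocytosis quantification and action-potential analysis.

Pool sizes are read off the capacitance trace as window-mean differences: the
reference is the average Cm over the 300 ms before the first pulse, and each
landmark is the average over the 300 ms after the designated pulse (or over
the 300 ms ending the total-release window). Windows are clipped to available
interpulse samples and never cross a pulse; Cm during a depolarization is
missing data, not interpolated. The immediately releasable pool (IRP) is the
change after the short-pulse train, the readily releasable pool (RRP) the
additional change after the long pulses, and total release the change at the
end of the 0-7 s window (time origin at first-pulse onset). Normalized values
are fF per pF of initial capacitance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .traces import CapacitanceRecording, Pulse, TraceError, VoltageTrace

__all__ = [
    "PulseProtocol",
    "Landmarks",
    "PoolEstimate",
    "QCThresholds",
    "APSummary",
    "landmark_deltas",
    "pool_decomposition",
    "qc_classify",
    "potentiation_delta",
    "detect_spikes",
]


@dataclass(frozen=True)
class PulseProtocol:
    """Depolarization train geometry plus measurement-window conventions."""

    name: Literal["pool10", "potentiation15", "custom"]
    pulses: tuple[Pulse, ...]
    measurement_window: float = 300.0  # ms
    post_train_window: float = 9.5  # s of recording after the last pulse
    total_window: float = 7.0  # s after first-pulse onset for total release
    short_pulse_max_ms: float = 50.0  # pulses at or below this count as short

    @classmethod
    def pool10(cls, interpulse: float = 300.0, start: float = 0.0) -> "PulseProtocol":
        """6 short 10-ms then 4 long 100-ms depolarizations, -70 to +20 mV."""
        pulses = []
        t = start
        for dur in [10.0] * 6 + [100.0] * 4:
            pulses.append(Pulse(t, dur, -70.0, 20.0))
            t += dur + interpulse
        return cls(name="pool10", pulses=tuple(pulses))

    @classmethod
    def potentiation15(cls, interpulse: float = 300.0, start: float = 0.0) -> "PulseProtocol":
        """15 square 500-ms depolarizations, -60 to 0 mV."""
        pulses = tuple(
            Pulse(start + i * (500.0 + interpulse), 500.0, -60.0, 0.0) for i in range(15)
        )
        return cls(name="potentiation15", pulses=pulses, post_train_window=2.0)

    def validate(self) -> None:
        for p, q in zip(self.pulses, self.pulses[1:]):
            if q.start < p.end:
                raise TraceError(
                    f"protocol {self.name!r}: pulses at {p.start} and {q.start} ms overlap"
                )

    @property
    def n_short(self) -> int:
        return sum(1 for p in self.pulses if p.duration <= self.short_pulse_max_ms)


@dataclass(frozen=True)
class Landmarks:
    """Window-mean Cm changes relative to the pre-train reference (fF)."""

    after_short: float  # after the last short pulse
    after_train: float  # after the last pulse of the train
    total: float  # at the end of the total-release window


@dataclass(frozen=True)
class PoolEstimate:
    cell_id: str
    cm0: float  # pF
    irp_ff: float
    irp_ff_per_pf: float
    rrp_ff: float
    rrp_ff_per_pf: float
    total_ff: float
    total_ff_per_pf: float
    rrp_convention: Literal["cumulative", "incremental"]
    qc_class: str | None = None


def _window_mean(
    rec: CapacitanceRecording, start: float, end: float, what: str
) -> float:
    mask = (rec.time >= start) & (rec.time < end)
    if not np.any(mask):
        raise TraceError(
            f"cell {rec.cell_id!r}: no Cm samples in {what} window [{start:g}, {end:g}) ms"
        )
    return float(rec.cm[mask].mean())


def _post_pulse_window(
    rec: CapacitanceRecording, protocol: PulseProtocol, pulse_index: int
) -> tuple[float, float]:
    """The measurement window after a pulse, clipped so it never crosses the next."""
    p = rec.pulses[pulse_index]
    end = p.end + protocol.measurement_window
    if pulse_index + 1 < len(rec.pulses):
        end = min(end, rec.pulses[pulse_index + 1].start)
    return p.end, end


def landmark_deltas(
    rec: CapacitanceRecording,
    protocol: PulseProtocol,
    total_window: float | None = None,
) -> Landmarks:
    """Cm landmarks relative to the 300-ms pre-train reference.

    ``total_window`` (s after first-pulse onset) overrides the protocol
    default of 7 s.
    """
    protocol.validate()
    if len(rec.pulses) != len(protocol.pulses):
        raise TraceError(
            f"cell {rec.cell_id!r}: recording has {len(rec.pulses)} pulses, "
            f"protocol {protocol.name!r} expects {len(protocol.pulses)}"
        )
    t0 = rec.pulses[0].start
    ref = _window_mean(rec, t0 - protocol.measurement_window, t0, "pre-train reference")

    n_short = protocol.n_short
    if n_short:
        a, b = _post_pulse_window(rec, protocol, n_short - 1)
        after_short = _window_mean(rec, a, b, f"post-pulse-{n_short}") - ref
    else:
        after_short = 0.0
    a, b = _post_pulse_window(rec, protocol, len(rec.pulses) - 1)
    after_train = _window_mean(rec, a, b, f"post-pulse-{len(rec.pulses)}") - ref

    tw = protocol.total_window if total_window is None else total_window
    t_end = t0 + tw * 1000.0
    total = _window_mean(
        rec, t_end - protocol.measurement_window, t_end, "end-of-total-window"
    ) - ref
    return Landmarks(after_short=after_short, after_train=after_train, total=total)


def pool_decomposition(
    landmarks: Landmarks,
    cm0: float,
    cell_id: str = "",
    convention: Literal["cumulative", "incremental"] = "incremental",
    qc_class: str | None = None,
) -> PoolEstimate:
    """Decompose landmark deltas into IRP / RRP / total release.

    Under the ``cumulative`` convention the RRP is the full change after the
    long-pulse train; under ``incremental`` (default) the IRP is subtracted so
    the RRP is the pool accessible beyond it. The two differ by exactly the
    IRP. All values are reported both absolute (fF) and normalized to initial
    capacitance (fF/pF).
    """
    if not cm0 > 0:
        raise TraceError("cm0 must be positive")
    irp = landmarks.after_short
    rrp = landmarks.after_train if convention == "cumulative" else landmarks.after_train - irp
    total = landmarks.total
    return PoolEstimate(
        cell_id=cell_id,
        cm0=cm0,
        irp_ff=irp,
        irp_ff_per_pf=irp / cm0,
        rrp_ff=rrp,
        rrp_ff_per_pf=rrp / cm0,
        total_ff=total,
        total_ff_per_pf=total / cm0,
        rrp_convention=convention,
        qc_class=qc_class,
    )


@dataclass(frozen=True)
class QCThresholds:
    """Operational thresholds for the qualitative exclusion taxonomy."""

    noise_floor_k: float = 3.0  # multiples of pre-train Cm SD
    current_threshold: float = 20.0  # pA, |peak current| above this is "robust"
    corr_threshold: float = 0.5  # pulse alignment of Cm increments


def _block_means(
    rec: CapacitanceRecording, block_ms: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Means of consecutive ``block_ms`` blocks within contiguous segments.

    Returns (block start times, block end times, block means). Segment breaks
    (pulse gaps) also break blocks.
    """
    t = rec.time
    gaps = np.flatnonzero(np.diff(t) > 2.5 * np.median(np.diff(t)))
    seg_bounds = np.concatenate([[0], gaps + 1, [len(t)]])
    starts, ends, means = [], [], []
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        seg_t, seg_c = t[a:b], rec.cm[a:b]
        edges = np.arange(seg_t[0], seg_t[-1] + 1e-9, block_ms)
        for lo in edges:
            hi = lo + block_ms
            m = (seg_t >= lo) & (seg_t < hi)
            if np.any(m):
                starts.append(lo)
                ends.append(min(hi, seg_t[m][-1] + 1e-9))
                means.append(seg_c[m].mean())
    return np.asarray(starts), np.asarray(ends), np.asarray(means)


def qc_classify(
    rec: CapacitanceRecording,
    protocol: PulseProtocol,
    thresholds: QCThresholds | None = None,
    unstable: bool = False,
) -> str:
    """Assign a recording to the exclusion taxonomy.

    Classes: ``provoked`` (clear Cm increase aligned with current peaks),
    ``no_exocytosis`` (no Cm change despite robust inward currents),
    ``spontaneous`` (Cm fluctuations uncorrelated with the pulse train), and
    ``unstable`` (caller-supplied access-resistance/conductance flag). The
    decision statistics are block-mean increments of the Cm trace versus an
    indicator of pulse occurrence between blocks.
    """
    th = thresholds or QCThresholds()
    if unstable:
        return "unstable"
    if any(np.isnan(p.peak_current) for p in rec.pulses):
        raise TraceError(f"cell {rec.cell_id!r}: pulses lack peak-current annotations")

    t0 = rec.pulses[0].start
    pre = rec.cm[(rec.time >= t0 - protocol.measurement_window) & (rec.time < t0)]
    if len(pre) < 2:
        raise TraceError(f"cell {rec.cell_id!r}: pre-train reference window is empty")
    baseline_sd = float(np.std(pre, ddof=1))
    floor = max(th.noise_floor_k * baseline_sd, 1e-6)

    starts, ends, means = _block_means(rec, protocol.measurement_window)
    inc = np.diff(means)
    pulse_between = np.array(
        [
            any(ends[j] - 1e-9 <= p.start <= starts[j + 1] + 1e-9 for p in rec.pulses)
            for j in range(len(inc))
        ]
    )
    robust = (
        np.mean([abs(p.peak_current) >= th.current_threshold for p in rec.pulses]) >= 0.5
    )

    if pulse_between.any() and (~pulse_between).any() and np.std(inc) > 0:
        corr = float(np.corrcoef(inc, pulse_between.astype(float))[0, 1])
    else:
        corr = 0.0
    mean_pulse_inc = float(inc[pulse_between].mean()) if pulse_between.any() else 0.0
    max_free_inc = (
        float(np.abs(inc[~pulse_between]).max()) if (~pulse_between).any() else 0.0
    )

    if corr >= th.corr_threshold and mean_pulse_inc > floor:
        return "provoked"
    if max_free_inc > floor:
        return "spontaneous"
    if robust:
        return "no_exocytosis"
    # quiescent trace without robust currents: nothing was provoked either way
    return "no_exocytosis"


def potentiation_delta(
    rec: CapacitanceRecording,
    protocol: PulseProtocol | None = None,
) -> tuple[float, float]:
    """Train-evoked Cm change for the potentiation protocol.

    Difference between the average Cm over the 300 ms before the first pulse
    and over the 300 ms after the last pulse. Returns (fF, fF/pF).
    """
    protocol = protocol or PulseProtocol.potentiation15()
    protocol.validate()
    if len(rec.pulses) != len(protocol.pulses):
        raise TraceError(
            f"cell {rec.cell_id!r}: recording has {len(rec.pulses)} pulses, "
            f"protocol {protocol.name!r} expects {len(protocol.pulses)}"
        )
    t0 = rec.pulses[0].start
    ref = _window_mean(rec, t0 - protocol.measurement_window, t0, "pre-train reference")
    a, b = _post_pulse_window(rec, protocol, len(rec.pulses) - 1)
    delta = _window_mean(rec, a, b, "post-train") - ref
    return delta, delta / rec.cm0


@dataclass(frozen=True)
class APSummary:
    """Per-cell action-potential summary for one current step."""

    cell_id: str
    spike_count: int
    resting_vm: float  # mV, before the step
    threshold: float  # mV, mean over spikes (nan if none)
    overshoot: float  # mV, mean spike peak
    half_width: float  # ms, mean width at half amplitude (threshold to peak)
    spikes: tuple[dict, ...] = field(default_factory=tuple)


def detect_spikes(
    vt: VoltageTrace,
    step_index: int = 0,
    detection_level: float = -20.0,
    refractory: float = 5.0,
    slope_criterion: float = 10.0,
    hysteresis: float = 10.0,
) -> APSummary:
    """Count and characterize action potentials within one current step.

    Spikes are upward crossings of ``detection_level`` with a refractory
    lockout; the detector re-arms only once Vm has fallen ``hysteresis`` mV
    below the detection level, so noise riding on the repolarization cannot
    re-trigger it. The biophysical threshold of each spike is estimated separately
    from the detection level: walking back from the crossing, it is the
    membrane potential where dV/dt first exceeds ``slope_criterion`` (mV/ms).
    Overshoot is the spike peak; half-width is the duration at the level
    halfway between threshold and peak, sub-sample interpolated.
    """
    if not vt.step_annotations:
        raise TraceError(f"cell {vt.cell_id!r}: no current-step annotations")
    try:
        s_start, s_end, _amp = vt.step_annotations[step_index]
    except IndexError:
        raise TraceError(
            f"cell {vt.cell_id!r}: step index {step_index} out of range"
        ) from None
    in_step = (vt.time >= s_start) & (vt.time < s_end)
    if not np.any(in_step):
        raise TraceError(f"cell {vt.cell_id!r}: current step contains no samples")
    t, v = vt.time, vt.vm
    idx = np.flatnonzero(in_step)

    accepted: list[int] = []
    armed = True
    for i in idx:
        if i == 0:
            continue
        if armed and v[i - 1] <= detection_level < v[i]:
            if not accepted or t[i] - t[accepted[-1]] > refractory:
                accepted.append(i)
                armed = False
        elif not armed and v[i] < detection_level - hysteresis:
            armed = True

    dvdt = np.diff(v) / np.diff(t)  # slope of segment [i, i+1]
    spikes = []
    for k, i in enumerate(accepted):
        # spike region: from this crossing until Vm falls back below the level
        j = i
        last = accepted[k + 1] if k + 1 < len(accepted) else idx[-1] + 1
        while j < last - 1 and v[j] > detection_level:
            j += 1
        peak_rel = int(np.argmax(v[i:j + 1]))
        peak_i = i + peak_rel
        # threshold: walk back along the fast upstroke
        m = i - 1
        while m > 0 and dvdt[m - 1] >= slope_criterion:
            m -= 1
        threshold = float(v[m])
        peak = float(v[peak_i])
        half = threshold + (peak - threshold) / 2.0
        hw = _half_width(t, v, peak_i, half)
        spikes.append(
            {"t_peak": float(t[peak_i]), "threshold": threshold, "overshoot": peak,
             "half_width": hw}
        )

    before = v[vt.time < s_start]
    resting = float(np.median(before)) if len(before) else float(np.median(v))
    if spikes:
        thr = float(np.mean([s["threshold"] for s in spikes]))
        ovs = float(np.mean([s["overshoot"] for s in spikes]))
        hw = float(np.nanmean([s["half_width"] for s in spikes]))
    else:
        thr = ovs = hw = float("nan")
    return APSummary(
        cell_id=vt.cell_id,
        spike_count=len(spikes),
        resting_vm=resting,
        threshold=thr,
        overshoot=ovs,
        half_width=hw,
        spikes=tuple(spikes),
    )


def _half_width(t: np.ndarray, v: np.ndarray, peak_i: int, level: float) -> float:
    """Width at ``level`` around the peak, linearly interpolated (ms)."""
    i = peak_i
    while i > 0 and v[i] >= level:
        i -= 1
    if v[i] >= level:
        return float("nan")
    t_up = t[i] + (t[i + 1] - t[i]) * (level - v[i]) / (v[i + 1] - v[i])
    j = peak_i
    while j < len(v) - 1 and v[j] >= level:
        j += 1
    if v[j] >= level:
        return float("nan")
    t_dn = t[j - 1] + (t[j] - t[j - 1]) * (v[j - 1] - level) / (v[j - 1] - v[j])
    return float(t_dn - t_up)
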
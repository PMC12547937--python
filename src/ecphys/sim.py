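"""Synthetic cohorts with known ground truth for every analysis stage.

The generator emulates the acquisition protocols of the study system —
perfusion imaging sampled at 0.5 Hz (one exposure every 2 s), capacitance
trains of 6 short + 4 long depolarizations with 300-ms interpulse measurement
windows, 1-s current-step injections, and ELISA secretion plates with
log-normal well noise — while keeping the underlying response models
deliberately phenomenological: a multiplicative step on the ratio, sequential
depletion of two vesicle pools, stereotyped spike waveforms, and a single
fold-change parameter per plate. Every simulator takes an explicit seed and is
bit-reproducible; there is no global random state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .ephys import PulseProtocol
from .traces import (
    CapacitanceRecording,
    Epoch,
    EpochSchedule,
    Pulse,
    RatioTrace,
    VoltageTrace,
)

__all__ = [
    "ImagingEpochSpec",
    "ImagingSimConfig",
    "PoolSimConfig",
    "SecretionSimConfig",
    "simulate_imaging_cohort",
    "simulate_capacitance",
    "simulate_voltage_trace",
    "simulate_secretion_plate",
]


class ImagingEpochSpec(BaseModel):
    """One stimulus epoch: label, duration and the true multiplicative effect.

    ``amplitude`` is the plateau ratio during the epoch relative to the
    baseline ratio (1.0 means no effect); it applies only to cells drawn as
    responders for this epoch.
    """

    label: str
    duration: float = Field(gt=0, description="s")
    amplitude: float = Field(ge=0, description="multiplicative, 1 = no effect")


class ImagingSimConfig(BaseModel):
    """Perfusion-imaging cohort: step responses on a noisy, drifting ratio.

    The time grid is ``sample_interval`` seconds apart (default 2 s, the
    0.5 Hz acquisition cadence). The recording is baseline, then each test
    epoch followed by a washout at baseline level, then the positive-control
    epoch. Responder status is drawn per cell and per epoch with probability
    ``responder_fraction``; the positive control applies to every cell.
    """

    n_cells: int = Field(ge=1)
    sample_interval: float = Field(default=2.0, gt=0, description="s")
    baseline_dur: float = Field(default=120.0, gt=0, description="s")
    baseline_ratio: float = Field(default=1.0, gt=0)
    epochs: list[ImagingEpochSpec] = Field(default_factory=list)
    washout_dur: float = Field(default=60.0, gt=0, description="s between test epochs")
    noise_sd: float = Field(default=0.0, ge=0, description="ratio units")
    drift_slope: float = Field(default=0.0, description="ratio units per s")
    positive_control_amplitude: float = Field(default=1.5, ge=0)
    positive_control_dur: float = Field(default=60.0, gt=0, description="s")
    responder_fraction: float = Field(default=1.0, ge=0, le=1)
    ramp_samples: int = Field(default=0, ge=0, le=1, description="1-sample linear onset")
    modality: str = "fura2"
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "ImagingSimConfig":
        if self.baseline_dur < 60.0:
            raise ValueError("baseline_dur: must cover at least the 60-s reference window")
        return self


def _build_imaging_schedule(cfg: ImagingSimConfig) -> EpochSchedule:
    eps = [Epoch("baseline", 0.0, cfg.baseline_dur, "baseline")]
    t = cfg.baseline_dur
    for i, spec in enumerate(cfg.epochs):
        eps.append(Epoch(spec.label, t, t + spec.duration, "test"))
        t += spec.duration
        eps.append(Epoch(f"washout{i + 1}", t, t + cfg.washout_dur, "washout"))
        t += cfg.washout_dur
    eps.append(Epoch("positive_control", t, t + cfg.positive_control_dur, "positive_control"))
    return EpochSchedule(eps)


def simulate_imaging_cohort(
    cfg: ImagingSimConfig,
) -> tuple[list[RatioTrace], EpochSchedule, pd.DataFrame]:
    """Simulate a perfusion-imaging cohort.

    Returns the traces (the simulated ratio is carried in chanA with chanB
    fixed at 1, so the ratio operation recovers it exactly), the shared epoch
    schedule, and a ground-truth table with one row per cell x epoch recording
    the drawn responder status and the true plateau amplitude.
    """
    rng = np.random.default_rng(cfg.seed)
    schedule = _build_imaging_schedule(cfg)
    total_dur = schedule.epochs[-1].end
    time = np.arange(0.0, total_dur, cfg.sample_interval)

    # per-epoch multiplicative profile shared by all responders to that epoch
    profiles = {}
    for spec in cfg.epochs:
        ep = schedule[spec.label]
        mask = (time >= ep.start) & (time < ep.end)
        prof = np.ones_like(time)
        prof[mask] = spec.amplitude
        if cfg.ramp_samples and mask.any():
            prof[np.flatnonzero(mask)[0]] = (1.0 + spec.amplitude) / 2.0
        profiles[spec.label] = prof
    pc = schedule["positive_control"]
    pc_prof = np.ones_like(time)
    pc_mask = (time >= pc.start) & (time < pc.end)
    pc_prof[pc_mask] = cfg.positive_control_amplitude
    if cfg.ramp_samples and pc_mask.any():
        pc_prof[np.flatnonzero(pc_mask)[0]] = (1.0 + cfg.positive_control_amplitude) / 2.0

    traces: list[RatioTrace] = []
    truth_rows = []
    for i in range(cfg.n_cells):
        cell_id = f"cell{i:04d}"
        amp = np.ones_like(time)
        for spec in cfg.epochs:
            is_resp = bool(rng.random() < cfg.responder_fraction)
            if is_resp:
                amp = amp * profiles[spec.label]
            truth_rows.append(
                {
                    "cell_id": cell_id,
                    "epoch": spec.label,
                    "true_responder": is_resp,
                    "true_amplitude": spec.amplitude if is_resp else 1.0,
                }
            )
        amp = amp * pc_prof
        truth_rows.append(
            {
                "cell_id": cell_id,
                "epoch": "positive_control",
                "true_responder": True,
                "true_amplitude": cfg.positive_control_amplitude,
            }
        )
        r = cfg.baseline_ratio * amp + cfg.drift_slope * time
        if cfg.noise_sd > 0:
            r = r + rng.normal(0.0, cfg.noise_sd, size=time.shape)
        traces.append(
            RatioTrace(
                cell_id=cell_id,
                time=time.copy(),
                chanA=r,
                chanB=np.ones_like(time),
                modality=cfg.modality,  # type: ignore[arg-type]
            )
        )
    truth = pd.DataFrame(truth_rows)
    return traces, schedule, truth


class PoolSimConfig(BaseModel):
    """Forward model for depolarization-evoked exocytosis.

    Two sequential pools deplete geometrically: each short pulse releases
    ``release_fraction_short`` of the remaining immediately releasable pool
    (IRP); the first long pulse additionally liberates whatever IRP remains,
    and each long pulse releases ``release_fraction_long`` of the remaining
    readily releasable pool (RRP). Sustained exocytosis adds linear Cm growth
    during the post-train window; endocytosis subtracts linearly everywhere
    after the first pulse. Cm samples exist only in measurement windows (the
    sine-wave estimate is invalid during depolarizations).
    """

    irp_size: float = Field(default=3.5, ge=0, description="fF")
    rrp_size: float = Field(default=91.0, ge=0, description="fF")
    sustained_rate: float = Field(default=0.0, ge=0, description="fF/s, post-train only")
    release_fraction_short: float = Field(default=0.35, ge=0, le=1)
    release_fraction_long: float = Field(default=0.55, ge=0, le=1)
    endocytosis_rate: float = Field(default=0.0, ge=0, description="fF/s")
    cm0: float = Field(default=10.8, gt=0, description="pF initial capacitance")
    noise_sd: float = Field(default=0.0, ge=0, description="fF per sample")
    sample_interval: float = Field(default=10.0, gt=0, description="ms between Cm samples")
    pre_dur: float = Field(default=1000.0, gt=0, description="ms of pre-train recording")
    peak_current: float = Field(default=-150.0, description="pA; ~0 fabricates no-current cells")
    current_jitter: float = Field(default=0.05, ge=0, description="fractional jitter")
    seed: int = 0


def _cumulative_release(cfg: PoolSimConfig, protocol: PulseProtocol) -> np.ndarray:
    """Pool release added by each pulse, cumulatively, in pulse order (fF)."""
    irp_rem = cfg.irp_size
    rrp_rem = cfg.rrp_size
    out = []
    total = 0.0
    for p in protocol.pulses:
        if p.duration <= protocol.short_pulse_max_ms:
            rel = cfg.release_fraction_short * irp_rem
            irp_rem -= rel
        else:
            rel = irp_rem + cfg.release_fraction_long * rrp_rem
            irp_rem = 0.0
            rrp_rem -= cfg.release_fraction_long * rrp_rem
        total += rel
        out.append(total)
    return np.asarray(out)


def simulate_capacitance(
    cfg: PoolSimConfig,
    protocol: PulseProtocol | None = None,
    cell_id: str = "sim",
) -> tuple[CapacitanceRecording, dict]:
    """Simulate one capacitance recording under a pulse protocol.

    Returns the recording and a ground-truth dict with the cumulative release
    after every pulse plus the configured pool parameters.
    """
    if protocol is None:
        protocol = PulseProtocol.pool10()
    protocol.validate()
    rng = np.random.default_rng(cfg.seed)
    pulses = protocol.pulses
    t0 = pulses[0].start
    cum = _cumulative_release(cfg, protocol)

    # sample times: pre window, interpulse gaps, post-train window
    segments = [(t0 - cfg.pre_dur, t0)]
    for p, q in zip(pulses, pulses[1:]):
        segments.append((p.end, q.start))
    post_end = pulses[-1].end + protocol.post_train_window * 1000.0
    segments.append((pulses[-1].end, post_end))
    times = np.concatenate(
        [np.arange(a, b, cfg.sample_interval) for (a, b) in segments]
    )

    release = np.zeros_like(times)
    for p, c in zip(pulses, cum):
        release[times >= p.end] = c
    sustained = np.where(
        times > pulses[-1].end,
        cfg.sustained_rate * (times - pulses[-1].end) / 1000.0,
        0.0,
    )
    endo = np.where(times > t0, cfg.endocytosis_rate * (times - t0) / 1000.0, 0.0)
    cm = cfg.cm0 * 1000.0 + release + sustained - endo
    if cfg.noise_sd > 0:
        cm = cm + rng.normal(0.0, cfg.noise_sd, size=cm.shape)

    annotated = tuple(
        Pulse(
            p.start,
            p.duration,
            p.v_from,
            p.v_to,
            peak_current=cfg.peak_current
            * (1.0 + cfg.current_jitter * rng.standard_normal()),
        )
        for p in pulses
    )
    rec = CapacitanceRecording(
        cell_id=cell_id, time=times, cm=cm, pulses=annotated, cm0=cfg.cm0
    )
    n_short = sum(1 for p in pulses if p.duration <= protocol.short_pulse_max_ms)
    truth = {
        "cum_release": cum,
        "released_after_shorts": float(cum[n_short - 1]) if n_short else 0.0,
        "released_after_train": float(cum[-1]),
        "irp_size": cfg.irp_size,
        "rrp_size": cfg.rrp_size,
        "cm0": cfg.cm0,
    }
    return rec, truth


def simulate_voltage_trace(
    spike_times: list[float],
    threshold: float = -23.5,
    peak: float = 35.5,
    half_width: float = 19.1,
    baseline: float = -70.0,
    noise_sd: float = 0.0,
    sample_interval: float = 0.1,
    duration: float | None = None,
    foot_dur: float = 10.0,
    upstroke_dur: float = 1.5,
    step: tuple[float, float, float] | None = None,
    seed: int = 0,
    cell_id: str = "sim",
) -> VoltageTrace:
    """Stereotyped action potentials on a flat baseline (all times in ms).

    Each spike is piecewise linear: a slow depolarizing foot from baseline to
    ``threshold`` over ``foot_dur`` (below the downstream dV/dt threshold
    criterion), a fast upstroke to ``peak`` over ``upstroke_dur``, then a
    linear decay back to baseline whose slope is chosen so the width at the
    half-amplitude level (threshold + peak)/2 equals ``half_width``. Spikes
    are anchored at their peak times and may not overlap.
    """
    spike_times = sorted(float(s) for s in spike_times)
    amp = peak - baseline
    if amp <= 0 or peak <= threshold or threshold <= baseline:
        raise ValueError("require baseline < threshold < peak")
    # decay duration making total width at the half level equal half_width
    half_level_drop = (peak - threshold) / 2.0  # from peak down to half level
    decay_dur = (half_width - upstroke_dur * 0.5) * amp / half_level_drop
    if decay_dur <= 0:
        raise ValueError("half_width too small for the configured upstroke")
    span = foot_dur + upstroke_dur + decay_dur
    for a, b in zip(spike_times, spike_times[1:]):
        if b - a < span:
            raise ValueError(f"spikes at {a} and {b} ms overlap (span {span:.1f} ms)")
    if duration is None:
        duration = (spike_times[-1] + span + 50.0) if spike_times else 1000.0
    if spike_times and (
        spike_times[0] - (foot_dur + upstroke_dur) < 0 or spike_times[-1] + decay_dur > duration
    ):
        raise ValueError("spike waveform extends outside the trace duration")

    t = np.arange(0.0, duration, sample_interval)
    vm = np.full_like(t, baseline)
    for s in spike_times:
        t_foot = s - upstroke_dur - foot_dur
        t_up = s - upstroke_dur
        seg = np.zeros_like(t)
        m = (t >= t_foot) & (t < t_up)
        seg[m] = (threshold - baseline) * (t[m] - t_foot) / foot_dur
        m = (t >= t_up) & (t < s)
        seg[m] = (threshold - baseline) + (peak - threshold) * (t[m] - t_up) / upstroke_dur
        m = (t >= s) & (t < s + decay_dur)
        seg[m] = amp * (1.0 - (t[m] - s) / decay_dur)
        vm = np.maximum(vm, baseline + seg)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vm = vm + rng.normal(0.0, noise_sd, size=vm.shape)
    steps = (step,) if step is not None else ((0.0, duration, 30.0),)
    return VoltageTrace(cell_id=cell_id, time=t, vm=vm, step_annotations=steps)


class SecretionSimConfig(BaseModel):
    """One ELISA secretion plate with log-normal well-to-well variability.

    Basal wells scatter log-normally around ``basal_mean`` (default the
    0.47 ng/mL cross-experiment basal release); treatment wells around
    ``true_fold`` times that. Values outside the assay range
    [``lod_low``, ``lod_high``] are clipped to the bound and flagged.
    """

    n_basal_wells: int = Field(default=6, ge=1)
    n_treatment_wells: int = Field(default=6, ge=1)
    basal_mean: float = Field(default=0.47, gt=0, description="ng/mL")
    true_fold: float = Field(default=2.0, ge=0)
    cv: float = Field(default=0.3, ge=0, description="fractional CV, log-normal")
    lod_low: float = Field(default=0.015, description="ng/mL")
    lod_high: float = Field(default=2.5, description="ng/mL")
    treatment_label: str = "treatment"
    plate_id: str = "plate1"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SecretionSimConfig":
        if not self.lod_low < self.lod_high:
            raise ValueError("lod_low: must be below lod_high")
        return self


def _lognormal_mean_cv(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def simulate_secretion_plate(cfg: SecretionSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate one secretion plate.

    Returns a tidy plate table (plate_id, well, condition, ng_per_ml,
    in_range) and the ground truth fold change.
    """
    rng = np.random.default_rng(cfg.seed)
    basal = _lognormal_mean_cv(rng, cfg.basal_mean, cfg.cv, cfg.n_basal_wells)
    treat = _lognormal_mean_cv(
        rng, cfg.true_fold * cfg.basal_mean, cfg.cv, cfg.n_treatment_wells
    )
    rows = []
    well = 0
    for cond, vals in (("basal", basal), (cfg.treatment_label, treat)):
        for v in vals:
            in_range = bool(cfg.lod_low <= v <= cfg.lod_high)
            rows.append(
                {
                    "plate_id": cfg.plate_id,
                    "well": f"W{well:02d}",
                    "condition": cond,
                    "ng_per_ml": float(np.clip(v, cfg.lod_low, cfg.lod_high)),
                    "in_range": in_range,
                }
            )
            well += 1
    truth = {"true_fold": cfg.true_fold, "basal_mean": cfg.basal_mean}
    return pd.DataFrame(rows), truth
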
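"""Single-cell stimulus-response quantification for perfusion imaging.

The pipeline mirrors the field's standard workflow for ratiometric Ca2+
(Fura2 340/380) and FRET cAMP (CFP/YFP) perfusion recordings:

* cells enter the analysis only if their positive control (KCl or
  forskolin + IBMX) elevates the ratio by at least 10% over baseline;
* a cell is a *responder* to a stimulus if the z-score of its ratio,
  standardized against the 60 s of baseline samples immediately preceding the
  stimulus addition, exceeds 3 for at least 2 consecutive acquired timepoints
  during the stimulus epoch;
* per-cell effect sizes are R/R0 fold changes, the ratio of an aggregate
  (default: maximum) over the stimulus epoch to the same aggregate over the
  preceding 60-s basal window;
* Gi-mediated inhibition is quantified as the minimum ratio during
  IBMX + agonist, expressed as a percentage of the forskolin + IBMX maximum
  of the same cell, bracketed by the IBMX-alone maxima before and after.

Excluded cells are retained in outputs with ``included=False`` and a reason
code rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .traces import EpochSchedule, RatioTrace, TraceError, ratio, slice_epoch

__all__ = [
    "ResponderCall",
    "InhibitionCall",
    "inclusion_gate",
    "zscore_series",
    "classify_responder",
    "fold_change",
    "quantify_inhibition",
    "analyze_imaging_cohort",
    "BASELINE_WINDOW_S",
]

BASELINE_WINDOW_S = 60.0

_AGGREGATORS: dict[str, Callable[[np.ndarray], float]] = {
    "max": lambda x: float(np.max(x)),
    "mean": lambda x: float(np.mean(x)),
}


@dataclass(frozen=True)
class ResponderCall:
    cell_id: str
    stimulus: str
    included: bool
    exclusion_reason: str | None
    responder: bool
    run_length: int
    z_max: float
    fold_change: float
    aggregator: Literal["max", "mean"]


@dataclass(frozen=True)
class InhibitionCall:
    """Ratios around an IBMX + Gi-agonist application, as % of the F+I max."""

    cell_id: str
    pct_ibmx1_max: float
    pct_agonist_min: float
    pct_ibmx2_max: float


def _baseline_window(
    time: np.ndarray, values: np.ndarray, epoch_start: float, window_s: float
) -> np.ndarray:
    mask = (time >= epoch_start - window_s) & (time < epoch_start)
    return values[mask]


def inclusion_gate(
    time: np.ndarray,
    values: np.ndarray,
    schedule: EpochSchedule,
    threshold_pct: float = 10.0,
) -> tuple[bool, str | None]:
    """Positive-control gate: at least a ``threshold_pct`` % elevation.

    The baseline reference is the mean ratio over the 60-s window preceding
    the first test epoch; the cell is included iff the maximum ratio within
    the positive-control epoch reaches (1 + threshold_pct/100) times that
    reference (boundary inclusive). Returns (included, reason); a missing
    positive-control epoch or empty window yields an exclusion reason code,
    never a silent drop.
    """
    pcs = schedule.by_role("positive_control")
    if not pcs:
        return False, "no_positive_control_epoch"
    tests = schedule.by_role("test")
    anchor = tests[0].start if tests else pcs[0].start
    base = _baseline_window(time, values, anchor, BASELINE_WINDOW_S)
    if base.size == 0:
        return False, "empty_baseline_window"
    try:
        _, pc_vals = slice_epoch(time, values, schedule, pcs[0].label)
    except TraceError:
        return False, "empty_positive_control_epoch"
    ref = float(base.mean())
    if ref <= 0:
        return False, "nonpositive_baseline_reference"
    if float(pc_vals.max()) >= (1.0 + threshold_pct / 100.0) * ref:
        return True, None
    return False, "positive_control_below_threshold"


def zscore_series(
    time: np.ndarray,
    values: np.ndarray,
    schedule: EpochSchedule,
    label: str,
    baseline_s: float = BASELINE_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray]:
    """z_t = (F_t - mean F_b) / SD F_b over the stimulus epoch.

    F_b are the baseline samples acquired during the ``baseline_s`` seconds
    immediately before the epoch start (stimulus addition); SD uses the n-1
    denominator. Returns (epoch sample times, z values).
    """
    epoch = schedule[label]
    base = _baseline_window(time, values, epoch.start, baseline_s)
    if base.size < 2:
        raise TraceError(
            f"epoch {label!r}: only {base.size} baseline sample(s) in the "
            f"{baseline_s:g}-s window before t={epoch.start:g}"
        )
    sd = float(np.std(base, ddof=1))
    if sd == 0:
        raise TraceError(f"epoch {label!r}: degenerate baseline (SD = 0)")
    t_ep, v_ep = slice_epoch(time, values, schedule, label)
    return t_ep, (v_ep - float(base.mean())) / sd


def classify_responder(
    z: np.ndarray, threshold: float = 3.0, min_run: int = 2
) -> tuple[bool, int]:
    """Responder iff z > threshold (strict) on >= min_run consecutive samples.

    Returns (responder, longest run length), the run length reported even
    when it falls short of ``min_run``.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise TraceError("empty z-score series")
    above = z > threshold
    best = run = 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    return best >= min_run, best


def fold_change(
    time: np.ndarray,
    values: np.ndarray,
    schedule: EpochSchedule,
    label: str,
    aggregator: Literal["max", "mean"] = "max",
    baseline_s: float = BASELINE_WINDOW_S,
) -> float:
    """R/R0: aggregate over the stimulus epoch over the same aggregate over
    the 60-s basal window preceding it."""
    agg = _AGGREGATORS[aggregator]
    epoch = schedule[label]
    _, v_ep = slice_epoch(time, values, schedule, label)
    base = _baseline_window(time, values, epoch.start, baseline_s)
    if base.size == 0:
        raise TraceError(f"epoch {label!r}: empty basal reference window")
    r0 = agg(base)
    if r0 <= 0:
        raise TraceError(f"epoch {label!r}: non-positive basal reference")
    return agg(v_ep) / r0


def quantify_inhibition(
    time: np.ndarray,
    values: np.ndarray,
    schedule: EpochSchedule,
    cell_id: str = "",
    labels: tuple[str, str, str, str] = ("IBMX1", "IBMX+agonist", "IBMX2", "F+I"),
) -> InhibitionCall:
    """Quantify cAMP lowering by a Gi agonist under phosphodiesterase block.

    Returns the IBMX-alone maxima (before and after the agonist) and the
    minimum during IBMX + agonist, each as a percentage of the
    forskolin + IBMX maximum recorded in the same cell.
    """
    lab_pre, lab_ag, lab_post, lab_fi = labels
    for lab in labels:
        if lab not in schedule:
            raise TraceError(f"required epoch {lab!r} missing from schedule")
    _, fi = slice_epoch(time, values, schedule, lab_fi)
    denom = float(fi.max())
    if denom <= 0:
        raise TraceError("non-positive forskolin+IBMX maximum")
    _, pre = slice_epoch(time, values, schedule, lab_pre)
    _, ag = slice_epoch(time, values, schedule, lab_ag)
    _, post = slice_epoch(time, values, schedule, lab_post)
    return InhibitionCall(
        cell_id=cell_id,
        pct_ibmx1_max=100.0 * float(pre.max()) / denom,
        pct_agonist_min=100.0 * float(ag.min()) / denom,
        pct_ibmx2_max=100.0 * float(post.max()) / denom,
    )


def analyze_imaging_cohort(
    traces: Sequence[RatioTrace],
    schedule: EpochSchedule,
    stimuli: Sequence[str] | None = None,
    z_threshold: float = 3.0,
    min_run: int = 2,
    aggregator: Literal["max", "mean"] = "max",
    gate_threshold_pct: float = 10.0,
) -> pd.DataFrame:
    """Run gate, z-score classification and fold change for a whole cohort.

    One row per cell x stimulus. Cells failing the positive-control gate are
    retained with ``included=False`` (and are never responders); cohort
    statistics downstream should filter on ``included``.
    """
    if stimuli is None:
        stimuli = [e.label for e in schedule.by_role("test")]
    rows = []
    for tr in traces:
        r = ratio(tr)
        included, reason = inclusion_gate(tr.time, r, schedule, gate_threshold_pct)
        for stim in stimuli:
            _, z = zscore_series(tr.time, r, schedule, stim)
            rule_hit, run = classify_responder(z, z_threshold, min_run)
            fc = fold_change(tr.time, r, schedule, stim, aggregator)
            rows.append(
                ResponderCall(
                    cell_id=tr.cell_id,
                    stimulus=stim,
                    included=included,
                    exclusion_reason=reason,
                    responder=included and rule_hit,
                    run_length=run,
                    z_max=float(np.max(z)),
                    fold_change=fc,
                    aggregator=aggregator,
                )
            )
    return pd.DataFrame([vars(c) for c in rows])
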
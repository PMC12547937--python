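"""Cohort-level statistics and tidy report output.

The statistical conventions follow how this kind of single-cell perfusion /
secretion data is usually treated: per-cell fold changes are compared against
the no-effect value of 1 with a one-sample Wilcoxon signed-rank test (imaging,
non-normal) or a one-sample t-test (secretion), repeated-measures designs on
the same cells use a Friedman test with Dunn's post hoc comparisons, and
independent or paired group contrasts use Mann-Whitney, paired t, or one-way
ANOVA with Dunnett's test against a designated control.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ephys import APSummary, PoolEstimate

__all__ = [
    "WilcoxonResult",
    "FriedmanDunnResult",
    "GroupCompareResult",
    "one_sample_wilcoxon_vs_1",
    "friedman_dunn",
    "group_compare",
    "cohort_report",
]


@dataclass(frozen=True)
class WilcoxonResult:
    n: int
    n_used: int  # after dropping values tied at exactly 1
    median: float
    ci_low: float
    ci_high: float
    p_value: float
    degenerate: bool


def one_sample_wilcoxon_vs_1(
    values: np.ndarray | Sequence[float], confidence: float = 0.95
) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test against 1.

    Values equal to exactly 1 are dropped per the signed-rank convention (the
    count is recorded in ``n_used``). The median CI is distribution-free, from
    binomial order statistics at the requested confidence. With fewer than
    two usable values the result is flagged degenerate.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    diffs = x[x != 1.0]
    med = float(np.median(x)) if n else float("nan")
    lo, hi = _median_ci(x, confidence)
    if diffs.size < 2:
        return WilcoxonResult(n, diffs.size, med, lo, hi, float("nan"), True)
    res = stats.wilcoxon(diffs - 1.0, alternative="two-sided")
    return WilcoxonResult(n, diffs.size, med, lo, hi, float(res.pvalue), False)


def _median_ci(x: np.ndarray, confidence: float) -> tuple[float, float]:
    """Distribution-free CI for the median from order statistics."""
    n = x.size
    if n < 3:
        return float("nan"), float("nan")
    xs = np.sort(x)
    alpha = 1.0 - confidence
    k = int(stats.binom.ppf(alpha / 2.0, n, 0.5))  # 0-based lower index
    k = max(k, 0)
    upper = n - 1 - k
    if upper <= k:
        return float(xs[0]), float(xs[-1])
    return float(xs[k]), float(xs[upper])


@dataclass(frozen=True)
class FriedmanDunnResult:
    statistic: float
    p_value: float
    n_blocks: int
    mean_ranks: dict[str, float]
    pairwise: pd.DataFrame  # cond_a, cond_b, z, p_raw, p_adj


def friedman_dunn(
    matrix: pd.DataFrame,
    control: str | None = None,
    p_adjust: Literal["bonferroni", "none"] = "bonferroni",
) -> FriedmanDunnResult:
    """Friedman test over complete blocks with Dunn's post hoc comparisons.

    ``matrix`` has one row per cell (block) and one column per repeated
    condition; blocks must be complete. If ``control`` is given the post hoc
    family is control versus each other condition (mirroring how these
    designs are usually reported); otherwise all pairs. Dunn's z uses the
    Friedman mean ranks with standard error sqrt(k(k+1)/(6n)), adjusted by
    Bonferroni over the family.
    """
    if matrix.isna().any().any():
        raise ValueError("friedman_dunn requires complete blocks (no missing values)")
    k = matrix.shape[1]
    n = matrix.shape[0]
    if k < 3:
        raise ValueError("need at least 3 repeated conditions")
    if n < 2:
        raise ValueError("need at least 2 blocks")
    ranks = matrix.rank(axis=1)
    mean_ranks = ranks.mean(axis=0)
    if matrix.nunique(axis=1).eq(1).all():
        statistic, p = 0.0, 1.0
    else:
        statistic, p = stats.friedmanchisquare(*[matrix[c] for c in matrix.columns])
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    if control is not None:
        if control not in matrix.columns:
            raise KeyError(f"control condition {control!r} not in matrix")
        pairs = [(control, c) for c in matrix.columns if c != control]
    else:
        cols = list(matrix.columns)
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    rows = []
    m = len(pairs)
    for a, b in pairs:
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m) if p_adjust == "bonferroni" else p_raw
        rows.append({"cond_a": a, "cond_b": b, "z": z, "p_raw": p_raw, "p_adj": p_adj})
    return FriedmanDunnResult(
        statistic=float(statistic),
        p_value=float(p),
        n_blocks=n,
        mean_ranks={c: float(mean_ranks[c]) for c in matrix.columns},
        pairwise=pd.DataFrame(rows),
    )


@dataclass(frozen=True)
class GroupCompareResult:
    design: str
    p_value: float  # overall (ANOVA) or the single two-sided p
    pairwise: pd.DataFrame | None = None  # Dunnett: treatment vs control


def group_compare(
    design: Literal["mann_whitney", "paired_t", "anova_dunnett"],
    *groups: np.ndarray | Sequence[float],
    control_index: int = 0,
    labels: Sequence[str] | None = None,
) -> GroupCompareResult:
    """Two-sided group comparison under the named design.

    ``mann_whitney`` and ``paired_t`` take exactly two groups (paired t
    requires equal lengths; a constant nonzero paired difference is reported
    as p = 0 rather than a division-by-zero failure, and a uniformly zero
    difference as p = 1). ``anova_dunnett`` takes >= 3 groups, with
    ``control_index`` designating the control; the overall p is one-way ANOVA
    and the pairwise table is Dunnett's test of each treatment vs control.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if design == "mann_whitney":
        if len(gs) != 2:
            raise ValueError("mann_whitney needs exactly two groups")
        p = float(stats.mannwhitneyu(gs[0], gs[1], alternative="two-sided").pvalue)
        return GroupCompareResult(design, p)
    if design == "paired_t":
        if len(gs) != 2 or len(gs[0]) != len(gs[1]):
            raise ValueError("paired_t needs two equal-length groups")
        d = gs[0] - gs[1]
        if np.std(d, ddof=1) == 0:
            return GroupCompareResult(design, 0.0 if d[0] != 0 else 1.0)
        p = float(stats.ttest_rel(gs[0], gs[1]).pvalue)
        return GroupCompareResult(design, p)
    if design == "anova_dunnett":
        if len(gs) < 3:
            raise ValueError("anova_dunnett needs at least three groups")
        control = gs[control_index]
        treatments = [g for i, g in enumerate(gs) if i != control_index]
        if labels is None:
            labels = [f"group{i}" for i in range(len(gs))]
        t_labels = [l for i, l in enumerate(labels) if i != control_index]
        overall = float(stats.f_oneway(*gs).pvalue)
        dn = stats.dunnett(*treatments, control=control)
        pairwise = pd.DataFrame(
            {
                "treatment": t_labels,
                "control": labels[control_index],
                "statistic": np.atleast_1d(dn.statistic),
                "p_adj": np.atleast_1d(dn.pvalue),
            }
        )
        return GroupCompareResult(design, overall, pairwise)
    raise ValueError(f"unknown design {design!r}")


_RESPONDER_COLS = [
    "cell_id", "stimulus", "included", "exclusion_reason", "responder",
    "run_length", "z_max", "fold_change", "aggregator",
]
_POOL_COLS = [
    "cell_id", "cm0", "irp_ff", "irp_ff_per_pf", "rrp_ff", "rrp_ff_per_pf",
    "total_ff", "total_ff_per_pf", "rrp_convention", "qc_class",
]
_AP_COLS = ["cell_id", "spike_count", "resting_vm", "threshold", "overshoot", "half_width"]


def cohort_report(
    out_dir: str | Path,
    responder_calls: pd.DataFrame | None = None,
    pool_estimates: Iterable[PoolEstimate] | pd.DataFrame | None = None,
    ap_summaries: Iterable[APSummary] | pd.DataFrame | None = None,
    secretion_folds: pd.DataFrame | None = None,
    test_results: pd.DataFrame | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write tidy CSV tables, a JSON manifest and a run log.

    Outputs are deterministic: re-running with identical inputs and config
    produces byte-identical files (no timestamps). The manifest records the
    config hash, seed, software version, and responder counts recomputed from
    the responder table (n responders / N included per stimulus).
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _frame(obj, cols):
        if isinstance(obj, pd.DataFrame):
            return obj
        records = [] if obj is None else [
            asdict(o) if not isinstance(o, dict) else dict(o) for o in obj
        ]
        if not records:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(records)[cols]

    ap_in = ap_summaries
    if ap_in is not None and not isinstance(ap_in, pd.DataFrame):
        ap_in = [
            {k: v for k, v in (asdict(a) if not isinstance(a, dict) else a).items()
             if k != "spikes"}
            for a in ap_in
        ]
    tables = {
        "responders.csv": _frame(responder_calls, _RESPONDER_COLS),
        "pools.csv": _frame(pool_estimates, _POOL_COLS),
        "ap_summaries.csv": _frame(ap_in, _AP_COLS),
        "secretion_folds.csv": _frame(
            secretion_folds, ["plate_id", "well", "condition", "ng_per_ml", "in_range", "fold"]
        ),
        "test_results.csv": _frame(test_results, ["name", "statistic", "p_value"]),
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format="%.12g")

    resp = tables["responders.csv"]
    responder_counts = {}
    if len(resp):
        for stim, g in resp.groupby("stimulus"):
            inc = g[g["included"].astype(bool)]
            responder_counts[str(stim)] = {
                "responders": int(inc["responder"].astype(bool).sum()),
                "included": int(len(inc)),
                "recorded": int(len(g)),
            }
    cfg = config or {}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "software": {"name": "ecphys", "version": __version__},
        "seed": seed,
        "config_sha256": cfg_hash,
        "config": cfg,
        "tables": sorted(tables),
        "responder_counts": responder_counts,
        "n_rows": {name: int(len(df)) for name, df in tables.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log_lines = [f"wrote {name} ({len(df)} rows)" for name, df in tables.items()]
    log_lines.append(f"config sha256 {cfg_hash}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
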
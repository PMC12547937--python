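# Methods

## Data model and conventions

Imaging traces are per-cell two-channel fluorescence series on native
timestamps in seconds; electrophysiology uses milliseconds. The channel ratio
is computed after per-sample background subtraction, r = (A − bgA)/(B − bgB),
and a non-positive denominator anywhere invalidates the trace with the sample
index reported. Epochs are half-open [start, end) so adjacent epochs
partition a regular sampling grid without double counting. Nothing is ever
resampled or interpolated: the responder rule counts consecutive *acquired*
samples, so any regridding would change its operating characteristics.
Schedules require ≥ 60 s of cumulative baseline coverage before each test
epoch and exactly one positive-control epoch unless explicitly waived.

## Responder classification

z_t = (F_t − mean F_b)/SD F_b, with F_b the samples in the 60 s immediately
preceding the stimulus addition and SD using the n−1 denominator. For
protocols with several stimuli the baseline window re-anchors to each
stimulus, i.e. the 60 s preceding that epoch (typically a washout back at
baseline level). A responder shows z > 3 (strict) on ≥ 2 consecutive
samples; ties at exactly 3 do not count. The inclusion gate is boundary-
inclusive: a positive-control maximum of exactly 1.10 × the baseline mean is
included. Excluded cells are retained in outputs with `included=False` and a
reason code; they are never responders and are dropped only from cohort
statistics.

Because every z in a cell shares the estimated baseline mean and SD, null
tail excursions are positively dependent across timepoints: the null
probability of a 2-run is E[(1 − Φ(m̂ + 3ŝ))²] per adjacent pair (m̂, ŝ the
baseline estimates), about 3× larger than the naive product of marginal tail
probabilities at 30 baseline samples. The test suite checks the empirical
null rate against both a brute-force Monte Carlo oracle and this
quadrature-evaluated expression.

R/R₀ uses the maximum over the stimulus epoch and over the preceding 60-s
basal window by default, with the mean available; the aggregator is recorded
in every output row because, with a max statistic, both R and R₀ are biased
upward under noise and the bias must be attributable. Gi inhibition reports
max(IBMX before), min(IBMX + agonist), and max(IBMX after), each as a
percentage of the forskolin + IBMX maximum of the same cell.

## Capacitance quantification

All landmarks are 300-ms window means relative to the 300 ms before the
first pulse; windows clip to available interpulse samples and never cross a
pulse, and capacitance during a depolarization is missing data (the sine + DC
measurement is invalid there). IRP = change after the 6th (last short) pulse;
RRP defaults to the *incremental* convention (change after the 10th pulse
minus IRP) with the cumulative convention available and the choice recorded —
the two differ by exactly the IRP, which is small, but silent disagreement
between conventions is worse than an explicit toggle. Total release uses the
window ending 7 s after first-pulse onset (the protocol's time origin;
configurable).

QC taxonomy: the trace is segmented into consecutive 300-ms block means, and
the increments between blocks are compared with an indicator of pulse
occurrence between them. Provoked: point-biserial correlation ≥ 0.5 and mean
pulse-locked increment above the noise floor (3 × pre-train SD). Spontaneous:
some pulse-free increment exceeds the floor without pulse alignment.
No-exocytosis: a quiescent trace (canonically despite robust inward currents,
≥ 20 pA on at least half the pulses). Unstable is a caller-supplied
access-resistance flag. All thresholds are config values with the defaults
above, because the underlying definitions are qualitative.

Potentiation uses the 15 × 500 ms protocol (−60 → 0 mV) and a single landmark:
300 ms after the last pulse minus 300 ms before the first.

## Action potentials

Spike detection (−20 mV upward crossing, 5-ms refractory lockout, 10-mV
hysteresis re-arm) is deliberately distinct from biophysical threshold
estimation (the Vm where dV/dt first exceeds 10 mV/ms walking back along the
upstroke); conflating the two would report detection artifacts as biology.
The hysteresis re-arm exists because noise riding the slow repolarization
otherwise re-triggers the crossing detector; with it, counts are exact on
noiseless fixtures and stable to ≥ 2 mV RMS noise. Half-width is measured at
the threshold-to-peak half-amplitude level with sub-sample linear
interpolation, giving better-than-one-sample accuracy on piecewise-linear
fixtures.

## Secretion

Folds are well ÷ mean basal of the same plate, so basal folds average exactly
1 per plate and folds are invariant to plate-wide rescaling. Wells outside
the assay's validated 0.015–2.5 ng/mL range are clipped, flagged, and
excluded from means by default (includable by option). Wells are the unit of
analysis unless a batch column is supplied. Condition tests are one-sample
t-tests against 1; zero-variance inputs return a flagged degenerate result
instead of raising.

## Synthetic-data generator

The generator reproduces the acquisition protocols, not the biophysics:

* **Imaging** — 0.5 Hz sampling (one 100-ms exposure every 2 s); baseline,
  test epochs each followed by a washout, then a positive-control epoch.
  Responses are multiplicative steps on the ratio (optional one-sample ramp),
  drawn per cell per epoch with a configurable responder fraction; additive
  Gaussian noise and linear drift apply to the ratio, because the analysis
  operates on ratios and channel-level noise would be non-identifiable. The
  simulated ratio is carried in channel A with channel B ≡ 1 so the ratio
  operation recovers it exactly.
* **Capacitance** — sequential geometric depletion of two pools: each short
  pulse releases a fixed fraction of the remaining IRP; the first long pulse
  liberates the IRP remainder and each long pulse a fixed fraction of the
  remaining RRP; optional linear sustained release after the train and
  linear endocytosis after the first pulse (default 0). Samples exist only in
  measurement windows. Default pool scale (3.5 fF IRP, 91 fF RRP, 10.8 pF
  initial capacitance) matches the cell type's reported magnitudes. Pulse
  annotations carry a robust synthetic peak current (−150 pA, 5 % jitter),
  configurable to ~0 to fabricate no-exocytosis-despite-currents fixtures.
* **Voltage** — stereotyped piecewise-linear spikes: a slow foot from
  baseline to threshold (below the dV/dt criterion), a fast upstroke, and a
  linear decay whose slope is solved so the width at the half-amplitude level
  equals the configured half-width (default 19.1 ms, with −23.5 mV threshold
  and +35.5 mV overshoot, the reported EC-cell values).
* **Secretion** — log-normal wells with configured mean and CV around a
  0.47 ng/mL basal (the cross-experiment average), treatment wells at
  true_fold × basal, clipped-and-flagged outside the assay range.

Seeds are mandatory; there is no global random state, and identical
config + seed is bit-reproducible. What the generator does *not* emulate:
photobleaching and focus drift beyond a linear term, kinetic response shapes
(plateaus are steps), access-resistance dynamics, Ca²⁺-dependence of
release, or plate-position effects. Passing tests therefore demonstrate the
correctness of the quantification chain under the stated noise models, not
robustness to every artifact of real recordings.

## Statistics

Wilcoxon (exact where scipy's exact path applies), Friedman, Mann-Whitney,
paired t, one-way ANOVA and Dunnett all come from scipy; Dunn's post hoc z
after Friedman is computed from the Friedman mean ranks with SE
√(k(k+1)/(6n)) and Bonferroni adjustment over the reported family (control
vs treatments when a control is named, mirroring how such designs are usually
figured; all pairs otherwise). Median CIs are distribution-free from binomial
order statistics. Constant paired differences report p = 0 (nonzero) or 1
(zero) rather than failing on zero variance; other zero-variance inputs
return flagged degenerate results.

## Problem sizes and numerical choices

Simulation-based checks use 10,000 null cells (responder-rule calibration
against a 400,000-replicate vectorized oracle), 500 cells per amplitude for
sensitivity, 100 noisy recordings for pool recovery (median |error| bounded
by 2·noise/√30, the per-window sample count), and 1,000 plates for secretion
power against a 20,000-replicate oracle — sizes chosen to make binomial CIs
decisively narrower than the effects under test. Window arithmetic is exact
to < 1e-9 fF on noiseless fixtures. Report output is deterministic (no
timestamps), so a re-run with identical inputs is byte-identical.

## Known limitations

The pool model is phenomenological; it cannot express facilitation,
Ca²⁺-current rundown, or pool refilling, so recovery tests only validate the
landmark arithmetic under additive noise. The QC classifier's thresholds are
operational defaults, not fitted to real recordings. The spike templates are
piecewise linear, so the dV/dt threshold estimator sees an idealized
upstroke. Instrument file formats (ABF/HEKA) are out of scope; inputs begin
at extracted per-cell series in CSV.
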
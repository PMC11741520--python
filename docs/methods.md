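# Methods

This note documents the models, parameter conventions and numerical choices
behind `kisspulse`, and what the synthetic validation does and does not
demonstrate.

## Photometry preprocessing

Two demodulated channels are recorded on a scheduled duty cycle (default
5 s on / 15 s off at 10 Hz, so 25% of wall-clock time is sampled): a 490 nm
calcium-dependent signal and a 405 nm control that shares motion and
photobleaching artifacts but is insensitive to calcium. The control is
smoothed with a Savitzky–Golay filter (window 101 samples ≈ 10 s of retained
signal, order 2) and mapped onto the signal channel by a single global OLS
fit with intercept; the fitted control is then subtracted from and divided
into the signal channel, giving ΔF/F in percent.

Choices that were genuinely open:

* **Gap handling.** The retained on-window samples are concatenated and
  treated as contiguous for filtering and regression. Event *durations* are
  therefore measured in retained-sample time, while event *frequencies* are
  measured against elapsed wall-clock time, which keeps events/hr physically
  meaningful for a duty-cycled recording.
* **Global vs per-segment regression.** A single global fit is used; the
  shared artifacts in the generator (and in a well-behaved rig) are
  multiplicative gains on a common underlying signal, which a global affine
  map removes. Per-window refitting would add variance without a model
  reason.
* **Trace statistics.** `trace_mean`/`trace_sd` are computed over the full
  trace including events (sample SD, ddof = 1). The 3 SD detection
  threshold therefore rises with event load; this is inherent to the
  method and is reflected in the generator design (below).
* The fit is scale-equivariant, so ΔF/F is invariant under independent
  rescaling of either channel — this is property-tested, as is rejection of
  common-mode transients.

Per-animal normalisation divides a trace by the mean of the per-trace
maximum ΔF/F over three reference (pre-pregnancy) recordings; amplitudes are
then comparable within an animal across states. A warning (not an error) is
raised when a different number of reference traces is supplied.

## Synchronised-event detection

Threshold = trace mean + k·SD (k = 3). A maximal supra-threshold run lasting
at least `min_duration` (2 s of retained signal) is a candidate event;
candidates are merged when their peaks are closer than `min_separation`
(30 s) **or** when one run begins less than `min_separation` after the
previous run ends — a slowly decaying transient that dips briefly below
threshold (sampling gaps and noise make this common) is one event, not two.
Onset and end are the threshold crossings; the defaults reject single-sample
noise while never merging distinct events even at the highest physiological
rate (~4.8/hr, ≥ 5 min spacing).

Relative amplitude is peak minus the minimum of the trace between the
previous event's end (or trace start) and the peak, looking back at most
120 s; it is conventionally computed on normalised traces. Baseline metrics
(median, SD, fraction of non-event samples above mean + 1 SD) quantify the
raised-baseline phenotype of late pregnancy / late lactation; samples inside
detected events are excluded, and an all-event trace returns a flagged empty
result.

## LH pulse detection

Serial whole-blood LH (6-min grid, ng/ml) is censored to the assay working
range (LOD 0.04 to cap 4 ng/ml; censoring is idempotent). Pulses are found
by run criteria on baseline-subtracted residuals scaled by the assay SD,
with parameters: smoothing 0.7, peak split 2.5, LOD 0.04, amplitude
distance 3, assay variability (0, 2.5, 3.3), G(1)…G(5) = 3.5, 2.6, 1.9,
1.5, 1.2.

Conventions adopted where the parameter set alone is ambiguous:

* **Smoothing** is the baseline window half-width in hours (0.7 h ≈ ±7
  samples at 6-min sampling), applied in time, not sample index.
* **Assay variability** coefficients give the assay SD directly:
  SD(y) = (c₀ + c₁y + c₂y²)/100. Over the typical 0.3–1 ng/ml range this
  implies a CV of ~4–6%, consistent with the ELISA's reported intra-assay
  CV of 4.40%. The alternative CV-quadratic reading
  (SD = y·(c₀ + c₁y + c₂y²)/100, selectable via
  `assay_sd_convention="cv"`) implies CVs above 25% at 2.5 ng/ml, which no
  sandwich ELISA exhibits and under which pulses peaking above ~2.4 ng/ml
  can never satisfy G(1); both readings agree at 1 ng/ml. The SD is floored
  at the LOD so residual scaling cannot diverge near zero.
* **Baseline.** Iterated (3 passes) time-windowed weighted moving average
  with Tukey bisquare down-weighting of *positive* scaled residuals, cut
  off at G(1). A hard include/exclude rule at G(1) fails on sustained
  multi-pulse elevations: with the baseline inflated, genuine pulse peaks
  sit at u ≈ 3–3.4, are never excluded, and then never reach criterion.
  The smooth weights suppress exactly those points. Windows with fewer than
  two samples widen to the two nearest points.
* **G indexing.** The published criteria list G(1)–G(4) then "G(6)"; by
  default the last value is treated as G(5) (standard five-criteria form),
  with the literal gapped indexing selectable (`g_indexing="g6"`).
* **Peak splitting** is evaluated on the concentration scale: a run splits
  where an interior trough falls more than 2.5 assay-SDs (local SD at the
  trough) below both flanking maxima. Measured on the residual scale the
  growing SD at high concentration flattens multi-pulse plateaus so deep
  concentration troughs never split. The trough sample joins neither
  sub-run.
* **Amplitude** is peak concentration minus the minimum of the
  `amplitude_distance` (3) samples preceding the run, falling back to the
  local baseline when the run starts the series; non-positive-amplitude
  runs are dropped (they do not occur under normal operation).

Mean LH is the arithmetic mean of all censored samples.

## SE–LH pairing and association

Each detected SE is matched one-to-one (greedy earliest) to the first
unmatched pulse peaking within `window_min` = 12 min (two sampling
intervals) after the SE peak. The association test builds a 2×2 table from
post-SE windows versus equal-width control windows immediately preceding
each SE, each scored for pulse occurrence, and applies Pearson's χ² (1 df,
no continuity correction); a zero margin raises rather than silently
falling back. Per-state summaries report between-session mean ± SEM (the
session, i.e. the animal-day, is the unit of replication; a single-session
state reports SEM = NaN).

## Synthetic-data generator

The generator's presets define the study conditions for validation:

| state | SE rate /hr | amplitude (ΔF/F %) | baseline mode |
|---|---|---|---|
| nl_diestrus | 1.25 | 15 | normal |
| preg_d4 | 0.29 | 12 | normal |
| preg_d14 | 0 | – | normal |
| preg_d18 | 2.18 | 5 | elevated (osc 2.0%) |
| lact_d7 | 0 | – | normal |
| lact_d14 | 0.58 | 10 | normal |
| lact_d18 | 0.85 | 12 | elevated (osc 0.8%) |
| postwean_24h | 1.38 | 15 | normal |
| postwean_diestrus | 1.67 | 15 | normal |
| ovx | 4.78 | 25 | normal |

* **Event process.** Stationary renewal: inter-event gaps are a hard
  refractory plus an exponential whose mean makes the process rate equal
  the preset rate; the first event is drawn from the equilibrium
  forward-recurrence distribution so the expected count is rate × duration
  exactly. The refractory is 900 s for all states except OVX (300 s):
  diestrus-like LH pulses are tens of minutes apart, and a 5-min refractory
  would produce 5–12-min doublets (absent from real recordings) whose LH
  boluses merge irresolvably at 6-min sampling; OVX activity genuinely
  arrives in faster clusters.
* **SE waveform.** Two-exponential transient (rise τ 5 s, decay τ 40 s),
  peak-normalised, added to the 490 nm channel only. Amplitudes are
  lognormal with the preset mean and CV 0.1: population-summed events are
  stereotyped, and at OVX rates the event-dominated trace SD puts the 3 SD
  threshold near 0.6× the mean amplitude, so a broad amplitude distribution
  would hide a visible fraction of events below their own threshold —
  a feature real OVX recordings (large, stereotyped events) do not show.
  Absolute amplitudes are conventions: only within-animal relative
  amplitudes are meaningful.
* **Shared artifacts.** Both channels carry exponential photobleaching
  (τ 14 400 s wall clock — duty cycling spreads illumination over 4× the
  illuminated time) and a slow common-mode motion artifact (Gaussian
  process, 60 s correlation, SD 0.01 a.u.) with gains proportional to the
  channel baselines (1.0 / 2.0 a.u.), plus white noise (0.002 / 0.003
  a.u.). Proportional gains reflect shared fibre coupling and are what make
  isosbestic regression effective; the motion correlation time is chosen
  slower than the Savitzky–Golay window's wall-clock span, since motion
  faster than the 15-s acquisition gaps is uncorrectable by any method on a
  duty-cycled rig.
* **Elevated-baseline mode** (late pregnancy, late lactation) adds
  low-amplitude events (1/5 the state amplitude, twice the SE rate, plain
  Poisson) and a slow sinusoidal baseline oscillation (10-min period).
  One-quarter amplitude would put the mini-event mode directly on the 3 SD
  line and generate false SEs; at 1/5 the baseline activity stays
  sub-threshold, as it does in the recordings the counts come from.
* **LH model.** Each SE triggers a secretory bolus with probability
  `coupling_prob` (1.0), delayed uniformly by 0.5–3 min; concentration is
  basal (0.2 ng/ml) plus boluses (lognormal mean 1.5 ng/ml, CV 0.2)
  cleared with a 15-min half-life; sampling on the 6-min grid plus an extra
  draw 2 min after an SE whenever the next scheduled draw is over 3 min
  away; multiplicative assay noise at CV 4.40%; censoring to 0.04–4 ng/ml.
  In paired protocols the sampling grid extends one pairing window past the
  photometry session end, as when scheduled sampling continues after the
  last event.
* **Reproducibility.** All randomness flows from one seed; in the pipeline,
  named substreams per (state, session, stage) mean adding sessions never
  perturbs existing ones. Identical (preset, seed) gives bit-identical
  output.

## What the validation shows — and does not

The recovery experiments (8 × 3 h sessions per state; ≥ 50 paired sessions
at coupling probability 1) show that the implemented chain is unbiased and
internally consistent: detected SE frequency recovers the injected rate
within sampling error in every preset including the zero-rate false-positive
controls, and every detected SE is matched to a detected LH pulse under
full coupling. Cohort means over 8 sessions carry an intrinsic SD of
~0.1/hr at these rates, so individual recovered values scatter accordingly;
the recovery criterion is agreement within 3 between-session SEM.

The generator does **not** emulate several features of real data: slow
drifts in indicator expression across months, state transitions within a
session, non-stationary pulse-generator dynamics, correlated assay drift,
or miniature sub-population events beyond the simple elevated-baseline
model. Passing recovery therefore validates the analysis implementation
under the stated statistical structure, not the biology.

Known limitations:

* Low-amplitude SEs riding an elevated, oscillating baseline (the
  day-18/19 pregnancy pattern) are systematically under-detected by the
  pure 3 SD rule (~40% recovery in that preset) — the regime in which the
  original workflow resorted to manual shape analysis, which is
  deliberately not implemented.
* At SE rates approaching the refractory limit the trace SD is
  event-dominated and the 3 SD threshold scales with event amplitude;
  detection there depends on the amplitude distribution being narrow.
* PULSAR-style run criteria cannot resolve two boluses closer than about
  two sampling intervals; the paired-session presets avoid this regime the
  same way the real pulse generator does (long inter-event intervals).
* The χ² table construction (post-SE vs preceding control windows) is one
  defensible choice among several; with sparse pulses it is conservative.
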
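# Methods

## Scope and data model

The unit of observation is one neuron's spike train: strictly increasing
timestamps (seconds) within a recording of known duration. Analyses assume
spike-sorted data; there is no waveform handling, so dopaminergic identity can
only be screened by the rate gate (0.5–10 Hz), not by spike shape.

Two gates control what gets analysed, mirroring standard practice for in vivo
single-unit recordings of midbrain dopaminergic neurons:

* `is_putative_da`: mean rate (spike count / duration) in [0.5, 10] Hz;
* `is_classifiable`: at least 500 consecutive spikes and at least 180 s of
  recording.

Trains failing a gate are reported as `unclassified` with a machine-readable
reason; they are excluded from pattern proportions and group tests (the group
percentages therefore sum to 100 over the three pattern labels).

## Regularity metric

CV<sub>ISI</sub> = 100 × SD(ISI) / mean(ISI), with the sample (n−1) standard
deviation. The direction of the ratio matters: SD/mean makes low values mean
regular, which is the convention under which "the lower CV<sub>ISI</sub>, the
more regular" holds and under which a regular-shifted cohort has a *lower*
median. The inverted ratio (mean/SD × 100), which some sources print, is
available behind `cv_isi(..., literal=True)` for auditability. For n ≥ 500
spikes the ddof choice is numerically irrelevant but is fixed for
reproducibility.

## Synthetic spike trains

The generators define the study conditions for all recovery results; they are
renewal/semi-renewal point-process models, not biophysical neuron models.

**Tonic modes** are gamma-renewal processes: ISIs i.i.d. Gamma(κ, 1/(rate·κ)),
so mean ISI = 1/rate and expected CV<sub>ISI</sub> = 100/√κ. Defaults: κ = 12
for regular (CV ≈ 29 %, the pacemaker regime) and κ = 1.8 for irregular
(CV ≈ 75 %, noisy tonic firing just short of Poisson).

**The bursty mode** alternates bursts and pauses: burst size 2 + Geometric
(mean 4 spikes), intra-burst ISIs Gamma(shape 3, mean 70 ms), inter-burst
pauses exponential. The pause mean is solved from the rate constraint
`pause = B/rate − (B−1)·d` (B mean burst size, d intra-burst ISI mean), so the
long-run rate matches the target; rates for which the solved pause would not
exceed the intra-burst ISI are rejected, as are burst-size parameters below 2
(single-spike "bursts" degenerate to a renewal process). The resulting ISI
mixture has CV<sub>ISI</sub> well above 100 %.

**Cohorts.** Each neuron draws a ground-truth pattern from the cohort mixture
— allocated deterministically by largest-remainder rounding so that, e.g., 48
neurons at (0.42, 0.46, 0.12) give exactly (20, 22, 6) — and a target rate
from a truncated normal on [0.5, 10] Hz. Genotype presets: `wt` = 48 neurons,
mixture (0.42, 0.46, 0.12), rate 3.3 Hz; `ko` = 63 neurons, mixture
(0.66, 0.26, 0.08), rate 3.6 Hz. The bursty proportions are the complements of
the two headline percentages; the rate SDs (0.2·√n) are chosen to give a
standard error of ≈ 0.2 Hz at the cohort size. Per-neuron seeds are spawned
from the cohort seed by index (`numpy.random.SeedSequence`), so any single
neuron can be regenerated independently of cohort order, and identical seeds
give identical timestamp sequences.

Recordings default to 300 s; when a slow neuron would fall below 600 spikes at
that duration the recording is extended until the floor is met (`min_spikes`,
default 600 in cohorts), emulating the practice of recording slow units for
longer. Empirical rates land within 5 % of the target for ≥ 300 s recordings.

What the generators do *not* emulate: rate drift and non-stationarity,
refractory-period hard floors, anesthesia depth effects, electrode drift or
sorting contamination, and any correlation structure beyond the renewal or
burst–pause assumptions. Recovery results below therefore certify the
classifiers against clean renewal-class ground truth, not against every
pathology of real recordings.

## Autocorrelogram classifier

The ACG bins the lags of all ordered spike pairs into 10 ms bins up to 2 s
(200 bins; the zero-lag self-pairings are excluded). The implementation
differences the sorted timestamp vector at increasing offsets and is exactly
equivalent to the O(n²) pair count (tested).

Features are extracted from a 5-bin (50 ms) centred moving average; the
steady state is the mean raw count over lags 1.5–2.0 s.

* **Regular-peak run.** Candidate peaks come from `scipy.signal.find_peaks`.
  A *fundamental* peak must clear three gates relative to the steady state
  `ss`: prominence ≥ 0.30·ss, height ≥ 1.25·ss, and a deep pre-period trough
  (mean smoothed count over lags 0.15–0.60 of the candidate lag ≤ 0.25·ss).
  The height and trough gates are what reject noise bumps riding the rising
  edge of an irregular ACG, whose raw prominence is inflated by the deep
  initial trough; the trough gate integrates many bins and therefore stays
  informative for slow, low-count units where single-bin heights are noisy.
  From the fundamental, a greedy run of evenly spaced *follower* peaks is
  grown: the next peak must lie within ±30 % of one period beyond the last
  matched peak, with the period re-estimated from the run as it grows, and
  followers need only ≥ 0.02·ss prominence — the ACG ripple of a
  gamma-renewal train decays geometrically with harmonic order (for κ = 12
  the third peak modulates the steady state by only a few percent), so a
  single threshold cannot both find it and reject noise.
* **Initial segment.** Mean raw count over bins 1–5 (10–60 ms; bin 0 is
  refractory-dominated), compared to the steady state at ±15 %: above ⇒
  `peak`, below ⇒ `trough`, else `flat`.
* **Label.** The initial-peak cue (bursty) is checked *first*: short
  intra-burst lags elevate the leading bins only in burst firing, and
  intra-burst harmonics can otherwise masquerade as an evenly spaced run,
  while genuine pacemakers at ≤ 10 Hz never elevate the 10–60 ms bins. Then
  a run of ≥ 3 regular peaks ⇒ regular — reduced to however many periods fit
  into 2 s (never below 2) for slow pacemakers, since a 1 Hz regular unit
  cannot show three peaks below the 2 s lag limit by construction. Then
  `trough` ⇒ irregular; anything else is unclassified.

## Discharge density histogram classifier

The recording is tiled with consecutive non-overlapping windows of length
m/rate (trailing partial window discarded) and the per-window spike counts
are histogrammed. A count value is *occupied* if it holds ≥ 1 % of windows.
Decision rules, checked in order:

1. **bursty**: ≥ 6 occupied bins and the modal bin is the lowest occupied
   count (quiescent inter-burst windows dominate);
2. **regular**: ≤ 5 occupied bins, mirror-symmetric occupancy (total
   |mismatch| about the midpoint of the occupied range ≤ 20 % of the
   windows), and a sub-floor tail — the summed occupancy of the 1–2 bins
   pruned by the noise floor — under 1 % of the largest bin;
3. **irregular**: ≤ 6 occupied bins;
4. otherwise unclassified.

`m = 2` by default. This choice makes the classical bin-count rules hold as
written for the renewal regimes of interest: at m = 2 a κ = 1.8 irregular
train occupies ≤ 6 count values at the 1 % floor and a κ = 12 pacemaker
occupies ~3 symmetric values with a sub-1 % tail, whereas larger windows
(m = 3) push irregular trains to 7–8 occupied values and give pacemakers a
tail just above the 1 % rule. Symmetry is mirrored about the occupied-range
midpoint rather than the modal bin because a perfectly symmetric histogram
with two tied central bins has no single central mode.

## Consensus and cohort statistics

The ACG label is final by default (`acg-primary`); the DDH label is recorded
as confirmation together with an agreement flag. `strict` maps disagreements
to unclassified (never flipping a label); `ddh-primary` swaps the roles.

Group tests (two-group cohorts): pooled-variance unpaired two-sided Student's
t on firing rate (df = n₁ + n₂ − 2); Mann-Whitney U on CV<sub>ISI</sub> with
midrank ties, reported as min(U₁, U₂), exact p for small tie-free samples and
tie-corrected normal approximation otherwise; Pearson chi-square without
continuity correction on the group × pattern table, with all-zero pattern
columns dropped (the statistic is undefined on zero margins). All three are
computed via scipy.stats and are verified in the test suite against
independent oracles (exhaustive pair enumeration for U at n ≤ 8, the direct
Σ(O−E)²/E formula for chi-square).

## Numerical choices and degenerate inputs

* Lag binning is right-inclusive: bin b covers (b·w, (b+1)·w], so a lag
  exactly equal to a bin edge lands in the lower bin and a lag equal to
  `max_lag` is counted. The brute-force oracle uses the same convention.
* Timestamp files serialize at microsecond precision; durations are rounded
  *up* at that precision so a final rounded spike cannot fall outside the
  recording.
* Degenerate trains (0–2 spikes) yield NaN ISI statistics and false gates
  rather than errors; classification refusals surface as `unclassified` with
  a reason, and only structurally invalid inputs (unsorted timestamps,
  non-positive durations, malformed files) raise.
* An all-zero ACG (no pairs within 2 s) is a feature-extraction error; a
  steady-state window with zero counts falls back to the global ACG mean.
* Largest-remainder ties are broken by mixture position (regular before
  irregular before bursty).

## Tuning provenance and limitations

The classification rules are inherently qualitative; every quantitative
threshold above (prominence and height gates, trough depth, spacing
tolerance, initial-segment window and tolerance, m, noise floor, symmetry
tolerance) is a configuration key whose default was selected on the
ground-truth recovery suite — cohorts of 100 synthetic neurons per firing
mode drawn from the preset rate distribution with ≥ 600 spikes each. With the
defaults, recovery is ≈ 95 % (regular), 100 % (irregular) and 97 % (bursty)
for the ACG classifier and ≈ 100/98/100 % for the DDH classifier; the
acceptance tests assert ≥ 85 % / ≥ 80 % per mode and ≥ 90 % pooled for the
final label.

Known limitations:

* Slow pacemakers. Below ~1.5 Hz the mean ISI exceeds 2/3 of the maximum lag,
  so the three-peak criterion is structurally unsatisfiable; the classifier
  falls back to requiring the visible number of periods (≥ 2), and below
  1 Hz regular units are usually labelled irregular. With the preset rate
  distributions this affects a few percent of neurons and is the dominant
  error mode of the ACG classifier.
* At the 500–600-spike inclusion floor the third ACG peak of a κ = 12
  pacemaker is close to the Poisson noise floor; the lenient follower gate
  trades a small false-regular risk (screened by the fundamental gates) for
  sensitivity there.
* The DDH bursty rule assumes pauses long enough to empty whole windows;
  burst firing at very high rates with short pauses would erode the
  zero-count mode.
* Pattern labels, not burst statistics: the package deliberately implements
  shape-based classification only — no ISI-threshold burst detection (e.g.
  80/160 ms onset/offset rules), no percent-spikes-in-burst metrics.
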
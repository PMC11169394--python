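# Methods

## Scope and model

`epiquant` quantifies epileptiform activity in chronic two-channel
epidural mouse telemetry EEG. The signal model is deliberately
amplitude-based: all detection criteria are multiples of a per-file
background amplitude scale ("baseline activity") plus absolute μV
bounds, because that is how long-term rodent telemetry is quantified in
practice — spectral or EMG-based verification of seizures, and
behavioral (Racine-scale) severity staging from synchronized video, are
out of scope.

Acquisition constants assumed throughout: 1000 Hz sampling, 100 Hz
low-pass at acquisition, ±10 mV full scale, channels "EEG1"/"EEG2".
Voltages are handled in μV internally; EDF physical dimensions (mV, V)
are normalized to μV on read. Times are seconds from recording start.

## Detection pipeline

**Baseline.** `b = 1.4826 · median(|x − median(x)|)` on the optionally
high-passed trace (default 1 Hz, 2nd-order Butterworth, zero-phase).
The MAD-based Gaussian-equivalent sigma is used rather than the sample
SD because the estimator must be insensitive to the transients being
detected: planted spikes occupying ≤ 1% of samples move it by a few
percent (the sample SD would move by far more). A flat trace raises a
degenerate-baseline error rather than silently producing a zero
threshold; records shorter than 10 s are rejected as insufficient for
an autonomous estimate.

**Amplitude convention.** "Amplitude" is the absolute deviation from
the channel median (after optional high-pass), not peak-to-peak. This
gives a single scalar comparable with the absolute 200/1500 μV
constants and with multiples of `b`.

**Spike candidates.** Maximal runs of `|x| ≥ max(2b, 200 μV)`. Each run
contributes one candidate: its largest sample (earliest on ties) with
width equal to the run duration. The two printed thresholds are
combined as a max because the absolute floor is a filter applied to
already-detected candidates. A refractory rule then keeps, among
candidates closer than the maximum admissible spike width (200 ms),
only the largest — this is what makes a biphasic spike, whose
after-going lobe also crosses threshold, count once. Finally candidates
above 1500 μV become artifact annotations (only the offending peak is
removed, not surrounding samples), and candidates wider than 200 ms are
discarded. Consequences under the default configuration: every emitted
spike has amplitude in [200, 1500] μV and width ≤ 200 ms, and
consecutive spikes are ≥ 200 ms apart, so the 100 ms minimum ictal ISI
can never be violated by construction.

**Seizures before events.** "Interictal" is defined relative to
seizures, so seizures are detected first and mask their member spikes.
The ictal ISI band combines the two published bounds into [0.1 s, 5 s):
intervals of at least 100 ms keep discharges distinct, intervals under
5 s keep the run ictal. Duration is measured first-to-last member peak.
No minimum spike count is imposed beyond what the duration and ISI band
imply (≥ 3).

**Interictal events.** Single-linkage clustering in time with gap
≤ 10 s over non-ictal spikes at ≥ 3b; clusters need more than 3 spikes.
A cluster can never straddle a seizure: bridging one would require a
gap longer than the seizure's own ≥ 10 s duration, which already breaks
the linkage, so the event/seizure partition holds structurally.

**Cross-channel merging.** Channels are processed independently, then
merged: seizure intervals are united across channels (the two epidural
leads watch one brain, and generalized discharges appear on both),
while interictal events are deduplicated when they overlap ≥ 50% in
time relative to the shorter event. Spikes and artifacts remain
per-channel annotations. Determinism: identical input and configuration
produce bit-identical annotations; there is no randomness anywhere in
the detection path.

**Scoring.** Detected and reference annotations are matched one-to-one,
greedily in time order, per kind; a pair matches when the intervals
overlap or their midpoints are within a tolerance (default 0.2 s, which
accommodates peak shifts caused by noise riding on a planted
transient). Empty denominators yield precision/recall 0 with an
explicit `undefined_*` flag.

## Synthetic data generator

The generator emulates what a post-traumatic epilepsy telemetry study
records, and emits ground truth consistent with the detection criteria
by construction — on noiseless renders, detection recovers the truth
with precision = recall = 1 for every kind, which is property-tested.

**Background.** Gaussian noise shaped in the frequency domain to a
power-law PSD ∝ f^−β above a 1 Hz knee, zero above the 100 Hz
acquisition cutoff, rescaled to the requested sample SD (default
50 μV). The default β = 2.5 reflects the strongly low-frequency-
dominant spectrum of rodent cortical EEG (reported slopes ≈ 2–3 over
1–100 Hz); β is a scenario parameter and β = 0 gives flat band-limited
noise. The spectral shape matters for detector validation: a flat
spectrum concentrates variance at high frequencies and crosses the
200 μV floor ~120 times per hour at σ = 50 μV (a level-crossing-rate
consequence, not a detector property), which no realistic spike
detector should be asked to call signal; at β = 2.5 such crossings are
rare (~5/hour), giving an honest high-signal-to-noise regime.

**Spike kernel.** A biphasic raised-cosine: positive lobe with FWHM
equal to the requested width and peak equal to the requested amplitude,
followed by an overlapping negative lobe at 0.35× amplitude. The
after-going lobe deliberately exercises the refractory rule. A separate
plateau injector produces flat-topped transients for testing the
maximum-width filter.

**Cluster-level truth.** Planted spike trains are labeled by the same
criteria the detector applies: an equally spaced train spanning ≥ 10 s
at ISI ∈ [0.1, 5) s is truth-labeled a seizure even if requested as an
"event" (and a requested "seizure" of e.g. 8 s is truth-labeled an
interictal event if it satisfies the event rules). Without this the
ground truth would contradict the criteria it is meant to oracle.
Planted items appear synchronously on both channels; spike truth is per
channel, cluster truth is one merged annotation per item — the same
shape the detector emits.

**Default high-SNR scenario.** One hour, σ = 50 μV: three interictal
events (5 spikes @ ISI 2 s; 6 @ 6 s; 10 @ 1 s), one 20 s seizure at
ISI 0.25 s with a 20% first-to-last amplitude ramp and post-ictal
suppression (background ×0.3 for 10 s), two interference artifacts
(2000/2500 μV), and twenty isolated spikes drawn from 300–800 μV and
20–80 ms. All planted amplitudes are ≥ 6× the noise sigma. Isolated
spikes are placed ≥ 15 s from each other and from every planted item so
that stray spikes cannot chain into clusters that the truth does not
know about.

**What the generator does not emulate.** Real EEG non-stationarity
(sleep/wake cycles, movement artifact other than the super-threshold
interference class), 1/f spectral detail beyond a single power law,
electrode drift, and any waveform variability beyond the parameterized
kernel. Passing the recovery tests therefore demonstrates correctness
of the detection logic under the stated signal model, not field
performance on arbitrary recordings.

**Cohorts.** Simulated at the event level (weekly tables) rather than
as twelve weeks of raw signal, which keeps a full study runnable in
milliseconds; any animal-week can still be rendered to EDF via a
scenario. Weekly interictal-event counts are Poisson with group rates
scaled by recorded hours relative to the 45 h reference week (9 h ×
5 days); the schedule is continuous for the first 8 days, then
intermittent. Default group rates rise over the study in the untreated
group and drop to ~35% of it from week 4 in the treated group,
mirroring the qualitative pattern such studies report; defaults for
incidence are 0.71 (untreated) vs 0.0 (treated) with onset week uniform
over weeks 3–12 (monitoring for spontaneous seizures begins at week 3),
~0.6 seizures/week after onset, and seizure durations Gaussian
(40 ± 15 s) truncated at the 10 s electrographic minimum. Where the
underlying study reports only a figure, these distributions are free
parameters of the generator, not calibrated estimates.

## Longitudinal aggregation

Events and seizures are assigned to the study week containing their
start (an event straddling a week boundary counts once, in its start
week). Rates (events per recorded hour) are the primary comparable
quantity because recorded hours differ across weeks; raw counts are
emitted alongside. Weeks with zero recorded hours are flagged missing,
never reported as zero. An annotation outside every recorded segment
raises a consistency error, since a detection cannot come from
unrecorded time. Animals that never seize are right-censored at their
last observed week (not at a fixed week 12), so truncated cohorts
remain analyzable.

## Statistics

Exact tests are used at study sample sizes (n = 7–8 per group), where
asymptotic p-values are unreliable. The Mann–Whitney U null is obtained
by complete enumeration of all C(n1+n2, n1) group assignments whenever
both groups have ≤ 8 observations (exact under ties), with the standard
two-sided rule of twice the smaller tail probability clipped to 1 — the
same convention as R's `wilcox.test`; larger samples use the
tie-corrected normal approximation with continuity correction.
Kaplan–Meier and the log-rank test come from `lifelines`; a comparison
with no events in either group is reported as degenerate with p = 1
rather than NaN. Incidence proportions carry exact Clopper–Pearson 95%
intervals. All tests are two-sided. No multiple-testing correction is
applied across the weekly comparisons by default (matching how such
studies present per-week significance); a Bonferroni option is exposed.
Weekly comparisons support both the normalized rate and the raw count
as the compared quantity, since either axis is defensible.

## Numerical and I/O choices

- EDF: classic 16-bit EDF, one data record per second, physical range
  ±10 mV. The quantization step is 20000/65535 ≈ 0.305 μV; round-trips
  are exact to within one step. Trailing partial seconds are
  zero-padded. Files with per-channel sampling rates are rejected as an
  unsupported layout. Written files are cross-checked against MNE's
  independent EDF reader in the test suite.
- Annotations: sidecar CSV/JSON (subject, channel, kind, start, end,
  peak μV), bit-exact round-trip, separate from the signal container so
  traces and events stay independently editable.
- Configuration: flat YAML keyed by the `DetectionConfig` field names;
  missing keys take the published defaults; invariant violations (e.g.
  a minimum peak height above the artifact ceiling) are configuration
  errors.
- Ties and order: candidate ties in amplitude break toward the earlier
  peak; all sorting is stable; float comparisons in tests use explicit
  tolerances at the 1e-9 level where sample-grid arithmetic is exact.

## Problem sizes used in validation

The test suite validates oracle equivalence on 200 random scenarios of
30–60 s, planted-truth recovery on 20 one-hour renders, baseline
robustness on 50 four-minute renders, and log-rank power on 1000
replicated study-sized cohorts; the acceptance script uses 5 one-hour
renders, 50 oracle scenarios and 400 power replicates. These sizes were
chosen so the whole validation runs comfortably on a laptop while
keeping Monte-Carlo error well below the asserted margins.

## Known limitations

- The baseline is a single per-file scalar; slow within-file changes in
  background amplitude (state transitions, drift beyond the 1 Hz
  high-pass) are not tracked.
- Artifact handling removes only super-threshold peaks; lower-amplitude
  movement artifact is indistinguishable from spikes under a purely
  amplitude-based model.
- Cross-channel merging assumes generalized (synchronous) discharges;
  focal unilateral events are counted per channel and deduplicated only
  on ≥ 50% temporal overlap.
- The exact Mann–Whitney enumeration is limited to groups of ≤ 8 by
  combinatorial growth; beyond that the normal approximation is used.
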
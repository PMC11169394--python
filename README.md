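# epiquant

Automated quantification of epileptiform activity in long-term rodent
telemetry EEG: spike detection, interictal-event clustering,
electrographic-seizure detection, and the longitudinal/incidence
statistics used to compare injured and treated cohorts.

## Who this is for

Epilepsy researchers running chronic video-EEG telemetry in rodents
(e.g. post-traumatic epilepsy models) who need months of two-channel
epidural recordings turned into per-animal weekly event counts, seizure
incidence curves and group comparisons — without manually reviewing
thousands of hours of signal. Because chronic telemetry datasets are
rarely shareable, the package also ships a synthetic mouse-EEG generator
that emits ground-truth annotations, so every stage of the pipeline is
testable end to end.

## The algorithm

For each recording (μV, 1000 Hz sampling, 100 Hz acquisition low-pass,
±10 mV full scale):

1. **Baseline.** The background amplitude scale *b* is estimated
   autonomously per file as the MAD-based Gaussian-equivalent sigma,
   `b = 1.4826 · median(|x − median(x)|)`, after optional 1 Hz
   drift-removal high-pass. A median-based scale is insensitive to the
   very transients being detected.
2. **Spikes.** Candidate transients are maximal excursions of |x| above
   `max(2b, 200 μV)`. Within a refractory window equal to the maximum
   admissible spike width, only the largest peak is kept (multiphasic
   spikes count once). Candidates above 1500 μV are classified as
   electrical-interference artifacts; candidates wider than 200 ms
   (width measured between the threshold crossings) are rejected.
3. **Seizures.** Over spikes with amplitude ≥ 3*b*, a discharge run
   extends while consecutive inter-spike intervals (ISIs) lie in
   [0.1 s, 5 s); a run spanning ≥ 10 s first-to-last peak is an
   electrographic seizure. Post-ictal suppression is flagged when the
   mean |x| in the 10 s after the seizure falls below *b*/2.
4. **Interictal events.** Spikes inside seizures are masked; remaining
   ≥ 3*b* spikes are clustered by single linkage with gap ≤ 10 s, and
   clusters of more than 3 spikes become events.

Downstream, events and seizures are aggregated per study week under the
actual recording schedule (continuous days post-injury, then 8–10 h/day
five days a week), rates are normalized by recorded hours, and groups
are compared with an exact Mann–Whitney U test per week and with
Kaplan–Meier / log-rank analysis of time to first seizure
(never-seizing animals right-censored).

## Worked example

```python
import epiquant as eq

# one hour of synthetic two-channel EEG: 3 interictal events, 1 seizure
# with post-ictal suppression, 2 interference artifacts, 20 stray spikes
scenario = eq.default_scenario(seed=1)
record, truth = eq.simulate_recording(scenario)

annotations = eq.run_detection(record)
print("detected:", annotations.counts())
scores = eq.score_detection(annotations, truth.annotations)
for kind in ("spike", "interictal_event", "seizure"):
    s = scores[kind]
    print(f"{kind}: precision={s.precision:.3f} recall={s.recall:.3f}")

# a simulated 12-week study: 7 injured vs 8 treated animals
cohort = eq.simulate_cohort(eq.CohortConfig(seed=4))
table = cohort.first_seizure_table()
tbi = table[table.group == "TBI"]; tn = table[table.group == "T+N"]
inc = eq.incidence_proportion(tbi.event)
print(f"TBI incidence: {100*inc.proportion:.1f}% (95% CI {inc.ci_low:.2f}-{inc.ci_high:.2f})")
lr = eq.log_rank(tbi.time_weeks, tbi.event, tn.time_weeks, tn.event)
print(f"log-rank p = {lr.p_value:.4f}")
```

Output:

```
detected: {'spike': 244, 'interictal_event': 3, 'seizure': 1, 'artifact': 4}
spike: precision=1.000 recall=1.000
interictal_event: precision=1.000 recall=1.000
seizure: precision=1.000 recall=1.000
TBI incidence: 71.4% (95% CI 0.29-0.96)
log-rank p = 0.0041
```

The detector recovers every planted item of the high-SNR hour exactly
(244 spike annotations = 122 planted transients on each of 2 channels),
and in this cohort realization 5 of 7 untreated animals develop
post-traumatic seizures (71.4%) versus none of the treated animals, a
difference the log-rank test flags at p ≈ 0.004.

The same steps are available from the shell:

```bash
epiquant simulate --out-edf rec.edf --out-truth truth.csv --seed 1
epiquant detect --edf rec.edf --out annotations.csv
epiquant summarize --annotations annotations.csv --schedule sched.csv --out weekly.csv
epiquant compare --weekly-a tbi.csv --weekly-b tn.csv --out stats.json
```

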
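"""Synthetic two-channel mouse telemetry EEG with ground truth.

Emulates the signal classes a post-traumatic-epilepsy telemetry study
produces: 1/f-like Gaussian background activity band-limited to the
100 Hz acquisition cutoff, isolated epileptiform spikes (sharp biphasic
transients of tens of ms and hundreds of μV), interictal events
(clusters of >3 spikes with gaps up to 10 s), electrographic seizures
(≥10 s of dense ramping discharges with optional post-ictal
suppression), and super-threshold electrical-interference artifacts.
Every planted item is recorded in a :class:`GroundTruth` annotation set
that is consistent with the detection criteria by construction, so the
generator doubles as the oracle for detector validation.

Cohort simulation works at the event level (weekly tables rather than
twelve weeks of raw signal): per-animal weekly interictal-event counts
are Poisson with group rates scaled by recorded hours under the
telemetry schedule, and seizure incidence/onset follow the configured
distributions. Any animal-week can still be rendered to a signal via
:func:`simulate_recording`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Annotation, AnnotationSet, EEGRecord

__all__ = [
    "ScenarioError",
    "SpikeSpec",
    "EventSpec",
    "SeizureSpec",
    "ArtifactSpec",
    "ScenarioConfig",
    "CohortConfig",
    "GroundTruth",
    "CohortDataset",
    "make_background",
    "inject_spike",
    "inject_plateau",
    "inject_interictal_event",
    "inject_seizure",
    "simulate_recording",
    "default_scenario",
    "simulate_cohort",
]

ARTIFACT_THRESHOLD_UV = 1500.0

#: ratio of the secondary (negative) lobe to the main lobe of the spike kernel
NEG_LOBE_RATIO = 0.35


class ScenarioError(ValueError):
    """Inconsistent or out-of-range planted scenario."""


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-emitted reference annotations (plus cohort tables)."""

    annotations: AnnotationSet = field(default_factory=AnnotationSet)

    def counts(self) -> dict:
        return self.annotations.counts()


def _spike_kernel(fs: float, amplitude: float, width_s: float):
    """Biphasic raised-cosine transient.

    The positive lobe has full width at half maximum ``width_s`` and
    absolute peak ``amplitude``; a trailing negative lobe of
    ``NEG_LOBE_RATIO × amplitude`` gives the sharp after-going deflection
    seen in epidural spikes. Returns ``(kernel, peak_offset_samples)``.
    """
    T = width_s  # half-base of the positive lobe == FWHM
    n_pre = int(round(T * fs))
    n_post = int(round(1.5 * T * fs))
    t = np.arange(-n_pre, n_post + 1) / fs
    pos = np.where(np.abs(t) <= T, 0.5 * (1 + np.cos(np.pi * t / T)), 0.0)
    tn = t - 0.75 * T
    neg = np.where(
        np.abs(tn) <= 0.75 * T, 0.5 * (1 + np.cos(np.pi * tn / (0.75 * T))), 0.0
    )
    return amplitude * (pos - NEG_LOBE_RATIO * neg), n_pre


def make_background(
    duration: float,
    fs: float = 1000.0,
    noise_sigma: float = 50.0,
    seed: int = 0,
    n_channels: int = 2,
    channel_ids: Sequence[str] = ("EEG1", "EEG2"),
    spectral_exponent: float = 2.5,
    knee_hz: float = 1.0,
    cutoff_hz: float = 100.0,
    subject_id: str = "",
) -> EEGRecord:
    """Generate band-limited Gaussian background activity.

    Channels are independent. The default spectrum is power-law
    (PSD ∝ f^−2.5 above a 1 Hz knee, zero above the 100 Hz acquisition
    cutoff), matching the strongly low-frequency-dominant spectrum of
    rodent cortical EEG; ``spectral_exponent=0`` gives flat band-limited
    noise. Each channel is rescaled to sample SD ``noise_sigma`` μV.
    Fully deterministic for a fixed seed.
    """
    if duration <= 0:
        raise ScenarioError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(f)
    band = (f > 0) & (f <= cutoff_hz)
    shape[band] = np.maximum(f[band], knee_hz) ** (-spectral_exponent / 2.0)
    chans = []
    for _ in range(n_channels):
        if noise_sigma == 0:
            chans.append(np.zeros(n))
            continue
        white = rng.standard_normal(n)
        y = np.fft.irfft(np.fft.rfft(white) * shape, n)
        sd = y.std()
        chans.append(y * (noise_sigma / sd) if sd > 0 else y)
    return EEGRecord(
        samples=np.vstack(chans),
        fs=fs,
        channel_ids=tuple(channel_ids[:n_channels]),
        subject_id=subject_id,
    )


def _add_kernel(record: EEGRecord, channel: str, time: float, kernel, peak_offset):
    idx = record.channel_ids.index(channel)
    peak_i = int(round(time * record.fs))
    i0 = peak_i - peak_offset
    i1 = i0 + kernel.size
    if i0 < 0 or i1 > record.n_samples:
        raise ScenarioError(
            f"planted transient at t={time:.3f}s does not fit in the record"
        )
    record.samples[idx, i0:i1] += kernel


def inject_spike(
    record: EEGRecord,
    channel: str,
    time: float,
    amplitude: float,
    width: float,
    truth: AnnotationSet | None = None,
):
    """Plant one biphasic spike (``width`` in ms) and log it in ``truth``.

    Waveforms add linearly to whatever the record already contains; on a
    zero background the absolute peak equals ``amplitude`` at ``time``.
    Transients above 1500 μV are logged as artifacts, not spikes.
    """
    kernel, off = _spike_kernel(record.fs, amplitude, width / 1000.0)
    _add_kernel(record, channel, time, kernel, off)
    kind = "artifact" if amplitude > ARTIFACT_THRESHOLD_UV else "spike"
    ann = Annotation(record.subject_id, channel, kind, time, time, amplitude)
    if truth is not None:
        truth.add(ann)
    return record, ann


def inject_plateau(
    record: EEGRecord, channel: str, time: float, amplitude: float, width: float
):
    """Plant a flat-topped transient (``width`` ms at full amplitude).

    Used to exercise the maximum-peak-width filter: a plateau longer
    than the admissible spike width must be rejected by the detector, so
    no ground-truth annotation is emitted.
    """
    fs = record.fs
    ramp = max(2, int(round(0.005 * fs)))
    top = int(round(width / 1000.0 * fs))
    up = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
    kernel = amplitude * np.concatenate([up, np.ones(top), up[::-1]])
    _add_kernel(record, channel, time, kernel, ramp + top // 2)
    return record


def _train_truth_kind(n_spikes: int, isi: float) -> str | None:
    """What an equally spaced train of qualifying spikes is, per the criteria.

    A train spanning at least 10 s with inter-spike intervals in
    [0.1, 5) s is an electrographic seizure; otherwise more than 3
    spikes with gaps ≤ 10 s form an interictal event; anything else is
    just spikes.
    """
    span = (n_spikes - 1) * isi
    if span >= 10.0 and 0.1 <= isi < 5.0:
        return "seizure"
    if n_spikes >= 4 and isi <= 10.0:
        return "interictal_event"
    return None


def inject_interictal_event(
    record: EEGRecord,
    channel: str,
    start: float,
    n_spikes: int,
    isi: float,
    amplitude_factor: float,
    baseline_sigma: float,
    width: float = 40.0,
    truth: AnnotationSet | None = None,
):
    """Plant ``n_spikes`` equally spaced spikes at ``amplitude_factor ×
    baseline_sigma``.

    The member spikes are always logged. The cluster-level truth follows
    the detection criteria: a train of more than 3 spikes with gaps
    ≤ 10 s is an interictal event — unless it also spans ≥ 10 s at
    ISI < 5 s, in which case the criteria make it an electrographic
    seizure and the truth says so.
    """
    if n_spikes < 1 or isi <= 0:
        raise ScenarioError("need n_spikes >= 1 and isi > 0")
    amp = amplitude_factor * baseline_sigma
    increments = []
    for k in range(n_spikes):
        _, ann = inject_spike(
            record, channel, start + k * isi, amp, width, truth=truth
        )
        increments.append(ann)
    kind = _train_truth_kind(n_spikes, isi)
    if kind is not None:
        ev = Annotation(
            record.subject_id,
            channel,
            kind,
            start,
            start + (n_spikes - 1) * isi,
            amp,
        )
        if truth is not None:
            truth.add(ev)
        increments.append(ev)
    return record, increments


def inject_seizure(
    record: EEGRecord,
    channel: str,
    start: float,
    duration: float,
    isi: float,
    amplitude_factor: float,
    baseline_sigma: float,
    postictal: bool = False,
    width: float = 30.0,
    truth: AnnotationSet | None = None,
):
    """Plant a dense discharge train spanning ``duration`` seconds.

    Spikes sit at ``start + k·isi`` (``floor(duration/isi)+1`` of them)
    with amplitudes ramping up 20% first-to-last, the crescendo typical
    of electrographic seizures. With ``postictal=True`` the background in
    the 10 s after the last spike is scaled to 0.3×, reproducing
    post-ictal suppression. Cluster-level truth follows the detection
    criteria: the train is a seizure when it spans ≥ 10 s at
    ISI ∈ [0.1, 5) s; a sub-threshold train (e.g. 8 s of discharges)
    that still has more than 3 spikes with gaps ≤ 10 s is logged as an
    interictal event instead.
    """
    if duration <= 0 or isi <= 0:
        raise ScenarioError("need positive duration and isi")
    n = int(np.floor(duration / isi)) + 1
    base = amplitude_factor * baseline_sigma
    last = start + (n - 1) * isi
    idx = record.channel_ids.index(channel)
    if postictal:
        i0 = int(round(last * record.fs)) + 1
        i1 = int(round((last + 10.0) * record.fs))
        if i1 > record.n_samples:
            raise ScenarioError("post-ictal window does not fit in the record")
        record.samples[idx, i0:i1] *= 0.3
    increments = []
    for k in range(n):
        ramp = 1.0 + (0.2 * k / (n - 1) if n > 1 else 0.0)
        _, ann = inject_spike(
            record, channel, start + k * isi, base * ramp, width, truth=truth
        )
        increments.append(ann)
    kind = _train_truth_kind(n, isi)
    if kind is not None:
        sz = Annotation(
            record.subject_id, channel, kind, start, last,
            base * (1.2 if kind == "seizure" else 1.0),
        )
        if truth is not None:
            truth.add(sz)
        increments.append(sz)
    return record, increments


@dataclass(frozen=True)
class SpikeSpec:
    time: float
    amplitude: float  # μV
    width: float  # ms


@dataclass(frozen=True)
class EventSpec:
    start: float
    n_spikes: int
    isi: float
    amplitude_factor: float


@dataclass(frozen=True)
class SeizureSpec:
    start: float
    duration: float
    isi: float
    amplitude_factor: float
    postictal: bool = False

    @property
    def end(self) -> float:
        n = int(np.floor(self.duration / self.isi)) + 1
        return self.start + (n - 1) * self.isi


@dataclass(frozen=True)
class ArtifactSpec:
    time: float
    amplitude: float  # μV, must exceed 1500

    def __post_init__(self):
        if self.amplitude <= ARTIFACT_THRESHOLD_UV:
            raise ScenarioError(
                f"artifact amplitude must exceed {ARTIFACT_THRESHOLD_UV} μV"
            )


@dataclass
class ScenarioConfig:
    """One synthetic recording: background plus planted items.

    ``reference_sigma`` is the amplitude scale that ``amplitude_factor``
    multiplies (defaults to ``noise_sigma``; set it explicitly for
    noiseless renders). Isolated spikes are placed at seeded random
    times kept at least ``isolation_gap`` seconds away from every other
    planted item and from each other, so they can never chain into
    spurious clusters of the planted truth.
    """

    duration: float = 3600.0
    fs: float = 1000.0
    noise_sigma: float = 50.0
    spectral_exponent: float = 2.5
    spike_amplitude_range: tuple = (300.0, 800.0)
    spike_width_range: tuple = (20.0, 80.0)  # ms
    n_isolated_spikes: int = 20
    events: list = field(default_factory=list)
    seizures: list = field(default_factory=list)
    artifacts: list = field(default_factory=list)
    seed: int = 0
    reference_sigma: float | None = None
    isolation_gap: float = 15.0
    channel_ids: tuple = ("EEG1", "EEG2")

    @property
    def sigma_ref(self) -> float:
        return self.noise_sigma if self.reference_sigma is None else self.reference_sigma

    def validate(self) -> None:
        if self.duration <= 0:
            raise ScenarioError("duration must be positive")
        spans = []
        for ev in self.events:
            spans.append((ev.start, ev.start + (ev.n_spikes - 1) * ev.isi))
        sz_spans = [(sz.start, sz.end + (10.0 if sz.postictal else 0.0)) for sz in self.seizures]
        for s0, s1 in sorted(sz_spans):
            spans.append((s0, s1))
        for s0, s1 in spans:
            if s0 < 0 or s1 > self.duration:
                raise ScenarioError("planted item extends outside the record")
        ordered = sorted(sz_spans)
        for (a0, a1), (b0, b1) in zip(ordered, ordered[1:]):
            if b0 <= a1:
                raise ScenarioError("planted seizures overlap in time")
        for art in self.artifacts:
            if not 0 <= art.time <= self.duration:
                raise ScenarioError("artifact outside the record")
        if (self.events or self.seizures) and self.sigma_ref <= 0:
            raise ScenarioError(
                "amplitude_factor items need a positive reference sigma"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        raw = dict(raw)
        raw["events"] = [EventSpec(**e) for e in raw.get("events", [])]
        raw["seizures"] = [SeizureSpec(**s) for s in raw.get("seizures", [])]
        raw["artifacts"] = [ArtifactSpec(**a) for a in raw.get("artifacts", [])]
        for key in ("spike_amplitude_range", "spike_width_range", "channel_ids"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _planted_intervals(scenario: ScenarioConfig):
    spans = []
    for ev in scenario.events:
        spans.append((ev.start, ev.start + (ev.n_spikes - 1) * ev.isi))
    for sz in scenario.seizures:
        spans.append((sz.start, sz.end + (10.0 if sz.postictal else 0.0)))
    for art in scenario.artifacts:
        spans.append((art.time, art.time))
    return spans


def _draw_isolated_times(scenario: ScenarioConfig, rng) -> list[float]:
    gap = scenario.isolation_gap
    taken = _planted_intervals(scenario)
    times: list[float] = []
    lo, hi = gap, scenario.duration - gap
    if hi <= lo:
        return times
    attempts = 0
    while len(times) < scenario.n_isolated_spikes and attempts < 10000:
        attempts += 1
        t = rng.uniform(lo, hi)
        if any(s - gap <= t <= e + gap for s, e in taken):
            continue
        if any(abs(t - u) < gap for u in times):
            continue
        times.append(t)
    if len(times) < scenario.n_isolated_spikes:
        raise ScenarioError(
            "could not place isolated spikes with the required isolation gap"
        )
    return sorted(times)


def simulate_recording(scenario: ScenarioConfig):
    """Render a scenario to an :class:`EEGRecord` plus :class:`GroundTruth`.

    Every planted item appears synchronously on both channels (epidural
    leads see generalized discharges together). Spike/artifact truth is
    per channel; event and seizure truth is one annotation per planted
    item, labeled with the joined channel ids — the same shape the
    detector's cross-channel merge emits.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    record = make_background(
        scenario.duration,
        scenario.fs,
        scenario.noise_sigma,
        seed=int(rng.integers(2**31)),
        n_channels=len(scenario.channel_ids),
        channel_ids=scenario.channel_ids,
        spectral_exponent=scenario.spectral_exponent,
        subject_id=f"sim{scenario.seed}",
    )
    truth = AnnotationSet()
    merged_label = "+".join(scenario.channel_ids)
    sigma = scenario.sigma_ref

    iso_times = _draw_isolated_times(scenario, rng)
    iso_amp = rng.uniform(*scenario.spike_amplitude_range, size=len(iso_times))
    iso_wid = rng.uniform(*scenario.spike_width_range, size=len(iso_times))
    for t, a, w in zip(iso_times, iso_amp, iso_wid):
        for chan in record.channel_ids:
            inject_spike(record, chan, t, float(a), float(w), truth=truth)

    def merge_cluster_truth(start: float, kind: str) -> None:
        """Collapse per-channel cluster truths into one merged annotation."""
        rows = [
            a for a in truth.records if a.kind == kind and a.start_s == start
        ]
        if not rows:
            return
        truth.records = [a for a in truth.records if a not in rows]
        truth.add(
            Annotation(
                record.subject_id, merged_label, kind,
                rows[0].start_s, rows[0].end_s, rows[0].peak_uv,
            )
        )

    for ev in scenario.events:
        for chan in record.channel_ids:
            inject_interictal_event(
                record, chan, ev.start, ev.n_spikes, ev.isi,
                ev.amplitude_factor, sigma, truth=truth,
            )
        kind = _train_truth_kind(ev.n_spikes, ev.isi)
        if kind is not None:
            merge_cluster_truth(ev.start, kind)

    for sz in scenario.seizures:
        for chan in record.channel_ids:
            inject_seizure(
                record, chan, sz.start, sz.duration, sz.isi,
                sz.amplitude_factor, sigma, postictal=sz.postictal, truth=truth,
            )
        kind = _train_truth_kind(int(np.floor(sz.duration / sz.isi)) + 1, sz.isi)
        if kind is not None:
            merge_cluster_truth(sz.start, kind)

    for art in scenario.artifacts:
        for chan in record.channel_ids:
            inject_spike(record, chan, art.time, art.amplitude, 30.0, truth=truth)

    truth.records.sort(key=lambda a: (a.start_s, a.kind, a.channel))
    return record, GroundTruth(annotations=truth)


def default_scenario(seed: int = 0, duration: float = 3600.0) -> ScenarioConfig:
    """The canonical high-SNR validation scenario.

    One hour of σ = 50 μV background with three interictal events, one
    20 s seizure with post-ictal suppression, two interference
    artifacts, and twenty sporadic isolated spikes — all planted at
    amplitudes of at least 6× the noise sigma.
    """
    return ScenarioConfig(
        duration=duration,
        noise_sigma=50.0,
        events=[
            # a brief dense cluster (span < 10 s keeps it sub-ictal), a
            # sparse 30 s cluster (ISI > 5 s), and a 9 s run of 10 spikes
            EventSpec(start=600.0, n_spikes=5, isi=2.0, amplitude_factor=8.0),
            EventSpec(start=1500.0, n_spikes=6, isi=6.0, amplitude_factor=8.0),
            EventSpec(start=2400.0, n_spikes=10, isi=1.0, amplitude_factor=8.0),
        ],
        seizures=[
            SeizureSpec(
                start=3000.0, duration=20.0, isi=0.25, amplitude_factor=8.0,
                postictal=True,
            )
        ],
        artifacts=[ArtifactSpec(300.0, 2000.0), ArtifactSpec(3300.0, 2500.0)],
        n_isolated_spikes=20,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort-level simulation


@dataclass
class CohortConfig:
    """Multi-week two-group telemetry study design.

    Weekly event rates are expected interictal-event counts under the
    reference intermittent week (five 9-h days = 45 recorded hours);
    actual weekly counts are Poisson with the rate scaled by that week's
    recorded hours. Seizure incidence is the probability an animal ever
    develops post-traumatic seizures; onset week is categorical over
    ``onset_weeks`` (monitoring for spontaneous seizures begins in week
    3). Seizure durations are Gaussian, truncated at the 10 s
    electrographic minimum.
    """

    n_per_group: dict = field(default_factory=lambda: {"TBI": 7, "T+N": 8})
    weeks: int = 12
    weekly_event_rate: dict = field(
        default_factory=lambda: {
            "TBI": [10, 12, 14, 16, 18, 20, 21, 22, 23, 24, 24, 24],
            "T+N": [10, 12, 14, 6, 6, 7, 7, 7, 8, 8, 8, 8],
        }
    )
    seizure_incidence: dict = field(
        default_factory=lambda: {"TBI": 0.71, "T+N": 0.0}
    )
    onset_weeks: tuple = tuple(range(3, 13))
    onset_week_probs: tuple | None = None  # uniform when None
    seizure_rate_per_week: float = 0.6  # Poisson mean in weeks at/after onset
    seizure_duration_mean: float = 40.0  # s
    seizure_duration_sd: float = 15.0  # s
    continuous_days: int = 8
    hours_per_day: float = 9.0  # within the published 8-10 h/day window
    days_per_week: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.weeks < 1:
            raise ScenarioError("weeks must be >= 1")
        for g, p in self.seizure_incidence.items():
            if not 0 <= p <= 1:
                raise ScenarioError(f"incidence for {g} outside [0, 1]")
        for g, rates in self.weekly_event_rate.items():
            if len(rates) < self.weeks:
                raise ScenarioError(f"need {self.weeks} weekly rates for {g}")
            if any(r < 0 for r in rates):
                raise ScenarioError("weekly rates must be >= 0")
        if min(self.onset_weeks) < 1 or max(self.onset_weeks) > self.weeks:
            raise ScenarioError("onset weeks outside the study window")

    def recorded_hours(self, week: int) -> float:
        """Recorded hours in study week ``week`` (1-based).

        Continuous 24 h/day for the first ``continuous_days`` days, then
        ``hours_per_day`` on the first ``days_per_week`` days of each
        week.
        """
        hours = 0.0
        for day in range(7 * (week - 1), 7 * week):
            if day < self.continuous_days:
                hours += 24.0
            elif day % 7 < self.days_per_week:
                hours += self.hours_per_day
        return hours

    @property
    def reference_hours(self) -> float:
        return self.hours_per_day * self.days_per_week

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        raw = dict(raw)
        for key in ("onset_weeks", "onset_week_probs"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CohortDataset:
    """Per-animal weekly event/seizure tables for a simulated cohort."""

    animals: pd.DataFrame  # animal_id, group, seizes, onset_week
    weekly: pd.DataFrame  # animal_id, group, week, recorded_hours, n_events, ...
    seizures: pd.DataFrame  # animal_id, group, week, duration_s
    config: CohortConfig

    def group_weekly(self, group: str) -> pd.DataFrame:
        return self.weekly[self.weekly.group == group].reset_index(drop=True)

    def first_seizure_table(self) -> pd.DataFrame:
        """(animal_id, group, time_weeks, event) with right-censoring."""
        rows = []
        for a in self.animals.itertuples(index=False):
            if a.seizes:
                rows.append((a.animal_id, a.group, int(a.onset_week), 1))
            else:
                rows.append((a.animal_id, a.group, int(self.config.weeks), 0))
        return pd.DataFrame(rows, columns=["animal_id", "group", "time_weeks", "event"])

    def to_dir(self, path) -> None:
        from pathlib import Path
        import json

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.weekly.to_csv(path / "weekly.csv", index=False)
        self.seizures.to_csv(path / "seizures.csv", index=False)
        self.animals.to_csv(path / "animals.csv", index=False)
        manifest = {
            "n_animals": int(len(self.animals)),
            "groups": {
                g: int(n) for g, n in self.animals.group.value_counts().items()
            },
            "weeks": int(self.config.weeks),
            "seed": int(self.config.seed),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def simulate_cohort(cohort: CohortConfig) -> CohortDataset:
    """Draw a full two-group study at the event level.

    Deterministic for a fixed ``cohort.seed``.
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    onset_probs = (
        np.asarray(cohort.onset_week_probs, dtype=float)
        if cohort.onset_week_probs is not None
        else np.full(len(cohort.onset_weeks), 1.0 / len(cohort.onset_weeks))
    )
    onset_probs = onset_probs / onset_probs.sum()

    animal_rows, weekly_rows, seizure_rows = [], [], []
    for group, n_animals in cohort.n_per_group.items():
        rates = cohort.weekly_event_rate[group]
        incidence = cohort.seizure_incidence[group]
        for i in range(n_animals):
            animal_id = f"{group.replace('+', '')}-{i + 1:02d}"
            seizes = bool(rng.random() < incidence)
            onset = (
                int(rng.choice(cohort.onset_weeks, p=onset_probs)) if seizes else 0
            )
            animal_rows.append((animal_id, group, seizes, onset))
            for week in range(1, cohort.weeks + 1):
                hours = cohort.recorded_hours(week)
                lam = rates[week - 1] * hours / cohort.reference_hours
                n_events = int(rng.poisson(lam)) if lam > 0 else 0
                if seizes and week >= onset:
                    n_sz = int(rng.poisson(cohort.seizure_rate_per_week))
                    if week == onset:
                        n_sz = max(1, n_sz)
                else:
                    n_sz = 0
                durations = []
                for _ in range(n_sz):
                    d = rng.normal(
                        cohort.seizure_duration_mean, cohort.seizure_duration_sd
                    )
                    durations.append(float(max(10.0, d)))
                    seizure_rows.append((animal_id, group, week, durations[-1]))
                weekly_rows.append(
                    (
                        animal_id,
                        group,
                        week,
                        hours,
                        n_events,
                        n_events / hours if hours > 0 else np.nan,
                        n_sz,
                        float(np.mean(durations)) if durations else np.nan,
                    )
                )

    animals = pd.DataFrame(
        animal_rows, columns=["animal_id", "group", "seizes", "onset_week"]
    )
    weekly = pd.DataFrame(
        weekly_rows,
        columns=[
            "animal_id",
            "group",
            "week",
            "recorded_hours",
            "n_events",
            "events_per_hour",
            "n_seizures",
            "mean_seizure_duration_s",
        ],
    )
    seizures = pd.DataFrame(
        seizure_rows, columns=["animal_id", "group", "week", "duration_s"]
    )
    return CohortDataset(animals=animals, weekly=weekly, seizures=seizures, config=cohort)
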
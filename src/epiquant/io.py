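"""Core containers and file I/O for rodent telemetry EEG analysis.

Signals travel as :class:`EEGRecord` (μV, seconds), events as
:class:`AnnotationSet` rows, and algorithm constants as
:class:`DetectionConfig`. EDF is the on-disk signal container
(16-bit, one data record per second, channels "EEG1"/"EEG2");
annotations live in a sidecar CSV/JSON so traces and events stay
independently editable, and configuration is flat YAML keyed exactly
by the :class:`DetectionConfig` field names.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import _edf
from ._edf import EDFFormatError

__all__ = [
    "EEGRecord",
    "DetectionConfig",
    "Annotation",
    "AnnotationSet",
    "ANNOTATION_KINDS",
    "EDFFormatError",
    "ConfigError",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "load_config",
]

#: full-scale acquisition bound: ±10 mV expressed in μV
FULL_SCALE_UV = 10_000.0

ANNOTATION_KINDS = ("spike", "interictal_event", "seizure", "artifact")


class ConfigError(ValueError):
    """Invalid or inconsistent detection configuration."""


@dataclass
class EEGRecord:
    """A uniformly sampled multichannel voltage trace.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltages in μV.
    fs : float
        Sampling frequency in Hz.
    channel_ids : sequence of str
        Ordered channel labels, e.g. ``("EEG1", "EEG2")``.
    start_time : float
        Absolute start timestamp in seconds (epoch); event times within the
        record are seconds from this origin.
    subject_id : str
        Animal identifier.
    """

    samples: np.ndarray
    fs: float
    channel_ids: Sequence[str] = ("EEG1", "EEG2")
    start_time: float = 0.0
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels, samples)")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match channel count")
        self.channel_ids = tuple(str(c) for c in self.channel_ids)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        """Return the 1-D trace for one channel label."""
        try:
            idx = self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"no such channel: {channel_id!r}") from None
        return self.samples[idx]


@dataclass(frozen=True)
class DetectionConfig:
    """Constants of the spike/event/seizure detection algorithm.

    Defaults follow the published criteria for epidural mouse telemetry:
    candidate spikes must exceed both twice the autonomously estimated
    baseline amplitude and an absolute floor of 200 μV, transients above
    1500 μV are electrical-interference artifacts, spikes wider than
    200 ms are rejected, an interictal event needs more than 3 spikes at
    3× baseline with gaps ≤ 10 s, and an electrographic seizure is ≥ 10 s
    of discharges with inter-spike intervals in [100 ms, 5 s).
    """

    lower_threshold_factor: float = 2.0
    event_amplitude_factor: float = 3.0
    upper_threshold: float = 1500.0  # μV
    min_peak_height: float = 200.0  # μV
    max_peak_width: float = 200.0  # ms
    event_max_isi: float = 10.0  # s
    event_min_spikes: int = 4  # ">3 spikes"
    seizure_min_isi: float = 0.1  # s
    seizure_max_isi: float = 5.0  # s
    seizure_min_duration: float = 10.0  # s
    highpass_cutoff: float | None = 1.0  # Hz; None disables drift removal

    def __post_init__(self):
        if not 0 < self.min_peak_height < self.upper_threshold:
            raise ConfigError(
                "require 0 < min_peak_height < upper_threshold "
                f"(got {self.min_peak_height}, {self.upper_threshold})"
            )
        if not self.seizure_min_isi < self.seizure_max_isi <= self.event_max_isi:
            raise ConfigError(
                "require seizure_min_isi < seizure_max_isi <= event_max_isi"
            )
        if self.seizure_min_duration <= 0:
            raise ConfigError("seizure_min_duration must be positive")
        if self.event_min_spikes < 2:
            raise ConfigError("event_min_spikes must be at least 2")
        if self.lower_threshold_factor <= 0 or self.event_amplitude_factor <= 0:
            raise ConfigError("threshold factors must be positive")
        if self.highpass_cutoff is not None and self.highpass_cutoff <= 0:
            raise ConfigError("highpass_cutoff must be positive or None")


@dataclass(frozen=True)
class Annotation:
    """One time-bounded detection or ground-truth item."""

    subject_id: str
    channel: str
    kind: str
    start_s: float
    end_s: float
    peak_uv: float

    def __post_init__(self):
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.end_s < self.start_s:
            raise ValueError("annotation end precedes start")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


class AnnotationSet:
    """An ordered collection of :class:`Annotation` rows."""

    def __init__(self, records: Iterable[Annotation] = ()):
        self.records: list[Annotation] = list(records)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other):
        return isinstance(other, AnnotationSet) and self.records == other.records

    def add(self, annotation: Annotation) -> None:
        self.records.append(annotation)

    def of_kind(self, kind: str) -> list[Annotation]:
        if kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {kind!r}")
        return [a for a in self.records if a.kind == kind]

    def counts(self) -> dict:
        """Number of annotations per kind."""
        return {k: len(self.of_kind(k)) for k in ANNOTATION_KINDS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(a) for a in self.records],
            columns=["subject_id", "channel", "kind", "start_s", "end_s", "peak_uv"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnnotationSet":
        required = ["subject_id", "channel", "kind", "start_s", "end_s", "peak_uv"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise EDFFormatError(f"annotation table missing columns: {missing}")
        records = [
            Annotation(
                subject_id=str(row.subject_id),
                channel=str(row.channel),
                kind=str(row.kind),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                peak_uv=float(row.peak_uv),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records)


def read_edf(path) -> EEGRecord:
    """Read a classic EDF file into an :class:`EEGRecord` (μV).

    Raises :class:`EDFFormatError` for malformed files and for layouts
    with per-channel sampling rates, which this pipeline does not model.
    """
    samples, fs, labels, start_time, subject_id = _edf.read_edf_arrays(path)
    return EEGRecord(
        samples=samples,
        fs=fs,
        channel_ids=labels,
        start_time=start_time,
        subject_id=subject_id,
    )


def write_edf(record: EEGRecord, path) -> str:
    """Write an :class:`EEGRecord` to classic EDF.

    The declared physical range is the acquisition full scale (±10 mV),
    so the 16-bit quantization step is ``20000/65535 ≈ 0.305`` μV.
    Samples outside the full scale, or non-finite samples, raise
    ``ValueError``.
    """
    return _edf.write_edf_arrays(
        path,
        record.samples,
        record.fs,
        record.channel_ids,
        start_time=record.start_time,
        subject_id=record.subject_id,
        physical_max_uv=FULL_SCALE_UV,
    )


def write_annotations(annotations: AnnotationSet, path) -> str:
    """Write annotations to CSV (or JSON if the suffix is ``.json``)."""
    path = Path(path)
    frame = annotations.to_frame()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
    else:
        frame.to_csv(path, index=False)
    return str(path)


def read_annotations(path) -> AnnotationSet:
    """Read an annotation CSV/JSON written by :func:`write_annotations`.

    Unknown ``kind`` strings and reversed intervals raise a format error.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        frame = pd.DataFrame(
            rows, columns=["subject_id", "channel", "kind", "start_s", "end_s", "peak_uv"]
        )
    else:
        frame = pd.read_csv(
            path, dtype={"subject_id": str, "channel": str, "kind": str}
        )
        if frame.empty and frame.columns.size == 0:
            raise EDFFormatError("annotation file has no header")
    try:
        return AnnotationSet.from_frame(frame)
    except ValueError as exc:
        raise EDFFormatError(str(exc)) from exc


def load_config(path=None, **overrides) -> DetectionConfig:
    """Load a :class:`DetectionConfig` from flat YAML.

    Missing keys take the published defaults; unknown keys and invariant
    violations raise :class:`ConfigError`. ``path=None`` (or an empty
    file) yields the defaults.
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must be a flat key-value mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in dataclasses.fields(DetectionConfig)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return DetectionConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
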
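"""Minimal 16-bit European Data Format (EDF) reader/writer.

Implements the classic EDF layout: a 256-byte ASCII global header,
256 ASCII bytes per signal, then little-endian int16 data records.
One data record per second; all channels must share a sampling rate.
Physical values are handled in μV (mV/V dimension strings are
normalized on read).
"""

from __future__ import annotations

import datetime
import math

import numpy as np

__all__ = ["EDFFormatError", "read_edf_arrays", "write_edf_arrays"]

_DIG_MIN = -32768
_DIG_MAX = 32767

# scale factors into μV by declared physical dimension
_UNIT_TO_UV = {
    "uv": 1.0,
    "µv": 1.0,
    "μv": 1.0,
    "mv": 1e3,
    "v": 1e6,
    "": 1.0,
}


class EDFFormatError(ValueError):
    """Raised when a file does not parse as classic EDF."""


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")
    if len(raw) > width:
        raw = raw[:width]
    return raw.ljust(width)


def _field(raw: bytes, start: int, width: int) -> str:
    return raw[start : start + width].decode("ascii", errors="replace").strip()


def write_edf_arrays(
    path,
    samples: np.ndarray,
    fs: float,
    channel_ids,
    start_time: float = 0.0,
    subject_id: str = "",
    physical_max_uv: float = 10_000.0,
) -> str:
    """Write ``samples`` (n_channels, n_samples) in μV to a classic EDF file.

    Uses one-second data records and a symmetric physical range of
    ``±physical_max_uv`` mapped onto the full int16 digital range. The
    trailing partial second, if any, is zero-padded.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise EDFFormatError("samples must be a 2-D (channels, samples) array")
    if not np.isfinite(samples).all():
        raise ValueError("EDF samples must be finite (NaN/inf outside physical range)")
    if np.abs(samples).max(initial=0.0) > physical_max_uv:
        raise ValueError(
            f"sample magnitude exceeds declared physical maximum {physical_max_uv} μV"
        )
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise EDFFormatError("EDF writer requires a positive integer sampling rate")
    fs_i = int(round(fs))
    n_ch, n_samp = samples.shape
    if len(channel_ids) != n_ch:
        raise EDFFormatError("channel_ids length does not match sample array")

    n_records = max(1, math.ceil(n_samp / fs_i))
    padded = np.zeros((n_ch, n_records * fs_i))
    padded[:, :n_samp] = samples

    phys_min, phys_max = -physical_max_uv, physical_max_uv
    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min) * gain + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    start_dt = datetime.datetime.fromtimestamp(
        int(round(start_time)), tz=datetime.timezone.utc
    )
    header = b"".join(
        [
            _pad("0", 8),
            _pad(subject_id or "X", 80),
            _pad("Startdate " + start_dt.strftime("%d-%b-%Y").upper(), 80),
            _pad(start_dt.strftime("%d.%m.%y"), 8),
            _pad(start_dt.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),  # record duration, seconds
            _pad(str(n_ch), 4),
        ]
    )

    def sig(fmt: str, width: int) -> bytes:
        return b"".join(_pad(fmt.format(c=c), width) for c in channel_ids)

    sig_header = b"".join(
        [
            sig("{c}", 16),  # label
            sig("", 80),  # transducer
            sig("uV", 8),  # physical dimension
            b"".join(_pad(f"{phys_min:g}", 8) for _ in channel_ids),
            b"".join(_pad(f"{phys_max:g}", 8) for _ in channel_ids),
            b"".join(_pad(str(_DIG_MIN), 8) for _ in channel_ids),
            b"".join(_pad(str(_DIG_MAX), 8) for _ in channel_ids),
            sig("LP:100Hz", 80),  # prefiltering
            b"".join(_pad(str(fs_i), 8) for _ in channel_ids),
            sig("", 32),  # reserved
        ]
    )

    # interleave: per record, all samples of channel 0, then channel 1, ...
    records = digital.reshape(n_ch, n_records, fs_i).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(records.tobytes())
    return str(path)


def read_edf_arrays(path):
    """Read a classic EDF file.

    Returns ``(samples_uv, fs, channel_ids, start_time, subject_id)`` with
    ``samples_uv`` shaped (n_channels, n_samples). All channels must share
    one sampling rate (epidural telemetry layout); otherwise an
    :class:`EDFFormatError` ("unsupported layout") is raised.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFFormatError("truncated EDF header")
        try:
            header_bytes = int(_field(head, 184, 8))
            n_records = int(_field(head, 236, 8))
            record_dur = float(_field(head, 244, 8))
            n_ch = int(_field(head, 252, 4))
        except ValueError as exc:
            raise EDFFormatError(f"malformed EDF header: {exc}") from exc
        if n_ch < 1:
            raise EDFFormatError("EDF file declares no signals")
        subject_id = _field(head, 8, 80)
        date_s, time_s = _field(head, 168, 8), _field(head, 176, 8)
        try:
            start_dt = datetime.datetime.strptime(
                date_s + " " + time_s, "%d.%m.%y %H.%M.%S"
            ).replace(tzinfo=datetime.timezone.utc)
            start_time = start_dt.timestamp()
        except ValueError:
            start_time = 0.0

        sig_raw = fh.read(256 * n_ch)
        if len(sig_raw) < 256 * n_ch:
            raise EDFFormatError("truncated EDF signal header")

        # sequential field blocks of the signal header, widths per signal
        pos = 0
        fields = {}
        for name, width in [
            ("label", 16),
            ("transducer", 80),
            ("dim", 8),
            ("phys_min", 8),
            ("phys_max", 8),
            ("dig_min", 8),
            ("dig_max", 8),
            ("prefilter", 80),
            ("n_per_record", 8),
            ("reserved", 32),
        ]:
            fields[name] = [
                _field(sig_raw, pos + i * width, width) for i in range(n_ch)
            ]
            pos += width * n_ch

        labels = fields["label"]
        try:
            phys_min = np.array([float(v) for v in fields["phys_min"]])
            phys_max = np.array([float(v) for v in fields["phys_max"]])
            dig_min = np.array([float(v) for v in fields["dig_min"]])
            dig_max = np.array([float(v) for v in fields["dig_max"]])
            n_per_record = [int(v) for v in fields["n_per_record"]]
        except ValueError as exc:
            raise EDFFormatError(f"malformed EDF signal header: {exc}") from exc
        if len(set(n_per_record)) != 1:
            raise EDFFormatError(
                "unsupported layout: channels have different sampling rates"
            )
        spr = n_per_record[0]
        if record_dur <= 0 or spr <= 0:
            raise EDFFormatError("non-positive record duration or sample count")
        fs = spr / record_dur

        if header_bytes != 256 * (1 + n_ch):
            # tolerate but do not seek past declared header
            fh.seek(header_bytes)
        payload = fh.read()

    expected = 2 * n_ch * spr
    if n_records < 0:  # -1 means "unknown" per the EDF spec
        n_records = len(payload) // expected
    if len(payload) < n_records * expected:
        raise EDFFormatError("EDF payload shorter than declared record count")
    data = np.frombuffer(payload[: n_records * expected], dtype="<i2")
    data = data.reshape(n_records, n_ch, spr).transpose(1, 0, 2)
    data = data.reshape(n_ch, n_records * spr).astype(float)

    span_d = dig_max - dig_min
    if np.any(span_d == 0):
        raise EDFFormatError("degenerate digital range in EDF signal header")
    gain = (phys_max - phys_min) / span_d
    phys = (data - dig_min[:, None]) * gain[:, None] + phys_min[:, None]

    for i in range(n_ch):
        unit = fields["dim"][i].lower()
        scale = _UNIT_TO_UV.get(unit)
        if scale is None:
            raise EDFFormatError(f"unsupported physical dimension {fields['dim'][i]!r}")
        phys[i] *= scale

    return phys, fs, labels, start_time, subject_id
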
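"""Minimal EDF/EDF+ writer for synthetic fixtures.

Writes standard 16-bit EDF with an optional EDF+ annotation channel
(timestamped annotation lists, "EDF+C" continuous recording).  Only the
features the fixture generator needs are supported: integer-second signal
lengths, a common sampling rate for all data channels, and text
annotations such as per-epoch sleep-stage labels.  Reading is delegated to
mne elsewhere in the package; this module exists because no installed
library writes EDF.
"""

from __future__ import annotations

import datetime
import math

import numpy as np

RECORD_DURATION = 1.0  # seconds per data record


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _fmt_number(x: float) -> str:
    """Compact EDF+ number: no trailing zeros, at most ms resolution."""
    s = f"{x:.3f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _annotation_records(annotations, n_records: int) -> list[bytes]:
    """Per-record TAL byte strings (timekeeping TAL + onsets in record)."""
    per_record: list[list[bytes]] = [[] for _ in range(n_records)]
    for onset, duration, text in annotations:
        rec = min(int(onset // RECORD_DURATION), n_records - 1)
        tal = b"+" + _fmt_number(onset).encode("ascii")
        if duration is not None:
            tal += b"\x15" + _fmt_number(duration).encode("ascii")
        tal += b"\x14" + str(text).encode("utf-8") + b"\x14\x00"
        per_record[rec].append(tal)
    records = []
    for r in range(n_records):
        keeper = b"+" + _fmt_number(r * RECORD_DURATION).encode("ascii") + b"\x14\x14\x00"
        records.append(keeper + b"".join(per_record[r]))
    return records


def write_edf(path, channels, sample_rate: float, annotations=None,
              patient_id: str = "X X X X", recording_id: str = "Startdate 01-JAN-2000 X X X",
              start: datetime.datetime | None = None) -> None:
    """Write ``channels`` (list of ``(label, samples)``) to an EDF(+) file.

    All channels share ``sample_rate``; signal length must be a whole
    number of seconds.  ``annotations`` is an optional list of
    ``(onset_s, duration_s or None, text)`` triples; providing it switches
    the file to EDF+C with a dedicated annotation channel.  Samples are
    quantised to 16 bits over a symmetric physical range chosen per
    channel, so the round-trip error is at most ``phys_max / 32767``.
    """
    channels = [(str(label), np.asarray(data, dtype=np.float64))
                for label, data in channels]
    if not channels:
        raise ValueError("at least one channel is required")
    n_samples = channels[0][1].size
    for label, data in channels:
        if data.ndim != 1 or data.size != n_samples:
            raise ValueError("all channels must be 1-D and equally long")
    spr = int(round(sample_rate * RECORD_DURATION))
    if abs(spr - sample_rate * RECORD_DURATION) > 1e-9 or spr < 1:
        raise ValueError(f"unsupported sample rate {sample_rate}")
    if n_samples % spr:
        raise ValueError(
            f"signal length {n_samples} is not a whole number of "
            f"{RECORD_DURATION}-s records at {sample_rate} Hz")
    n_records = n_samples // spr

    # digital conversion per channel
    digital: list[np.ndarray] = []
    phys: list[tuple[float, float]] = []
    for _, data in channels:
        pmax = float(max(1.0, math.ceil(np.abs(data).max()))) if data.size else 1.0
        scaled = np.clip(np.round(data / pmax * 32767.0), -32767, 32767)
        digital.append(scaled.astype("<i2"))
        phys.append((-pmax, pmax))

    ann_records: list[bytes] | None = None
    ann_spr = 0
    if annotations is not None:
        ann_records = _annotation_records(list(annotations), n_records)
        ann_bytes = max(len(r) for r in ann_records)
        ann_spr = (ann_bytes + 1) // 2 + 8  # headroom, in 2-byte samples

    labels = [label for label, _ in channels]
    if ann_records is not None:
        labels.append("EDF Annotations")
    ns = len(labels)

    start = start or datetime.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        _ascii("0", 8),
        _ascii(patient_id, 80),
        _ascii(recording_id, 80),
        _ascii(start.strftime("%d.%m.%y"), 8),
        _ascii(start.strftime("%H.%M.%S"), 8),
        _ascii(256 * (ns + 1), 8),
        _ascii("EDF+C" if ann_records is not None else "", 44),
        _ascii(n_records, 8),
        _ascii(_fmt_number(RECORD_DURATION), 8),
        _ascii(ns, 4),
    ])

    def field(values, width):
        return b"".join(_ascii(v, width) for v in values)

    phys_dims = ["uV"] * len(channels) + ([""] if ann_records is not None else [])
    phys_mins = [f"{lo:g}" for lo, _ in phys] + (["-1"] if ann_records is not None else [])
    phys_maxs = [f"{hi:g}" for _, hi in phys] + (["1"] if ann_records is not None else [])
    dig_mins = ["-32767"] * len(channels) + (["-32768"] if ann_records is not None else [])
    dig_maxs = ["32767"] * len(channels) + (["32767"] if ann_records is not None else [])
    sprs = [spr] * len(channels) + ([ann_spr] if ann_records is not None else [])

    signal_header = b"".join([
        field(labels, 16),
        field([""] * ns, 80),          # transducer
        field(phys_dims, 8),
        field(phys_mins, 8),
        field(phys_maxs, 8),
        field(dig_mins, 8),
        field(dig_maxs, 8),
        field([""] * ns, 80),          # prefiltering
        field(sprs, 8),
        field([""] * ns, 32),          # reserved
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            for dig in digital:
                fh.write(dig[r * spr:(r + 1) * spr].tobytes())
            if ann_records is not None:
                block = ann_records[r].ljust(2 * ann_spr, b"\x00")
                fh.write(block)
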
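"""PSG reading, stage-label handling and epoching.

Recordings are read from EDF/EDF+ files (via mne); hypnograms come either
from an EDF+ annotation channel or from a plain-text sidecar with one
R&K code per 30-s epoch.  Preprocessing follows the subject-independent
protocol: R&K -> AASM stage mapping with MOVEMENT/UNKNOWN epochs excluded,
S3/S4 merged into N3, wake trimmed to 30 min (60 epochs) around the sleep
period, polyphase resampling to 100 Hz where needed, and segmentation into
non-overlapping 3000-sample epochs.  No filtering or amplitude
normalisation is applied.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

EPOCH_SECONDS = 30
TARGET_RATE = 100.0
EPOCH_SAMPLES = int(EPOCH_SECONDS * TARGET_RATE)

#: R&K scoring code -> AASM class index (W=0, N1=1, N2=2, N3=3, REM=4)
RK_TO_AASM = {"W": 0, "S1": 1, "S2": 2, "S3": 3, "S4": 3, "REM": 4}
EXCLUDED_CODES = {"MOVEMENT", "UNKNOWN"}

#: annotation-text dialects normalised to R&K codes
_ANNOTATION_ALIASES = {
    "W": "W", "SLEEP STAGE W": "W", "WAKE": "W",
    "S1": "S1", "SLEEP STAGE 1": "S1", "1": "S1",
    "S2": "S2", "SLEEP STAGE 2": "S2", "2": "S2",
    "S3": "S3", "SLEEP STAGE 3": "S3", "3": "S3",
    "S4": "S4", "SLEEP STAGE 4": "S4", "4": "S4",
    "REM": "REM", "R": "REM", "SLEEP STAGE R": "REM",
    "MOVEMENT": "MOVEMENT", "MOVEMENT TIME": "MOVEMENT",
    "UNKNOWN": "UNKNOWN", "SLEEP STAGE ?": "UNKNOWN", "?": "UNKNOWN",
}


class EdfParseError(ValueError):
    """The EDF file could not be parsed."""


class ChannelNotFoundError(KeyError):
    """Requested channel is absent from the recording."""


class NoSleepError(ValueError):
    """The record contains no scored sleep epoch."""


class AlignmentError(ValueError):
    """Signal length and label count disagree by more than one epoch."""


@dataclass
class SubjectRecord:
    """One subject's continuous signal with per-epoch stage labels.

    ``labels`` holds AASM class indices with -1 at excluded epochs;
    ``mask`` is True for scoreable epochs.  This is the unit of
    subject-wise cross-validation.
    """

    subject_id: str
    signal: np.ndarray
    sample_rate: float
    channel_name: str = "EEG Fpz-Cz"
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    events: list = field(default_factory=list)   # per-epoch annotation lists

    @property
    def n_epochs(self) -> int:
        return int(len(self.signal) // (EPOCH_SECONDS * self.sample_rate))


@dataclass
class EpochDataset:
    """Epoched, labelled data: epochs (N, 1, 3000), labels in {0..4}."""

    epochs: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.epochs.ndim != 3 or self.epochs.shape[1] != 1:
            raise ValueError(f"epochs must be (N, 1, L), got {self.epochs.shape}")
        if not (len(self.epochs) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("epochs, labels and subject_ids must be equally long")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices) -> "EpochDataset":
        indices = np.asarray(indices)
        return EpochDataset(self.epochs[indices], self.labels[indices],
                            self.subject_ids[indices])

    def class_counts(self, n_classes: int = 5) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_classes)

    @classmethod
    def concatenate(cls, datasets) -> "EpochDataset":
        datasets = list(datasets)
        return cls(np.concatenate([d.epochs for d in datasets]),
                   np.concatenate([d.labels for d in datasets]),
                   np.concatenate([d.subject_ids for d in datasets]))

    def save(self, path) -> None:
        """Binary container (.npz) plus JSON manifest alongside."""
        path = Path(path)
        np.savez(path, epochs=self.epochs, labels=self.labels,
                 subject_ids=self.subject_ids.astype(str))
        manifest = {
            "n_epochs": int(len(self)),
            "epoch_samples": int(self.epochs.shape[2]),
            "label_map": {"W": 0, "N1": 1, "N2": 2, "N3": 3, "REM": 4},
            "subjects": sorted({str(s) for s in self.subject_ids}),
            "class_counts": self.class_counts().tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "EpochDataset":
        with np.load(Path(path), allow_pickle=False) as data:
            return cls(data["epochs"], data["labels"], data["subject_ids"])


# ---------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------

def read_psg(path, channel_name: str) -> tuple[np.ndarray, float]:
    """Read one channel from an EDF/EDF+ file; returns (samples_uV, rate)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise EdfParseError(f"cannot parse EDF file {path}: {exc}") from exc
    if channel_name not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel_name!r} not found; available: {raw.ch_names}")
    try:
        data = raw.get_data(picks=[channel_name], units="uV")[0]
    except ValueError:
        # channel without a unit (e.g. misc): take raw values
        data = raw.get_data(picks=[channel_name])[0]
    return np.asarray(data, dtype=np.float64), float(raw.info["sfreq"])


def _normalise_code(text: str) -> str:
    key = str(text).strip().upper()
    if key not in _ANNOTATION_ALIASES:
        raise ValueError(f"unrecognised stage code {text!r}")
    return _ANNOTATION_ALIASES[key]


def read_hypnogram(path) -> list[str]:
    """Per-epoch R&K codes from an EDF+ annotation channel or a text file."""
    path = Path(path)
    if path.suffix.lower() in (".edf", ".rec"):
        import mne
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
        ann = raw.annotations
        if len(ann) == 0:
            raise ValueError(f"no annotations found in {path}")
        entries = sorted(zip(ann.onset, ann.duration, ann.description))
        n_epochs = int(round((entries[-1][0] + max(entries[-1][1],
                                                   EPOCH_SECONDS)) / EPOCH_SECONDS))
        codes = ["UNKNOWN"] * n_epochs
        for onset, duration, desc in entries:
            code = _normalise_code(desc)
            start = int(round(onset / EPOCH_SECONDS))
            n = max(1, int(round((duration or EPOCH_SECONDS) / EPOCH_SECONDS)))
            for i in range(start, min(start + n, n_epochs)):
                codes[i] = code
        return codes
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    return [_normalise_code(ln) for ln in lines if ln]


# ---------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------

def map_stages(raw_labels) -> tuple[np.ndarray, np.ndarray]:
    """R&K codes -> (AASM labels, scoreable mask).

    W->0, S1->1, S2->2, S3->3, S4->3, REM->4; MOVEMENT and UNKNOWN are
    masked out (label -1, mask False).  Unrecognised codes raise.
    """
    labels = np.full(len(raw_labels), -1, dtype=np.int64)
    mask = np.zeros(len(raw_labels), dtype=bool)
    for i, code in enumerate(raw_labels):
        code = _normalise_code(code)
        if code in EXCLUDED_CODES:
            continue
        labels[i] = RK_TO_AASM[code]
        mask[i] = True
    return labels, mask


def trim_wake(labels, mask=None, margin_epochs: int = 60) -> tuple[int, int]:
    """Retained inclusive epoch range keeping <= ``margin_epochs`` of wake
    (60 epochs = 30 min) before and after the sleep period.

    The sleep period spans the first to the last scoreable non-wake epoch.
    Only wake epochs outside the margins are removed.
    """
    labels = np.asarray(labels)
    if mask is None:
        mask = labels >= 0
    sleep = np.flatnonzero((labels > 0) & mask)
    if sleep.size == 0:
        raise NoSleepError("record contains only wake epochs")
    start = max(0, int(sleep[0]) - margin_epochs)
    stop = min(len(labels) - 1, int(sleep[-1]) + margin_epochs)
    return start, stop


def resample_signal(signal, from_rate: float, to_rate: float) -> np.ndarray:
    """Polyphase (anti-aliased) rational resampling, e.g. 125 -> 100 Hz."""
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("sampling rates must be positive")
    signal = np.asarray(signal, dtype=np.float64)
    if from_rate == to_rate:
        return signal.copy()
    frac = Fraction(to_rate / from_rate).limit_denominator(1000)
    return resample_poly(signal, frac.numerator, frac.denominator)


def epoch_signal(record: SubjectRecord) -> EpochDataset:
    """Cut a 100 Hz record into labelled non-overlapping 3000-sample epochs.

    Masked (excluded) epochs are dropped; a trailing partial window is
    discarded with a logged warning.  Signal/label counts may disagree by
    at most one epoch, otherwise an :class:`AlignmentError` is raised.
    """
    if record.sample_rate != TARGET_RATE:
        raise ValueError(
            f"record must be at {TARGET_RATE:g} Hz (resample first), "
            f"got {record.sample_rate:g}")
    n_sig = len(record.signal) // EPOCH_SAMPLES
    n_lab = len(record.labels)
    if abs(n_sig - n_lab) > 1:
        raise AlignmentError(
            f"signal holds {n_sig} epochs but {n_lab} labels were provided")
    n = min(n_sig, n_lab)
    leftover = len(record.signal) - n * EPOCH_SAMPLES
    if leftover:
        logger.warning("dropping %d trailing samples of %s (partial epoch)",
                       leftover, record.subject_id)
    mask = record.mask[:n] if len(record.mask) else np.ones(n, dtype=bool)
    keep = np.flatnonzero(mask)
    epochs = record.signal[:n * EPOCH_SAMPLES].reshape(n, 1, EPOCH_SAMPLES)
    return EpochDataset(epochs[keep].astype(np.float32),
                        record.labels[:n][keep],
                        np.full(keep.size, record.subject_id, dtype=object))


def load_subject(psg_path, hypnogram_path, channel_name: str = "EEG Fpz-Cz",
                 subject_id: str | None = None,
                 trim_margin: int = 60) -> SubjectRecord:
    """Read + preprocess one subject: map stages, trim wake, resample."""
    signal, rate = read_psg(psg_path, channel_name)
    if rate != TARGET_RATE:
        signal = resample_signal(signal, rate, TARGET_RATE)
        rate = TARGET_RATE
    codes = read_hypnogram(hypnogram_path)
    labels, mask = map_stages(codes)
    start, stop = trim_wake(labels, mask, trim_margin)
    labels = labels[start:stop + 1]
    mask = mask[start:stop + 1]
    signal = signal[start * EPOCH_SAMPLES:(stop + 1) * EPOCH_SAMPLES]
    return SubjectRecord(
        subject_id=subject_id or Path(psg_path).stem,
        signal=signal, sample_rate=rate, channel_name=channel_name,
        labels=labels, mask=mask)
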
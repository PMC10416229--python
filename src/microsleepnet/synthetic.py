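"""Synthetic stage-specific EEG: feature waves over a 1/f background.

Each generated 30-s epoch carries the hallmark graphoelements scorers use:

* W   - alpha rhythm (8-13 Hz) covering more than half of the epoch
* N1  - theta activity (4-7 Hz) plus a few vertex sharp transients
* N2  - sleep spindles (11-16 Hz, 0.5-1.5 s) and K-complexes (~0.7 s
        biphasic deflections)
* N3  - high-amplitude slow waves (0.5-2 Hz) covering at least 20%
* REM - low-amplitude mixed frequency with asymmetric sawtooth runs

All injected intervals are returned as annotations, which serve as ground
truth for CAM localisation scoring.  Whole nights are produced by a
first-order Markov chain over stages, and fixtures can be written to
EDF+ with stage annotations.  No physiological realism beyond these
scoring hallmarks is claimed; the signals exist to exercise the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data_io import EPOCH_SAMPLES, EpochDataset, SubjectRecord
from .edf import write_edf

STAGE_COUNT = 5

#: AASM label -> EDF+ annotation text (hypnogram dialect)
AASM_TO_ANNOTATION = {0: "Sleep stage W", 1: "Sleep stage 1",
                      2: "Sleep stage 2", 3: "Sleep stage 3",
                      4: "Sleep stage R", -1: "Sleep stage ?"}
#: AASM label -> R&K sidecar code
AASM_TO_RK = {0: "W", 1: "S1", 2: "S2", 3: "S3", 4: "REM", -1: "UNKNOWN"}


@dataclass
class EventAnnotation:
    """An injected feature-wave interval, half-open samples [start, end)."""

    kind: str
    start_sample: int
    end_sample: int

    _KINDS = ("alpha_run", "vertex_sharp", "spindle", "k_complex",
              "slow_wave_run", "sawtooth_run")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0 <= self.start_sample < self.end_sample <= EPOCH_SAMPLES:
            raise ValueError(
                f"event ({self.start_sample}, {self.end_sample}) outside epoch")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_sample, self.end_sample)


@dataclass
class SyntheticConfig:
    """Generator parameters (amplitudes in uV, durations in seconds)."""

    sample_rate: float = 100.0
    noise_exponent: float = 1.0          # 1/f^exponent background slope
    background_rms: dict = field(default_factory=lambda: {
        0: 8.0, 1: 10.0, 2: 12.0, 3: 14.0, 4: 8.0})
    alpha_band: tuple[float, float] = (8.0, 13.0)
    alpha_amp: float = 25.0
    alpha_coverage: tuple[float, float] = (0.55, 0.70)   # W: > 0.5 required
    theta_band: tuple[float, float] = (4.0, 7.0)
    theta_amp: float = 20.0
    theta_coverage: tuple[float, float] = (0.35, 0.50)
    vertex_per_epoch: tuple[int, int] = (1, 3)
    vertex_amp: float = 60.0
    spindle_band: tuple[float, float] = (11.0, 16.0)
    spindle_amp: float = 25.0
    spindle_duration: tuple[float, float] = (0.5, 1.5)
    spindles_per_epoch: tuple[int, int] = (2, 5)
    kcomplex_amp: float = 100.0
    kcomplex_duration: float = 0.7
    kcomplexes_per_epoch: tuple[int, int] = (1, 3)
    slow_band: tuple[float, float] = (0.5, 2.0)
    slow_amp: float = 80.0
    slow_coverage: tuple[float, float] = (0.25, 0.40)    # N3: >= 0.2 required
    sawtooth_band: tuple[float, float] = (2.0, 4.5)
    sawtooth_amp: float = 35.0
    sawtooth_runs: tuple[int, int] = (2, 4)
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        for name in ("alpha_coverage", "theta_coverage", "slow_coverage"):
            lo, hi = getattr(self, name)
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.alpha_coverage[0] <= 0.5:
            raise ValueError("alpha_coverage must exceed 0.5 (wake criterion)")
        if self.slow_coverage[0] < 0.2:
            raise ValueError("slow_coverage must be >= 0.2 (N3 criterion)")
        return self


# ---------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------

def pink_noise(n: int, exponent: float, rms: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum and given RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    spectrum = (rng.standard_normal(freqs.size)
                + 1j * rng.standard_normal(freqs.size))
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spectrum * scale, n=n)
    std = x.std()
    return x * (rms / std) if std > 0 else x


def _tapered_oscillation(n: int, freq_hz: float, amp: float, rate: float,
                         rng: np.random.Generator, waveform: str = "sine",
                         width: float = 0.85) -> np.ndarray:
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    if waveform == "sawtooth":
        w = sps.sawtooth(2 * np.pi * freq_hz * t + phase, width=width)
    else:
        w = np.sin(2 * np.pi * freq_hz * t + phase)
    return amp * w * np.hanning(n)


def _vertex_sharp(n: int, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Sharp biphasic transient (derivative-of-Gaussian shape)."""
    t = np.linspace(-1.0, 1.0, n)
    w = -t * np.exp(-(t ** 2) / 0.08)
    return amp * w / np.abs(w).max() * rng.uniform(0.8, 1.2)


def _k_complex(n: int, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Large sharp negative wave followed by a slower positive component."""
    t = np.linspace(0.0, 1.0, n)
    neg = -np.exp(-((t - 0.3) ** 2) / (2 * 0.05 ** 2))
    pos = 0.6 * np.exp(-((t - 0.6) ** 2) / (2 * 0.12 ** 2))
    w = (neg + pos) * np.hanning(n)
    return amp * w / np.abs(w).max() * rng.uniform(0.8, 1.2)


def _place_intervals(rng: np.random.Generator, n_total: int,
                     dur_samples, n_events: int | None = None,
                     coverage: float | None = None,
                     max_tries: int = 500) -> list[tuple[int, int]]:
    """Draw non-overlapping [start, end) intervals.

    Either a fixed number of events or a minimum union coverage fraction
    is requested; placement is rejection sampling against overlap.
    """
    placed: list[tuple[int, int]] = []
    covered = 0
    tries = 0
    lo, hi = dur_samples

    def want_more() -> bool:
        if n_events is not None:
            return len(placed) < n_events
        return covered < coverage * n_total

    while want_more() and tries < max_tries:
        tries += 1
        dur = int(rng.integers(lo, hi + 1))
        if dur >= n_total:
            dur = n_total - 1
        start = int(rng.integers(0, n_total - dur))
        end = start + dur
        if any(s < end and start < e for s, e in placed):
            continue
        placed.append((start, end))
        covered += dur
    return sorted(placed)


# ---------------------------------------------------------------------
# epoch / subject generation
# ---------------------------------------------------------------------

def gen_epoch(stage: int, cfg: SyntheticConfig | None = None,
              rng: np.random.Generator | None = None
              ) -> tuple[np.ndarray, list[EventAnnotation]]:
    """One labelled 30-s epoch (3000 samples, uV) plus event annotations."""
    cfg = (cfg or SyntheticConfig()).validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if stage not in range(STAGE_COUNT):
        raise ValueError(f"stage must be in 0..{STAGE_COUNT - 1}, got {stage}")
    n = EPOCH_SAMPLES
    rate = cfg.sample_rate
    x = pink_noise(n, cfg.noise_exponent, cfg.background_rms[stage], rng)
    events: list[EventAnnotation] = []

    def add_runs(kind, band, amp, dur_s, *, n_events=None, coverage=None,
                 waveform="sine", annotate=True):
        dur_samples = (int(dur_s[0] * rate), int(dur_s[1] * rate))
        for start, end in _place_intervals(rng, n, dur_samples,
                                           n_events=n_events,
                                           coverage=coverage):
            freq = rng.uniform(*band)
            x[start:end] += _tapered_oscillation(end - start, freq, amp, rate,
                                                 rng, waveform)
            if annotate:
                events.append(EventAnnotation(kind, start, end))

    if stage == 0:      # W: alpha rhythm over more than half of the epoch
        coverage = rng.uniform(*cfg.alpha_coverage)
        add_runs("alpha_run", cfg.alpha_band, cfg.alpha_amp, (1.0, 3.0),
                 coverage=coverage)
    elif stage == 1:    # N1: theta background + vertex sharp transients
        add_runs("alpha_run", cfg.theta_band, cfg.theta_amp, (1.0, 3.0),
                 coverage=rng.uniform(*cfg.theta_coverage), annotate=False)
        n_vertex = int(rng.integers(cfg.vertex_per_epoch[0],
                                    cfg.vertex_per_epoch[1] + 1))
        dur = int(0.2 * rate)
        for start, end in _place_intervals(rng, n, (dur, dur),
                                           n_events=n_vertex):
            x[start:end] += _vertex_sharp(end - start, cfg.vertex_amp, rng)
            events.append(EventAnnotation("vertex_sharp", start, end))
    elif stage == 2:    # N2: spindles + K-complexes
        n_spindles = int(rng.integers(cfg.spindles_per_epoch[0],
                                      cfg.spindles_per_epoch[1] + 1))
        add_runs("spindle", cfg.spindle_band, cfg.spindle_amp,
                 cfg.spindle_duration, n_events=n_spindles)
        n_kc = int(rng.integers(cfg.kcomplexes_per_epoch[0],
                                cfg.kcomplexes_per_epoch[1] + 1))
        dur = int(cfg.kcomplex_duration * rate)
        for start, end in _place_intervals(rng, n, (dur, dur), n_events=n_kc):
            x[start:end] += _k_complex(end - start, cfg.kcomplex_amp, rng)
            events.append(EventAnnotation("k_complex", start, end))
    elif stage == 3:    # N3: slow-wave activity over >= 20% of the epoch
        coverage = rng.uniform(*cfg.slow_coverage)
        add_runs("slow_wave_run", cfg.slow_band, cfg.slow_amp, (1.5, 4.0),
                 coverage=coverage)
    else:               # REM: low-amplitude mixed frequency + sawtooth runs
        n_runs = int(rng.integers(cfg.sawtooth_runs[0],
                                  cfg.sawtooth_runs[1] + 1))
        add_runs("sawtooth_run", cfg.sawtooth_band, cfg.sawtooth_amp,
                 (1.0, 3.0), n_events=n_runs, waveform="sawtooth")
    return x, events


def default_transition_matrix() -> np.ndarray:
    """Plausible 30-s stage-transition probabilities (rows W,N1,N2,N3,REM)."""
    return np.array([
        [0.90, 0.08, 0.02, 0.00, 0.00],
        [0.05, 0.50, 0.40, 0.00, 0.05],
        [0.01, 0.05, 0.75, 0.12, 0.07],
        [0.00, 0.00, 0.15, 0.83, 0.02],
        [0.02, 0.10, 0.10, 0.00, 0.78],
    ])


def sample_stage_sequence(n_epochs: int, transition_matrix: np.ndarray,
                          rng: np.random.Generator,
                          start_stage: int = 0) -> np.ndarray:
    """First-order Markov stage sequence starting in ``start_stage`` (W)."""
    tm = np.asarray(transition_matrix, dtype=np.float64)
    if tm.shape != (STAGE_COUNT, STAGE_COUNT):
        raise ValueError(f"transition matrix must be 5x5, got {tm.shape}")
    if np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    stages = np.empty(n_epochs, dtype=np.int64)
    state = start_stage
    for i in range(n_epochs):
        stages[i] = state
        state = int(rng.choice(STAGE_COUNT, p=tm[state]))
    return stages


def gen_subject(n_epochs: int, transition_matrix: np.ndarray | None = None,
                cfg: SyntheticConfig | None = None,
                rng: np.random.Generator | None = None,
                subject_id: str = "synthetic") -> SubjectRecord:
    """A whole-night record: Markov stage sequence starting in W.

    The per-epoch event annotations are stored on ``record.events`` (one
    list per epoch).
    """
    cfg = (cfg or SyntheticConfig()).validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    tm = (default_transition_matrix() if transition_matrix is None
          else np.asarray(transition_matrix, dtype=np.float64))
    stages = sample_stage_sequence(n_epochs, tm, rng)
    signal_parts = []
    events: list[list[EventAnnotation]] = []
    for stage in stages:
        epoch, ev = gen_epoch(int(stage), cfg, rng)
        signal_parts.append(epoch)
        events.append(ev)
    signal = (np.concatenate(signal_parts) if signal_parts
              else np.zeros(0, dtype=np.float64))
    return SubjectRecord(subject_id=subject_id, signal=signal,
                         sample_rate=cfg.sample_rate, labels=stages,
                         mask=np.ones(n_epochs, dtype=bool), events=events)


def gen_dataset(n_epochs: int, cfg: SyntheticConfig | None = None,
                rng: np.random.Generator | None = None,
                subject_id: str = "synthetic"
                ) -> tuple[EpochDataset, list[list[EventAnnotation]]]:
    """A balanced labelled dataset (stages cycled) with event annotations."""
    cfg = (cfg or SyntheticConfig()).validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    epochs = np.empty((n_epochs, 1, EPOCH_SAMPLES), dtype=np.float32)
    labels = np.empty(n_epochs, dtype=np.int64)
    events: list[list[EventAnnotation]] = []
    for i in range(n_epochs):
        stage = i % STAGE_COUNT
        x, ev = gen_epoch(stage, cfg, rng)
        epochs[i, 0] = x
        labels[i] = stage
        events.append(ev)
    ds = EpochDataset(epochs, labels,
                      np.full(n_epochs, subject_id, dtype=object))
    return ds, events


# ---------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------

def write_fixture_edf(record: SubjectRecord, path,
                      with_annotations: bool = True) -> None:
    """Write a record as EDF(+) with one channel and stage annotations."""
    annotations = None
    if with_annotations and len(record.labels):
        annotations = [
            (i * 30.0, 30.0, AASM_TO_ANNOTATION[int(lab)])
            for i, lab in enumerate(record.labels)
        ]
    write_edf(path, [(record.channel_name, record.signal)],
              record.sample_rate, annotations=annotations)


def write_hypnogram_txt(record: SubjectRecord, path) -> None:
    """Sidecar per-epoch R&K codes, one per line."""
    lines = [AASM_TO_RK[int(lab)] for lab in record.labels]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
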
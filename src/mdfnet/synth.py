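"""Seeded synthetic EEG cohort generator.

Emulates the statistical structure the downstream analysis assumes for
resting-state Parkinson's disease (PD) vs. healthy control (HC) EEG:

* 32-channel recordings at 500 Hz, ~5 min long, built from a bank of
  band-limited oscillations (delta 1-4, theta 4-8, alpha 8-13, beta 13-30 Hz)
  riding on a 1/f background, mixed from a small set of shared latent
  sources so that the channels are correlated (and ICA has a plausible
  mixing structure to invert);
* a class contrast concentrated below 10 Hz: the PD class has its delta+theta
  *relative* power increased by a configurable effect size (relative, not
  absolute, so per-channel z-scoring cannot erase it);
* class-conditional demographics (age, sex, Hoehn-Yahr stage) matching the
  cohort table of the target study population;
* optional ocular (blink-like, frontal) and muscular (broadband burst)
  artifacts for exercising ICA rejection.

Everything is driven by a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical specs give bit-identical
cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "ConfigurationError",
    "SubjectMeta",
    "RawRecording",
    "CohortSpec",
    "FREQUENCY_BANDS",
    "CHANNELS_32",
    "FRONTAL_CHANNELS",
    "sample_cohort_metadata",
    "generate_cohort",
    "inject_artifacts",
]


class ConfigurationError(ValueError):
    """Raised when a user-supplied configuration field is invalid."""


# Standard 10-20 labels of a 32-electrode cap.
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT9",
    "FC5", "FC1", "FC2", "FC6", "FT10", "T7", "C3", "Cz",
    "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
)

FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")

#: canonical EEG rhythm bands (Hz)
FREQUENCY_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

# Baseline band amplitudes (arbitrary units, scaled to microvolts later) and
# the class-conditional demographics of the emulated cohort.
_BAND_WEIGHTS = {"delta": 1.0, "theta": 0.9, "alpha": 1.1, "beta": 0.7}
_AGE_DIST = {"HC": (55.8, 9.2), "PD": (63.8, 7.5)}
_MALE_PROP = {"HC": 145 / 289, "PD": 71 / 126}
_HY_DIST = (1.9, 0.8)

# Fractional delta+theta amplitude gain per unit effect size for the PD class.
_LOW_BAND_GAIN_PER_EFFECT = 0.3


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata: identity, class label and demographics."""

    subject_id: str
    label: Literal["HC", "PD"]
    age: float
    sex: Literal["M", "F"]
    hoehn_yahr: int | None = None

    def __post_init__(self):
        if self.label not in ("HC", "PD"):
            raise ConfigurationError(f"label must be 'HC' or 'PD', got {self.label!r}")
        if self.age <= 0:
            raise ConfigurationError(f"age must be positive, got {self.age}")
        if (self.hoehn_yahr is not None) != (self.label == "PD"):
            raise ConfigurationError("hoehn_yahr must be present iff label == 'PD'")


@dataclass
class RawRecording:
    """One subject's multi-channel EEG at its native sampling rate."""

    meta: SubjectMeta
    sampling_rate: float
    signal: np.ndarray  # [n_channels, n_samples], microvolts
    channel_names: tuple[str, ...] = CHANNELS_32
    artifact_events: tuple[tuple[float, str], ...] = ()  # (onset_s, kind)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ConfigurationError("signal must be a 2-D [channels, samples] array")
        if self.signal.shape[0] != len(self.channel_names):
            raise ConfigurationError(
                f"signal has {self.signal.shape[0]} channels but "
                f"{len(self.channel_names)} channel names were given"
            )
        if not np.isfinite(self.signal).all():
            raise ConfigurationError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, **kwargs) -> "RawRecording":
        out = dataclasses.replace(self, **kwargs)
        out.signal = np.array(out.signal, copy=True)
        return out


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic two-class EEG cohort."""

    n_hc: int
    n_pd: int
    duration_s: float = 300.0
    base_rate: float = 500.0
    effect_size: float = 1.0
    artifact_rate: float = 0.0  # events / minute
    noise_profile: dict = field(default_factory=lambda: {"exponent": 1.0, "scale": 1.0})
    rng_seed: int = 0
    n_channels: int = 32
    n_sources: int = 8

    def validate(self) -> None:
        if self.n_hc < 0:
            raise ConfigurationError(f"n_hc must be >= 0, got {self.n_hc}")
        if self.n_pd < 0:
            raise ConfigurationError(f"n_pd must be >= 0, got {self.n_pd}")
        if self.duration_s <= 0:
            raise ConfigurationError(f"duration_s must be > 0, got {self.duration_s}")
        if self.effect_size < 0:
            raise ConfigurationError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.artifact_rate < 0:
            raise ConfigurationError(f"artifact_rate must be >= 0, got {self.artifact_rate}")
        f_max = max(hi for _, hi in FREQUENCY_BANDS.values())
        if self.base_rate <= 2 * f_max:
            raise ConfigurationError(
                f"base_rate must exceed twice the highest synthesized oscillation "
                f"({2 * f_max:g} Hz), got {self.base_rate}"
            )
        if self.n_channels != len(CHANNELS_32):
            raise ConfigurationError("n_channels other than 32 is not supported")


# --------------------------------------------------------------------------- #
# demographics
# --------------------------------------------------------------------------- #
def _sample_meta(label: str, idx: int, rng: np.random.Generator) -> SubjectMeta:
    mu, sd = _AGE_DIST[label]
    age = float(np.clip(rng.normal(mu, sd), 18.0, 95.0))
    sex = "M" if rng.random() < _MALE_PROP[label] else "F"
    hy = None
    if label == "PD":
        hy = int(np.clip(np.round(rng.normal(*_HY_DIST)), 1, 5))
    return SubjectMeta(subject_id=f"{label.lower()}{idx:03d}", label=label, age=age,
                       sex=sex, hoehn_yahr=hy)


def sample_cohort_metadata(n_hc: int, n_pd: int, rng_seed: int = 0) -> list[SubjectMeta]:
    """Draw class-conditional demographics only (no signals)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0xD3A0]))
    metas = [_sample_meta("HC", i, rng) for i in range(n_hc)]
    metas += [_sample_meta("PD", i, rng) for i in range(n_pd)]
    return metas


# --------------------------------------------------------------------------- #
# signal synthesis
# --------------------------------------------------------------------------- #
def _band_limited_noise(band: tuple[float, float], n: int, rate: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to `band`."""
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(n: int, rate: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent (power) background noise, unit variance."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _synthesize_recording(meta: SubjectMeta, spec: CohortSpec,
                          rng: np.random.Generator,
                          base_mixing: np.ndarray) -> RawRecording:
    n = int(round(spec.duration_s * spec.base_rate))
    n_src = spec.n_sources
    exponent = float(spec.noise_profile.get("exponent", 1.0))
    noise_scale = float(spec.noise_profile.get("scale", 1.0))

    # per-subject band amplitudes: baseline x lognormal jitter (x PD low gain)
    gains = {}
    for band, w in _BAND_WEIGHTS.items():
        g = w * float(np.exp(rng.normal(0.0, 0.15)))
        if meta.label == "PD" and band in ("delta", "theta"):
            g *= 1.0 + _LOW_BAND_GAIN_PER_EFFECT * spec.effect_size
        gains[band] = g

    sources = np.empty((n_src, n))
    for s in range(n_src):
        acc = noise_scale * _pink_noise(n, spec.base_rate, exponent, rng)
        for band, (lo, hi) in FREQUENCY_BANDS.items():
            # small per-source jitter keeps sources non-identical in spectrum
            amp = gains[band] * float(np.exp(rng.normal(0.0, 0.1)))
            acc += amp * _band_limited_noise((lo, hi), n, spec.base_rate, rng)
        sources[s] = acc

    # scalp topography: cohort-shared source mixing with a small per-subject
    # perturbation (same cap layout and broadly similar head geometry across
    # subjects, individual anatomical variation on top)
    mixing = base_mixing + 0.2 * rng.normal(0.0, 1.0, size=base_mixing.shape) / np.sqrt(n_src)
    sensor_noise = 0.1 * rng.standard_normal((spec.n_channels, n))
    x = 10.0 * (mixing @ sources + sensor_noise)  # microvolt scale

    return RawRecording(meta=meta, sampling_rate=spec.base_rate, signal=x)


def generate_cohort(spec: CohortSpec) -> list[RawRecording]:
    """Generate ``spec.n_hc + spec.n_pd`` seeded synthetic recordings."""
    spec.validate()
    metas = sample_cohort_metadata(spec.n_hc, spec.n_pd, spec.rng_seed)
    n_total = len(metas)
    streams = np.random.SeedSequence([int(spec.rng_seed), 0x516]).spawn(max(n_total, 1))
    cohort_rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), 0x70B0]))
    base_mixing = cohort_rng.normal(
        0.0, 1.0, size=(spec.n_channels, spec.n_sources)) / np.sqrt(spec.n_sources)
    recordings = []
    for meta, ss in zip(metas, streams):
        rng = np.random.default_rng(ss)
        rec = _synthesize_recording(meta, spec, rng, base_mixing)
        if spec.artifact_rate > 0:
            rec = inject_artifacts(rec, spec.artifact_rate,
                                   rng_seed=int(rng.integers(0, 2**31 - 1)))
        recordings.append(rec)
    return recordings


# --------------------------------------------------------------------------- #
# artifacts
# --------------------------------------------------------------------------- #
def _blink_waveform(dur_samples: int, rate: float) -> np.ndarray:
    """Smooth biphasic low-frequency transient (ocular)."""
    t = np.arange(dur_samples) / rate
    total = dur_samples / rate
    envelope = np.hanning(dur_samples)
    return envelope * np.sin(2 * np.pi * t / total)


def inject_artifacts(rec: RawRecording, rate: float, rng_seed: int) -> RawRecording:
    """Add blink-like frontal transients and broadband muscle bursts.

    Returns a new recording (input unmodified); the number and placement of
    events is fully determined by ``rng_seed``.
    """
    if rate < 0:
        raise ConfigurationError(f"artifact rate must be >= 0, got {rate}")
    if rate == 0:
        return rec.copy_with()
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0xA27]))
    minutes = rec.duration_s / 60.0
    n_events = int(rng.poisson(rate * minutes))
    x = np.array(rec.signal, copy=True)
    fs = rec.sampling_rate
    frontal_idx = [rec.channel_names.index(c) for c in FRONTAL_CHANNELS
                   if c in rec.channel_names]
    frontal_load = np.array([1.0, 1.0, 0.6, 0.5, 0.5, 0.5, 0.4])[: len(frontal_idx)]
    events: list[tuple[float, str]] = []
    for _ in range(n_events):
        kind = "blink" if rng.random() < 0.6 else "muscle"
        if kind == "blink":
            dur = int(0.3 * fs)
        else:
            dur = int(0.4 * fs)
        if dur >= rec.n_samples:
            continue
        start = int(rng.integers(0, rec.n_samples - dur))
        if kind == "blink":
            wave = _blink_waveform(dur, fs)
            amp = rng.uniform(120.0, 220.0)
            for ch, load in zip(frontal_idx, frontal_load):
                x[ch, start:start + dur] += amp * load * wave
        else:
            hi = min(100.0, 0.45 * fs)
            sos = sps.butter(4, [20.0, hi], btype="bandpass", fs=fs, output="sos")
            burst = sps.sosfiltfilt(sos, rng.standard_normal(dur))
            sd = burst.std()
            if sd > 0:
                burst /= sd
            burst *= np.hanning(dur)
            amp = rng.uniform(40.0, 80.0)
            ch0 = int(rng.integers(0, rec.n_channels - 5))
            for k in range(6):
                x[ch0 + k, start:start + dur] += amp * rng.uniform(0.5, 1.0) * burst
        events.append((start / fs, kind))
    return rec.copy_with(signal=x, artifact_events=tuple(sorted(events)))
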
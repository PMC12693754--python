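"""Preprocessing pipeline for raw EEG recordings.

Fixed stage order: band-pass filter -> ICA artifact rejection -> resampling
-> per-channel z-score normalization -> non-overlapping segmentation.
``run_pipeline`` executes exactly this order; the individual stages are also
exposed for testing and for the sampling-setting sweeps.

Conventions (documented because the choices are not forced):

* the band-pass is a zero-phase 5th-order Butterworth applied forward-backward
  (order chosen so a 50 Hz mains tone is suppressed by more than 20 dB);
* ICA is FastICA with a seeded initialisation; a component is rejected when
  its back-projected variance exceeds the 90th percentile of the per-component
  variances, or its source kurtosis exceeds the 90th percentile of the
  per-component kurtoses (union of the two flags);
* resampling is polyphase with anti-alias filtering at the new Nyquist;
* z-scoring uses the population standard deviation (ddof = 0), computed per
  channel over the whole recording, before segmentation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.decomposition import FastICA

from .synth import ConfigurationError, RawRecording

__all__ = [
    "PreprocessConfig",
    "Segment",
    "bandpass_filter",
    "remove_artifacts_ica",
    "resample",
    "zscore_normalize",
    "segment",
    "run_pipeline",
]

logger = logging.getLogger("mdfnet.preprocess")


@dataclass(frozen=True)
class PreprocessConfig:
    band_low: float = 1.0
    band_high: float = 40.0
    ica_components: int = 15
    reject_percentile: float = 90.0
    target_rate: float = 20.0
    window_s: float = 1.0

    def validate(self, native_rate: float) -> None:
        nyquist = native_rate / 2.0
        if not (0 < self.band_low < self.band_high < nyquist):
            raise ConfigurationError(
                f"band [{self.band_low}, {self.band_high}] Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist:g} Hz)"
            )
        if self.target_rate > native_rate:
            raise ConfigurationError(
                f"target_rate {self.target_rate} Hz exceeds native rate {native_rate} Hz"
            )
        n = self.window_s * self.target_rate
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ConfigurationError(
                f"window_s x target_rate must be an integer >= 2, got {n}"
            )
        if self.ica_components < 1:
            raise ConfigurationError("ica_components must be >= 1")
        if not (0 < self.reject_percentile <= 100):
            raise ConfigurationError("reject_percentile must be in (0, 100]")


@dataclass
class Segment:
    """A fixed-length, resampled, normalized window of one recording."""

    subject_id: str
    label: str
    start_time: float
    data: np.ndarray  # [n_channels, N]
    sampling_rate: float

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def bandpass_filter(rec: RawRecording, low: float, high: float) -> RawRecording:
    """Zero-phase Butterworth band-pass, per channel."""
    nyquist = rec.sampling_rate / 2.0
    if not (0 < low < high < nyquist):
        raise ConfigurationError(
            f"band [{low}, {high}] Hz outside (0, Nyquist={nyquist:g}) Hz"
        )
    sos = sps.butter(5, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=-1)
    return rec.copy_with(signal=filtered)


def remove_artifacts_ica(
    rec: RawRecording, cfg: PreprocessConfig, rng_seed: int
) -> tuple[RawRecording, int]:
    """Reject high-variance / high-kurtosis independent components.

    The cleaned signal is the input minus the back-projection of the flagged
    components only, so rejecting nothing is exactly the identity.
    """
    cfg.validate(rec.sampling_rate)
    x = rec.signal  # [C, N]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(
                n_components=cfg.ica_components,
                random_state=int(rng_seed) % (2**31 - 1),
                whiten="unit-variance",
                max_iter=500,
            )
            sources = ica.fit_transform(x.T)  # [N, k]
    except Exception as exc:  # pragma: no cover - convergence failure path
        logger.warning("ICA failed (%s); passing signal through unmodified", exc)
        return rec.copy_with(), 0
    mixing = ica.mixing_  # [C, k]

    proj_var = (mixing**2).sum(axis=0) * sources.var(axis=0)
    kurt = stats.kurtosis(sources, axis=0)
    var_thr = np.percentile(proj_var, cfg.reject_percentile)
    kurt_thr = np.percentile(kurt, cfg.reject_percentile)
    flagged = np.flatnonzero((proj_var > var_thr) | (kurt > kurt_thr))

    removed = mixing[:, flagged] @ sources[:, flagged].T  # [C, N]
    cleaned = x - removed
    logger.debug(
        "ICA removed %d/%d components for %s",
        flagged.size, cfg.ica_components, rec.meta.subject_id,
    )
    return rec.copy_with(signal=cleaned), int(flagged.size)


def resample(rec: RawRecording, target_rate: float) -> RawRecording:
    """Anti-aliased polyphase rate conversion (down-sampling only)."""
    if target_rate > rec.sampling_rate:
        raise ConfigurationError(
            f"upsampling ({rec.sampling_rate} -> {target_rate} Hz) is not supported"
        )
    if target_rate == rec.sampling_rate:
        return rec.copy_with()
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(10_000)
    out = sps.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=-1)
    return rec.copy_with(signal=out, sampling_rate=target_rate)


def zscore_normalize(rec: RawRecording) -> RawRecording:
    """Per-channel z-score over the whole recording (population sigma)."""
    mu = rec.signal.mean(axis=1, keepdims=True)
    sd = rec.signal.std(axis=1, ddof=0, keepdims=True)
    zero_var = sd[:, 0] == 0
    if zero_var.any():
        logger.warning(
            "%d zero-variance channel(s) set to zero in %s",
            int(zero_var.sum()), rec.meta.subject_id,
        )
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (rec.signal - mu) / sd_safe
    z[zero_var, :] = 0.0
    return rec.copy_with(signal=z)


def segment(rec: RawRecording, window_s: float) -> list[Segment]:
    """Consecutive non-overlapping windows; trailing remainder discarded."""
    n = int(round(window_s * rec.sampling_rate))
    n_windows = rec.n_samples // n
    if n_windows == 0:
        logger.warning(
            "recording %s (%.2f s) shorter than window (%.2f s); no segments",
            rec.meta.subject_id, rec.duration_s, window_s,
        )
        return []
    out = []
    for w in range(n_windows):
        out.append(
            Segment(
                subject_id=rec.meta.subject_id,
                label=rec.meta.label,
                start_time=w * n / rec.sampling_rate,
                data=np.array(rec.signal[:, w * n:(w + 1) * n], copy=True),
                sampling_rate=rec.sampling_rate,
            )
        )
    return out


def run_pipeline(
    rec: RawRecording, cfg: PreprocessConfig, rng_seed: int = 0
) -> tuple[list[Segment], dict]:
    """Full pipeline in the fixed order; returns segments and a stage report."""
    cfg.validate(rec.sampling_rate)
    stages: list[str] = []
    rec = bandpass_filter(rec, cfg.band_low, cfg.band_high)
    stages.append("bandpass")
    rec, removed = remove_artifacts_ica(rec, cfg, rng_seed)
    stages.append("ica")
    rec = resample(rec, cfg.target_rate)
    stages.append("resample")
    rec = zscore_normalize(rec)
    stages.append("zscore")
    segs = segment(rec, cfg.window_s)
    stages.append("segment")
    assert stages == ["bandpass", "ica", "resample", "zscore", "segment"]
    report = {
        "subject_id": rec.meta.subject_id,
        "removed_components": removed,
        "n_segments": len(segs),
        "stages": stages,
    }
    return segs, report
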
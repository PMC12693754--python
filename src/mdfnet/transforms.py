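"""Per-segment domain representations for the three network branches.

A segment ``x`` of shape [channels, N] is expanded into

* its raw time series (temporal branch),
* the one-sided FFT amplitude spectrum |X(k)|, k = 0..floor(N/2)
  (frequency branch) -- raw DFT magnitude, no 1/N factor, no dB scaling,
* the single-level discrete wavelet transform with the db4 basis, returning
  the concatenation [cA || cD] (wavelet branch).  Under symmetric signal
  extension a 20-sample channel yields 13 + 13 = 26 coefficients.

Plus the relative band-power utility used by the sampling-rate analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .preprocess import Segment
from .synth import ConfigurationError

__all__ = [
    "WaveletConfig",
    "DomainFeatures",
    "amplitude_spectrum",
    "dwt_features",
    "dwt_feature_length",
    "build_domain_features",
    "relative_band_power",
]

logger = logging.getLogger("mdfnet.transforms")


@dataclass(frozen=True)
class WaveletConfig:
    family: str = "db4"
    levels: int = 1
    extension: str = "symmetric"

    def validate(self) -> None:
        if self.family not in pywt.wavelist(kind="discrete"):
            raise ConfigurationError(f"unknown wavelet family {self.family!r}")
        if self.levels != 1:
            raise ConfigurationError("only single-level decomposition is supported")
        if self.extension not in pywt.Modes.modes:
            raise ConfigurationError(f"unknown extension mode {self.extension!r}")


@dataclass
class DomainFeatures:
    """The (time, frequency, wavelet) triple feeding the three branches."""

    time: np.ndarray     # [C, N]
    freq: np.ndarray     # [C, floor(N/2)+1], non-negative amplitudes
    wavelet: np.ndarray  # [C, len(cA)+len(cD)]


def amplitude_spectrum(segment_data: np.ndarray) -> np.ndarray:
    """One-sided amplitude spectrum per channel: |X(k)|, k = 0..floor(N/2)."""
    x = np.asarray(segment_data, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ConfigurationError("need at least 2 samples for a spectrum")
    bad = ~np.isfinite(x).all(axis=-1)
    if bad.any():
        raise ValueError(f"non-finite input in channel(s) {np.flatnonzero(bad).tolist()}")
    return np.abs(np.fft.rfft(x, axis=-1))


def dwt_features(segment_data: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> np.ndarray:
    """Single-level DWT per channel, concatenated [cA || cD]."""
    cfg.validate()
    x = np.asarray(segment_data, dtype=np.float64)
    filt_len = pywt.Wavelet(cfg.family).dec_len
    if x.shape[-1] < filt_len:
        raise ConfigurationError(
            f"segment length {x.shape[-1]} shorter than {cfg.family} filter ({filt_len})"
        )
    cA, cD = pywt.dwt(x, cfg.family, mode=cfg.extension, axis=-1)
    return np.concatenate([cA, cD], axis=-1)


def dwt_feature_length(n_samples: int, cfg: WaveletConfig = WaveletConfig()) -> int:
    """Number of concatenated coefficients for an `n_samples` channel."""
    per_band = pywt.dwt_coeff_len(n_samples, pywt.Wavelet(cfg.family).dec_len,
                                  mode=cfg.extension)
    return 2 * per_band


def build_domain_features(seg: Segment, cfg: WaveletConfig = WaveletConfig()) -> DomainFeatures:
    """Bundle the three per-segment domain matrices."""
    data = np.asarray(seg.data, dtype=np.float64)
    return DomainFeatures(
        time=np.array(data, copy=True),
        freq=amplitude_spectrum(data),
        wavelet=dwt_features(data, cfg),
    )


def stack_domain_features(
    segments, cfg: WaveletConfig = WaveletConfig()
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Build batched branch inputs from a list of segments.

    Returns ``(features, labels, subject_ids)`` where features maps
    'time'/'freq'/'wavelet' to [n, C, L] arrays, labels is an int array
    (HC = 0, PD = 1) and subject_ids an object array.
    """
    if not segments:
        raise ConfigurationError("no segments to featurize")
    time = np.stack([np.asarray(s.data, dtype=np.float64) for s in segments])
    features = {
        "time": time,
        "freq": amplitude_spectrum(time),
        "wavelet": dwt_features(time, cfg),
    }
    labels = np.array([0 if s.label == "HC" else 1 for s in segments], dtype=int)
    subject_ids = np.array([s.subject_id for s in segments], dtype=object)
    return features, labels, subject_ids


def relative_band_power(signal: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    """Fraction of total spectral power inside ``band`` (one-sided spectrum)."""
    x = np.asarray(signal, dtype=np.float64).ravel()
    f_lo, f_hi = band
    nyquist = rate / 2.0
    if f_hi > nyquist:
        logger.warning("band upper edge %.3g Hz clipped to Nyquist %.3g Hz", f_hi, nyquist)
        f_hi = nyquist
    spec = np.abs(np.fft.rfft(x))
    power = spec**2
    # one-sided doubling: interior bins carry both +f and -f energy
    power[1:] *= 2.0
    if x.size % 2 == 0 and power.size > 1:
        power[-1] /= 2.0  # Nyquist bin is unique
    total = power.sum()
    if total == 0:
        raise ValueError("zero total power: relative band power undefined")
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    return float(power[in_band].sum() / total)
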
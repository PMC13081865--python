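"""Synthetic inputs for the analysis pipeline.

Three generators cover the three kinds of data the pipeline consumes:

* :func:`generate_alpha_eeg` — multichannel resting-state-like EEG built from
  posterior-weighted narrowband (8–10 Hz by default) oscillatory sources mixed
  over 1/f broadband noise.  It stands in for cleaned, 100 Hz, eyes-closed
  recordings whose low-alpha rhythm dominates posterior channels.
* :func:`generate_langevin_series` — a one-dimensional overdamped Langevin
  state series dz = f(z) dt + sqrt(2 D) dW integrated by Euler–Maruyama, with
  a cubic drift polynomial f(z) = a z^3 + b z^2 + c z + d and constant
  diffusion D, so the landscape-inversion machinery can be validated against
  known ground truth (rigidity kappa = -c/2, noise = D).
* :func:`generate_cohort` — a subjects-by-45 feature table whose ability
  scores are a linear combination of a chosen feature subset plus Gaussian
  noise, for prediction-recovery and permutation-calibration experiments.

Every generator is fully determined by the integer seed in its spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .gsp import FEATURE_NAMES

__all__ = [
    "EEGSimSpec",
    "LangevinSimSpec",
    "CohortSimSpec",
    "GroundTruth",
    "EEGRecording",
    "generate_alpha_eeg",
    "generate_langevin_series",
    "generate_cohort",
    "posterior_topography",
]


@dataclass
class EEGRecording:
    """Channels x samples matrix with its sampling rate in Hz."""

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be a 2-D channels x samples array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class GroundTruth:
    """Generating parameters carried alongside each synthetic dataset."""

    true_kappa: float | None = None
    true_noise: float | None = None
    true_coupling: np.ndarray | None = None
    coupled_indices: np.ndarray | None = None
    intercept: float | None = None
    source_signals: np.ndarray | None = None
    topography: np.ndarray | None = None


def posterior_topography(n_channels: int, center_frac: float = 0.8,
                         width_frac: float = 0.12) -> np.ndarray:
    """Nonnegative per-channel weights peaked toward the posterior end.

    Channels are treated as ordered front-to-back; the default is a Gaussian
    bump centred at 80% of the array with width 12% of the channel count.
    """
    idx = np.arange(n_channels, dtype=float)
    center = center_frac * (n_channels - 1)
    width = max(width_frac * n_channels, 1.0)
    return np.exp(-0.5 * ((idx - center) / width) ** 2)


@dataclass
class EEGSimSpec:
    """Parameters of the alpha-source EEG generator.

    ``snr`` is the ratio of mixed-source power to broadband-noise power,
    averaged over channels; ``np.inf`` gives the noise-free limit.
    Sources are generated directly at the pipeline's working rate (100 Hz);
    the acquisition/resampling chain is not simulated.
    """

    n_channels: int = 32
    sampling_rate: float = 100.0
    duration: float = 195.0
    n_sources: int = 2
    source_band: tuple[float, float] = (8.0, 10.0)
    source_topography: np.ndarray | None = None
    snr: float = 4.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_sources < 1:
            raise ValueError("n_channels and n_sources must be positive")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.duration < 195.0:
            raise ValueError(
                "duration must be at least 195 s to support the standard "
                "15 s discard + 180 s analysis segmentation"
            )
        lo, hi = self.source_band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError("source_band must lie inside (0, Nyquist)")
        if not (self.snr > 0):
            raise ValueError("snr must be positive (np.inf allowed)")
        if self.source_topography is not None:
            topo = np.atleast_2d(np.asarray(self.source_topography, dtype=float))
            if topo.shape[0] == 1 and self.n_sources > 1:
                topo = np.repeat(topo, self.n_sources, axis=0)
            if topo.shape != (self.n_sources, self.n_channels):
                raise ValueError(
                    "source_topography must have shape (n_sources, n_channels)"
                )
            if np.any(topo < 0) or not np.any(topo > 0):
                raise ValueError("topography weights must be nonnegative, not all zero")
            self.source_topography = topo


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      fs: float, exponent: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power spectral density ~ 1/f^exponent."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC component
    noise = np.fft.irfft(spec * shape[None, :], n=n_samples, axis=1)
    return noise


def generate_alpha_eeg(spec: EEGSimSpec) -> tuple[EEGRecording, GroundTruth]:
    """Mix narrowband oscillatory sources into channels over 1/f noise.

    Each source is unit-power bandpass-filtered Gaussian noise (a narrowband
    oscillation with naturally drifting amplitude and phase).  The mixed
    source signal is scaled against the broadband noise so that mean channel
    power ratio equals ``spec.snr``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    sos = sps.butter(4, spec.source_band, btype="bandpass", fs=spec.sampling_rate,
                     output="sos")
    raw = rng.standard_normal((spec.n_sources, n))
    sources = sps.sosfiltfilt(sos, raw, axis=1)
    sources /= sources.std(axis=1, keepdims=True)

    if spec.source_topography is not None:
        topo = spec.source_topography
    else:
        # stagger source centres over the posterior quarter of the array
        centers = np.linspace(0.72, 0.88, spec.n_sources)
        topo = np.stack([posterior_topography(spec.n_channels, c) for c in centers])
    mixed = topo.T @ sources  # channels x samples

    if math.isinf(spec.snr):
        data = mixed
    else:
        noise = _one_over_f_noise(rng, spec.n_channels, n, spec.sampling_rate,
                                  spec.noise_exponent)
        noise /= np.sqrt(np.mean(noise**2))
        p_sig = np.mean(mixed**2)
        noise *= np.sqrt(p_sig / spec.snr)
        data = mixed + noise

    rec = EEGRecording(data=data, sampling_rate=spec.sampling_rate)
    truth = GroundTruth(source_signals=sources, topography=topo)
    return rec, truth


@dataclass
class LangevinSimSpec:
    """Euler–Maruyama integration of dz = (a z^3 + b z^2 + c z + d) dt + sqrt(2D) dW."""

    drift_coefficients: tuple[float, float, float, float] = (0.0, 0.0, -1.0, 0.0)
    diffusion: float = 0.5
    dt: float = 0.01
    n_samples: int = 100_000
    initial_state: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(tuple(self.drift_coefficients)) != 4:
            raise ValueError("drift_coefficients must be a 4-tuple (a, b, c, d)")
        if self.diffusion < 0:
            raise ValueError("diffusion D must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_samples < 1000:
            raise ValueError("n_samples must be >= 1000 (pipeline validity floor)")


def generate_langevin_series(spec: LangevinSimSpec) -> tuple[np.ndarray, GroundTruth]:
    """Integrate the Langevin equation; returns the path and its ground truth.

    ``true_kappa`` is -c/2 of the generating cubic drift (the rigidity the
    landscape inversion should recover) and ``true_noise`` is D.
    """
    a, b, c, d = spec.drift_coefficients
    rng = np.random.default_rng(spec.seed)
    dw = rng.standard_normal(spec.n_samples - 1) * math.sqrt(2.0 * spec.diffusion * spec.dt)
    z = np.empty(spec.n_samples)
    z[0] = spec.initial_state
    zt = spec.initial_state
    dt = spec.dt
    for t in range(spec.n_samples - 1):
        zt = zt + (((a * zt + b) * zt + c) * zt + d) * dt + dw[t]
        z[t + 1] = zt
    truth = GroundTruth(true_kappa=-c / 2.0, true_noise=spec.diffusion)
    return z, truth


@dataclass
class CohortSimSpec:
    """Cohort of subjects whose ability score is linearly coupled to features.

    ``feature_covariance`` may be ``None`` (identity), a scalar rho in (-1, 1)
    (equicorrelation), or a full 45 x 45 positive-definite matrix.
    """

    n_subjects: int = 45
    n_features: int = 45
    coupled_feature_indices: Sequence[int] = (0, 1, 2, 3, 4)
    coupling_weights: Sequence[float] = (5.0, 5.0, 5.0, 5.0, 5.0)
    intercept: float = 100.0
    ability_noise_sd: float = 2.5
    feature_covariance: float | np.ndarray | None = None
    missing_rate: float = 0.0
    group: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        idx = list(self.coupled_feature_indices)
        if len(set(idx)) != len(idx):
            raise ValueError("coupled_feature_indices must be distinct")
        if idx and (min(idx) < 0 or max(idx) >= self.n_features):
            raise ValueError("coupled_feature_indices out of range")
        if len(idx) != len(list(self.coupling_weights)):
            raise ValueError("coupling_weights must match coupled_feature_indices")
        if self.ability_noise_sd < 0:
            raise ValueError("ability_noise_sd must be nonnegative")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")

    def covariance_matrix(self) -> np.ndarray:
        p = self.n_features
        if self.feature_covariance is None:
            return np.eye(p)
        if np.isscalar(self.feature_covariance):
            rho = float(self.feature_covariance)
            cov = np.full((p, p), rho)
            np.fill_diagonal(cov, 1.0)
        else:
            cov = np.asarray(self.feature_covariance, dtype=float)
            if cov.shape != (p, p):
                raise ValueError("feature_covariance matrix must be n_features square")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("feature covariance is not positive definite") from exc
        return cov


def generate_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a feature table with linearly coupled ability scores.

    Returns a DataFrame with ``subject_id``, ``group``, ``ability`` and the 45
    canonical feature columns (or generic names if ``n_features != 45``).
    """
    cov = spec.covariance_matrix()
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(cov)
    X = rng.standard_normal((spec.n_subjects, spec.n_features)) @ chol.T
    idx = np.asarray(list(spec.coupled_feature_indices), dtype=int)
    w = np.asarray(list(spec.coupling_weights), dtype=float)
    ability = spec.intercept + (X[:, idx] @ w if idx.size else 0.0)
    ability = ability + rng.normal(0.0, spec.ability_noise_sd, spec.n_subjects)

    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X = np.where(mask, np.nan, X)

    if spec.n_features == len(FEATURE_NAMES):
        cols = list(FEATURE_NAMES)
    else:
        cols = [f"f{i:02d}" for i in range(spec.n_features)]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "ability", ability)
    df.insert(0, "group", spec.group)
    df.insert(0, "subject_id", [f"s{i:03d}" for i in range(spec.n_subjects)])
    truth = GroundTruth(true_coupling=w, coupled_indices=idx, intercept=spec.intercept)
    return df, truth
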
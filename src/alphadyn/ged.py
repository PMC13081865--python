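"""Low-alpha reconstruction by generalized eigendecomposition (GED).

A signal covariance S is computed from 8–10 Hz bandpassed data and a
reference covariance R from the broadband record, both mean-centred and
Ledoit–Wolf shrunk.  Solving R w = lambda S w yields spatial filters whose
*small* eigenvalues mark strong low-alpha enrichment relative to broadband
(the eigenvalue is the broadband-to-alpha variance ratio), so eigenpairs are
kept in ascending order.  Between 3 and 12 components are retained by a
relative-stability rule on consecutive eigenvalue gaps; spatial maps are
derived from the alpha covariance, polarity-corrected at the peak loading,
min–max rescaled to [0, 1], and the electrode-level alpha signal is rebuilt
as the 1/lambda-weighted back-projection of the retained components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal as sps
from sklearn.covariance import ledoit_wolf

from .synthetic import EEGRecording

__all__ = [
    "CovariancePair",
    "GEDModel",
    "ReconstructedAlpha",
    "bandpass",
    "compute_covariances",
    "solve_ged",
    "select_components",
    "finalize_model",
    "backproject",
    "topography_concentration",
    "reconstruct_alpha",
]

LOW_ALPHA = (8.0, 10.0)


@dataclass
class CovariancePair:
    S: np.ndarray                     # narrowband (signal) covariance
    R: np.ndarray                     # broadband (reference) covariance
    shrinkage_intensities: tuple[float, float]
    alpha_data: np.ndarray | None = None  # mean-centred bandpassed data


@dataclass
class GEDModel:
    filters: np.ndarray               # channels x components, columns w
    eigenvalues: np.ndarray           # ascending
    n_retained: int | None = None
    maps: np.ndarray | None = None    # channels x retained, in [0, 1]
    weights: np.ndarray | None = None # per-component 1/lambda


@dataclass
class ReconstructedAlpha:
    signal: np.ndarray                # channels x samples
    sampling_rate: float


def bandpass(data: np.ndarray, fs: float, band: tuple[float, float],
             order: int = 4) -> np.ndarray:
    """Zero-phase (forward–backward) IIR bandpass along the last axis."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def _shrunk_cov(data: np.ndarray) -> tuple[np.ndarray, float]:
    # data: channels x samples; Ledoit-Wolf expects samples x features
    cov, intensity = ledoit_wolf(data.T, assume_centered=False)
    return cov, float(intensity)


def compute_covariances(rec: EEGRecording, band: tuple[float, float] = LOW_ALPHA
                        ) -> CovariancePair:
    """Narrowband and broadband covariances with Ledoit–Wolf shrinkage.

    Raises ``ValueError`` on NaN input or constant (zero-variance) channels.
    """
    data = np.asarray(rec.data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in EEG data")
    variances = data.var(axis=1)
    if np.any(variances == 0):
        bad = np.flatnonzero(variances == 0).tolist()
        raise ValueError(f"constant (zero-variance) channel(s): {bad}")

    alpha = bandpass(data, rec.sampling_rate, band)
    alpha = alpha - alpha.mean(axis=1, keepdims=True)
    broad = data - data.mean(axis=1, keepdims=True)
    S, gamma_s = _shrunk_cov(alpha)
    R, gamma_r = _shrunk_cov(broad)
    return CovariancePair(S=S, R=R, shrinkage_intensities=(gamma_s, gamma_r),
                          alpha_data=alpha)


def solve_ged(pair: CovariancePair) -> GEDModel:
    """All generalized eigenpairs of R w = lambda S w, ascending.

    Smaller eigenvalues correspond to stronger low-alpha enrichment.
    """
    evals, evecs = linalg.eigh(pair.R, pair.S)
    if not np.all(np.isfinite(evals)) or not np.all(np.isfinite(evecs)):
        raise ValueError("non-finite generalized eigenpairs; covariances may be "
                         "singular despite shrinkage")
    order = np.argsort(evals, kind="stable")
    return GEDModel(filters=evecs[:, order], eigenvalues=evals[order])


def select_components(eigenvalues: np.ndarray, lo: int = 3, hi: int = 12,
                      rel_gap: float = 0.05) -> int:
    """Retention count by the relative-stability rule, clamped to [3, 12].

    Scanning ascending eigenvalues, retain components 1..i where i is the
    first index whose following gap satisfies lambda_{i+1} - lambda_i
    < rel_gap * lambda_i; if no gap is that small, retain the cap.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < lo:
        raise ValueError(f"need at least {lo} eigenvalues, got {lam.size}")
    hi = min(hi, lam.size)
    k = hi
    for i in range(1, lam.size):
        if lam[i] - lam[i - 1] < rel_gap * lam[i - 1]:
            k = i
            break
    return int(np.clip(k, lo, hi))


def finalize_model(model: GEDModel, alpha_data: np.ndarray,
                   n_retained: int | None = None) -> GEDModel:
    """Attach retained maps: polarity-corrected, min–max rescaled to [0, 1].

    The spatial map of each retained component is (alpha covariance) x filter
    — the standard pattern-from-filter construction.  If the largest-|loading|
    entry is negative, both map and filter (hence the component time series)
    are sign-flipped; maps are then linearly rescaled so each column spans
    exactly [0, 1].
    """
    if n_retained is None:
        n_retained = select_components(model.eigenvalues)
    alpha = np.asarray(alpha_data, dtype=float)
    alpha = alpha - alpha.mean(axis=1, keepdims=True)
    cov_a = (alpha @ alpha.T) / alpha.shape[1]

    filters = model.filters.copy()
    k = n_retained
    maps = cov_a @ filters[:, :k]
    for j in range(k):
        col = maps[:, j]
        if np.allclose(col, 0):
            raise ValueError(f"component {j}: all-zero spatial map")
        peak = int(np.argmax(np.abs(col)))
        if col[peak] < 0:
            maps[:, j] = -col
            filters[:, j] = -filters[:, j]
        lo_v, hi_v = maps[:, j].min(), maps[:, j].max()
        if hi_v == lo_v:
            raise ValueError(f"component {j}: constant spatial map")
        maps[:, j] = (maps[:, j] - lo_v) / (hi_v - lo_v)

    lam = model.eigenvalues[:k]
    if np.any(lam == 0):
        raise ValueError("zero eigenvalue among retained components")
    return GEDModel(filters=filters, eigenvalues=model.eigenvalues,
                    n_retained=k, maps=maps, weights=1.0 / lam)


def backproject(model: GEDModel, alpha_data: np.ndarray,
                sampling_rate: float) -> ReconstructedAlpha:
    """Electrode signal = sum_k (1/lambda_k) map_k (w_k^T alpha_data)."""
    if model.n_retained is None or model.maps is None or model.weights is None:
        raise ValueError("model must be finalized before back-projection")
    alpha = np.asarray(alpha_data, dtype=float)
    alpha = alpha - alpha.mean(axis=1, keepdims=True)
    k = model.n_retained
    comp_ts = model.filters[:, :k].T @ alpha              # components x samples
    recon = (model.maps * model.weights[None, :]) @ comp_ts
    return ReconstructedAlpha(signal=recon, sampling_rate=sampling_rate)


def topography_concentration(model: GEDModel, channels: np.ndarray) -> np.ndarray:
    """Share of each retained component's map mass on a channel subset.

    An advisory report, not a filter: the reference workflow screens for a
    posterior-dominant scalp distribution by eye, so the pipeline exposes
    the concentration (sum of normalized map weights over ``channels``
    divided by the total) and leaves the accept/reject decision to the user.
    """
    if model.maps is None:
        raise ValueError("model must be finalized first")
    channels = np.asarray(channels, dtype=int)
    total = model.maps.sum(axis=0)
    return model.maps[channels].sum(axis=0) / total


def reconstruct_alpha(rec: EEGRecording, band: tuple[float, float] = LOW_ALPHA
                      ) -> tuple[ReconstructedAlpha, GEDModel]:
    """Full chain: covariances -> GED -> retention -> finalize -> back-project."""
    pair = compute_covariances(rec, band)
    model = solve_ged(pair)
    model = finalize_model(model, pair.alpha_data)
    recon = backproject(model, pair.alpha_data, rec.sampling_rate)
    return recon, model
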
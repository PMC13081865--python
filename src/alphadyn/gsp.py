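"""Graph-spectral machinery and the 45-feature extraction.

The functional graph is analysed through its symmetric normalized Laplacian
L = I - D^{-1/2} W D^{-1/2}.  Its eigenvalues are the graph frequencies
(all within [0, 2]) and its orthonormal eigenvectors the graph harmonics; the
graph Fourier transform of a nodal signal x is x_hat = U^T x.  Three
descriptors summarise how a signal sits on the graph:

* smoothness — the Dirichlet energy x^T L x; lower means the signal varies
  gradually across strongly connected electrodes;
* spectral entropy — Shannon entropy (nats) of the normalized graph-spectral
  energy p_i = x_hat_i^2 / sum_j x_hat_j^2;
* frequency spread — the energy-weighted standard deviation of graph
  frequencies around their energy-weighted mean.

Descriptors are computed for three nodal signal families (0D backbone
participation, 1D cyclic participation, nodal alpha power) in three regimes:
once on the global graph/signal, averaged over the 60 epoch-level values, and
as dynamic summaries (SD, mean absolute first difference, sample entropy with
m = 2) of the 60-point epochwise series — 45 features per subject in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FAMILIES",
    "DESCRIPTORS",
    "REGIMES",
    "FEATURE_NAMES",
    "GraphSpectrum",
    "normalized_laplacian",
    "gft",
    "smoothness",
    "spectral_entropy",
    "frequency_spread",
    "sampen",
    "mafd",
    "cohort_tolerances",
    "descriptor_triplet",
    "extract_features",
]

FAMILIES = ("part0d", "part1d", "alphapow")
DESCRIPTORS = ("smoothness", "entropy", "spread")
REGIMES = ("global", "epoch_mean", "sd", "mafd", "sampen")

#: Canonical, stable ordering of the 45 feature names:
#: family-major, then descriptor, then regime.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{fam}_{desc}_{reg}" for fam in FAMILIES for desc in DESCRIPTORS for reg in REGIMES
)


def _weights(g) -> np.ndarray:
    """Accept a ConnectivityGraph or a bare adjacency array."""
    return np.asarray(getattr(g, "weights", g), dtype=float)


def _signal(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


@dataclass
class GraphSpectrum:
    """Normalized Laplacian with its eigendecomposition."""

    laplacian: np.ndarray
    frequencies: np.ndarray  # ascending eigenvalues, within [0, 2]
    harmonics: np.ndarray    # orthonormal eigenvectors, columns
    degree: np.ndarray       # per-node strengths

    @property
    def n_nodes(self) -> int:
        return self.laplacian.shape[0]


def normalized_laplacian(g) -> GraphSpectrum:
    """Compute L = I - D^{-1/2} W D^{-1/2} and its eigendecomposition.

    Raises
    ------
    ValueError
        If any node has zero strength (the normalization is undefined).
    """
    W = _weights(g)
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        bad = np.flatnonzero(deg <= 0).tolist()
        raise ValueError(f"zero-strength node(s) {bad}: normalized Laplacian undefined")
    dinv = 1.0 / np.sqrt(deg)
    lap = np.eye(W.shape[0]) - (dinv[:, None] * W) * dinv[None, :]
    lap = 0.5 * (lap + lap.T)
    freqs, U = np.linalg.eigh(lap)
    return GraphSpectrum(laplacian=lap, frequencies=freqs, harmonics=U, degree=deg)


def gft(x, spec: GraphSpectrum) -> np.ndarray:
    """Graph Fourier transform x_hat = U^T x."""
    xv = _signal(x)
    if xv.shape[0] != spec.n_nodes:
        raise ValueError("signal length does not match graph size")
    return spec.harmonics.T @ xv


def smoothness(x, spec: GraphSpectrum) -> float:
    """Dirichlet energy x^T L x."""
    xv = _signal(x)
    if xv.shape[0] != spec.n_nodes:
        raise ValueError("signal length does not match graph size")
    return float(xv @ spec.laplacian @ xv)


def _energy_distribution(x, spec: GraphSpectrum) -> np.ndarray:
    xhat = gft(x, spec)
    energy = xhat**2
    total = energy.sum()
    if total <= 0:
        raise ValueError("zero signal: spectral energy distribution undefined")
    return energy / total


def spectral_entropy(x, spec: GraphSpectrum) -> float:
    """Shannon entropy (nats) of the normalized graph-spectral energy."""
    p = _energy_distribution(x, spec)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def frequency_spread(x, spec: GraphSpectrum) -> float:
    """Energy-weighted standard deviation of graph frequencies."""
    p = _energy_distribution(x, spec)
    mu = float(p @ spec.frequencies)
    var = float(p @ (spec.frequencies - mu) ** 2)
    return float(np.sqrt(max(var, 0.0)))


def descriptor_triplet(x, spec: GraphSpectrum) -> tuple[float, float, float]:
    """(smoothness, entropy, spread) of one signal on one graph."""
    return (smoothness(x, spec), spectral_entropy(x, spec), frequency_spread(x, spec))


# ---------------------------------------------------------------------------
# dynamic summaries


def mafd(series: np.ndarray) -> float:
    """Mean absolute first difference over consecutive points."""
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise ValueError("MAFD needs at least two points")
    return float(np.mean(np.abs(np.diff(s))))


def sampen(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with Chebyshev matching, self-matches excluded.

    ``B`` counts template pairs of length ``m`` (templates i = 0..n-m-1, the
    last one dropped so the m and m+1 template sets align), ``A`` pairs of
    length ``m + 1``.  When A or B is zero the ratio is regularised with the
    smallest positive float so a finite (large) value is returned instead of
    infinity; such series are effectively perfectly regular or too short.

    Parameters
    ----------
    series : 1-D array, length >= 10
    m : embedding dimension (default 2)
    r : tolerance; must be positive
    """
    s = np.asarray(series, dtype=float)
    n = s.size
    if n < 10:
        raise ValueError("sampen needs a series of length >= 10")
    if r is None or r <= 0:
        raise ValueError("tolerance r must be positive")
    n_templates = n - m
    # embedding matrices: rows are templates of length m and m+1
    emb_m = np.lib.stride_tricks.sliding_window_view(s, m)[:n_templates]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(s, m + 1)
    # Chebyshev distances between all template pairs
    dist_m = np.abs(emb_m[:, None, :] - emb_m[None, :, :]).max(axis=2)
    dist_m1 = np.abs(emb_m1[:, None, :] - emb_m1[None, :, :]).max(axis=2)
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.count_nonzero(dist_m[iu] <= r))
    a = int(np.count_nonzero(dist_m1[iu] <= r))
    if a == 0 or b == 0:
        tiny = np.finfo(float).tiny
        return float(-np.log((a + tiny) / (b + tiny)))
    return float(-np.log(a / b))


def cohort_tolerances(epoch_series: np.ndarray) -> np.ndarray:
    """SampEn tolerances r per (family, descriptor) across a cohort.

    r = 0.2 x the median across subjects of the per-subject standard
    deviation of the corresponding 60-point feature time series.

    Parameters
    ----------
    epoch_series : array (n_subjects, 3, 3, n_epochs)
        Epochwise feature series indexed (subject, family, descriptor, epoch).

    Returns
    -------
    array (3, 3) of tolerances.
    """
    arr = np.asarray(epoch_series, dtype=float)
    if arr.ndim != 4 or arr.shape[1] != 3 or arr.shape[2] != 3:
        raise ValueError("epoch_series must have shape (n_subjects, 3, 3, n_epochs)")
    sds = np.nanstd(arr, axis=3, ddof=1)          # (n_subjects, 3, 3)
    med = np.nanmedian(sds, axis=0)               # (3, 3)
    if np.any(med <= 0) or np.any(~np.isfinite(med)):
        raise ValueError("zero or undefined median SD: tolerance undefined")
    return 0.2 * med


# ---------------------------------------------------------------------------
# 45-feature assembly


def extract_features(global_values: np.ndarray, epoch_series: np.ndarray,
                     tolerances: np.ndarray | None = None) -> pd.Series:
    """Assemble the 45 named features of one subject.

    Parameters
    ----------
    global_values : array (3, 3)
        Static/global descriptors, indexed (family, descriptor).
    epoch_series : array (3, 3, n_epochs)
        Epochwise descriptor series (family, descriptor, epoch).
    tolerances : array (3, 3), optional
        Cohort-level SampEn tolerances.  When absent, each series falls back
        to 0.2 x its own standard deviation (single-subject mode).

    Missing epochs (NaN) propagate: epoch means ignore NaN; dynamic summaries
    of a series containing NaN are NaN and are left for downstream imputation.
    """
    gv = np.asarray(global_values, dtype=float)
    es = np.asarray(epoch_series, dtype=float)
    if gv.shape != (3, 3) or es.ndim != 3 or es.shape[:2] != (3, 3):
        raise ValueError("expected global (3,3) and epoch (3,3,n_epochs) arrays")

    values: dict[str, float] = {}
    for i, fam in enumerate(FAMILIES):
        for j, desc in enumerate(DESCRIPTORS):
            series = es[i, j]
            values[f"{fam}_{desc}_global"] = gv[i, j]
            values[f"{fam}_{desc}_epoch_mean"] = float(np.nanmean(series))
            if np.any(np.isnan(series)):
                sd = md = se = np.nan
            else:
                sd = float(np.std(series, ddof=1))
                md = mafd(series)
                r = tolerances[i, j] if tolerances is not None else 0.2 * sd
                se = sampen(series, m=2, r=r) if r > 0 else np.nan
            values[f"{fam}_{desc}_sd"] = sd
            values[f"{fam}_{desc}_mafd"] = md
            values[f"{fam}_{desc}_sampen"] = se
    return pd.Series([values[name] for name in FEATURE_NAMES], index=list(FEATURE_NAMES))
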
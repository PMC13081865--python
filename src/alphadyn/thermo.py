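"""Inverse Langevin modeling of alpha-power smoothness dynamics.

The state variable is the sample-wise Dirichlet energy of instantaneous
alpha power on the epoch's functional graph, S(t) = x(t)^T L x(t),
concatenated across epochs and globally z-scored.  Treating z(t) as an
overdamped Langevin process dz/dt = -U'(z) + sqrt(2 D(z)) xi(t), the drift
and diffusion are estimated by conditional Kramers–Moyal averages of the
increments dz over 20 linear bins spanning the central 95% of the state
distribution (bins with more than 10 samples are valid):

    D1(z_k) = E[dz | z in k] / dt,      D2(z_k) = Var[dz | z in k] / (2 dt).

A cubic polynomial D1(z) = a z^3 + b z^2 + c z + d fitted to the valid
binwise drift (at least 4 bins required) integrates to the quartic potential
U(z) = -a/4 z^4 - b/3 z^3 - c/2 z^2 - d z (+ C, U(0) = 0).  Two scalars
summarise each subject: central rigidity kappa = -c/2 (local confinement at
the standardized operating point z = 0) and central noise, the mean D2 over
valid bins with centres in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .connectivity import ConnectivityGraph, EpochSet
from .ged import ReconstructedAlpha
from .gsp import normalized_laplacian

__all__ = [
    "SmoothnessSeries",
    "BinnedKM",
    "DriftFit",
    "Potential",
    "ThermoMetrics",
    "SubjectExcludedError",
    "samplewise_smoothness",
    "estimate_km",
    "fit_drift",
    "reconstruct_potential",
    "extract_metrics",
    "landscape_from_series",
    "subject_thermo",
]

MIN_VALID_SAMPLES = 1000


class SubjectExcludedError(ValueError):
    """Raised when a subject fails the validity floor for landscape fitting."""


@dataclass
class SmoothnessSeries:
    values: np.ndarray
    dt: float
    n_valid: int
    standardized: bool = True
    #: indices into ``values`` where a new epoch starts (None for continuous
    #: series such as simulated Langevin paths)
    epoch_starts: np.ndarray | None = None

    @classmethod
    def from_values(cls, values: np.ndarray, dt: float,
                    standardize: bool = False) -> "SmoothnessSeries":
        """Wrap an arbitrary state series (e.g. a simulated Langevin path)."""
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if standardize:
            sd = v.std()
            if sd == 0:
                raise ValueError("zero-variance series cannot be standardized")
            v = (v - v.mean()) / sd
        return cls(values=v, dt=dt, n_valid=v.size, standardized=standardize)


@dataclass
class BinnedKM:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    counts: np.ndarray
    drift: np.ndarray       # D1 per bin (NaN where empty)
    diffusion: np.ndarray   # D2 per bin (NaN where empty)
    valid: np.ndarray       # count > 10


@dataclass
class DriftFit:
    coefficients: tuple[float, float, float, float]  # a, b, c, d
    n_bins_used: int
    fit_residual: float

    def __call__(self, z: np.ndarray) -> np.ndarray:
        a, b, c, d = self.coefficients
        z = np.asarray(z, dtype=float)
        return ((a * z + b) * z + c) * z + d


@dataclass
class Potential:
    """U(z) = -a/4 z^4 - b/3 z^3 - c/2 z^2 - d z + C with U(0) = 0."""

    quartic_coefficients: tuple[float, float, float, float, float]
    constant: float = 0.0

    def __call__(self, z: np.ndarray) -> np.ndarray:
        c4, c3, c2, c1, c0 = self.quartic_coefficients
        z = np.asarray(z, dtype=float)
        return (((c4 * z + c3) * z + c2) * z + c1) * z + c0


@dataclass
class ThermoMetrics:
    kappa: float          # central rigidity, -c/2
    central_noise: float  # mean D2 over valid bins with |center| <= 1
    n_valid: int
    drift_coefficients: tuple[float, float, float, float] | None = None


def samplewise_smoothness(power: np.ndarray, laplacians: list[np.ndarray],
                          dt: float = 0.01) -> SmoothnessSeries:
    """S(t) = x(t)^T L_e x(t), concatenated across epochs and z-scored.

    Parameters
    ----------
    power : array (n_epochs, n_channels, n_samples_per_epoch)
        Instantaneous alpha power (squared analytic-signal amplitude),
        epoch-aligned so each sample maps to exactly one epoch Laplacian.
    laplacians : list of (n_channels, n_channels) normalized Laplacians,
        one per epoch.
    dt : sampling interval in seconds (1/100 at the standard rate).

    Raises
    ------
    SubjectExcludedError
        If fewer than 1000 valid (finite) samples remain.
    ValueError
        If the raw series has zero variance (cannot be standardized).
    """
    power = np.asarray(power, dtype=float)
    if power.ndim != 3 or power.shape[0] != len(laplacians):
        raise ValueError("power must be (n_epochs, channels, samples) matching "
                         "one Laplacian per epoch")
    parts = []
    for X, L in zip(power, laplacians):
        parts.append(np.einsum("ct,cd,dt->t", X, L, X))
    raw = np.concatenate(parts)
    finite = np.isfinite(raw)
    n_valid = int(finite.sum())
    if n_valid < MIN_VALID_SAMPLES:
        raise SubjectExcludedError(
            f"fewer than {MIN_VALID_SAMPLES} valid smoothness samples ({n_valid})"
        )
    vals = raw[finite]
    sd = vals.std()
    if sd == 0:
        raise ValueError("smoothness series has zero variance; cannot z-score")
    # epoch starts in post-NaN-removal coordinates
    per_epoch = power.shape[2]
    starts_raw = np.arange(0, raw.size, per_epoch)
    starts = np.cumsum(finite)[starts_raw] - finite[starts_raw]
    return SmoothnessSeries(values=(vals - vals.mean()) / sd, dt=dt,
                            n_valid=n_valid, epoch_starts=starts)


def estimate_km(series: SmoothnessSeries, n_bins: int = 20,
                central: tuple[float, float] = (2.5, 97.5),
                min_count: int = 10,
                drop_boundary_increments: bool = False) -> BinnedKM:
    """Binwise Kramers–Moyal drift and diffusion of the state series.

    Increments dz_t = z_{t+dt} - z_t are conditioned on the *starting* state
    z_t; the state range is restricted to the central 95% (2.5th–97.5th
    percentiles) and divided into ``n_bins`` linear bins.  Bins with more
    than ``min_count`` increments are valid.  Diffusion uses the conditional
    sample variance (n-1 denominator).

    Increments spanning an epoch boundary are retained by default (the
    series is a single concatenated record); set
    ``drop_boundary_increments=True`` for sensitivity analysis when the
    series carries epoch-start indices.
    """
    z = np.asarray(series.values, dtype=float)
    if z.size < 2:
        raise ValueError("series too short for increments")
    dz = np.diff(z)
    start = z[:-1]
    if drop_boundary_increments and series.epoch_starts is not None:
        last = series.epoch_starts[1:] - 1  # final sample of each epoch
        keep = np.ones(dz.size, dtype=bool)
        keep[last[last < dz.size]] = False
        dz, start = dz[keep], start[keep]
    lo, hi = np.percentile(z, central)
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    inside = (start >= lo) & (start <= hi)
    idx = np.clip(np.digitize(start[inside], edges) - 1, 0, n_bins - 1)
    dz_in = dz[inside]

    counts = np.bincount(idx, minlength=n_bins)
    drift = np.full(n_bins, np.nan)
    diffusion = np.full(n_bins, np.nan)
    dt = series.dt
    for k in range(n_bins):
        sel = idx == k
        if counts[k] == 0:
            continue
        d = dz_in[sel]
        drift[k] = d.mean() / dt
        diffusion[k] = (d.var(ddof=1) / (2.0 * dt)) if counts[k] > 1 else 0.0
    valid = counts > min_count
    return BinnedKM(bin_edges=edges, bin_centers=centers, counts=counts,
                    drift=drift, diffusion=diffusion, valid=valid)


def fit_drift(km: BinnedKM, min_bins: int = 4) -> DriftFit:
    """Unweighted least-squares cubic through (bin centre, D1) of valid bins."""
    ok = km.valid & np.isfinite(km.drift)
    n_used = int(ok.sum())
    if n_used < min_bins:
        raise ValueError(f"only {n_used} valid bins; need at least {min_bins} "
                         "for the cubic drift fit")
    coeffs = np.polyfit(km.bin_centers[ok], km.drift[ok], 3)
    resid = float(np.sum((np.polyval(coeffs, km.bin_centers[ok]) - km.drift[ok]) ** 2))
    a, b, c, d = (float(v) for v in coeffs)
    return DriftFit(coefficients=(a, b, c, d), n_bins_used=n_used,
                    fit_residual=resid)


def reconstruct_potential(fit: DriftFit) -> Potential:
    """Integrate the negative fitted drift; constant fixed by U(0) = 0."""
    a, b, c, d = fit.coefficients
    return Potential(quartic_coefficients=(-a / 4.0, -b / 3.0, -c / 2.0, -d, 0.0))


def extract_metrics(fit: DriftFit, km: BinnedKM,
                    central_range: tuple[float, float] = (-1.0, 1.0),
                    count_weighted: bool = False) -> ThermoMetrics:
    """Central rigidity kappa = -c/2 and central noise (mean D2, |z| <= 1).

    Central noise averages unweighted over valid bins whose centres fall in
    ``central_range`` (``count_weighted=True`` weights by bin occupancy);
    raises when none qualify.
    """
    a, b, c, d = fit.coefficients
    kappa = -c / 2.0
    sel = km.valid & (km.bin_centers >= central_range[0]) \
        & (km.bin_centers <= central_range[1]) & np.isfinite(km.diffusion)
    if not np.any(sel):
        raise ValueError("no valid bins with centres in the central range")
    if count_weighted:
        noise = float(np.average(km.diffusion[sel], weights=km.counts[sel]))
    else:
        noise = float(np.mean(km.diffusion[sel]))
    return ThermoMetrics(kappa=float(kappa), central_noise=noise,
                         n_valid=int(km.counts.sum()),
                         drift_coefficients=fit.coefficients)


def landscape_from_series(values: np.ndarray, dt: float,
                          standardize: bool = False) -> ThermoMetrics:
    """KM estimation + cubic drift fit + metric extraction for a state series."""
    series = SmoothnessSeries.from_values(values, dt, standardize=standardize)
    if series.n_valid < MIN_VALID_SAMPLES:
        raise SubjectExcludedError(
            f"fewer than {MIN_VALID_SAMPLES} valid samples ({series.n_valid})"
        )
    km = estimate_km(series)
    fit = fit_drift(km)
    return extract_metrics(fit, km)


def subject_thermo(recon: ReconstructedAlpha,
                   epoch_graphs: list[ConnectivityGraph],
                   signal_epochs: EpochSet, discard: float = 15.0) -> ThermoMetrics:
    """Full per-subject landscape inversion from reconstructed alpha.

    Instantaneous alpha power is the squared analytic-signal amplitude of the
    continuous reconstruction, segmented in register with the epoch graphs
    (``discard`` must match the segmentation used to build them).
    """
    from .connectivity import segment

    power_full = np.abs(hilbert(recon.signal, axis=-1)) ** 2
    n_ep = signal_epochs.n_epochs
    fs = signal_epochs.sampling_rate
    power = segment(power_full, fs, discard=discard,
                    analyze=n_ep * signal_epochs.epoch_length,
                    epoch_len=signal_epochs.epoch_length)
    laplacians = [normalized_laplacian(g).laplacian for g in epoch_graphs]
    series = samplewise_smoothness(power.epochs, laplacians, dt=1.0 / fs)
    km = estimate_km(series)
    fit = fit_drift(km)
    return extract_metrics(fit, km)
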
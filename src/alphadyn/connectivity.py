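"""Functional connectivity graphs from reconstructed alpha signals.

Phase synchrony between electrodes is measured with the corrected imaginary
phase-locking value (ciPLV): from the complex PLV

    PLV_ab = (1/T) sum_t exp(i (phi_a(t) - phi_b(t))),

ciPLV = Im(PLV) / sqrt(1 - Re(PLV)^2), which discounts zero-lag coupling
(volume conduction produces purely real PLV).  Graph edge weights are
|ciPLV|, giving symmetric, zero-diagonal adjacency matrices with entries in
[0, 1].

Instantaneous phase is taken from the analytic signal of the *continuous*
reconstructed alpha record, computed once before segmentation, which avoids
per-epoch Hilbert edge artifacts.  Epoch-level graphs average complex PLV
over 10 non-overlapping windows within each 3 s epoch before conversion; the
global graph averages whole-epoch complex PLV across epochs and then
converts.  For simulated per-cell voltage traces (no volume conduction) an
absolute-Pearson-correlation graph is provided instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .ged import ReconstructedAlpha

__all__ = [
    "EpochSet",
    "ConnectivityGraph",
    "segment",
    "instantaneous_phase",
    "complex_plv",
    "plv_matrix",
    "ciplv_from_complex",
    "epoch_graph",
    "global_graph",
    "correlation_graph",
    "subject_graphs",
]


@dataclass
class EpochSet:
    """Non-overlapping contiguous equal-length blocks of a recording."""

    epochs: np.ndarray          # (n_epochs, channels, samples)
    epoch_length: float         # seconds
    sampling_rate: float

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class ConnectivityGraph:
    """Symmetric nonnegative weighted adjacency with zero diagonal."""

    weights: np.ndarray
    kind: str  # ciplv_epoch | ciplv_global | abs_correlation

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def segment(data, sampling_rate: float | None = None, discard: float = 15.0,
            analyze: float = 180.0, epoch_len: float = 3.0) -> EpochSet:
    """Drop the first ``discard`` seconds, split the next ``analyze`` seconds
    into floor(analyze/epoch_len) non-overlapping epochs.

    ``data`` may be a :class:`ReconstructedAlpha` or a channels x samples
    array (then ``sampling_rate`` is required).  Standard settings
    (195 s at 100 Hz, discard 15, analyze 180, epochs of 3 s) give 60 epochs
    of 300 samples.
    """
    if isinstance(data, ReconstructedAlpha):
        arr, fs = data.signal, data.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for bare arrays")
        arr, fs = np.asarray(data, dtype=float), float(sampling_rate)
    n_needed = int(round((discard + analyze) * fs))
    if arr.shape[-1] < n_needed:
        raise ValueError(
            f"recording too short: need {discard + analyze:g} s "
            f"({n_needed} samples at {fs:g} Hz), got {arr.shape[-1]}"
        )
    start = int(round(discard * fs))
    samp_per = int(round(epoch_len * fs))
    n_epochs = int(np.floor(analyze / epoch_len))
    blocks = arr[..., start:start + n_epochs * samp_per]
    epochs = blocks.reshape(arr.shape[0], n_epochs, samp_per).transpose(1, 0, 2)
    return EpochSet(epochs=epochs, epoch_length=epoch_len, sampling_rate=fs)


def instantaneous_phase(recon) -> np.ndarray:
    """Phase of the analytic signal, computed on the full continuous record."""
    sig = recon.signal if isinstance(recon, ReconstructedAlpha) else np.asarray(recon)
    return np.angle(hilbert(sig, axis=-1))


def complex_plv(phase_a: np.ndarray, phase_b: np.ndarray) -> complex:
    """(1/T) sum_t exp(i (phi_a - phi_b)) for one channel pair."""
    pa, pb = np.asarray(phase_a, float), np.asarray(phase_b, float)
    if pa.size == 0 or pa.shape != pb.shape:
        raise ValueError("phase series must be equal-length and non-empty")
    return complex(np.mean(np.exp(1j * (pa - pb))))


def plv_matrix(phases: np.ndarray) -> np.ndarray:
    """All-pairs complex PLV for a channels x samples phase block."""
    E = np.exp(1j * np.asarray(phases))
    return (E @ E.conj().T) / phases.shape[-1]


def ciplv_from_complex(plv: np.ndarray | complex) -> np.ndarray | float:
    """Im(PLV) / sqrt(1 - Re(PLV)^2), with ciPLV := 0 where Re^2 = 1.

    When |Re(PLV)| = 1 the imaginary part is necessarily 0; the guard returns
    the limit value 0 instead of 0/0.
    """
    p = np.asarray(plv, dtype=complex)
    re, im = p.real, p.imag
    denom_sq = 1.0 - re**2
    out = np.zeros_like(re, dtype=float)
    ok = denom_sq > 1e-12
    out = np.divide(im, np.sqrt(denom_sq, where=ok, out=np.ones_like(re)),
                    where=ok, out=out)
    return float(out) if np.isscalar(plv) or p.ndim == 0 else out


def _to_graph(cplv: np.ndarray, kind: str) -> ConnectivityGraph:
    W = np.abs(ciplv_from_complex(cplv))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return ConnectivityGraph(weights=np.clip(W, 0.0, 1.0), kind=kind)


def epoch_graph(phases: np.ndarray, n_windows: int = 10) -> ConnectivityGraph:
    """ciPLV graph of one epoch from window-averaged complex PLV.

    The epoch (channels x samples of instantaneous phase) is split into
    ``n_windows`` non-overlapping windows; complex PLV matrices are computed
    per window and averaged before the ciPLV conversion.
    """
    phases = np.asarray(phases, dtype=float)
    n_samp = phases.shape[-1]
    if n_samp % n_windows != 0:
        raise ValueError(f"epoch length {n_samp} not divisible by {n_windows} windows")
    w = n_samp // n_windows
    acc = np.zeros((phases.shape[0], phases.shape[0]), dtype=complex)
    for k in range(n_windows):
        acc += plv_matrix(phases[:, k * w:(k + 1) * w])
    return _to_graph(acc / n_windows, "ciplv_epoch")


def global_graph(phase_epochs: np.ndarray) -> ConnectivityGraph:
    """Subject-level graph: whole-epoch complex PLV averaged across epochs,
    then converted to |ciPLV|.

    ``phase_epochs``: (n_epochs, channels, samples) of instantaneous phase.
    """
    pe = np.asarray(phase_epochs, dtype=float)
    if pe.ndim != 3 or pe.shape[0] < 1:
        raise ValueError("need at least one (channels x samples) phase epoch")
    acc = np.zeros((pe.shape[1], pe.shape[1]), dtype=complex)
    for ep in pe:
        acc += plv_matrix(ep)
    return _to_graph(acc / pe.shape[0], "ciplv_global")


def correlation_graph(signals: np.ndarray) -> ConnectivityGraph:
    """|Pearson correlation| graph for simulated per-cell signals."""
    X = np.asarray(signals, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 signal rows")
    if np.any(X.std(axis=1) == 0):
        bad = np.flatnonzero(X.std(axis=1) == 0).tolist()
        raise ValueError(f"constant row(s) {bad}: correlation undefined")
    W = np.abs(np.corrcoef(X))
    np.fill_diagonal(W, 0.0)
    return ConnectivityGraph(weights=np.clip(W, 0.0, 1.0), kind="abs_correlation")


def subject_graphs(recon: ReconstructedAlpha, discard: float = 15.0,
                   analyze: float = 180.0, epoch_len: float = 3.0,
                   phase_mode: str = "continuous"
                   ) -> tuple[list[ConnectivityGraph], ConnectivityGraph, EpochSet]:
    """Epoch-level graphs, the global graph, and the signal epochs.

    By default phase is extracted once from the continuous record and then
    segmented (avoids per-epoch transform edge artifacts);
    ``phase_mode="per_epoch"`` instead runs the analytic signal on each
    epoch separately, for sensitivity analysis.
    """
    signal_epochs = segment(recon, None, discard, analyze, epoch_len)
    if phase_mode == "per_epoch":
        phase_blocks = np.stack([instantaneous_phase(ep)
                                 for ep in signal_epochs.epochs])
        phase_epochs = EpochSet(epochs=phase_blocks, epoch_length=epoch_len,
                                sampling_rate=signal_epochs.sampling_rate)
    elif phase_mode == "continuous":
        phases = instantaneous_phase(recon)
        phase_epochs = segment(phases, recon.sampling_rate, discard, analyze,
                               epoch_len)
    else:
        raise ValueError("phase_mode must be 'continuous' or 'per_epoch'")
    egs = [epoch_graph(p) for p in phase_epochs.epochs]
    gg = global_graph(phase_epochs.epochs)
    return egs, gg, signal_epochs
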
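"""Plain-text I/O: delimited matrices with JSON sidecars, optional EDF reading.

Matrices (EEG, reconstructed signals, graphs) are stored as tab-delimited
text; metadata (sampling rate, channel names, graph kind) lives in a JSON
sidecar named ``<file>.json``.  EDF recordings are read through ``mne`` when
it is installed; writing is always delimited text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .connectivity import ConnectivityGraph
from .synthetic import EEGRecording
from .topology import TopologyDecomposition

__all__ = [
    "write_matrix", "read_matrix", "read_eeg",
    "write_graph", "read_graph", "write_decomposition",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_matrix(path: str | Path, data: np.ndarray, **meta) -> None:
    path = Path(path)
    np.savetxt(path, np.asarray(data), delimiter="\t")
    if meta:
        _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t")
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return data, meta


def read_eeg(path: str | Path, sampling_rate: float | None = None) -> EEGRecording:
    """Read an EEG recording from EDF (via mne) or delimited text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading EDF requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return EEGRecording(data=raw.get_data(), sampling_rate=raw.info["sfreq"],
                            channel_names=list(raw.ch_names))
    data, meta = read_matrix(path)
    fs = sampling_rate or meta.get("sampling_rate")
    if fs is None:
        raise ValueError("sampling_rate required (argument or JSON sidecar)")
    return EEGRecording(data=np.atleast_2d(data), sampling_rate=float(fs),
                        channel_names=meta.get("channel_names"))


def write_graph(path: str | Path, graph: ConnectivityGraph,
                channel_names: list[str] | None = None) -> None:
    write_matrix(path, graph.weights, kind=graph.kind,
                 channel_names=channel_names)


def read_graph(path: str | Path) -> ConnectivityGraph:
    data, meta = read_matrix(path)
    return ConnectivityGraph(weights=data, kind=meta.get("kind", "unknown"))


def write_decomposition(path: str | Path, decomp: TopologyDecomposition) -> None:
    """Edge list: node_i, node_j, weight, subgraph tag (mst | cycle)."""
    lines = ["node_i\tnode_j\tweight\tsubgraph"]
    for i, j, w in decomp.mst_edges:
        lines.append(f"{i}\t{j}\t{w:.12g}\tmst")
    for i, j, w in decomp.cycle_edges:
        lines.append(f"{i}\t{j}\t{w:.12g}\tcycle")
    Path(path).write_text("\n".join(lines) + "\n")
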
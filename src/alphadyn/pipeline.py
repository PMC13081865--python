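"""End-to-end subject and cohort analysis.

Chains the pipeline stages: GED alpha reconstruction -> segmentation ->
ciPLV epoch/global graphs -> birth–death decomposition -> nodal signals ->
graph-spectral feature series -> 45-feature vector, plus the inverse
Langevin landscape metrics.  Cohort assembly computes the cohort-level
SampEn tolerances before finalizing any subject's dynamic features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import connectivity, ged, gsp, thermo, topology
from .synthetic import EEGRecording

__all__ = ["SubjectAnalysis", "analyze_subject", "assemble_feature_table"]


@dataclass
class SubjectAnalysis:
    """Intermediate per-subject products of the pipeline."""

    global_values: np.ndarray     # (3 families, 3 descriptors)
    epoch_series: np.ndarray      # (3, 3, n_epochs)
    thermo_metrics: thermo.ThermoMetrics | None
    n_epochs: int
    ged_model: ged.GEDModel


def _signals_for_graph(graph, alpha_power: np.ndarray) -> list[np.ndarray]:
    decomp = topology.birth_death_decompose(graph)
    s0 = topology.participation_signal(decomp, "0d").values
    s1 = topology.participation_signal(decomp, "1d").values
    return [s0, s1, np.asarray(alpha_power, dtype=float)]


def analyze_subject(rec: EEGRecording, band: tuple[float, float] = (8.0, 10.0),
                    discard: float = 15.0, analyze: float = 180.0,
                    epoch_len: float = 3.0, with_thermo: bool = True
                    ) -> SubjectAnalysis:
    """Run the full single-subject pipeline on a cleaned recording."""
    recon, model = ged.reconstruct_alpha(rec, band)
    epoch_graphs, global_g, signal_epochs = connectivity.subject_graphs(
        recon, discard, analyze, epoch_len)
    n_ep = signal_epochs.n_epochs

    ap_epoch = topology.alpha_power_epoch_signal(recon, signal_epochs, band)
    ap_global = topology.alpha_power_global_signal(recon, discard, analyze, band)

    spec_g = gsp.normalized_laplacian(global_g)
    global_values = np.array([
        gsp.descriptor_triplet(x, spec_g)
        for x in _signals_for_graph(global_g, ap_global)
    ])

    epoch_series = np.empty((3, 3, n_ep))
    for e in range(n_ep):
        spec_e = gsp.normalized_laplacian(epoch_graphs[e])
        for i, x in enumerate(_signals_for_graph(epoch_graphs[e], ap_epoch[e])):
            epoch_series[i, :, e] = gsp.descriptor_triplet(x, spec_e)

    tm = None
    if with_thermo:
        tm = thermo.subject_thermo(recon, epoch_graphs, signal_epochs, discard)
    return SubjectAnalysis(global_values=global_values, epoch_series=epoch_series,
                           thermo_metrics=tm, n_epochs=n_ep, ged_model=model)


def assemble_feature_table(analyses: list[SubjectAnalysis],
                           ability: np.ndarray | None = None,
                           group: str | list[str] = "control",
                           subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Cohort feature table with cohort-level SampEn tolerances.

    Tolerances r = 0.2 x the median across-subject SD of each epochwise
    feature series are computed first, then every subject's 45 features are
    extracted with those shared tolerances.
    """
    if not analyses:
        raise ValueError("need at least one subject analysis")
    stack = np.stack([a.epoch_series for a in analyses])
    tol = gsp.cohort_tolerances(stack)
    rows = [gsp.extract_features(a.global_values, a.epoch_series, tol)
            for a in analyses]
    df = pd.DataFrame(rows).reset_index(drop=True)
    n = len(analyses)
    ids = subject_ids or [f"s{i:03d}" for i in range(n)]
    groups = [group] * n if isinstance(group, str) else list(group)
    df.insert(0, "ability", np.full(n, np.nan) if ability is None else ability)
    df.insert(0, "group", groups)
    df.insert(0, "subject_id", ids)
    return df
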
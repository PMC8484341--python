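"""End-to-end orchestration: gate -> wavelet -> cluster -> combine -> enrich.

These functions tie the library stages together the way a full analysis
run uses them; the command-line interface is a thin wrapper around them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import CombinedClustering, PulseKMeans, combine
from .errors import ContractError
from .io import PulseDataset
from .phase import GateConfig, assign_groups, enrichment_table, gate_phases, gate_singlets
from .wavelets import ModwtFeaturizer

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_CHANNELS = ("FSCL", "FSCU")


def baseline_subtract(dataset: PulseDataset, channel: str, n_pre: int = 5) -> np.ndarray:
    """Per-pulse baseline removal (median of the pre-trigger samples)."""
    pulses = dataset.channel(channel)
    base = np.median(pulses[:, :n_pre], axis=1, keepdims=True)
    return pulses - base


@dataclass
class ChannelModel:
    """Frozen featurizer + cluster model of one scatter channel."""

    channel: str
    featurizer: ModwtFeaturizer
    clusterer: PulseKMeans
    features: np.ndarray | None = None


@dataclass
class FitResult:
    """Everything a reference-sample fit produces."""

    channels: tuple
    models: dict                      # channel -> ChannelModel
    combined: CombinedClustering
    events: pd.DataFrame              # gated, labeled, with cluster columns
    enrichment: pd.DataFrame          # grouped enrichment table
    seed: int = 0


def fit_reference(
    dataset: PulseDataset,
    events: pd.DataFrame,
    channels=DEFAULT_CLUSTER_CHANNELS,
    k: int = 8,
    seed: int = 0,
    n_init: int = 10,
    wavelet: str = "haar",
    level: int | None = None,
    max_level: int = 6,
    gate_config: GateConfig = GateConfig(),
    size_cutoff_fraction: float = 0.005,
    t_specific: float = 1.5,
    t_mixed: float = 1.1,
) -> FitResult:
    """Run the full reference analysis on a linked cohort.

    Gates singlets and reference phases from fluorescence, selects the
    wavelet feature level per channel, clusters each channel's coefficient
    vectors into k clusters, combines two channels into k*k combined
    clusters, and assigns every combined cluster to a cell-cycle group by
    enrichment.
    """
    if len(events) != dataset.n_events:
        raise ContractError("events table and pulse dataset disagree in length")
    n_in = len(events)
    events = gate_singlets(events, gate_config)
    events = gate_phases(events, gate_config)
    logger.info("gating: %d events in, %d singlets, %d labeled", n_in,
                int(events["singlet"].sum()),
                int(events["reference_phase"].isin(("G1", "S", "G2M")).sum()))

    models: dict[str, ChannelModel] = {}
    for ch in channels:
        X = baseline_subtract(dataset, ch)
        fz = ModwtFeaturizer(wavelet=wavelet, level=level, max_level=max_level).fit(X)
        F = fz.transform(X)
        km = PulseKMeans(n_clusters=k, seed=seed, n_init=n_init,
                         channel=ch, level=fz.level_).fit(F)
        logger.info("channel %s: feature level %d, inertia %.3g", ch, fz.level_, km.inertia_)
        models[ch] = ChannelModel(channel=ch, featurizer=fz, clusterer=km, features=F)
        events[f"cluster_{ch}"] = km.labels_

    ch_a, ch_b = channels[0], channels[1]
    combined = combine(models[ch_a].clusterer.labels_, models[ch_b].clusterer.labels_,
                       k_a=k, k_b=k,
                       fingerprint_a=models[ch_a].clusterer.fingerprint_,
                       fingerprint_b=models[ch_b].clusterer.fingerprint_)
    events["combined_cluster"] = combined.combined_ids
    table = enrichment_table(combined, events, size_cutoff_fraction)
    table = assign_groups(table, t_specific=t_specific, t_mixed=t_mixed)
    return FitResult(channels=tuple(channels), models=models, combined=combined,
                     events=events, enrichment=table, seed=seed)


def transfer_assign(dataset: PulseDataset, fit: FitResult) -> CombinedClustering:
    """Assign a new acquisition to the frozen reference centroids (no refit)."""
    labels = {}
    for ch in fit.channels:
        X = baseline_subtract(dataset, ch)
        F = fit.models[ch].featurizer.transform(X)
        labels[ch] = fit.models[ch].clusterer.predict(F)
    ch_a, ch_b = fit.channels
    return combine(labels[ch_a], labels[ch_b],
                   k_a=fit.models[ch_a].clusterer.n_clusters,
                   k_b=fit.models[ch_b].clusterer.n_clusters,
                   fingerprint_a=fit.models[ch_a].clusterer.fingerprint_,
                   fingerprint_b=fit.models[ch_b].clusterer.fingerprint_)


def group_heatmap_frame(fit: FitResult) -> pd.DataFrame:
    """k_a x k_b table of group labels (rows: channel-A cluster, cols: B)."""
    k_a = fit.models[fit.channels[0]].clusterer.n_clusters
    k_b = fit.models[fit.channels[1]].clusterer.n_clusters
    groups = fit.enrichment["group"].to_numpy().reshape(k_a, k_b)
    return pd.DataFrame(groups,
                        index=[f"{fit.channels[0]}_{i}" for i in range(k_a)],
                        columns=[f"{fit.channels[1]}_{j}" for j in range(k_b)])
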
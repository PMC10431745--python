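"""Sensor-space searchlight of the cross-decoding analysis.

For every magnetometer, the cross-decoding analysis is repeated on that
channel's neighborhood (the channel plus its 14 nearest magnetometers by
layout distance), keeping same-time (diagonal) accuracies only.  The 50
diagonal accuracies are averaged into consecutive 50-ms clusters, giving
a channels x 10 map per subject per condition.  Object-based scene
facilitation is then tested per time cluster: a paired sign-flip TFCE
test of scene-with-object minus scene-alone over the channel dimension,
on the symmetrized mutual-neighborhood channel graph.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .adjacency import Adjacency
from .containers import EpochsSet
from .decoding import DecoderConfig, category_labels, train_lda
from .inference import InferenceConfig, PermutationResult, paired_contrast
from .layout import SensorLayout


@dataclass
class SearchlightConfig:
    neighborhood_size: int = 15  # channels per searchlight, center included
    time_cluster_ms: float = 50.0
    conditions_compared: tuple[str, str] = ("scene_with_object", "scene")

    def __post_init__(self) -> None:
        if self.neighborhood_size < 1:
            raise ValueError("neighborhood_size must be >= 1")
        if self.time_cluster_ms <= 0:
            raise ValueError("time_cluster_ms must be > 0")


def channel_neighborhoods(
    layout: SensorLayout, k: int = 15
) -> tuple[dict[str, list[str]], Adjacency]:
    """k-nearest-channel searchlight neighborhoods and their graph.

    The neighborhood of channel c is c plus its k-1 nearest magnetometers
    by Euclidean distance in layout coordinates (ties broken by channel
    id).  The returned adjacency connects channels that appear in each
    other's neighborhoods, symmetrized — the spatial connectivity used
    for sensor-map TFCE.
    """
    ids = layout.magnetometer_ids
    n = len(ids)
    if k > n:
        raise ValueError(f"neighborhood size {k} exceeds {n} channels")
    pos = layout.positions(ids)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    neighborhoods: dict[str, list[str]] = {}
    neighbor_lists: list[list[int]] = []
    for i in range(n):
        order = sorted(range(n), key=lambda j: (d[i, j], ids[j]))
        members = order[:k]
        if i not in members:  # distance ties could push the center out
            members = [i] + members[: k - 1]
        neighborhoods[ids[i]] = [ids[j] for j in members]
        neighbor_lists.append([j for j in members if j != i])
    return neighborhoods, Adjacency.from_neighbors(neighbor_lists)


def n_time_clusters(times_ms: np.ndarray, cluster_ms: float) -> int:
    bin_ms = float(times_ms[1] - times_ms[0])
    span = times_ms.size * bin_ms
    if span % cluster_ms or cluster_ms % bin_ms:
        raise ValueError(
            f"window of {span} ms is not divisible into {cluster_ms}-ms clusters"
        )
    return int(round(span / cluster_ms))


def _diagonal_accuracies(
    train: EpochsSet,
    y_train: np.ndarray,
    test: EpochsSet,
    y_test: np.ndarray,
    channel_idx: np.ndarray,
    config: DecoderConfig,
) -> np.ndarray:
    """Same-time decoding accuracy per bin on a channel subset."""
    n_t = train.n_times
    acc = np.empty(n_t)
    Xtr = train.data[:, channel_idx, :]
    Xte = test.data[:, channel_idx, :]
    for t in range(n_t):
        model = train_lda(Xtr[:, :, t], y_train, config)
        scores = Xte[:, :, t] @ model.weights + model.bias
        c0, c1 = model.class_labels
        pred = np.where(scores > 0, c1, c0)
        acc[t] = np.mean(pred == y_test)
    return acc


def searchlight_decode(
    localizer: tuple[EpochsSet, pd.DataFrame],
    main: tuple[EpochsSet, pd.DataFrame],
    layout: SensorLayout,
    decoder_config: DecoderConfig | None = None,
    sl_config: SearchlightConfig | None = None,
) -> dict[str, np.ndarray]:
    """Whole-scalp searchlight maps for one subject.

    Inputs must be preprocessed with **all** magnetometers retained.
    Returns one ``(n_channels, n_clusters)`` accuracy map per compared
    condition, channel rows in layout order.
    """
    decoder_config = decoder_config or DecoderConfig()
    sl_config = sl_config or SearchlightConfig()
    loc_epochs, loc_table = localizer
    main_epochs, main_table = main
    ids = layout.magnetometer_ids
    if loc_epochs.channel_ids != ids or main_epochs.channel_ids != ids:
        raise ValueError("searchlight inputs must carry all magnetometers in layout order")

    neighborhoods, _ = channel_neighborhoods(layout, sl_config.neighborhood_size)
    index = {c: i for i, c in enumerate(ids)}
    n_clusters = n_time_clusters(loc_epochs.times_ms, sl_config.time_cluster_ms)
    bins_per_cluster = loc_epochs.n_times // n_clusters

    y_loc = category_labels(loc_table)
    maps: dict[str, np.ndarray] = {}
    for cond in sl_config.conditions_compared:
        sel = main_table["condition"].to_numpy() == cond
        if not sel.any():
            raise ValueError(f"main experiment lacks condition {cond!r}")
        test = main_epochs.select_trials(sel)
        y_test = category_labels(main_table.loc[sel])
        out = np.empty((len(ids), n_clusters))
        for c, cid in enumerate(ids):
            idx = np.array([index[m] for m in neighborhoods[cid]])
            diag = _diagonal_accuracies(
                loc_epochs, y_loc, test, y_test, idx, decoder_config
            )
            out[c] = diag.reshape(n_clusters, bins_per_cluster).mean(axis=1)
        maps[cond] = out
    return maps


def searchlight_contrast(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    adjacency: Adjacency,
    config: InferenceConfig | None = None,
) -> list[PermutationResult]:
    """Paired facilitation test per time cluster.

    ``maps_a``/``maps_b`` are subjects x channels x clusters.  Each of
    the clusters is tested independently (its own max-TFCE null) with a
    paired sign-flip test over channels, h0 = 0; the per-cluster seed is
    derived from the config seed so results are reproducible and
    independent of cluster order.
    """
    config = config or InferenceConfig()
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("need paired subjects x channels x clusters maps")
    results = []
    for k in range(a.shape[2]):
        seed_k = np.random.SeedSequence(config.seed, spawn_key=(k,)).generate_state(1)[0]
        cfg = replace(config, h0=0.0, seed=int(seed_k) % (2**31))
        results.append(paired_contrast(a[:, :, k], b[:, :, k], adjacency, cfg))
    return results
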
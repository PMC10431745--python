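"""Epoch preprocessing: one-back removal, detrending, exemplar
averaging, temporal smoothing and channel selection.

The canonical order is::

    drop_onebacks -> detrend_demean -> (decimate_to_grid) ->
    average_exemplars -> smooth_time -> select_channels

All operations are deterministic.  Smoothing uses truncated (shrinking)
windows at the epoch edges rather than padding — no data is invented
outside the 0–500 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import EpochsSet, check_aligned
from .layout import SensorLayout


@dataclass
class PreprocessConfig:
    smoothing_radius_bins: int = 2  # +/- 20 ms at 10-ms bins
    detrend_order: int = 1  # 0 = demean only, 1 = remove linear trend
    channel_scope: str = "left-posterior"

    def __post_init__(self) -> None:
        if self.smoothing_radius_bins < 0:
            raise ValueError("smoothing_radius_bins must be >= 0")
        if self.detrend_order not in (0, 1):
            raise ValueError("detrend_order must be 0 or 1")


def drop_onebacks(
    epochs: EpochsSet, table: pd.DataFrame
) -> tuple[EpochsSet, pd.DataFrame]:
    """Discard one-back target trials from data and metadata, order kept."""
    check_aligned(epochs, table)
    keep = ~table["is_oneback"].to_numpy(dtype=bool)
    return epochs.select_trials(keep), table.loc[keep].reset_index(drop=True)


def detrend_demean(epochs: EpochsSet, order: int = 1) -> EpochsSet:
    """Remove the best-fit polynomial of the given order per trial per channel."""
    if order not in (0, 1):
        raise ValueError("order must be 0 (demean) or 1 (linear detrend)")
    data = epochs.data
    if order == 0:
        out = data - data.mean(axis=2, keepdims=True)
    else:
        if epochs.n_times < 2:
            raise ValueError("linear detrend needs >= 2 time bins")
        t = epochs.times_ms - epochs.times_ms.mean()
        slope = (data * t).sum(axis=2, keepdims=True) / (t**2).sum()
        out = data - data.mean(axis=2, keepdims=True) - slope * t
    return replace(epochs, data=out)


def average_exemplars(
    epochs: EpochsSet, table: pd.DataFrame
) -> tuple[EpochsSet, pd.DataFrame]:
    """Average all repetitions of each (condition, category, exemplar).

    One-back targets must already have been dropped.  The output table
    has one row per unique triple, in first-appearance order, with an
    ``n_reps`` repetition count.
    """
    check_aligned(epochs, table)
    if table["is_oneback"].any():
        raise ValueError("drop one-back trials before averaging exemplars")
    keys = list(zip(table["condition"], table["category"], table["exemplar_id"]))
    order: dict[tuple, int] = {}
    for k in keys:
        order.setdefault(k, len(order))
    group = np.array([order[k] for k in keys])
    n_groups = len(order)
    sums = np.zeros((n_groups,) + epochs.data.shape[1:])
    np.add.at(sums, group, epochs.data)
    counts = np.bincount(group, minlength=n_groups)
    avg = sums / counts[:, None, None]
    rows = pd.DataFrame(
        [k for k in order], columns=["condition", "category", "exemplar_id"]
    )
    rows["n_reps"] = counts
    return replace(epochs, data=avg), rows


def smooth_time(epochs: EpochsSet, radius_bins: int = 2) -> EpochsSet:
    """Boxcar smoothing: each bin becomes the mean over bins within
    ``+/- radius_bins``, with windows truncated at the epoch edges."""
    if radius_bins < 0:
        raise ValueError("radius_bins must be >= 0")
    if radius_bins == 0:
        return epochs.copy()
    n_t = epochs.n_times
    csum = np.concatenate(
        [np.zeros(epochs.data.shape[:2] + (1,)), np.cumsum(epochs.data, axis=2)],
        axis=2,
    )
    lo = np.maximum(np.arange(n_t) - radius_bins, 0)
    hi = np.minimum(np.arange(n_t) + radius_bins, n_t - 1)
    out = (csum[:, :, hi + 1] - csum[:, :, lo]) / (hi - lo + 1)
    return replace(epochs, data=out)


def select_channels(
    epochs: EpochsSet, layout: SensorLayout, scope: str = "left-posterior"
) -> EpochsSet:
    """Restrict the channel axis to a layout scope, in layout order."""
    wanted = layout.channel_ids_for_scope(scope)  # layout order is canonical
    present = set(epochs.channel_ids)
    missing = [c for c in wanted if c not in present]
    if missing:
        raise KeyError(f"epochs lack requested channels: {missing[:5]}")
    if wanted == epochs.channel_ids:
        return epochs.copy()
    return epochs.select_channel_ids(wanted)


def decimate_to_grid(raw: EpochsSet, factor: int) -> EpochsSet:
    """Downsample by block means: each output bin is the mean of
    ``factor`` consecutive input samples (e.g. 1 kHz -> 100 Hz)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n_t = raw.n_times
    if n_t % factor:
        raise ValueError(f"epoch length {n_t} not divisible by factor {factor}")
    shape = raw.data.shape[:2] + (n_t // factor, factor)
    out = raw.data.reshape(shape).mean(axis=3)
    return replace(raw, data=out, times_ms=raw.times_ms[::factor].copy())


def preprocess_subject(
    epochs: EpochsSet,
    table: pd.DataFrame,
    layout: SensorLayout,
    config: PreprocessConfig | None = None,
) -> tuple[EpochsSet, pd.DataFrame]:
    """Full preprocessing chain in the canonical order."""
    config = config or PreprocessConfig()
    epochs, table = drop_onebacks(epochs, table)
    epochs = detrend_demean(epochs, config.detrend_order)
    epochs, table = average_exemplars(epochs, table)
    epochs = smooth_time(epochs, config.smoothing_radius_bins)
    epochs = select_channels(epochs, layout, config.channel_scope)
    return epochs, table
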
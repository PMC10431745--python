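"""Core data containers: epoched sensor data and trial metadata.

The universal currency of the pipeline is an :class:`EpochsSet` — a
``trials x channels x time`` array on a uniform 10-ms time grid — aligned
row-for-row with a trial-metadata table (condition, category, exemplar,
run, one-back flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: Column order of a trial table as written to CSV.
TRIAL_COLUMNS = [
    "trial_index",
    "run",
    "condition",
    "category",
    "exemplar_id",
    "is_oneback",
    "iti_ms",
]


@dataclass
class EpochsSet:
    """Epoched sensor data for one subject.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_times)`` in arbitrary
        field units.
    times_ms
        Bin-start times in milliseconds, strictly increasing with uniform
        spacing (default grid: 0, 10, ..., 490).
    channel_ids
        One label per channel, aligned with axis 1 of ``data``.
    subject_id
        Free-form subject label.
    """

    data: np.ndarray
    times_ms: np.ndarray
    channel_ids: list[str]
    subject_id: str = "sub-00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        self.channel_ids = [str(c) for c in self.channel_ids]
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[1] != len(self.channel_ids):
            raise ValueError(
                f"channel axis ({self.data.shape[1]}) does not match "
                f"channel_ids ({len(self.channel_ids)})"
            )
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis does not match times_ms")
        if self.times_ms.size > 1:
            steps = np.diff(self.times_ms)
            if not np.all(steps > 0):
                raise ValueError("times_ms must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValueError("times_ms must be uniformly spaced")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def bin_ms(self) -> float:
        if self.times_ms.size < 2:
            raise ValueError("need >= 2 bins to infer bin width")
        return float(self.times_ms[1] - self.times_ms[0])

    def copy(self) -> "EpochsSet":
        return replace(
            self,
            data=self.data.copy(),
            times_ms=self.times_ms.copy(),
            channel_ids=list(self.channel_ids),
        )

    def select_trials(self, index: np.ndarray) -> "EpochsSet":
        return replace(self, data=self.data[np.asarray(index)])

    def select_channel_ids(self, ids: list[str]) -> "EpochsSet":
        pos = {c: i for i, c in enumerate(self.channel_ids)}
        missing = [c for c in ids if c not in pos]
        if missing:
            raise KeyError(f"channels not present in epochs: {missing[:5]}")
        idx = [pos[c] for c in ids]
        return replace(self, data=self.data[:, idx, :], channel_ids=list(ids))

    # -- persistence ------------------------------------------------------

    def to_hdf5(self, path: str | Path) -> None:
        """Write datasets /data, /times_ms, /channel_ids and subject_id attr."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times_ms", data=self.times_ms)
            f.create_dataset(
                "channel_ids",
                data=np.array(self.channel_ids, dtype=h5py.string_dtype()),
            )
            f.attrs["subject_id"] = self.subject_id

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EpochsSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                times_ms=f["times_ms"][()],
                channel_ids=[c.decode() if isinstance(c, bytes) else str(c)
                             for c in f["channel_ids"][()]],
                subject_id=str(f.attrs.get("subject_id", "sub-00")),
            )


def check_aligned(epochs: EpochsSet, table: pd.DataFrame) -> None:
    """Reject epochs/table pairs whose row counts disagree."""
    if epochs.n_trials != len(table):
        raise ValueError(
            f"epochs have {epochs.n_trials} trials but table has "
            f"{len(table)} rows"
        )


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "is_oneback" in table.columns:
        table["is_oneback"] = table["is_oneback"].astype(bool)
    return table


def from_mne_epochs(epochs, subject_id: str = "sub-00") -> EpochsSet:
    """Convert an ``mne.Epochs``-like object, keeping magnetometers only.

    Times are converted from seconds to a milliseconds grid.  Requires the
    optional ``mne`` dependency.
    """
    import mne  # local import: optional dependency

    picks = mne.pick_types(epochs.info, meg="mag")
    if picks.size == 0:
        raise ValueError("no magnetometer channels found")
    data = epochs.get_data()[:, picks, :]
    names = [epochs.ch_names[i] for i in picks]
    return EpochsSet(
        data=data,
        times_ms=np.asarray(epochs.times) * 1000.0,
        channel_ids=names,
        subject_id=subject_id,
    )
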
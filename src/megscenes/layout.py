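"""Flattened-helmet sensor layout.

The layout mirrors a 306-channel system: 102 magnetometers arranged on
concentric rings of a flattened helmet (arbitrary units, +y anterior),
plus 204 planar gradiometers carried as metadata only — gradiometers
never enter decoding.  A designated left-posterior set of 24
magnetometers (the channel scope of the main decoding analyses) is
chosen by a deterministic coordinate rule: among channels with x < 0 and
y < 0, the 24 most posterior (smallest y, ties broken by channel id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LEFT_POSTERIOR_SIZE = 24

# ring populations summing to 102; half-step angular offsets keep every
# sensor off the x/y axes so hemisphere/region tags are unambiguous
_RING_COUNTS = (8, 12, 16, 20, 24, 22)
_RING_RADII = (0.18, 0.34, 0.50, 0.66, 0.82, 0.98)


@dataclass
class SensorLayout:
    """Channel metadata table with flattened 2-D helmet positions.

    ``table`` columns: channel_id, x, y, sensor_kind, hemisphere, region,
    in_left_posterior_set.
    """

    table: pd.DataFrame

    @property
    def magnetometers(self) -> pd.DataFrame:
        return self.table[self.table.sensor_kind == "magnetometer"]

    @property
    def magnetometer_ids(self) -> list[str]:
        return list(self.magnetometers.channel_id)

    @property
    def left_posterior_ids(self) -> list[str]:
        mags = self.magnetometers
        return list(mags.channel_id[mags.in_left_posterior_set])

    def positions(self, channel_ids: list[str]) -> np.ndarray:
        sub = self.table.set_index("channel_id").loc[channel_ids]
        return sub[["x", "y"]].to_numpy(dtype=float)

    def channel_ids_for_scope(self, scope: str) -> list[str]:
        if scope in ("all", "all-channels"):
            return self.magnetometer_ids
        if scope in ("left-posterior", "left_posterior"):
            return self.left_posterior_ids
        raise ValueError(f"unknown channel scope: {scope!r}")


def make_sensor_layout(n_magnetometers: int = 102) -> SensorLayout:
    """Build the deterministic flattened-helmet layout.

    Magnetometers fill concentric rings outward; each magnetometer site
    also hosts two orthogonal planar gradiometers (metadata only).  With
    fewer than 24 magnetometers the left-posterior set cannot exist, so
    such layouts are rejected.
    """
    if n_magnetometers < LEFT_POSTERIOR_SIZE:
        raise ValueError(
            f"need >= {LEFT_POSTERIOR_SIZE} magnetometers to define the "
            f"left-posterior set, got {n_magnetometers}"
        )
    xs, ys = [], []
    for count, radius in zip(_RING_COUNTS, _RING_RADII):
        theta = 2 * np.pi * (np.arange(count) + 0.5) / count
        xs.extend(radius * np.sin(theta))
        ys.extend(radius * np.cos(theta))
        if len(xs) >= n_magnetometers:
            break
    while len(xs) < n_magnetometers:  # overflow rings for large requests
        radius = 0.98 + 0.16 * (len(xs) // 102)
        count = min(26, n_magnetometers - len(xs))
        theta = 2 * np.pi * (np.arange(count) + 0.25) / count
        xs.extend(radius * np.sin(theta))
        ys.extend(radius * np.cos(theta))
    xs = np.asarray(xs[:n_magnetometers])
    ys = np.asarray(ys[:n_magnetometers])

    ids = [f"MAG{i + 1:03d}" for i in range(n_magnetometers)]
    hemisphere = np.where(xs < 0, "left", "right")
    region = np.where(ys < 0, "posterior", "anterior")

    # left-posterior set: the 24 most posterior of the left-posterior quadrant
    candidates = sorted(
        (i for i in range(n_magnetometers) if xs[i] < 0 and ys[i] < 0),
        key=lambda i: (ys[i], ids[i]),
    )
    if len(candidates) < LEFT_POSTERIOR_SIZE:
        raise ValueError(
            "layout has too few left-posterior magnetometers; "
            f"got {len(candidates)}, need {LEFT_POSTERIOR_SIZE}"
        )
    lp = np.zeros(n_magnetometers, dtype=bool)
    lp[candidates[:LEFT_POSTERIOR_SIZE]] = True

    rows = {
        "channel_id": ids,
        "x": xs,
        "y": ys,
        "sensor_kind": "magnetometer",
        "hemisphere": hemisphere,
        "region": region,
        "in_left_posterior_set": lp,
    }
    mag = pd.DataFrame(rows)

    # co-located planar gradiometer pairs: metadata only, tiny offsets keep
    # positions unique per channel
    grads = []
    for suffix, dx in (("A", 0.004), ("B", -0.004)):
        g = mag.copy()
        g["channel_id"] = [f"GRAD{i + 1:03d}{suffix}" for i in range(n_magnetometers)]
        g["x"] = g["x"] + dx
        g["sensor_kind"] = "gradiometer"
        g["in_left_posterior_set"] = False
        grads.append(g)
    table = pd.concat([mag] + grads, ignore_index=True)
    if table.duplicated(["x", "y"]).any():
        raise AssertionError("sensor positions must be unique")
    return SensorLayout(table=table)
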
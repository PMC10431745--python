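"""Group-level permutation inference with TFCE.

The stack implements one-sample random-effects inference over subject
maps (accuracy matrices, diagonal time courses, or sensor maps):

1. a one-sample t statistic per map element against the null value
   (0.5 for accuracy vs. chance, 0 for paired differences);
2. threshold-free cluster enhancement (TFCE) of the t map —
   ``TFCE(e) = sum over thresholds h = dh, 2dh, ... <= t(e) of
   extent(e, h)^E * h^H * dh`` with extent the size of the connected
   supra-threshold component containing e;
3. a sign-flip permutation null: each permutation flips the sign of each
   subject's entire centered map with probability 1/2, and records the
   maximum TFCE value (within the analysis mask), which corrects the
   resulting p-values for multiple comparisons family-wise.

Defaults follow common practice for this statistic: step dh = 0.1 on
the t scale, extent exponent E = 0.5, height exponent H = 2, 1,000
permutations, one-sided positive tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .adjacency import Adjacency

#: sentinel for infinite t at zero-variance elements (degenerate inputs)
T_SENTINEL = 1e12


@dataclass
class InferenceConfig:
    n_permutations: int = 1000
    alpha: float = 0.05
    tfce_dh: float = 0.1
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    h0: float = 0.5  # null value: 0.5 for accuracy, 0 for paired differences
    tail: str = "one-sided-positive"  # or "two-sided"
    #: |t| values are clamped here before TFCE (bounds the threshold ladder)
    stat_clamp: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tfce_dh <= 0:
            raise ValueError("tfce_dh must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tail not in ("one-sided-positive", "two-sided"):
            raise ValueError(f"unknown tail {self.tail!r}")


@dataclass
class PermutationResult:
    observed_stat: np.ndarray
    observed_tfce: np.ndarray
    null_max_tfce: np.ndarray
    p_corrected: np.ndarray  # NaN outside the mask
    significant_mask: np.ndarray
    mask_applied: np.ndarray | None
    alpha: float
    n_permutations: int


def group_tstat(subject_maps: np.ndarray, h0: float = 0.0) -> np.ndarray:
    """One-sample t = (mean - h0) / (sd / sqrt(n)), sd with denominator n-1.

    Zero-variance elements get ``+/- T_SENTINEL`` (or 0 when the mean
    equals h0 exactly).
    """
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    mean = maps.mean(axis=0) - h0
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    if np.any(degenerate):
        t = np.where(degenerate, np.sign(mean) * T_SENTINEL, t)
    return t


def _positive_tfce(
    values: np.ndarray, adjacency: Adjacency, dh: float, E: float, H: float
) -> np.ndarray:
    """TFCE of a non-negative-tail map, flattened.

    Thresholds between two consecutive distinct map values share the
    same supra-threshold set, so connected components are computed once
    per distinct positive value and the per-step weights ``h^H * dh``
    are accumulated analytically over each interval.
    """
    out = np.zeros(values.size)
    pos = values > 0
    if not pos.any():
        return out
    distinct = np.unique(values[pos])[::-1]  # descending
    for k, v in enumerate(distinct):
        lower = distinct[k + 1] if k + 1 < distinct.size else 0.0
        j_hi = int(np.floor(v / dh + 1e-9))
        j_lo = int(np.floor(lower / dh + 1e-9)) + 1
        if j_hi < j_lo:
            continue
        steps = dh * np.arange(j_lo, j_hi + 1)
        weight = dh * float(np.sum(steps**H))
        mask = values >= v
        labels, sizes = adjacency.component_labels(mask)
        active = np.flatnonzero(mask)
        out[active] += sizes[labels[active]] ** E * weight
    return out


def tfce(
    stat_map: np.ndarray, adjacency: Adjacency, config: InferenceConfig | None = None
) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic map.

    Under the one-sided-positive tail, negative values contribute (and
    receive) nothing.  Under the two-sided tail the transform is applied
    to ``|stat|`` and the sign restored.  Non-finite or sentinel values
    are clamped to ``config.stat_clamp`` first.
    """
    config = config or InferenceConfig()
    s = np.asarray(stat_map, dtype=float)
    if s.size != adjacency.n_elements:
        raise ValueError("stat map size does not match adjacency")
    shape = s.shape
    s = np.clip(np.nan_to_num(s.ravel()), -config.stat_clamp, config.stat_clamp)
    if config.tail == "two-sided":
        out = np.sign(s) * _positive_tfce(
            np.abs(s), adjacency, config.tfce_dh, config.tfce_E, config.tfce_H
        )
    else:
        out = _positive_tfce(s, adjacency, config.tfce_dh, config.tfce_E, config.tfce_H)
    return out.reshape(shape)


def _canonical_order(maps_flat: np.ndarray) -> np.ndarray:
    """Deterministic subject ordering so permutation p-values depend on
    neither the input row order nor the labelling of map elements: rows
    are keyed by their sorted value multiset, lexicographically."""
    keys = np.sort(maps_flat, axis=1)
    return np.lexsort(keys.T[::-1])


def signflip_permutation(
    subject_maps: np.ndarray,
    adjacency: Adjacency,
    config: InferenceConfig | None = None,
    mask: np.ndarray | None = None,
) -> PermutationResult:
    """Max-TFCE sign-flip permutation test over subject maps.

    ``subject_maps`` is subjects x elements (any trailing shape).  Each
    permutation flips the sign of each subject's whole centered map
    (map - h0) with probability 1/2, recomputes t and TFCE, and records
    the maximum TFCE within the mask.  Corrected p-values are
    ``(1 + #{perm max >= observed}) / (1 + n_permutations)``; the
    smallest attainable p is therefore ``1 / (n_permutations + 1)``.
    """
    config = config or InferenceConfig()
    maps = np.asarray(subject_maps, dtype=float)
    n_subj = maps.shape[0]
    map_shape = maps.shape[1:]
    flat = maps.reshape(n_subj, -1)
    if flat.shape[1] != adjacency.n_elements:
        raise ValueError("map size does not match adjacency")

    if mask is not None:
        mask = np.asarray(mask, dtype=bool).reshape(map_shape)
        if not mask.any():
            warnings.warn("empty analysis mask: nothing can be significant", stacklevel=2)
    centered = flat - config.h0

    t_obs = group_tstat(flat, config.h0).reshape(map_shape)
    tfce_obs = tfce(t_obs, adjacency, config)

    # flip signs in a canonical subject order: the test statistic is
    # symmetric in subjects, so this makes p-values exchangeable exactly
    order = _canonical_order(centered)
    canon = centered[order]

    rng = np.random.default_rng(config.seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(config.n_permutations, n_subj))
    # sum of squares is sign-invariant: only the mean changes per permutation
    ssq = np.einsum("se,se->e", canon, canon)
    mean_perm = signs @ canon / n_subj  # (n_perm, n_elem)
    var_perm = (ssq[None, :] - n_subj * mean_perm**2) / (n_subj - 1)
    var_perm = np.maximum(var_perm, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = mean_perm / np.sqrt(var_perm / n_subj)
    t_perm = np.where(var_perm == 0, np.sign(mean_perm) * T_SENTINEL, t_perm)

    flat_mask = None if mask is None else mask.ravel()
    null_max = np.empty(config.n_permutations)
    for p in range(config.n_permutations):
        tf = tfce(t_perm[p].reshape(map_shape), adjacency, config).ravel()
        if config.tail == "two-sided":
            tf = np.abs(tf)
        inside = tf if flat_mask is None else tf[flat_mask]
        null_max[p] = inside.max() if inside.size else 0.0

    obs_flat = tfce_obs.ravel()
    obs_cmp = np.abs(obs_flat) if config.tail == "two-sided" else obs_flat
    sorted_null = np.sort(null_max)
    exceed = config.n_permutations - np.searchsorted(sorted_null, obs_cmp, side="left")
    p_corr = (1.0 + exceed) / (1.0 + config.n_permutations)
    if flat_mask is not None:
        p_corr = np.where(flat_mask, p_corr, np.nan)
    p_corr = p_corr.reshape(map_shape)
    with np.errstate(invalid="ignore"):
        significant = p_corr < config.alpha
    significant = np.nan_to_num(significant).astype(bool)
    return PermutationResult(
        observed_stat=t_obs,
        observed_tfce=tfce_obs,
        null_max_tfce=null_max,
        p_corrected=p_corr,
        significant_mask=significant,
        mask_applied=mask,
        alpha=config.alpha,
        n_permutations=config.n_permutations,
    )


def build_temporal_mask(localizer_result: PermutationResult) -> np.ndarray:
    """Temporal mask for cross-decoding tests: the cells where intact-scene
    decoding was itself significant."""
    return localizer_result.significant_mask.copy()


def diagonal_mask(grid_mask: np.ndarray) -> np.ndarray:
    """Restrict a time x time mask to its diagonal, for time-course tests."""
    m = np.asarray(grid_mask, dtype=bool)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("need a square time x time mask")
    return np.diag(m).copy()


def paired_contrast(
    timecourses_a: np.ndarray,
    timecourses_b: np.ndarray,
    adjacency: Adjacency,
    config: InferenceConfig | None = None,
    mask: np.ndarray | None = None,
) -> PermutationResult:
    """Paired condition difference: sign-flip test on per-subject a - b
    maps with h0 = 0 (subjects must be aligned across conditions)."""
    config = config or InferenceConfig()
    a = np.asarray(timecourses_a, dtype=float)
    b = np.asarray(timecourses_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired conditions must have identical subjects x shape")
    from dataclasses import replace

    return signflip_permutation(a - b, adjacency, replace(config, h0=0.0), mask=mask)
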
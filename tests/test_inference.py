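"""TFCE and sign-flip permutation inference: analytic values, independent
oracles, exchangeability, masking."""

import numpy as np
import pytest
from scipy import stats

import megscenes as m
from megscenes.inference import T_SENTINEL


# ---------------------------------------------------------------- t stat


def test_tstat_zero_at_null():
    maps = np.full((6, 10), 0.5)
    np.testing.assert_array_equal(m.group_tstat(maps, h0=0.5), 0.0)


def test_tstat_hand_arithmetic():
    maps = np.array([[0.6], [0.7], [0.6], [0.7]])
    t = m.group_tstat(maps, h0=0.5)[0]
    assert t == pytest.approx(0.15 / (np.std([0.6, 0.7, 0.6, 0.7], ddof=1) / 2))
    assert t == pytest.approx(5.196, abs=1e-3)


def test_tstat_matches_scipy(rng):
    maps = rng.standard_normal((12, 40)) + 0.3
    t = m.group_tstat(maps, h0=0.1)
    ref = stats.ttest_1samp(maps, popmean=0.1, axis=0).statistic
    np.testing.assert_allclose(t, ref, atol=1e-12)


def test_tstat_zero_variance_sentinel():
    maps = np.tile([[0.8, 0.5]], (5, 1))
    t = m.group_tstat(maps, h0=0.5)
    assert t[0] == T_SENTINEL
    assert t[1] == 0.0


# ------------------------------------------------------------------ TFCE


def tfce_oracle(stat, neighbors, dh, E=0.5, H=2.0):
    """Independent per-threshold implementation: explicit threshold loop
    with breadth-first connected components."""
    stat = np.asarray(stat, float)
    n = stat.size
    out = np.zeros(n)
    h = dh
    while h <= stat.max() + 1e-12:
        active = stat >= h
        seen = np.zeros(n, bool)
        for start in range(n):
            if not active[start] or seen[start]:
                continue
            comp, queue = [], [start]
            seen[start] = True
            while queue:
                node = queue.pop()
                comp.append(node)
                for nb in neighbors(node):
                    if active[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
            for node in comp:
                out[node] += len(comp) ** E * h**H * dh
        h += dh
    return out


def test_tfce_plateau_analytic():
    """4-bin plateau of height 1.0: each bin scores sqrt(4)*0.1*sum((0.1 j)^2)
    over j=1..10, i.e. 0.77."""
    stat = np.zeros(12)
    stat[4:8] = 1.0
    out = m.tfce(stat, m.Adjacency.chain(12))
    np.testing.assert_allclose(out[4:8], 0.77, rtol=1e-12)
    assert np.all(out[:4] == 0) and np.all(out[8:] == 0)


def test_tfce_zero_map():
    np.testing.assert_array_equal(m.tfce(np.zeros(20), m.Adjacency.chain(20)), 0.0)


@pytest.mark.parametrize("kind", ["chain", "grid", "graph"])
def test_tfce_matches_bruteforce_oracle_same_step(kind, rng):
    """Interval-grouped implementation agrees exactly with an explicit
    per-threshold BFS oracle at the same dh."""
    if kind == "chain":
        adj = m.Adjacency.chain(30)
        stat = rng.normal(1.0, 1.5, 30)
    elif kind == "grid":
        adj = m.Adjacency.grid((6, 7))
        stat = rng.normal(1.0, 1.5, 42)
    else:
        lists = [[(i + 1) % 15, (i + 7) % 15] for i in range(15)]
        adj = m.Adjacency.from_neighbors(lists)
        stat = rng.normal(1.0, 1.5, 15)
    ours = m.tfce(stat, adj)
    ref = tfce_oracle(stat.ravel(), adj.neighbors, dh=0.1)
    np.testing.assert_allclose(ours.ravel(), ref, rtol=1e-9, atol=1e-12)


def test_tfce_step_converged_maps(rng):
    """On t-scale maps dominated by high thresholds, the 0.1-step ladder is
    within 1% of a 0.001-step Riemann-sum oracle."""
    stat = np.abs(rng.normal(0, 12, 25)) + 20.0
    adj = m.Adjacency.chain(25)
    ours = m.tfce(stat, adj)
    ref = tfce_oracle(stat, adj.neighbors, dh=0.001)
    np.testing.assert_allclose(ours, ref, rtol=0.01)


def test_tfce_monotone_in_map_height(rng):
    stat = np.abs(rng.normal(0, 2, 20))
    adj = m.Adjacency.chain(20)
    base = m.tfce(stat, adj)
    for idx in (0, 7, 19):
        raised = stat.copy()
        raised[idx] += 0.5
        assert np.all(m.tfce(raised, adj) >= base - 1e-12)


def test_tfce_two_sided_restores_sign():
    stat = np.zeros(10)
    stat[2:4] = 2.0
    stat[6:8] = -2.0
    cfg = m.InferenceConfig(tail="two-sided")
    out = m.tfce(stat, m.Adjacency.chain(10), cfg)
    assert np.all(out[2:4] > 0) and np.all(out[6:8] < 0)
    np.testing.assert_allclose(out[6:8], -out[2:4])


def test_adjacency_symmetry_and_components():
    adj = m.Adjacency.from_neighbors([[1], [0, 2], [1], []])
    for i in range(4):
        for j in adj.neighbors(i):
            assert i in adj.neighbors(j)
            assert j != i
    labels, sizes = adj.component_labels(np.array([True, True, False, True]))
    assert labels[0] == labels[1] != labels[3]
    assert sorted(sizes) == [1, 2]


# ------------------------------------------------- sign-flip permutation


def test_saturated_effect_min_p():
    """A huge homogeneous effect: every element significant at the smallest
    attainable p, 1/(n_permutations + 1)."""
    rng = np.random.default_rng(0)
    maps = rng.normal(0.7, 0.01, (28, 4))
    cfg = m.InferenceConfig(n_permutations=1000, seed=5)
    res = m.signflip_permutation(maps, m.Adjacency.chain(4), cfg)
    assert res.significant_mask.all()
    np.testing.assert_allclose(res.p_corrected, 1 / 1001)


def test_null_maps_mostly_nonsignificant(rng):
    maps = rng.normal(0.5, 0.05, (10, 20))
    cfg = m.InferenceConfig(n_permutations=200, seed=9)
    res = m.signflip_permutation(maps, m.Adjacency.chain(20), cfg)
    assert res.p_corrected.min() >= 1 / 201
    assert res.significant_mask.sum() <= 2


def test_reproducible_and_exchangeable(rng):
    maps = rng.normal(0.55, 0.1, (9, 15))
    cfg = m.InferenceConfig(n_permutations=150, seed=3)
    adj = m.Adjacency.chain(15)
    a = m.signflip_permutation(maps, adj, cfg)
    b = m.signflip_permutation(maps, adj, cfg)
    np.testing.assert_array_equal(a.p_corrected, b.p_corrected)
    np.testing.assert_array_equal(a.null_max_tfce, b.null_max_tfce)
    # permuting subject rows leaves p-values untouched
    c = m.signflip_permutation(maps[::-1], adj, cfg)
    np.testing.assert_array_equal(a.p_corrected, c.p_corrected)


def test_masked_inference(rng):
    maps = rng.normal(0.9, 0.02, (12, 10))  # strong effect everywhere
    mask = np.zeros(10, bool)
    mask[3:6] = True
    cfg = m.InferenceConfig(n_permutations=100, seed=1)
    res = m.signflip_permutation(maps, m.Adjacency.chain(10), cfg, mask=mask)
    assert res.significant_mask[3:6].all()
    assert not res.significant_mask[~mask].any()
    assert np.isnan(res.p_corrected[~mask]).all()


def test_empty_mask_warns(rng):
    maps = rng.normal(0.9, 0.02, (5, 6))
    with pytest.warns(UserWarning, match="empty"):
        res = m.signflip_permutation(
            maps,
            m.Adjacency.chain(6),
            m.InferenceConfig(n_permutations=50, seed=0),
            mask=np.zeros(6, bool),
        )
    assert not res.significant_mask.any()


def test_temporal_mask_and_diagonal():
    full = m.PermutationResult(
        observed_stat=np.zeros((5, 5)),
        observed_tfce=np.zeros((5, 5)),
        null_max_tfce=np.zeros(10),
        p_corrected=np.ones((5, 5)),
        significant_mask=np.eye(5, dtype=bool),
        mask_applied=None,
        alpha=0.05,
        n_permutations=10,
    )
    mask = m.build_temporal_mask(full)
    np.testing.assert_array_equal(mask, np.eye(5, dtype=bool))
    np.testing.assert_array_equal(m.diagonal_mask(mask), np.ones(5, bool))


def test_localizer_band_defines_mask(rng):
    """A planted diagonal band on the time x time grid yields a mask whose
    diagonal covers the band and excludes quiet bins."""
    n = 20
    maps = rng.normal(0.5, 0.03, (14, n, n))
    band = slice(6, 14)
    maps[:, band, band] += 0.2
    cfg = m.InferenceConfig(n_permutations=200, seed=4)
    res = m.signflip_permutation(maps, m.Adjacency.grid((n, n)), cfg)
    dm = m.diagonal_mask(m.build_temporal_mask(res))
    assert dm[6:14].all()
    assert not dm[:4].any() and not dm[16:].any()


def test_paired_contrast_properties(rng):
    a = rng.normal(0.6, 0.05, (8, 12))
    cfg = m.InferenceConfig(n_permutations=100, seed=2)
    adj = m.Adjacency.chain(12)
    same = m.paired_contrast(a, a.copy(), adj, cfg)
    np.testing.assert_array_equal(same.observed_stat, 0.0)
    assert not same.significant_mask.any()
    b = a + rng.normal(0, 0.05, a.shape)
    ab = m.paired_contrast(a, b, adj, cfg)
    ba = m.paired_contrast(b, a, adj, cfg)
    np.testing.assert_allclose(ab.observed_stat, -ba.observed_stat, atol=1e-10)


def test_config_validation():
    with pytest.raises(ValueError):
        m.InferenceConfig(tfce_dh=0.0)
    with pytest.raises(ValueError):
        m.InferenceConfig(n_permutations=0)
    with pytest.raises(ValueError):
        m.InferenceConfig(alpha=1.5)
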
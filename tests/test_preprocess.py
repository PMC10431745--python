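"""Preprocessing: one-back removal, detrending, averaging, smoothing,
channel selection, decimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import megscenes as m
from megscenes.containers import EpochsSet

from conftest import tiny_design


def epochs_for(table, n_channels=3, n_times=50, rng=None, subject="sub-00"):
    rng = rng or np.random.default_rng(0)
    return EpochsSet(
        data=rng.standard_normal((len(table), n_channels, n_times)),
        times_ms=10.0 * np.arange(n_times),
        channel_ids=[f"CH{i}" for i in range(n_channels)],
        subject_id=subject,
    )


@pytest.mark.parametrize(
    "design_fn,kept_per_run",
    [(m.main_experiment_design, 180), (m.localizer_design, 120)],
)
def test_drop_onebacks_counts(design_fn, kept_per_run):
    design = design_fn()
    table = m.build_trial_table(design, seed=0)
    epochs = epochs_for(table)
    clean, clean_table = m.drop_onebacks(epochs, table)
    assert len(clean_table) == design.n_runs * kept_per_run
    assert clean.n_trials == len(clean_table)
    assert not clean_table.is_oneback.any()


def test_drop_onebacks_identity_without_targets():
    table = m.build_trial_table(tiny_design(trials=6, n_exemplars=3), seed=0)
    epochs = epochs_for(table)
    clean, clean_table = m.drop_onebacks(epochs, table)
    np.testing.assert_array_equal(clean.data, epochs.data)
    pd.testing.assert_frame_equal(clean_table, table)


def test_drop_onebacks_misaligned_rejected():
    table = m.build_trial_table(tiny_design(trials=6, n_exemplars=3), seed=0)
    epochs = epochs_for(table.iloc[:-1])
    with pytest.raises(ValueError, match="rows"):
        m.drop_onebacks(epochs, table)


def test_detrend_constant_and_ramp():
    times = 10.0 * np.arange(50)
    const = EpochsSet(np.full((1, 1, 50), 3.7), times, ["a"])
    np.testing.assert_allclose(m.detrend_demean(const, order=0).data, 0, atol=1e-12)
    ramp = EpochsSet((2.0 * times - 5.0)[None, None, :], times, ["a"])
    np.testing.assert_allclose(m.detrend_demean(ramp, order=1).data, 0, atol=1e-9)


def test_detrend_matches_least_squares_oracle(rng):
    """Residual of ramp+bump equals the bump minus its own best linear fit."""
    times = 10.0 * np.arange(50)
    bump = np.exp(-0.5 * ((times - 250) / 40) ** 2)
    trace = 0.3 * times + 2.0 + bump
    epochs = EpochsSet(trace[None, None, :], times, ["a"])
    out = m.detrend_demean(epochs, order=1).data[0, 0]
    coef = np.polyfit(times, bump, 1)  # independent least-squares oracle
    expected = bump - np.polyval(coef, times)
    np.testing.assert_allclose(out, expected, atol=1e-9)


def test_detrend_single_bin_rejected():
    epochs = EpochsSet(np.ones((1, 1, 1)), np.array([0.0]), ["a"])
    with pytest.raises(ValueError):
        m.detrend_demean(epochs, order=1)


@pytest.mark.parametrize(
    "design_fn,n_rows,per_cell",
    [(m.main_experiment_design, 90, 15), (m.localizer_design, 120, 30)],
)
def test_average_exemplars_counts(design_fn, n_rows, per_cell):
    design = design_fn()
    table = m.build_trial_table(design, seed=2)
    epochs = epochs_for(table)
    clean, clean_table = m.drop_onebacks(epochs, table)
    avg, avg_table = m.average_exemplars(clean, clean_table)
    assert len(avg_table) == n_rows
    assert avg.n_trials == n_rows
    counts = avg_table.groupby(["condition", "category"]).size()
    assert (counts == per_cell).all()
    assert (avg_table.n_reps == design.n_runs * 30 // per_cell).all()


def test_average_exemplars_single_repetition_passthrough():
    table = m.build_trial_table(tiny_design(trials=3, n_exemplars=3), seed=0)
    epochs = epochs_for(table)
    avg, avg_table = m.average_exemplars(epochs, table)
    # one repetition each: values pass through, in first-appearance order
    for i, row in avg_table.iterrows():
        src = table[(table.exemplar_id == row.exemplar_id)
                    & (table.condition == row.condition)].index[0]
        np.testing.assert_array_equal(avg.data[i], epochs.data[src])


def test_average_exemplars_is_mean_of_repetitions(rng):
    table = m.build_trial_table(tiny_design(trials=6, n_exemplars=3, n_runs=2), seed=1)
    epochs = epochs_for(table, rng=rng)
    avg, avg_table = m.average_exemplars(epochs, table)
    row = avg_table.iloc[0]
    sel = (
        (table.condition == row.condition)
        & (table.category == row.category)
        & (table.exemplar_id == row.exemplar_id)
    ).to_numpy()
    np.testing.assert_allclose(avg.data[0], epochs.data[sel].mean(axis=0))
    assert row.n_reps == sel.sum()


def test_smooth_constant_unchanged():
    epochs = EpochsSet(np.full((2, 2, 30), 1.3), 10.0 * np.arange(30), ["a", "b"])
    np.testing.assert_allclose(m.smooth_time(epochs, 2).data, 1.3)


def test_smooth_interior_impulse():
    data = np.zeros((1, 1, 50))
    data[0, 0, 10] = 1.0
    epochs = EpochsSet(data, 10.0 * np.arange(50), ["a"])
    out = m.smooth_time(epochs, 2).data[0, 0]
    np.testing.assert_allclose(out[8:13], 0.2)
    assert np.all(out[:8] == 0) and np.all(out[13:] == 0)


def test_smooth_edge_truncation():
    data = np.zeros((1, 1, 50))
    data[0, 0, 0] = 1.0
    epochs = EpochsSet(data, 10.0 * np.arange(50), ["a"])
    out = m.smooth_time(epochs, 2).data[0, 0]
    np.testing.assert_allclose(out[:3], [1 / 3, 1 / 4, 1 / 5])
    assert np.all(out[3:] == 0)


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 5))
def test_smooth_preserves_interior_mass(radius):
    """Boxcar smoothing conserves total mass contributed by interior bins."""
    rng = np.random.default_rng(radius)
    data = np.zeros((1, 1, 40))
    data[0, 0, 15:25] = rng.standard_normal(10)
    epochs = EpochsSet(data, 10.0 * np.arange(40), ["a"])
    out = m.smooth_time(epochs, radius).data
    np.testing.assert_allclose(out.sum(), data.sum(), atol=1e-9)


def test_select_channels_left_posterior(layout102):
    table = m.build_trial_table(tiny_design(trials=2, n_exemplars=2), seed=0)
    epochs = epochs_for(table, n_channels=102)
    epochs.channel_ids = layout102.magnetometer_ids
    sel = m.select_channels(epochs, layout102, "left-posterior")
    assert sel.n_channels == 24
    assert sel.channel_ids == layout102.left_posterior_ids
    again = m.select_channels(sel, layout102, "left-posterior")
    np.testing.assert_array_equal(again.data, sel.data)
    full = m.select_channels(epochs, layout102, "all")
    np.testing.assert_array_equal(full.data, epochs.data)


def test_select_missing_channel_rejected(layout102):
    table = m.build_trial_table(tiny_design(trials=2, n_exemplars=2), seed=0)
    epochs = epochs_for(table, n_channels=5)
    with pytest.raises(KeyError):
        m.select_channels(epochs, layout102, "left-posterior")


def test_decimate_block_means(rng):
    raw = EpochsSet(
        rng.standard_normal((2, 3, 500)), 1.0 * np.arange(500), ["a", "b", "c"]
    )
    out = m.decimate_to_grid(raw, 10)
    assert out.n_times == 50
    # brute-force per-block oracle
    for t in range(50):
        np.testing.assert_allclose(
            out.data[:, :, t], raw.data[:, :, 10 * t : 10 * (t + 1)].mean(axis=2)
        )
    const = EpochsSet(np.full((1, 1, 500), 2.5), 1.0 * np.arange(500), ["a"])
    np.testing.assert_allclose(m.decimate_to_grid(const, 10).data, 2.5)
    with pytest.raises(ValueError, match="divisible"):
        m.decimate_to_grid(raw, 7)


def test_average_and_smooth_commute_for_equal_repetitions(rng):
    """Both operations are linear, so their order is irrelevant when every
    exemplar repeats equally often."""
    table = m.build_trial_table(tiny_design(trials=4, n_exemplars=2, n_runs=2), seed=3)
    epochs = epochs_for(table, rng=rng)
    a = m.smooth_time(m.average_exemplars(epochs, table)[0], 2)
    b = m.average_exemplars(m.smooth_time(epochs, 2), table)[0]
    np.testing.assert_allclose(a.data, b.data, atol=1e-12)
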
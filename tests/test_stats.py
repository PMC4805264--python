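"""Reliability statistics: ICC(3,1), Dice R12, sweeps, summary tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import dice_oracle, icc31_oracle

from netretest import (
    DegenerateInputError,
    SessionValueTable,
    SimulationConfig,
    dice_r12,
    icc31,
    network_reproducibility,
    run_in_memory,
    threshold_sweep,
)

WORKED = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])


def test_icc_worked_example_matches_hand_anova():
    res = icc31(WORKED)
    assert res.bms == pytest.approx(4.5, abs=1e-12)
    assert res.jms == pytest.approx(6.0, abs=1e-12)
    assert res.ems == pytest.approx(0.5, abs=1e-12)
    assert res.icc == pytest.approx(0.8, abs=1e-12)
    oracle = icc31_oracle(WORKED)
    for key in ("bms", "jms", "ems"):
        assert getattr(res, key) == pytest.approx(oracle[key], abs=1e-10)
    assert res.icc_raw == pytest.approx(oracle["icc"], abs=1e-10)


@given(
    n=st.integers(3, 10),
    k=st.integers(2, 4),
    seed=st.integers(0, 10_000),
)
def test_icc_agrees_with_brute_force_oracle(n, k, seed):
    y = np.random.default_rng(seed).normal(0, 2, size=(n, k)) + np.arange(n)[:, None]
    res = icc31(y)
    oracle = icc31_oracle(y)
    assert res.icc_raw == pytest.approx(oracle["icc"], abs=1e-10)
    assert res.bms == pytest.approx(oracle["bms"], abs=1e-10)
    assert res.ems == pytest.approx(oracle["ems"], abs=1e-10)


def test_identical_sessions_give_perfect_icc():
    y = np.column_stack([np.arange(5.0), np.arange(5.0)])
    res = icc31(y)
    assert res.ems == pytest.approx(0.0, abs=1e-12)
    assert res.icc == pytest.approx(1.0)


@pytest.mark.parametrize("shift", [-3.0, 0.01, 17.5])
def test_fixed_session_effect_leaves_icc_unchanged(shift, rng):
    y = rng.normal(0, 1, size=(8, 2)) + rng.normal(0, 2, size=(8, 1))
    base = icc31(y).icc_raw
    shifted = y.copy()
    shifted[:, 1] += shift
    assert icc31(shifted).icc_raw == pytest.approx(base, abs=1e-10)


def test_zero_total_variance_reports_zero_with_warning():
    with pytest.warns(RuntimeWarning, match="0/0"):
        res = icc31(np.full((4, 2), 3.0))
    assert res.icc == 0.0


def test_negative_raw_icc_is_clamped_but_surfaced():
    # within-subject disagreement dominates → raw ICC < 0
    y = np.array([[1.0, 2.1], [2.0, 0.9], [1.5, 1.6], [0.9, 2.0]])
    res = icc31(y)
    assert res.icc_raw < 0
    assert res.icc == 0.0


def test_icc_needs_three_complete_rows():
    with pytest.raises(DegenerateInputError, match=">= 3"):
        icc31(np.array([[1.0, 2.0], [2.0, 3.0]]))
    # NaN rows are dropped pairwise and n reflects it
    y = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [np.nan, 1.0]])
    res = icc31(SessionValueTable(y))
    assert res.n == 3
    assert res.icc == pytest.approx(0.8)


def test_icc_estimates_the_variance_component_ratio(rng):
    # y_ij = mu + b_i + e_ij with sigma_b^2 = 3, sigma_e^2 = 1 → ICC = 0.75
    n = 200
    b = rng.normal(0, np.sqrt(3), size=(n, 1))
    y = 10 + b + rng.normal(0, 1, size=(n, 2))
    assert icc31(y).icc == pytest.approx(0.75, abs=0.05)


def test_dice_identities_and_counts():
    a = np.zeros((5, 5, 5))
    a[:2, :2, :2] = 1.0
    same = dice_r12(a, a.copy(), 0.0)
    assert same.r12 == 1.0
    # constructed v1=4, v2=4, v_overlap=2 → 0.5
    bl = np.zeros(10)
    fu = np.zeros(10)
    bl[:4] = 1.0
    fu[2:6] = 1.0
    res = dice_r12(bl, fu, 0.0)
    assert (res.v1, res.v2, res.v_overlap) == (4, 4, 2)
    assert res.r12 == 0.5
    disjoint = dice_r12(bl, np.roll(bl, 5), 0.0)
    assert disjoint.r12 == 0.0
    with pytest.raises(DegenerateInputError, match="undefined"):
        dice_r12(np.zeros(4), np.zeros(4), 0.0)


@given(seed=st.integers(0, 5_000), thr=st.floats(-0.5, 1.5, allow_nan=False))
def test_dice_is_symmetric_bounded_and_matches_set_oracle(seed, thr):
    g = np.random.default_rng(seed)
    a = g.normal(0, 1, size=(4, 4, 4))
    b = g.normal(0, 1, size=(4, 4, 4))
    expected = dice_oracle(a, b, thr)
    if expected is None:
        with pytest.raises(DegenerateInputError):
            dice_r12(a, b, thr)
        return
    res = dice_r12(a, b, thr)
    assert res.r12 == pytest.approx(expected)
    assert res.r12 == pytest.approx(dice_r12(b, a, thr).r12)
    assert 0.0 <= res.r12 <= 1.0
    assert res.v_overlap <= min(res.v1, res.v2)


def test_threshold_sweep_matches_single_calls(rng):
    a = rng.normal(0, 1, size=(6, 6, 6))
    b = rng.normal(0, 1, size=(6, 6, 6))
    out = threshold_sweep(a, b, [0.0])
    assert len(out) == 1
    assert out[0].r12 == dice_r12(a, b, 0.0).r12
    ladder = threshold_sweep(a, b, [0.0, 1.0, 99.0])
    assert ladder[2] is None  # both sessions empty above 99: marker, not zero
    with pytest.raises(ValueError, match="strictly increasing"):
        threshold_sweep(a, b, [1.0, 0.5])


def test_identical_maps_overlap_fully_at_all_subthreshold_cutoffs():
    a = np.zeros((5, 5, 5))
    a[1:4, 1:4, 1:4] = 3.0
    for res in threshold_sweep(a, a.copy(), [0.0, 1.0, 2.0]):
        assert res.r12 == 1.0


def test_stable_noiseless_study_yields_perfect_overlap():
    """sigma_within = sigma_noise = 0: BL and FU maps are identical, so the
    overlap ratio is exactly 1 everywhere.  The saturated Z maps then carry
    no variance at all, which cascades into the documented zero-variance ICC
    degeneracy (reported as 0 with a warning, not as spurious reliability)."""
    import warnings

    cfg = SimulationConfig(
        grid_dims=(10, 10, 10),
        n_networks=2,
        n_subjects_per_group=3,
        n_timepoints=30,
        sigma_between=0.3,
        sigma_within=0.0,
        sigma_noise=0.0,
        seed=17,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        repro, _ = run_in_memory(cfg)
    assert np.allclose(repro["r12_mean"], 1.0)
    assert (repro["icc_roi"] == 0.0).all()


def test_stable_low_noise_study_yields_near_perfect_roi_icc():
    """With no within-subject amplitude variance and mild noise the ROI ICC
    approaches its perfect-reproducibility limit."""
    cfg = SimulationConfig(
        grid_dims=(10, 10, 10),
        n_networks=2,
        n_subjects_per_group=10,
        n_timepoints=60,
        sigma_between=0.4,
        sigma_within=0.0,
        sigma_noise=0.5,
        seed=17,
    )
    repro, _ = run_in_memory(cfg)
    assert repro["icc_roi"].mean() > 0.9
    assert (repro["icc_roi"] > 0.7).all()
    # whole-volume overlap at Z > 0 includes chance-level background overlap,
    # so even a stable study sits in a 0.6-0.7 band rather than at 1
    assert repro["r12_mean"].between(0.5, 0.85).all()


def test_repro_table_shape_and_columns(small_config):
    repro, extras = run_in_memory(small_config)
    # one row per network per group
    assert len(repro) == small_config.n_networks * 2
    assert list(repro.columns) == [
        "network",
        "group",
        "n",
        "icc_en",
        "icc_en_raw",
        "icc_roi",
        "icc_roi_raw",
        "r12_mean",
        "r12_sd",
        "threshold",
    ]
    assert repro["icc_roi"].between(0, 1).all()
    assert repro["r12_mean"].between(0, 1).all()


def test_reliability_falls_as_within_subject_variance_grows():
    """A 3-point sigma_within ladder strictly degrades both statistics.

    ROI ICC is checked at Z > 0.  The overlap ratio at Z > 0 depends only on
    voxel signs, which an amplitude perturbation rarely flips, so R12's
    sensitivity to within-subject variance shows at a magnitude-sensitive
    threshold — it is checked at Z > 1.5.
    """
    roi_icc, r12_z15 = [], []
    for sw in (0.05, 0.4, 0.9):
        cfg = SimulationConfig(
            grid_dims=(10, 10, 10),
            n_networks=2,
            n_subjects_per_group=10,
            n_timepoints=60,
            sigma_between=0.4,
            sigma_within=sw,
            sigma_noise=1.0,
            seed=23,
        )
        repro, extras = run_in_memory(cfg)
        roi_icc.append(repro["icc_roi"].mean())
        from netretest import per_subject_r12

        r12_z15.append(
            per_subject_r12(extras["subject_maps"], extras["templates"], 1.5)[
                "r12"
            ].mean()
        )
    assert roi_icc[0] > roi_icc[1] > roi_icc[2]
    assert r12_z15[0] > r12_z15[1] > r12_z15[2]
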
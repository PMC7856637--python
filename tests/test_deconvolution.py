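import numpy as np
import pytest

import tcmcorr as tc
from tcmcorr.deconvolution import (
    DesignDegenerateError,
    build_design,
    censor_frames,
    cluster_threshold,
    deconvolve,
    percent_change,
    smooth,
)
from tcmcorr.simulate import MotionParams, default_ground_truth, simulate_run


@pytest.fixture(scope="module")
def sched():
    return tc.make_schedule(seed=0)


@pytest.fixture(scope="module")
def design(sched):
    return build_design(sched, n_lags=8, poly_order=3, runs=[0])


# ---------------------------------------------------------------- scaling


def test_percent_change_constant_is_zero():
    x = np.full((2, 2, 1, 20), 7.0)
    scaled, flagged = percent_change(x, 7)
    np.testing.assert_array_equal(scaled, 0.0)
    assert not flagged.any()


def test_percent_change_arithmetic():
    series = np.array([10.0] * 7 + [11.0, 10.5])
    scaled, _ = percent_change(series[None, None, None, :], 7)
    assert scaled[0, 0, 0, 7] == pytest.approx(10.0)
    assert scaled[0, 0, 0, 8] == pytest.approx(5.0)


def test_percent_change_zero_baseline_flagged():
    x = np.zeros((1, 1, 1, 10))
    x[..., 7:] = 5.0
    scaled, flagged = percent_change(x, 7)
    assert flagged[0, 0, 0]
    assert np.isnan(scaled[0, 0, 0]).all()


def test_percent_change_matches_generator_amplitude(sched):
    gt = default_ground_truth(sched, seed=0, bold_amplitude=2.0,
                              tcm_amp_range=(0.0, 0.0), noise_sd=0.0, drift_coeffs=())
    run = simulate_run(sched, 0, gt, seed=0)
    scaled, _ = percent_change(run.data, 7)
    vox = np.argwhere(gt.bold_mask)[0]
    assert scaled[tuple(vox)].max() == pytest.approx(2.0, rel=1e-6)


# ---------------------------------------------------------------- censoring


def test_censor_zero_motion_keeps_all(sched):
    m = MotionParams(params=np.zeros((sched.n_frames, 6)))
    assert censor_frames(m).all()


def test_censor_rule_direct():
    p = np.zeros((4, 6))
    p[1, 0] = 0.2          # displacement 0.2 at frame 1
    p[2, 0] = 0.2 + 0.31   # displacement 0.31 at frame 2
    p[3, 0] = 0.51 - 0.1   # displacement 0.1 at frame 3
    keep = censor_frames(MotionParams(params=p), 0.3)
    assert list(keep) == [True, True, False, True]


def test_censor_random_walk_recount(rng):
    p = np.cumsum(rng.normal(0, 0.2, (100, 6)), axis=0)
    m = MotionParams(params=p)
    keep = censor_frames(m, 0.3)
    # independent scan
    expected = np.ones(100, bool)
    for i in range(1, 100):
        if np.linalg.norm(p[i] - p[i - 1]) > 0.3:
            expected[i] = False
    np.testing.assert_array_equal(keep, expected)


# ---------------------------------------------------------------- design


def test_design_no_trials_constant_column():
    s = tc.make_schedule(n_runs=1, trials_per_run=0, seed=0)
    d = build_design(s, n_lags=1, poly_order=0, runs=[0])
    # empty FIR block; drift block = single constant column
    assert d.matrix.shape[1] == 1
    assert d.fir_cols.size == 0
    const = d.matrix[:, 0]
    assert np.allclose(const, const[0])


def test_fir_columns_sum_at_most_n_trials(sched):
    d = build_design(sched, n_lags=8, runs=[0])
    sums = d.matrix[:, d.fir_cols].sum(axis=0)
    assert np.all(sums <= sched.trials_per_run)
    assert np.all(sums >= 1)


def test_column_count_counting_oracle(sched):
    rng = np.random.default_rng(0)
    motion = MotionParams(params=np.cumsum(rng.normal(0, 0.01, (sched.n_frames, 6)), axis=0))
    d = build_design(sched, n_lags=8, poly_order=3, motion=motion, runs=[0])
    # 8 FIR + (3+1) drift x 1 run + 6 motion + 6 derivatives
    assert d.matrix.shape[1] == 8 + 4 + 12
    assert len(d.names) == d.matrix.shape[1]


def test_fir_indicator_placement(sched):
    d = build_design(sched, n_lags=8, runs=[0])
    frames = sched.onset_frames(0)
    for j, col in enumerate(d.fir_cols):
        expected = np.zeros(sched.n_frames)
        for f in frames:
            if f + j < sched.n_frames:
                expected[f + j] = 1.0
        np.testing.assert_array_equal(d.matrix[:, col], expected)


def test_all_censored_raises(sched):
    with pytest.raises(DesignDegenerateError):
        build_design(sched, frame_keep=np.zeros(sched.n_frames, bool), runs=[0])


# ---------------------------------------------------------------- OLS


def test_exact_kernel_recovery(sched, design):
    rng = np.random.default_rng(1)
    kernel = rng.normal(0, 1, 8)
    y = design.matrix[:, design.fir_cols] @ kernel
    est = deconvolve(y, design)
    np.testing.assert_allclose(est.coefficients, kernel, atol=1e-8)
    assert est.r2 == pytest.approx(1.0)


def test_pure_drift_gives_zero_r2(sched, design):
    t = np.linspace(-1, 1, sched.n_frames)
    y = 3.0 + 2.0 * t + 0.5 * t**2
    est = deconvolve(y, design)
    np.testing.assert_allclose(est.coefficients, 0.0, atol=1e-6)
    assert est.r2 == pytest.approx(0.0, abs=1e-8)


def test_constant_series_r2_zero(design):
    est = deconvolve(np.full(design.matrix.shape[0], 5.0), design)
    assert est.r2 == 0.0


def test_normal_equations_oracle(rng):
    # 100 random small instances: coefficients match (X'X)^-1 X'y
    s = tc.make_schedule(n_runs=1, trials_per_run=2, n_volumes=50, n_discard=0,
                         iti_choices_s=(13.6,), seed=0)
    d = build_design(s, n_lags=4, poly_order=1, runs=[0])
    X = d.matrix
    for _ in range(100):
        y = rng.normal(0, 1, X.shape[0])
        est = deconvolve(y, d)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(est.coefficients, beta[d.fir_cols], atol=1e-8)


def test_censoring_invariance(sched):
    rng = np.random.default_rng(2)
    keep = np.ones(sched.n_frames, bool)
    keep[40:50] = False
    d = build_design(sched, frame_keep=keep, runs=[0])
    y = rng.normal(0, 1, sched.n_frames)
    a = deconvolve(y, d)
    y2 = y.copy()
    y2[40:50] = 1e6  # arbitrary garbage at censored frames
    b = deconvolve(y2, d)
    np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-7)
    assert a.r2 == pytest.approx(b.r2, abs=1e-9)


def test_r2_monotone_in_noise(sched, design):
    rng = np.random.default_rng(3)
    signal = design.matrix[:, design.fir_cols] @ np.ones(8)
    medians = []
    for sd in (0.1, 1.0, 10.0):
        r2s = [deconvolve(signal + rng.normal(0, sd, signal.shape), design).r2
               for _ in range(20)]
        medians.append(np.median(r2s))
    assert medians[0] >= medians[1] >= medians[2]


# ---------------------------------------------------------------- clusters


def test_cluster_all_zero_map():
    act = cluster_threshold(np.zeros((5, 5, 5)), 0.16, 30)
    assert not act.surviving_mask.any()


def test_cluster_29_voxels_removed():
    m = np.zeros((10, 10, 10))
    blob = np.argwhere(np.ones((3, 3, 4)))[:29]  # 29 connected voxels
    for v in blob:
        m[tuple(v)] = 0.5
    act = cluster_threshold(m, 0.16, 30)
    assert not act.surviving_mask.any()
    act2 = cluster_threshold(m, 0.16, 29)
    assert act2.surviving_mask.sum() == 29


def test_cluster_flood_fill_oracle(rng):
    m = (rng.random((12, 12, 8)) > 0.7).astype(float) * 0.5
    act = cluster_threshold(m, 0.16, 5)

    # independent 26-connectivity flood fill
    above = m >= 0.16
    seen = np.zeros_like(above)
    survivors = np.zeros_like(above)
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(above)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offsets:
                w = tuple(np.add(v, o))
                if all(0 <= w[d] < above.shape[d] for d in range(3)) \
                        and above[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        if len(comp) >= 5:
            for v in comp:
                survivors[v] = True
    np.testing.assert_array_equal(act.surviving_mask, survivors)


# ---------------------------------------------------------------- smoothing


def test_smooth_fwhm_zero_identity(rng):
    x = rng.normal(0, 1, (8, 8, 4, 3))
    np.testing.assert_array_equal(smooth(x, 0.0, 3.0), x)


def test_smooth_constant_preserved():
    x = np.full((10, 10, 6, 2), 4.2)
    np.testing.assert_allclose(smooth(x, 6.0, 3.0), x, rtol=1e-12)


def test_smooth_mask_normalized_constant_with_exclusion():
    x = np.full((10, 10, 6, 1), 4.2)
    excl = np.zeros((10, 10, 6), bool)
    excl[4:6, 4:6, 2:4] = True
    out = smooth(x, 6.0, 3.0, exclusion_mask=excl)
    np.testing.assert_allclose(out[~excl], 4.2, rtol=1e-12)
    # excluded voxels are passed through untouched
    np.testing.assert_array_equal(out[excl], x[excl])


def test_smooth_mass_conservation_point_source():
    x = np.zeros((25, 25, 25, 1))
    x[12, 12, 12, 0] = 1.0
    out = smooth(x, 6.0, 3.0, truncate=8.0)
    assert out.sum() == pytest.approx(1.0, abs=1e-6)
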
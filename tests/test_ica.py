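import numpy as np
import pytest

import tcmcorr as tc
from tcmcorr.deconvolution import build_design
from tcmcorr.hrf import canonical_hrf
from tcmcorr.ica import (
    FEATURE_NAMES,
    ICFeatureVector,
    apply_classifier,
    decompose,
    extract_features,
    hrf_ic_match,
    ic_irf,
    protection_matrix,
    remove_components,
    rule_label,
    task_regressor,
    train_classifier,
    true_ic_labels,
)
from tcmcorr.simulate import bold_waveform, tcm_waveform


@pytest.fixture(scope="module")
def sched():
    return tc.make_schedule(seed=0)


@pytest.fixture(scope="module")
def design(sched):
    return build_design(sched, n_lags=8, poly_order=3, runs=[0])


# ------------------------------------------------------------ decompose


def test_rank2_disjoint_sources_recovered(rng):
    n = 120
    t = np.arange(n)
    tc1 = np.sin(2 * np.pi * t / 20)
    tc2 = np.sign(np.sin(2 * np.pi * t / 7.3))
    # spatial sources with zero voxel mean and disjoint support, so they are
    # exactly uncorrelated across voxels (the identifiable case)
    m1 = np.zeros((8, 8, 2))
    m1[0], m1[1] = 1.0, -1.0
    m2 = np.zeros((8, 8, 2))
    m2[4], m2[5] = 1.0, -1.0
    data = 100.0 + 3.0 * m1[..., None] * tc1 + 2.0 * m2[..., None] * tc2
    d = decompose(data, n_ics=2, seed=0)
    assert d.n_ics == 2
    assert d.residual_frac < 1e-6
    # each source time course matched by one IC up to sign/permutation
    for src in (tc1, tc2):
        cs = [abs(np.corrcoef(src, tcx)[0, 1]) for tcx in d.timecourses]
        assert max(cs) > 0.999


def test_reconstruction_contract(default_run, decomp):
    recon = decomp.reconstruct()
    resid = default_run.data - recon
    demeaned = default_run.data - default_run.data.mean(axis=-1, keepdims=True)
    frac = np.sum(resid**2) / np.sum(demeaned**2)
    assert frac <= decomp.residual_frac + 1e-9


def test_decomposition_shapes_and_scaling(default_run, decomp):
    n = default_run.n_frames
    assert decomp.mixing.shape == (n, decomp.n_ics)
    assert decomp.timecourses.shape == (decomp.n_ics, n)
    np.testing.assert_allclose(decomp.timecourses.std(axis=1), 1.0, rtol=1e-6)
    # spatial maps are z-scored
    maps = decomp.spatial_maps.reshape(decomp.n_ics, -1)
    np.testing.assert_allclose(maps.mean(axis=1), 0.0, atol=1e-8)
    np.testing.assert_allclose(maps.std(axis=1), 1.0, rtol=1e-6)


def test_artifact_component_localized_in_tcm_mask(default_run, decomp):
    gt = default_run.ground_truth
    art = tcm_waveform(default_run.schedule, default_run.run_index,
                       gt.tcm_amplitudes[default_run.run_index], gt.tcm_window_trs)
    k = int(np.argmax([abs(np.corrcoef(art, t)[0, 1]) for t in decomp.timecourses]))
    zmap = np.abs(decomp.spatial_maps[k])
    top = zmap >= np.quantile(zmap, 0.9)
    frac = (top & gt.tcm_mask_true).sum() / top.sum()
    chance = gt.tcm_mask_true.mean()
    assert frac > max(2 * chance, 0.6)


def test_determinism(default_run):
    a = decompose(default_run, seed=5)
    b = decompose(default_run, seed=5)
    np.testing.assert_array_equal(a.mixing, b.mixing)


# ------------------------------------------------------------ ic_irf


def test_ic_irf_canonical(sched, design):
    y = bold_waveform(sched, 0, 2.0)
    est = ic_irf(y, design)
    expect = canonical_hrf(design.lag_times_s)
    expect = 0.02 * expect / canonical_hrf(np.arange(177) * 1.7).max()
    np.testing.assert_allclose(est.coefficients, expect, atol=1e-3)
    assert est.r2 > 0.99


def test_ic_irf_white_noise(sched, design, rng):
    est = ic_irf(rng.normal(0, 1, sched.n_frames), design)
    assert est.r2 < 0.2
    assert np.abs(est.coefficients).max() < 1.0


def test_ic_irf_tcm_early_energy(sched, design):
    amps = np.full(sched.trials_per_run, 3.0)
    est = ic_irf(tcm_waveform(sched, 0, amps), design)
    e = est.coefficients**2
    assert e[:3].sum() / e.sum() > 0.9


# ------------------------------------------------------------ features


def _fv(**kw):
    base = dict(ic_index=0, irf_template_corr=0, voxel_match_frac=0,
                psd_task_ratio=0, spatial_overlap=0, spikiness=0,
                early_energy_frac=0, match_flag=False)
    base.update(kw)
    return ICFeatureVector(**base)


def test_feature_psd_sinusoid_vs_noise(default_run, config, analysis, rng):
    # build decomposition-like inputs through the public API
    run = default_run
    sched = run.schedule
    design = build_design(sched, runs=[run.run_index])
    d = decompose(run, seed=1)
    # swap in synthetic time courses: a task-frequency sinusoid and white noise
    t = np.arange(sched.n_frames) * sched.tr_s
    sin_tc = np.sin(2 * np.pi * sched.task_freq_hz * t)
    noise_tc = rng.normal(0, 1, sched.n_frames)
    d2 = type(d)(
        spatial_maps=d.spatial_maps[:2], timecourses=np.vstack([sin_tc, noise_tc]),
        mixing=d.mixing[:, :2], maps_raw=d.maps_raw[:2], mean_image=d.mean_image,
        frame_offset=d.frame_offset, residual_frac=d.residual_frac, n_ics=2,
    )
    feats = extract_features(
        d2, sched, design, voxel_hrfs=analysis.hrf_coefs,
        active_mask=analysis.act_map.surviving_mask,
        tcm_mask=run.ground_truth.tcm_mask_true,
    )
    assert feats[0].psd_task_ratio > 10
    assert feats[1].psd_task_ratio < 5


def test_feature_constant_timecourse_convention(default_run, analysis):
    run = default_run
    design = build_design(run.schedule, runs=[run.run_index])
    d = decompose(run, seed=1)
    d2 = type(d)(
        spatial_maps=d.spatial_maps[:1],
        timecourses=np.ones((1, run.n_frames)),
        mixing=d.mixing[:, :1], maps_raw=d.maps_raw[:1], mean_image=d.mean_image,
        frame_offset=d.frame_offset, residual_frac=d.residual_frac, n_ics=1,
    )
    f = extract_features(
        d2, run.schedule, design, voxel_hrfs=analysis.hrf_coefs,
        active_mask=analysis.act_map.surviving_mask,
        tcm_mask=run.ground_truth.tcm_mask_true,
    )[0]
    assert f.spikiness == 0 and f.psd_task_ratio == 0 and not f.match_flag


def test_spatial_overlap_all_inside_mask(default_run, analysis):
    run = default_run
    gt = run.ground_truth
    design = build_design(run.schedule, runs=[run.run_index])
    d = decompose(run, seed=1)
    zmap = np.zeros_like(d.spatial_maps[:1])
    inside = np.argwhere(gt.tcm_mask_true)
    for v in inside[:50]:
        zmap[0][tuple(v)] = 5.0
    d2 = type(d)(
        spatial_maps=zmap, timecourses=d.timecourses[:1], mixing=d.mixing[:, :1],
        maps_raw=d.maps_raw[:1], mean_image=d.mean_image,
        frame_offset=d.frame_offset, residual_frac=d.residual_frac, n_ics=1,
    )
    f = extract_features(
        d2, run.schedule, design, voxel_hrfs=analysis.hrf_coefs,
        active_mask=analysis.act_map.surviving_mask, tcm_mask=gt.tcm_mask_true,
    )[0]
    assert f.spatial_overlap == pytest.approx(1.0)


# ------------------------------------------------------------ hrf_ic_match


def test_match_identical_hrfs():
    irf = canonical_hrf(np.arange(8) * 1.7)
    frac, flag = hrf_ic_match(np.tile(irf, (5, 1)), irf)
    assert frac == 1.0 and flag


def test_match_orthogonal_hrfs():
    irf = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
    orth = np.array([1.0, 1, 1, 1, 1, 1, 1, 1.0001])  # ~zero-variance direction
    frac, flag = hrf_ic_match(np.tile(orth, (5, 1)), irf)
    assert frac == 0.0 and not flag


def test_match_brute_force_oracle(rng):
    irf = canonical_hrf(np.arange(8) * 1.7)
    hrfs = []
    for i in range(10):
        if i < 4:  # constructed to correlate >= 0.7
            hrfs.append(irf * rng.uniform(0.5, 2.0) + rng.normal(0, 0.01 * irf.max(), 8))
        else:      # anti-correlated: signed r rule must reject
            hrfs.append(-irf + rng.normal(0, 0.01 * irf.max(), 8))
    hrfs = np.array(hrfs)
    # independent per-voxel correlation loop
    count = 0
    for h in hrfs:
        r = np.corrcoef(h, irf)[0, 1]
        if r >= 0.7:
            count += 1
    assert count == 4
    frac, flag = hrf_ic_match(hrfs, irf, r_thresh=0.7, min_frac=0.05)
    assert frac == pytest.approx(0.4)
    assert flag


def test_match_empty_warns():
    with pytest.warns(UserWarning):
        frac, flag = hrf_ic_match(np.empty((0, 8)), np.ones(8))
    assert frac == 0.0 and not flag


# ------------------------------------------------------------ rule


def test_rule_all_zero_is_signal():
    assert rule_label(_fv()).decision == "signal"


def test_rule_fires_on_flag_spike_overlap():
    f = _fv(match_flag=True, spikiness=10.0, spatial_overlap=0.9)
    assert rule_label(f).decision == "noise"


def test_rule_conservative_without_flag():
    f = _fv(match_flag=False, spikiness=10.0, psd_task_ratio=10.0, spatial_overlap=0.9)
    assert rule_label(f).decision == "signal"


def test_rule_needs_spatial_overlap():
    f = _fv(match_flag=True, spikiness=10.0, spatial_overlap=0.1)
    assert rule_label(f).decision == "signal"


# ------------------------------------------------------------ classifier


def _toy_sets(rng, n_sets=10, sep=4.0):
    from tcmcorr.ica import ICLabel
    feature_sets, label_sets = [], []
    for _ in range(n_sets):
        feats, labs = [], []
        for k in range(6):
            noise = k < 2
            vec = rng.normal(sep if noise else 0.0, 1.0, len(FEATURE_NAMES))
            feats.append(ICFeatureVector(k, *vec, match_flag=noise))
            labs.append(ICLabel(k, "noise" if noise else "signal",
                                1.0 if noise else 0.0, source="manual"))
        feature_sets.append(feats)
        label_sets.append(labs)
    return feature_sets, label_sets


def test_separable_training_accuracy_one(rng):
    fs, ls = _toy_sets(rng)
    clf = train_classifier(fs, ls, seed=0)
    preds = [l.decision for l in apply_classifier(clf, [f for s in fs for f in s])]
    truth = [l.decision for s in ls for l in s]
    assert preds == truth
    assert clf.training_meta["lodo_sensitivity"] == 1.0
    assert clf.training_meta["lodo_specificity"] == 1.0


def test_shuffled_labels_near_chance(rng):
    fs, ls = _toy_sets(rng)
    flat = [l for s in ls for l in s]
    perm = rng.permutation(len(flat))
    shuffled, i = [], 0
    for s in ls:
        shuffled.append([flat[perm[i + j]] for j in range(len(s))])
        i += len(s)
    clf = train_classifier(fs, shuffled, seed=0)
    acc = clf.training_meta["lodo_accuracy"]
    assert acc < 0.75


def test_fewer_than_ten_datasets_guard(rng):
    fs, ls = _toy_sets(rng, n_sets=3)
    with pytest.raises(ValueError):
        train_classifier(fs, ls, seed=0)
    with pytest.warns(UserWarning):
        train_classifier(fs, ls, seed=0, allow_few_datasets=True)


def test_apply_classifier_empty(rng):
    fs, ls = _toy_sets(rng)
    clf = train_classifier(fs, ls, seed=0)
    assert apply_classifier(clf, []) == []


# ------------------------------------------------------------ removal


def test_remove_empty_set_identity(default_run, decomp):
    out = remove_components(default_run, decomp, [])
    np.testing.assert_array_equal(out.data, default_run.data)


def test_remove_all_aggressive_residual_orthogonal(default_run, decomp):
    out = remove_components(default_run, decomp, list(range(decomp.n_ics)),
                            mode="aggressive")
    xd = (out.data - out.data.mean(axis=-1, keepdims=True)).reshape(-1, default_run.n_frames)
    T = decomp.mixing - decomp.mixing.mean(axis=0, keepdims=True)
    sel = xd[::97]  # subsample voxels for speed
    corr = np.corrcoef(np.vstack([T.T, sel]))[: decomp.n_ics, decomp.n_ics :]
    assert np.nanmax(np.abs(corr)) < 1e-8


def test_nonaggressive_variance_never_increases(default_run, decomp):
    P = protection_matrix(default_run.schedule, default_run.run_index)
    for protect in (None, P):
        out = remove_components(default_run, decomp, [0], protect=protect)
        v_in = default_run.data.var(axis=-1)
        v_out = out.data.var(axis=-1)
        assert np.all(v_out <= v_in + 1e-9)


def test_removal_preserves_mean(default_run, decomp):
    out = remove_components(default_run, decomp, [0])
    np.testing.assert_allclose(out.data.mean(axis=-1),
                               default_run.data.mean(axis=-1), rtol=1e-10)


def test_removal_before_after_contract(default_run, decomp):
    # unprotected removal of ground-truth noise ICs: artifact-region task-band
    # power drops, signal-region trial-average amplitude moves < 10%
    from scipy.signal import periodogram

    run = default_run
    gt = run.ground_truth
    art = tcm_waveform(run.schedule, run.run_index,
                       gt.tcm_amplitudes[run.run_index], gt.tcm_window_trs)
    labels = true_ic_labels(decomp, art)
    assert any(l.decision == "noise" for l in labels)
    cleaned = remove_components(run, decomp, labels)
    m = gt.tcm_mask_true & ~gt.bold_mask

    def band_power(data):
        y = data[m].mean(axis=0)
        f, p = periodogram(y - y.mean(), fs=1 / run.schedule.tr_s)
        i = int(np.argmin(np.abs(f - run.schedule.task_freq_hz)))
        return p[max(i - 1, 0): i + 2].sum()

    def trial_avg_amp(data):
        y = data[gt.bold_mask].mean(axis=0)
        wins = [y[f: f + 9] for f in run.schedule.onset_frames(run.run_index)
                if f + 9 <= len(y)]
        ta = np.mean(wins, axis=0)
        return ta.max() - ta.min()

    assert band_power(cleaned.data) < band_power(run.data)
    a0, a1 = trial_avg_amp(run.data), trial_avg_amp(cleaned.data)
    assert abs(a1 - a0) / a0 < 0.10


def test_task_regressor_shape_and_peak(sched):
    y = task_regressor(sched, 0)
    assert y.shape == (sched.n_frames,)
    assert y.max() <= sched.trials_per_run  # unit-peak kernel per trial
    assert y[: sched.onset_frames(0)[0]].max() == 0.0


def test_invalid_mode_raises(default_run, decomp):
    with pytest.raises(ValueError):
        remove_components(default_run, decomp, [0], mode="soft")
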
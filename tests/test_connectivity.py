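"""Connectivity pipeline: preprocessing contracts, NFQ arithmetic, ICC."""

import numpy as np
import pytest

from netfailq import connectivity as conn
from netfailq.connectivity import ComponentAtlas, ScanSession


def make_session(t=100, k=4, tr=0.8, seed=0):
    rng = np.random.default_rng(seed)
    return ScanSession(data=rng.standard_normal((t, k)), tr=tr,
                       motion=rng.normal(0, 0.01, (t, 6)))


# ---------------------------------------------------------------- trimming


def test_trim_removes_dummy_frames():
    s = make_session(t=488)
    out = conn.trim_initial_frames(s, 10)
    assert out.n_frames == 478
    np.testing.assert_array_equal(out.data, s.data[10:])
    np.testing.assert_array_equal(out.motion, s.motion[10:])


def test_trim_zero_is_identity():
    s = make_session(t=30)
    out = conn.trim_initial_frames(s, 0)
    np.testing.assert_array_equal(out.data, s.data)


def test_trim_too_many_frames_errors():
    with pytest.raises(ValueError):
        conn.trim_initial_frames(make_session(t=12), 12)


# ---------------------------------------------------------------- noise ROI


def test_noise_roi_erosion_geometry():
    """A fully probable 10^3 cube eroded by 2 voxels leaves the 6^3 core."""
    prob = np.ones((10, 10, 10))
    mask = conn.build_noise_roi(prob, np.zeros_like(prob), threshold=0.9, erosion=2)
    expected = np.zeros_like(mask)
    expected[2:8, 2:8, 2:8] = True
    np.testing.assert_array_equal(mask, expected)


def test_noise_roi_empty_probabilities_error():
    zero = np.zeros((6, 6, 6))
    with pytest.raises(ValueError, match="threshold"):
        conn.build_noise_roi(zero, zero)


def test_noise_roi_threshold_is_inclusive():
    prob = np.zeros((8, 8, 8))
    prob[4, 4, 4] = 0.9
    mask = conn.build_noise_roi(prob, np.zeros_like(prob), erosion=0)
    assert mask[4, 4, 4]
    prob[4, 4, 4] = 0.89
    with pytest.raises(ValueError):
        conn.build_noise_roi(prob, np.zeros_like(prob), erosion=0)


# ---------------------------------------------------------------- noise PCA


def test_noise_components_recover_dominant_signal(rng):
    t = 300
    sinus = np.sin(2 * np.pi * 0.03 * 0.8 * np.arange(t))
    data = np.zeros((t, 4, 4, 4))
    mask = np.zeros((4, 4, 4), bool)
    mask[:2] = True
    data[:, mask] = np.outer(sinus, rng.uniform(0.5, 2.0, mask.sum()))
    data += rng.normal(0, 1e-4, data.shape)
    session = ScanSession(data=data, tr=0.8)
    comps = conn.noise_components(session, mask, k=2)
    assert abs(np.corrcoef(comps[:, 0], sinus)[0, 1]) > 0.999


def test_noise_components_match_eigendecomposition(rng):
    t = 120
    data = rng.standard_normal((t, 3, 3, 3))
    mask = np.ones((3, 3, 3), bool)
    session = ScanSession(data=data, tr=0.8)
    comps = conn.noise_components(session, mask, k=4)
    # brute-force: eigendecomposition of the time-by-time covariance
    ts = data.reshape(t, -1)
    ts = ts - ts.mean(axis=0)
    w, v = np.linalg.eigh(ts @ ts.T)
    order = np.argsort(w)[::-1]
    for i in range(4):
        r = abs(np.corrcoef(comps[:, i], v[:, order[i]])[0, 1])
        assert r > 1 - 1e-8


def test_noise_components_k_zero_and_rank_error(rng):
    data = rng.standard_normal((50, 3, 3, 3))
    session = ScanSession(data=data, tr=0.8)
    mask = np.ones((3, 3, 3), bool)
    assert conn.noise_components(session, mask, k=0).shape == (50, 0)
    single = np.zeros((3, 3, 3), bool)
    single[0, 0, 0] = True
    with pytest.raises(ValueError, match="rank"):
        conn.noise_components(session, single, k=3)


# ---------------------------------------------------------------- nuisance


def test_nuisance_matrix_shape_and_derivatives(rng):
    t = 60
    motion = rng.standard_normal((t, 6))
    noise = rng.standard_normal((t, 6))
    design = conn.build_nuisance_matrix(motion, noise)
    assert design.shape == (t, 18)
    np.testing.assert_allclose(design.mean(axis=0), 0.0, atol=1e-12)
    # constant motion -> zero derivative columns (centred zeros)
    const = conn.build_nuisance_matrix(np.ones((t, 6)), np.empty((t, 0)))
    np.testing.assert_allclose(const[:, 6:12], 0.0, atol=1e-12)


def test_nuisance_ramp_derivative_is_step():
    t = 10
    motion = np.zeros((t, 6))
    motion[:, 0] = np.arange(t)
    design = conn.build_nuisance_matrix(motion, np.empty((t, 0)))
    deriv = design[:, 6] - design[:, 6].mean() + np.r_[0.0, np.ones(t - 1)].mean()
    np.testing.assert_allclose(deriv, np.r_[0.0, np.ones(t - 1)], atol=1e-12)


def test_nuisance_length_mismatch_errors(rng):
    with pytest.raises(ValueError, match="mismatch"):
        conn.build_nuisance_matrix(rng.standard_normal((10, 6)), rng.standard_normal((9, 2)))


# ---------------------------------------------------------------- filtering


def _sinusoid(freq, t=478, tr=0.8):
    return np.sin(2 * np.pi * freq * tr * np.arange(t))


def test_bandpass_passband_retained():
    x = _sinusoid(0.04)[:, None]
    y = conn.bandpass_and_regress(x, None, normalize=False)
    assert y.var() / x.var() > 0.95


def test_bandpass_stopband_attenuated():
    x = _sinusoid(0.2)[:, None]
    y = conn.bandpass_and_regress(x, None, normalize=False)
    assert y.var() / x.var() < 0.10


def test_regression_removes_nuisance_exactly(rng):
    t = 478
    nuis = rng.standard_normal((t, 1))
    data = nuis[:, 0] + _sinusoid(0.03, t)
    out = conn.bandpass_and_regress(data[:, None], nuis)
    filtered_nuis = conn.bandpass_and_regress(nuis, None, normalize=False)
    r = np.corrcoef(out[:, 0], filtered_nuis[:, 0])[0, 1]
    assert abs(r) < 1e-6


def test_residual_orthogonal_to_all_filtered_nuisance(rng):
    t = 400
    data = rng.standard_normal((t, 3))
    nuis = rng.standard_normal((t, 5))
    out = conn.bandpass_and_regress(data, nuis, normalize=False)
    fn = conn.bandpass_and_regress(nuis, None, normalize=False)
    dots = np.abs(fn.T @ out)
    bound = 1e-6 * np.linalg.norm(fn, axis=0)[:, None] * np.linalg.norm(out, axis=0)
    assert (dots < bound).all()


def test_bad_band_errors():
    with pytest.raises(ValueError, match="band"):
        conn.bandpass_and_regress(np.zeros((100, 1)), None, band=(0.01, 0.7), tr=0.8)


# ---------------------------------------------------------------- smoothing


def test_smoothing_identity_and_mass_conservation():
    vol = np.zeros((1, 21, 21, 21))
    vol[0, 10, 10, 10] = 1.0
    assert np.array_equal(conn.smooth_volumes(vol, 0.0), vol)
    out = conn.smooth_volumes(vol, 8.0, voxel_sizes=(2.0, 2.0, 2.0))
    assert abs(out.sum() - 1.0) < 1e-6
    # peak equals the analytic 3D Gaussian normalization at the centre
    sigma_vox = 8.0 / (2 * np.sqrt(2 * np.log(2))) / 2.0
    expected_peak = (1.0 / (2 * np.pi * sigma_vox**2) ** 1.5)
    assert abs(out[0, 10, 10, 10] - expected_peak) / expected_peak < 0.05


def test_smoothing_constant_image_unchanged_in_interior():
    vol = np.full((1, 16, 16, 16), 3.3)
    out = conn.smooth_volumes(vol, 4.0, voxel_sizes=(2.0, 2.0, 2.0))
    np.testing.assert_allclose(out[0, 6:10, 6:10, 6:10], 3.3, rtol=1e-6)


def test_negative_fwhm_errors():
    with pytest.raises(ValueError):
        conn.smooth_volumes(np.zeros((1, 4, 4, 4)), -1.0)


# ---------------------------------------------------------------- dual regression


def _blob_atlas(shape=(12, 12, 12), k=3, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    maps = np.zeros((k,) + shape)
    for i in range(k):
        c = rng.uniform(3, np.array(shape) - 3)
        maps[i] = np.exp(-sum((g - cc) ** 2 for g, cc in zip(grids, c)) / 8.0)
    return ComponentAtlas(maps=maps, labels=labels or {i: "pDMN" for i in range(k)})


def test_dual_regression_exact_on_orthogonalized_maps(rng):
    atlas = _blob_atlas(k=2, seed=1)
    t = 50
    s = np.sin(2 * np.pi * 0.05 * np.arange(t))
    series = s[:, None, None, None] * atlas.maps[0][None]
    courses = conn.dual_regression(series, atlas)
    r = np.corrcoef(courses[:, 0], s)[0, 1]
    assert r > 1 - 1e-10
    assert np.abs(np.corrcoef(courses[:, 1], s)[0, 1]) < 1e-6 or np.allclose(courses[:, 1], 0)


def test_dual_regression_zero_series():
    atlas = _blob_atlas(k=2)
    courses = conn.dual_regression(np.zeros((5,) + atlas.grid_shape), atlas)
    np.testing.assert_allclose(courses, 0.0, atol=1e-12)


def test_dual_regression_matches_normal_equations_oracle(rng):
    """Joint regression beats univariate on correlated maps and equals a
    brute-force normal-equations solve."""
    atlas = _blob_atlas(k=2, seed=3)
    # make the two maps overlap (correlated)
    atlas.maps[1] = 0.6 * atlas.maps[0] + 0.4 * atlas.maps[1]
    t = 150
    truth = rng.standard_normal((t, 2))
    series = np.einsum("tk,kxyz->txyz", truth, atlas.maps)
    series += rng.normal(0, 0.01, series.shape)
    joint = conn.dual_regression(series, atlas)
    # oracle: explicit normal equations on the centred map matrix
    x = atlas.maps.reshape(2, -1).T
    x = x - x.mean(axis=0)
    y = series.reshape(t, -1).T
    oracle = np.linalg.solve(x.T @ x, x.T @ y).T
    np.testing.assert_allclose(joint, oracle, atol=1e-6)
    for k in range(2):
        assert np.corrcoef(joint[:, k], truth[:, k])[0, 1] > 0.99
    # univariate regression is confounded by the shared support
    uni = y.T @ x / (x**2).sum(axis=0)
    r_uni = np.corrcoef(uni[:, 1], truth[:, 1])[0, 1]
    assert r_uni < 0.99


def test_dual_regression_collinear_maps_error():
    atlas = _blob_atlas(k=2)
    atlas.maps[1] = 2.0 * atlas.maps[0]
    with pytest.raises(ValueError, match="collinear"):
        conn.dual_regression(np.zeros((4,) + atlas.grid_shape), atlas)


def test_dual_regression_grid_mismatch_error():
    atlas = _blob_atlas(k=2)
    with pytest.raises(ValueError, match="grid"):
        conn.dual_regression(np.zeros((4, 5, 5, 5)), atlas)


# ---------------------------------------------------------------- connectivity stats


def _courses_with_cross_correlations(rs, t=400, seed=0):
    """Two components per subsystem with exact empirical cross-correlations.

    Build four orthonormal series, then mix so that corr(a_i, b_j) equals
    rs[i, j] exactly.
    """
    rng = np.random.default_rng(seed)
    # orthonormal columns that are also orthogonal to the constant vector,
    # so empirical (mean-centred) correlations equal the target exactly
    q_full, _ = np.linalg.qr(
        np.column_stack([np.ones(t), rng.standard_normal((t, 4))])
    )
    q = q_full[:, 1:5]
    target = np.eye(4)
    target[:2, 2:] = rs
    target[2:, :2] = rs.T
    w, v = np.linalg.eigh(target)
    root = (v * np.sqrt(np.clip(w, 0, None))) @ v.T
    mixed = q @ root.T * np.sqrt(t)
    return mixed


def test_pair_connectivity_median_of_hand_built_correlations():
    rs = np.array([[0.1, 0.2], [0.3, 0.4]])
    courses = _courses_with_cross_correlations(rs)
    labels = {0: "pDMN", 1: "pDMN", 2: "vDMN", 3: "vDMN"}
    pc = conn.subsystem_connectivity(courses, labels)
    assert pc[("pDMN", "vDMN")] == pytest.approx(0.25, abs=1e-10)


def test_identical_courses_give_unit_connectivity(rng):
    s = rng.standard_normal(100)
    courses = np.column_stack([s, s])
    pc = conn.subsystem_connectivity(courses, {0: "pDMN", 1: "vDMN"})
    assert pc[("pDMN", "vDMN")] == pytest.approx(1.0)


def test_orthogonal_sinusoids_give_zero_connectivity():
    t = np.arange(400)
    courses = np.column_stack([np.sin(2 * np.pi * t / 100), np.cos(2 * np.pi * t / 100)])
    pc = conn.subsystem_connectivity(courses, {0: "pDMN", 1: "vDMN"})
    assert abs(pc[("pDMN", "vDMN")]) < 1e-6


def test_zero_variance_course_excluded_with_warning(rng):
    courses = np.column_stack(
        [rng.standard_normal(50), np.zeros(50), rng.standard_normal(50)]
    )
    labels = {0: "pDMN", 1: "pDMN", 2: "vDMN"}
    with pytest.warns(UserWarning, match="zero-variance"):
        pc = conn.subsystem_connectivity(courses, labels)
    assert ("pDMN", "vDMN") in pc


def test_nfq_arithmetic_and_variants():
    pc = {("avDMN", "pDMN"): 0.3, ("adDMN", "pDMN"): 0.2, ("pDMN", "vDMN"): 0.25}
    assert conn.compute_nfq(pc) == pytest.approx(2.0)
    literal = conn.compute_nfq(pc, numerator=conn.nfq_numerator("literal"))
    assert literal == pytest.approx(1.8)
    # scale cancellation: all pairs equal
    pc_c = {k: 0.37 for k in pc}
    assert conn.compute_nfq(pc_c) == pytest.approx(2.0)


def test_nfq_degenerate_denominator_flagged():
    pc = {("avDMN", "pDMN"): 0.3, ("adDMN", "pDMN"): 0.2, ("pDMN", "vDMN"): 1e-9}
    with pytest.warns(UserWarning, match="denominator"):
        assert np.isnan(conn.compute_nfq(pc))


def test_nfq_invariant_to_component_relabelling(rng):
    labels = {0: "pDMN", 1: "pDMN", 2: "vDMN", 3: "avDMN", 4: "adDMN"}
    courses = rng.standard_normal((200, 5))
    nfq1 = conn.session_profile(courses, labels).nfq
    perm = np.array([3, 1, 4, 0, 2])
    relabelled = {i: labels[perm[i]] for i in range(5)}
    nfq2 = conn.session_profile(courses[:, perm], relabelled).nfq
    assert nfq1 == pytest.approx(nfq2, abs=1e-12)


def test_intensity_scale_invariance_volume_pipeline(rng):
    """Scaling voxel intensities leaves courses' correlations and NFQ
    unchanged (variance normalization)."""
    from netfailq.synthetic_cohort import (
        CohortConfig,
        generate_cohort,
        generate_scan,
        make_default_scene,
    )

    scene = make_default_scene()
    cfg = CohortConfig(
        n_normative=1, n_dad=0, n_ad=0, n_controls=0, seed=5,
        frames_per_session=150, components_per_subsystem=2,
    )
    cohort, truth = generate_cohort(cfg)
    scan = generate_scan(
        cohort.iloc[0]["id"], truth, cfg, rng, mode="volume", scene=scene,
        voxel_noise_sd=0.05,
    )
    def run(series):
        courses = conn.dual_regression(series, scene.atlas)
        cleaned = conn.bandpass_and_regress(courses, None, tr=cfg.tr)
        return conn.session_profile(cleaned, truth.labels)

    p1 = run(scan.data)
    p2 = run(scan.data * 7.3)
    assert p1.nfq == pytest.approx(p2.nfq, abs=1e-9)


# ---------------------------------------------------------------- averaging, ICC


def _profile(nfq):
    return conn.ConnectivityProfile({("pDMN", "vDMN"): 0.5}, nfq)


def test_average_sessions_mean_and_filtering():
    profiles = [_profile(v) for v in (1.0, 2.0, 3.0, 4.0)]
    assert conn.average_sessions(profiles).nfq == pytest.approx(2.5)
    assert conn.average_sessions([_profile(5.0)]).nfq == pytest.approx(5.0)
    mixed = [_profile(v) for v in (1.0, 2.0, 3.0, 10.0)]
    out = conn.average_sessions(mixed, included=[True, True, True, False])
    assert out.nfq == pytest.approx(2.0)
    assert out.n_sessions_used == 3


def test_average_sessions_no_passing_errors():
    with pytest.raises(ValueError, match="no QC-passing"):
        conn.average_sessions([_profile(1.0)], included=[False])


def test_icc_perfect_consistency():
    x = np.tile(np.arange(5, dtype=float)[:, None], (1, 3))
    assert conn.session_icc(x) == pytest.approx(1.0)


def test_icc_null_near_zero(rng):
    x = rng.standard_normal((200, 4))
    assert abs(conn.session_icc(x)) < 0.12


def test_icc_matches_anova_table_oracle():
    x = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 8.0]])
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert conn.session_icc(x) == pytest.approx(expected, abs=1e-12)


def test_icc_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(2)
    subj_effect = rng.standard_normal(30)
    x = subj_effect[:, None] + rng.normal(0, 0.5, (30, 4))
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(30), 4),
            "rater": np.tile(np.arange(4), 30),
            "value": x.ravel(),
        }
    )
    icc_pg = pingouin.intraclass_corr(
        long, targets="subject", raters="rater", ratings="value"
    )
    # row for the absolute-agreement single-rating form ICC(2,1) / ICC(A,1)
    mask = icc_pg["Type"].astype(str).str.contains("A,1|ICC2$", regex=True)
    expected = icc_pg.loc[mask, "ICC"].iloc[0]
    assert conn.session_icc(x) == pytest.approx(expected, abs=1e-6)


def test_icc_degenerate_errors():
    with pytest.raises(ValueError, match="variance"):
        conn.session_icc(np.ones((5, 3)))
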
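"""MER preprocessing, the IN/OUT signal model and brain-shift estimation."""

import numpy as np
import pandas as pd
import pytest

from stnseg.mer import (
    FitTransform,
    MerModelParams,
    MerTrajectorySet,
    apply_transform,
    classify_sites,
    compute_nrms,
    evaluate_containment,
    extract_rms,
    fit_transform,
    init_from_plan,
    init_max_likely_exit,
    sigmoid_transition,
    site_likelihood,
    train_mer_model,
)
from stnseg.mesh import mesh_to_mask, seed_sphere, signed_distance
from stnseg.synthetic import MerSimConfig, generate_mer_subject
from stnseg.volume import VoxelVolume


class TestNrms:
    def test_reference_sites_map_to_one(self):
        nrms = compute_nrms(np.array([2.0, 2.0, 2.0, 2.0, 2.0, 6.0]))
        np.testing.assert_allclose(nrms, [1, 1, 1, 1, 1, 3])

    def test_gain_invariance(self, rng):
        rms = rng.random(26) + 0.5
        np.testing.assert_allclose(compute_nrms(rms), compute_nrms(7.3 * rms), rtol=1e-12)

    def test_too_few_positions(self):
        with pytest.raises(ValueError, match="at least 5"):
            compute_nrms(np.ones(4))

    def test_nonpositive_rms(self):
        with pytest.raises(ValueError, match="positive"):
            compute_nrms(np.array([1.0, 1.0, 0.0, 1.0, 1.0, 1.0]))


class TestExtractRms:
    def test_sine_closed_form(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        a = 2.5
        rms = extract_rms(a * np.sin(2 * np.pi * 50 * t), fs)
        assert rms == pytest.approx(a / np.sqrt(2), rel=1e-3)

    def test_artifact_window_rejected(self, rng):
        fs = 1000.0
        clean = rng.normal(0, 1.0, int(10 * fs))
        signal = clean.copy()
        signal[3000:4000] *= 10.0  # one 10x artifact second
        rms = extract_rms(signal, fs)
        rms_clean = np.sqrt(np.mean(clean**2))
        assert abs(rms - rms_clean) / rms_clean < 0.05

    def test_zero_signal_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert extract_rms(np.zeros(5000), 1000.0) == 0.0

    def test_empty_signal_errors(self):
        with pytest.raises(ValueError):
            extract_rms(np.array([]), 1000.0)


class TestSigmoidAndLikelihood:
    def test_at_border_half(self):
        assert sigmoid_transition(0.0, 0.0, 2.0) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert sigmoid_transition(1.0, 1.0, 2.0) == pytest.approx(1 / (1 + np.exp(-3)), rel=1e-9)

    def test_limits(self):
        assert sigmoid_transition(-1e3, 0.0, 2.0) == pytest.approx(0.0, abs=1e-12)
        assert sigmoid_transition(1e3, 0.0, 2.0) == pytest.approx(1.0)

    def test_mixture_degenerates_to_components(self):
        p = MerModelParams(0.0, 2.0, np.log(2.5), 0.35, 0.0, 0.2)
        from scipy.stats import lognorm

        x = 1.7
        deep = site_likelihood(x, 1e3, p)
        out = site_likelihood(x, -1e3, p)
        assert deep == pytest.approx(lognorm.pdf(x, s=0.35, scale=2.5), rel=1e-9)
        assert out == pytest.approx(lognorm.pdf(x, s=0.2, scale=1.0), rel=1e-9)

    def test_hand_mixture_at_half(self):
        # S = 0.5 exactly at d = 0 with beta0 = 0; mixture = (p_in + p_out)/2
        p = MerModelParams(0.0, 2.0, np.log(2.5), 0.35, 0.0, 0.2)
        from scipy.stats import lognorm

        x = 1.3
        expected = 0.5 * lognorm.pdf(x, s=0.35, scale=2.5) + 0.5 * lognorm.pdf(x, s=0.2, scale=1.0)
        assert site_likelihood(x, 0.0, p) == pytest.approx(expected, rel=1e-12)


class TestTrainMerModel:
    def test_recovers_planted_parameters(self, rng):
        beta0, beta1 = 0.0, 2.0
        mu_in, sigma_in, mu_out, sigma_out = np.log(2.5), 0.35, 0.0, 0.2
        d = rng.uniform(-6, 6, 5000)
        state = rng.random(5000) < sigmoid_transition(d, beta0, beta1)
        nrms = np.exp(rng.normal(np.where(state, mu_in, mu_out), np.where(state, sigma_in, sigma_out)))
        labels = np.where(state, "IN", "OUT")
        p = train_mer_model(nrms, labels, d)
        assert abs(p.beta0 - beta0) < 0.1
        assert abs(p.beta1 - beta1) / beta1 < 0.1
        assert abs(p.mu_in - mu_in) / mu_in < 0.1
        assert abs(p.mu_out - mu_out) < 0.05
        assert abs(p.sigma_in - sigma_in) / sigma_in < 0.1
        assert abs(p.sigma_out - sigma_out) / sigma_out < 0.1

    def test_identical_classes_flagged_degenerate(self):
        # IN and OUT samples identical -> equal emissions, flagged degenerate
        nrms = np.tile([1.0, 2.0], 20)
        labels = np.array(["IN"] * 20 + ["OUT"] * 20)
        with pytest.warns(UserWarning, match="degenerate"):
            p = train_mer_model(nrms, labels, np.linspace(-3, 3, 40))
        assert p.degenerate
        assert p.mu_in == pytest.approx(p.mu_out)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="IN and OUT"):
            train_mer_model(np.ones(10), np.array(["IN"] * 10), np.zeros(10))


class TestContainment:
    def test_perfect_prediction(self):
        labels = np.array(["IN", "OUT", "IN", "OUT"])
        m = evaluate_containment(labels, labels)
        assert m["accuracy"] == 1.0 and m["youden_j"] == 1.0

    def test_constant_out_hand_confusion(self):
        expert = np.array(["IN"] * 20 + ["OUT"] * 80)
        pred = np.array(["OUT"] * 100)
        m = evaluate_containment(pred, expert)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["youden_j"] == 0.0

    def test_swapping_classes_swaps_sens_spec(self, rng):
        expert = np.where(rng.random(60) < 0.3, "IN", "OUT")
        pred = np.where(rng.random(60) < 0.4, "IN", "OUT")
        m = evaluate_containment(pred, expert)
        swap = {"IN": "OUT", "OUT": "IN"}
        m2 = evaluate_containment(
            np.vectorize(swap.get)(pred), np.vectorize(swap.get)(expert)
        )
        assert m["sensitivity"] == pytest.approx(m2["specificity"])
        assert m["specificity"] == pytest.approx(m2["sensitivity"])

    def test_missing_class_warns(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = evaluate_containment(np.array(["IN", "IN"]), np.array(["IN", "IN"]))
        assert np.isnan(m["specificity"])


class TestClassifySites:
    def _sites(self, positions):
        df = pd.DataFrame(positions, columns=["x_mm", "y_mm", "z_mm"])
        df["trajectory"] = "central"
        df["depth_mm"] = np.arange(len(df), dtype=float)
        df["nrms"] = 1.0
        return MerTrajectorySet(df)

    def test_centroid_in_far_out(self):
        mesh = seed_sphere(np.zeros(3), 3.0, subdivisions=2)
        sites = self._sites([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]])
        np.testing.assert_array_equal(classify_sites(mesh, sites), ["IN", "OUT"])

    def test_agreement_with_voxel_containment(self, rng):
        mesh = seed_sphere(np.zeros(3), 4.0, subdivisions=3)
        affine = np.diag([0.125, 0.125, 0.125, 1.0])
        affine[:3, 3] = -6.0
        grid = VoxelVolume(data=np.zeros((96, 96, 96)), affine=affine)
        mask = mesh_to_mask(mesh, grid)
        pts = rng.uniform(-5.5, 5.5, size=(1000, 3))
        pred = classify_sites(mesh, self._sites(pts)) == "IN"
        vox = mask.interpolate(pts, order=0) > 0.5
        assert (pred == vox).mean() >= 0.99


class TestTrajectoryLayout:
    def test_depth_zero_is_planned_target(self):
        target = np.array([1.0, -2.0, 3.0])
        sites = init_from_plan(target)
        central = sites.sites[(sites.sites.trajectory == "central") & (sites.sites.depth_mm == 0.0)]
        np.testing.assert_allclose(central[["x_mm", "y_mm", "z_mm"]].to_numpy()[0], target)

    def test_ben_gun_pairwise_distances_preserved(self):
        a = init_from_plan(np.zeros(3))
        b = init_from_plan(np.array([5.0, -1.0, 2.0]))
        pa, pb = a.positions, b.positions
        da = np.linalg.norm(pa[:, None] - pa[None, :], axis=-1)
        db = np.linalg.norm(pb[:, None] - pb[None, :], axis=-1)
        np.testing.assert_allclose(da, db, atol=1e-9)

    def test_site_count_and_monotone_depths(self):
        sites = init_from_plan(np.zeros(3), n_trajectories=5)
        assert sites.n_sites == 150
        for _, grp in sites.sites.groupby("trajectory"):
            assert np.all(np.diff(grp["depth_mm"].to_numpy()) > 0)

    def test_duplicate_depth_rejected(self):
        df = init_from_plan(np.zeros(3), n_trajectories=1).sites
        df.loc[1, "depth_mm"] = df.loc[0, "depth_mm"]
        with pytest.raises(ValueError, match="duplicate"):
            MerTrajectorySet(df)


class TestMaxLikelyExitInit:
    def test_delta_density_lands_on_vertex(self):
        mesh = seed_sphere(np.zeros(3), 4.0, subdivisions=2)
        sites = init_from_plan(np.array([1.0, 1.0, 1.0]))
        density = np.zeros(mesh.n_vertices)
        v = 37
        density[v] = 1.0
        shifted = init_max_likely_exit(density, mesh, sites)
        central0 = shifted.sites[
            (shifted.sites.trajectory == "central") & (shifted.sites.depth_mm == 0.0)
        ][["x_mm", "y_mm", "z_mm"]].to_numpy()[0]
        np.testing.assert_allclose(central0, mesh.vertices[v], atol=1e-12)

    def test_uniform_density_first_index_tiebreak(self):
        mesh = seed_sphere(np.zeros(3), 4.0, subdivisions=1)
        sites = init_from_plan(np.zeros(3))
        shifted = init_max_likely_exit(np.ones(mesh.n_vertices), mesh, sites)
        central0 = shifted.sites[
            (shifted.sites.trajectory == "central") & (shifted.sites.depth_mm == 0.0)
        ][["x_mm", "y_mm", "z_mm"]].to_numpy()[0]
        np.testing.assert_allclose(central0, mesh.vertices[0], atol=1e-12)

    def test_translation_magnitude_matches_geometry(self):
        mesh = seed_sphere(np.zeros(3), 4.0, subdivisions=2)
        sites = init_from_plan(np.array([0.5, 0.5, 0.5]))
        density = np.zeros(mesh.n_vertices)
        density[11] = 1.0
        shifted = init_max_likely_exit(density, mesh, sites)
        moved = shifted.positions - sites.positions
        expected = np.linalg.norm(mesh.vertices[11] - np.array([0.5, 0.5, 0.5]))
        np.testing.assert_allclose(np.linalg.norm(moved, axis=1), expected, atol=1e-9)


@pytest.fixture(scope="module")
def stn_mesh(small_population):
    return small_population.meshes["STN_R"][0]


class TestFitTransform:
    def test_nll_not_worse_than_init(self, stn_mesh):
        cfg = MerSimConfig()
        true = FitTransform(t=np.array([1.0, -0.5, 0.8]), s=np.array([1.05, 1.0, 0.95]))
        sites, _ = generate_mer_subject(stn_mesh, cfg, true, seed=5)
        from stnseg.mer import _colinear_groups, _negative_log_likelihood

        groups = _colinear_groups(sites)
        est = fit_transform(sites, stn_mesh, cfg.params)
        nll = lambda v: _negative_log_likelihood(
            v, sites.positions, sites.nrms, stn_mesh, stn_mesh.centroid, cfg.params, groups
        )
        assert nll(est.as_vector()) <= nll(FitTransform.identity().as_vector()) + 1e-9

    def test_identity_truth_recovered_on_average(self, stn_mesh):
        cfg = MerSimConfig()
        ests = []
        for r in range(5):
            sites, _ = generate_mer_subject(stn_mesh, cfg, FitTransform.identity(), seed=40 + r)
            ests.append(fit_transform(sites, stn_mesh, cfg.params).as_vector())
        mean = np.mean(ests, axis=0)
        assert np.all(np.abs(mean[:3]) <= 0.5)
        assert np.all(np.abs(mean[3:] - 1.0) <= 0.05)

    def test_out_of_bound_truth_clamps_exactly(self, stn_mesh):
        cfg = MerSimConfig()
        true = FitTransform(t=np.array([0.0, 3.0, 0.0]), s=np.ones(3))  # beyond +-2 mm
        sites, _ = generate_mer_subject(stn_mesh, cfg, true, seed=99)
        est = fit_transform(sites, stn_mesh, cfg.params)
        assert est.t[1] == 2.0

    def test_gain_invariance_of_fit(self, stn_mesh):
        # electrode gain scales raw RMS; NRMS and hence the fitted transform
        # are exactly invariant (the fit is deterministic in its inputs)
        cfg = MerSimConfig()
        cfg.n_trajectories = 2
        cfg.depths_mm = np.arange(-8.0, 6.1, 1.0)
        true = FitTransform(t=np.array([0.5, 1.0, -0.5]), s=np.ones(3))
        sites, _ = generate_mer_subject(stn_mesh, cfg, true, seed=13)
        from stnseg.mer import compute_nrms

        def fit_with_gain(gain):
            df = sites.sites.copy()
            parts = []
            for _, grp in df.groupby("trajectory", sort=True):
                raw_rms = gain * grp["nrms"].to_numpy() * 3.1  # pretend raw RMS
                parts.append(compute_nrms(raw_rms))
            df["nrms"] = np.concatenate(parts)
            return fit_transform(MerTrajectorySet(df), stn_mesh, cfg.params).as_vector()

        # invariance is exact up to float rounding of the NRMS division
        np.testing.assert_allclose(fit_with_gain(1.0), fit_with_gain(42.0), atol=1e-6)

    def test_sharp_border_matches_hard_containment(self, stn_mesh):
        cfg = MerSimConfig()
        cfg.params = MerModelParams(0.0, 100.0, np.log(2.5), 0.35, 0.0, 0.2)
        sites, truth = generate_mer_subject(stn_mesh, cfg, FitTransform.identity(), seed=21)
        d = truth["distance"]
        away = np.abs(d) > 0.1
        s = sigmoid_transition(d[away], 0.0, 100.0)
        np.testing.assert_allclose(s, (d[away] > 0).astype(float), atol=1e-3)
        labels = sites.labels[away]
        np.testing.assert_array_equal(labels == "IN", d[away] > 0)


def test_apply_transform_round_trip(stn_mesh):
    tr = FitTransform(t=np.array([1.0, -1.0, 0.5]), s=np.array([1.1, 0.95, 1.0]))
    moved = apply_transform(stn_mesh, tr)
    inv = FitTransform(t=-tr.t / tr.s, s=1.0 / tr.s)
    back = apply_transform(moved, inv, center=stn_mesh.centroid)
    np.testing.assert_allclose(back.vertices, stn_mesh.vertices, atol=1e-9)
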
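"""Generator tests: planted geometry, condition effects, factor-model scans,
retest reliability and confounds."""

import numpy as np
import pytest

import funcgrad as fg
from funcgrad.networks import NETWORKS
from funcgrad.synthetic import RetestSample, analytic_correlation


class TestLatentGeometry:
    def test_zero_spread_collapses_nodes_onto_centroids(self):
        g = fg.make_latent_geometry(28, 2, 0.0, seed=0)
        for i, name in enumerate(NETWORKS):
            np.testing.assert_array_equal(g.coords[g.members(name)],
                                          np.broadcast_to(g.centroids[i], (len(g.members(name)), 2)))

    def test_same_seed_reproduces_coordinates(self):
        a = fg.make_latent_geometry(70, 3, 0.4, seed=7)
        b = fg.make_latent_geometry(70, 3, 0.4, seed=7)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert list(a.labels) == list(b.labels)

    def test_empirical_spread_matches_requested(self):
        # 200 nodes per network: pooled per-coordinate SD within 10%
        g = fg.make_latent_geometry(1400, 2, 0.4, seed=3)
        for i, name in enumerate(NETWORKS):
            offsets = g.coords[g.members(name)] - g.centroids[i]
            sd = offsets.std()
            assert abs(sd - 0.4) / 0.4 < 0.10

    def test_rejects_negative_spread_and_tiny_n(self):
        with pytest.raises(ValueError):
            fg.make_latent_geometry(70, 2, -0.1, seed=0)
        with pytest.raises(ValueError):
            fg.make_latent_geometry(13, 2, 0.4, seed=0)

    def test_centroids_distinct(self):
        g = fg.make_latent_geometry(70, 2, 0.4, seed=0)
        d = np.linalg.norm(g.centroids[:, None] - g.centroids[None, :], axis=2)
        assert d[~np.eye(7, dtype=bool)].min() > 0.1


class TestConditionEffect:
    def test_identity_effect_preserves_geometry(self, geometry):
        eff = fg.ConditionEffect(
            spread_multipliers={n: 1.0 for n in NETWORKS},
            centroid_shifts={n: np.zeros(2) for n in NETWORKS},
        )
        out = fg.apply_condition_effect(geometry, eff)
        np.testing.assert_allclose(out.coords, geometry.coords)
        np.testing.assert_allclose(out.centroids, geometry.centroids)

    def test_half_multiplier_quarters_sum_of_squares(self, geometry):
        eff = fg.ConditionEffect(spread_multipliers={"VN": 0.5})
        out = fg.apply_condition_effect(geometry, eff)
        idx = geometry.members("VN")
        before = ((geometry.coords[idx] - geometry.centroids[0]) ** 2).sum()
        after = ((out.coords[idx] - out.centroids[0]) ** 2).sum()
        assert after == pytest.approx(0.25 * before, rel=1e-12)

    def test_outward_shift_increases_centroid_distances(self, geometry):
        eff = fg.default_condition_effect(geometry)
        out = fg.apply_condition_effect(geometry, eff)
        i = NETWORKS.index("FPN")
        others = [j for j in range(7) if j != i]
        before = np.linalg.norm(geometry.centroids[i] - geometry.centroids[others], axis=1).mean()
        after = np.linalg.norm(out.centroids[i] - out.centroids[others], axis=1).mean()
        assert after > before

    def test_unknown_network_rejected(self):
        with pytest.raises(ValueError):
            fg.ConditionEffect(spread_multipliers={"nope": 0.5})

    def test_labels_and_counts_unchanged(self, geometry):
        out = fg.apply_condition_effect(geometry, fg.default_condition_effect(geometry))
        assert out.n_nodes == geometry.n_nodes
        assert list(out.labels) == list(geometry.labels)


class TestSimulateTimeseries:
    def test_duplicate_coordinates_correlate_perfectly(self, design):
        g = fg.make_latent_geometry(28, 2, 0.0, seed=0)  # nodes identical per network
        ts = fg.simulate_timeseries(g, design, noise_sd=0.0, seed=5)
        r = np.corrcoef(ts.data, rowvar=False)
        idx = g.members("VN")
        np.testing.assert_allclose(r[np.ix_(idx, idx)], 1.0, atol=1e-10)

    def test_240_volumes_at_2s_is_an_8_minute_scan(self, geometry):
        d = fg.StudyDesign(n_timepoints=240, interval=2.0)
        ts = fg.simulate_timeseries(geometry, d, seed=0)
        assert ts.duration == 480.0

    def test_empirical_correlation_matches_factor_model_oracle(self, geometry):
        # closed-form factor-model correlation at long T
        d = fg.StudyDesign(n_timepoints=4800)
        ts = fg.simulate_timeseries(geometry, d, noise_sd=1.0, seed=2)
        r_emp = np.corrcoef(ts.data, rowvar=False)
        r_an = analytic_correlation(geometry, noise_sd=1.0)
        assert np.abs(r_emp - r_an).max() < 0.05

    def test_noiseless_correlation_is_exact(self, geometry, design):
        ts = fg.simulate_timeseries(geometry, design, noise_sd=0.0, seed=2)
        r_emp = np.corrcoef(ts.data, rowvar=False)
        np.testing.assert_allclose(r_emp, analytic_correlation(geometry, 0.0), atol=1e-10)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            fg.StudyDesign(n_timepoints=7)

    def test_negative_noise_rejected(self, geometry, design):
        with pytest.raises(ValueError):
            fg.simulate_timeseries(geometry, design, noise_sd=-1.0, seed=0)


class TestSimulateRetest:
    def test_no_session_noise_plants_perfect_reliability(self, geometry, design):
        s = fg.simulate_retest(geometry, design, 0.3, 0.0, seed=0)
        assert s.planted_icc == 1.0
        np.testing.assert_array_equal(s.parameter[:, 0], s.parameter[:, 1])

    def test_equal_variances_plant_half_reliability(self, geometry, design):
        s = fg.simulate_retest(geometry, design, 0.2, 0.2, seed=0)
        assert s.planted_icc == pytest.approx(0.5)

    def test_session_geometry_scales_spread_by_parameter(self, geometry, design):
        s = fg.simulate_retest(geometry, design, 0.2, 0.1, seed=3)
        g1 = s.sessions[0][0]
        idx = geometry.members("DMN")
        i = NETWORKS.index("DMN")
        base = ((geometry.coords[idx] - geometry.centroids[i]) ** 2).sum()
        scaled = ((g1.coords[idx] - g1.centroids[i]) ** 2).sum()
        expected = np.exp(2 * s.parameter[0, 0]) * base
        assert scaled == pytest.approx(expected, rel=1e-10)

    def test_planted_icc_recovered_by_anova_estimator(self, geometry):
        # Monte-Carlo oracle: mean ANOVA ICC over many small studies near 0.4
        d = fg.StudyDesign(n_subjects=21)
        sd_b, sd_w = 0.1, 0.1 * np.sqrt(1.5)  # icc = 0.4
        estimates = []
        for rep in range(300):
            s = fg.simulate_retest(geometry, d, sd_b, sd_w, seed=rep)
            estimates.append(fg.anova_icc(s.parameter).icc)
        assert abs(np.mean(estimates) - 0.4) < 0.05


class TestSimulateConfounds:
    def test_planted_fd_means_recovered(self):
        d = fg.StudyDesign(n_timepoints=240)
        means = {"EC": [], "EO": []}
        for rep in range(300):
            confs = fg.simulate_confounds(d, seed=rep)
            for cond in means:
                means[cond].append(confs[cond].fd[1:].mean())
        assert abs(np.mean(means["EC"]) - 0.053) / 0.053 < 0.10
        assert abs(np.mean(means["EO"]) - 0.044) / 0.044 < 0.10

    def test_exact_recovery_without_subject_spread(self):
        d = fg.StudyDesign()
        confs = fg.simulate_confounds(
            d, {"EC": 0.053, "EO": 0.044}, seed=0,
            fd_sd_by_condition={"EC": 0.0, "EO": 0.0},
        )
        assert confs["EC"].fd[1:].mean() == pytest.approx(0.053, abs=1e-12)
        assert confs["EO"].fd[1:].mean() == pytest.approx(0.044, abs=1e-12)

    def test_zero_amplitude_motion_gives_zero_fd(self, design):
        confs = fg.simulate_confounds(design, seed=0, motion_amplitude=0.0)
        assert np.all(confs["EC"].fd == 0)
        assert np.all(confs["EC"].motion == 0)

    def test_same_seed_reproduces_tables(self, design):
        a = fg.simulate_confounds(design, seed=11)
        b = fg.simulate_confounds(design, seed=11)
        np.testing.assert_array_equal(a["EO"].data, b["EO"].data)

    def test_fd_consistent_with_motion_columns(self, design):
        confs = fg.simulate_confounds(design, seed=4)
        fd = fg.compute_fd(confs["EC"].motion)
        np.testing.assert_allclose(fd, confs["EC"].fd, atol=1e-12)

    def test_nonpositive_mean_rejected(self, design):
        with pytest.raises(ValueError):
            fg.simulate_confounds(design, {"EC": 0.0, "EO": 0.04}, seed=0)


class TestSyntheticMask:
    def test_slab_voxel_count(self):
        mask = fg.make_synthetic_mask((20, 20, 4), "slab", 3.0)
        assert mask.n_voxels == 1600

    def test_single_connected_component(self):
        from scipy import ndimage
        from funcgrad.parcellation import STRUCTURE_6

        for shape in ("slab", "ellipsoid"):
            mask = fg.make_synthetic_mask((10, 12, 8), shape, 3.0)
            _, n = ndimage.label(mask.data, structure=STRUCTURE_6)
            assert n == 1

    def test_voxel_volume(self):
        mask = fg.make_synthetic_mask((8, 8, 4), "slab", 3.0)
        assert mask.voxel_volume == pytest.approx(27.0)

    def test_small_dims_rejected(self):
        with pytest.raises(ValueError):
            fg.make_synthetic_mask((3, 8, 8), "slab", 3.0)


def test_spread_multiplier_monotonicity(geometry):
    """Larger spread multipliers never decrease within-network dispersion."""
    values = []
    for m in (0.5, 1.0, 1.5):
        out = fg.apply_condition_effect(
            geometry, fg.ConditionEffect(spread_multipliers={"DAN": m})
        )
        values.append(fg.within_network_dispersion(out.coords, out.labels, "DAN", dims=2))
    assert values[0] < values[1] < values[2]
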
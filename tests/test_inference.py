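"""Lookup inversion, noise estimation and Monte-Carlo posterior tests."""

import numpy as np
import pytest

from mp3rage.forward import B1Map, ComplexGREImage, UniformSignalImage, mp2rage_signals, uniform_signal
from mp3rage.inference import (
    MonteCarloConfig,
    build_lookup,
    default_t1_grid,
    estimate_noise_roi,
    invert_lookup,
    load_posterior,
    map_estimate,
    map_t1_volume,
    point_estimate_t1,
    run_monte_carlo,
    save_posterior,
)


@pytest.fixture(scope="module")
def low_noise_posterior(protocol):
    cfg = MonteCarloConfig(n_trials=100_000, noise_sigma=1e-4, seed=5)
    return cfg, run_monte_carlo(protocol, 1.0, cfg, mode="pair")


class TestLookup:
    @pytest.mark.parametrize("b1", [0.8, 1.0, 1.2])
    def test_round_trip_within_one_grid_step(self, protocol, b1):
        tab = build_lookup(protocol, b1)
        grid = tab.t1_grid
        step = grid[1] - grid[0]
        sel = (grid >= 0.5) & (grid <= 3.5)
        t1, valid = invert_lookup(tab, tab.s_values[sel])
        assert valid.all()
        assert np.max(np.abs(t1 - grid[sel])) <= step

    def test_out_of_range_marked_invalid(self, protocol):
        tab = build_lookup(protocol, 1.0)
        lo, hi = tab.s_range
        t1, valid = invert_lookup(tab, np.array([hi + 0.01, lo - 0.01]))
        assert not valid.any()
        assert np.isnan(t1).all()

    def test_b1_one_equals_unscaled_flip_angles(self, protocol):
        a = build_lookup(protocol, 1.0)
        b = build_lookup(protocol.with_b1(1.0), 1.0)
        assert np.array_equal(a.s_values, b.s_values)


class TestPointEstimate:
    def test_recovers_forward_generated_voxel(self, protocol):
        cfg = MonteCarloConfig(n_trials=1000, seed=0)
        sig = mp2rage_signals(1.5, protocol, 1.0)
        s12 = uniform_signal(sig[0] + 0j, sig[1] + 0j)
        img = UniformSignalImage(np.full((2, 2, 1), s12))
        res = point_estimate_t1(img, B1Map(np.ones((2, 2, 1))), protocol, cfg)
        step = cfg.t1_grid[1] - cfg.t1_grid[0]
        assert res.valid_mask.all()
        assert np.allclose(res.t1_s, 1.5, atol=step)

    def test_between_grid_b1_interpolates(self, protocol):
        cfg = MonteCarloConfig(n_trials=1000, seed=0)
        b1_true = 0.93  # strictly between the 0.90 and 0.95 grid factors
        sig = mp2rage_signals(1.5, protocol, b1_true)
        s12 = uniform_signal(sig[0] + 0j, sig[1] + 0j)
        img = UniformSignalImage(np.full((1, 1, 1), s12))
        res = point_estimate_t1(img, B1Map(np.full((1, 1, 1), b1_true)), protocol, cfg)
        assert res.valid_mask.all()
        assert res.t1_s[0, 0, 0] == pytest.approx(1.5, abs=0.03)

    def test_zero_b1_map_all_invalid(self, protocol):
        cfg = MonteCarloConfig(n_trials=1000, seed=0)
        img = UniformSignalImage(np.full((2, 2, 1), 0.1))
        res = point_estimate_t1(img, B1Map(np.zeros((2, 2, 1))), protocol, cfg)
        assert not res.valid_mask.any()


class TestNoiseEstimate:
    def _gres(self, data):
        return [ComplexGREImage(data=d) for d in data]

    def test_max_rule_identity_scaling(self):
        rng = np.random.default_rng(0)
        shape = (10, 10, 10)
        roi = np.ones(shape, dtype=bool)
        g1 = rng.normal(0, 0.01, shape) + 1j * rng.normal(0, 0.01, shape)
        g2 = rng.normal(0, 0.02, shape) + 1j * rng.normal(0, 0.02, shape)
        est = estimate_noise_roi(self._gres([1 + g1, 1 + g2]), roi)
        assert est.sigma == max(est.per_channel_sds)
        assert est.sigma == pytest.approx(0.02, rel=0.2)

    def test_sampling_distribution_at_1000_voxels(self):
        rng = np.random.default_rng(7)
        shape = (10, 10, 10)
        roi = np.ones(shape, dtype=bool)
        g = 1 + rng.normal(0, 0.01, shape) + 1j * rng.normal(0, 0.01, shape)
        est = estimate_noise_roi(self._gres([g]), roi)
        assert est.sigma == pytest.approx(0.01, rel=0.10)
        assert est.roi_voxel_count == 1000

    def test_constant_roi_is_degenerate(self):
        roi = np.ones((5, 5, 5), dtype=bool)
        g = np.full((5, 5, 5), 1 + 1j)
        with pytest.raises(ValueError, match="zero variance"):
            estimate_noise_roi(self._gres([g]), roi)

    def test_small_roi_rejected(self):
        roi = np.zeros((5, 5, 5), dtype=bool)
        roi[0, 0, :3] = True
        with pytest.raises(ValueError, match="ROI too small"):
            estimate_noise_roi(self._gres([np.ones((5, 5, 5), complex)]), roi)


class TestMonteCarlo:
    def test_counts_conserve_trials(self, low_noise_posterior):
        cfg, post = low_noise_posterior
        assert post.counts.sum() == cfg.n_trials

    def test_likelihood_rows_normalize(self, low_noise_posterior):
        _, post = low_noise_posterior
        rows = post.likelihood().reshape(post.counts.shape[0], -1).sum(axis=1)
        assert np.allclose(rows, 1.0, atol=1e-9)

    def test_posterior_columns_normalize(self, low_noise_posterior):
        _, post = low_noise_posterior
        cols = post.posterior().reshape(post.counts.shape[0], -1).sum(axis=0)
        occupied = post.counts.reshape(post.counts.shape[0], -1).sum(axis=0) > 0
        assert np.allclose(cols[occupied], 1.0, atol=1e-6)

    def test_bit_identical_under_same_seed(self, protocol):
        cfg = MonteCarloConfig(n_trials=50_000, noise_sigma=0.005, seed=9)
        a = run_monte_carlo(protocol, 1.0, cfg)
        b = run_monte_carlo(protocol, 1.0, cfg)
        assert np.array_equal(a.counts, b.counts)

    def test_low_noise_mass_concentrates_on_consistent_t1(self, protocol):
        cfg = MonteCarloConfig(n_trials=100_000, noise_sigma=1e-6, seed=2)
        post = run_monte_carlo(protocol, 1.0, cfg)
        # in the delta limit each T1 row occupies exactly the bin its
        # noiseless S falls into
        sig = mp2rage_signals(cfg.t1_grid, protocol, 1.0)
        s12 = uniform_signal(sig[0] + 0j, sig[1] + 0j)
        expected_bin = np.clip(((s12 + 0.5) / 0.01).astype(int), 0, 99)
        observed_bin = np.argmax(post.counts, axis=1)
        assert np.mean(observed_bin == expected_bin) > 0.99

    def test_joint_mode_requires_three_blocks(self, protocol):
        cfg = MonteCarloConfig(n_trials=10_000, seed=0)
        from dataclasses import replace
        two = replace(protocol, inversion_times_s=protocol.inversion_times_s[:2],
                      flip_deg=protocol.flip_deg[:2])
        with pytest.raises(ValueError, match="joint"):
            run_monte_carlo(two, 1.0, cfg, mode="joint")


class TestMapEstimate:
    def test_tie_breaks_to_smaller_t1(self, low_noise_posterior):
        _, post = low_noise_posterior
        tied = post.__class__(
            t1_grid=np.array([1.0, 2.0]),
            counts=np.array([[0, 5], [0, 5]]),
            bin_edges=np.linspace(-0.5, 0.5, 3),
            b1=1.0, mode="pair", noise_sigma=0.005, n_trials=10)
        t1, sigma, ok = map_estimate(tied, 0.25)
        assert ok and t1 == 1.0

    def test_uniform_posterior_sigma_closed_form(self):
        from mp3rage.inference import PosteriorGrid
        grid = default_t1_grid(500)
        counts = np.zeros((500, 100), dtype=int)
        counts[:, 50] = 7  # uniform over T1 in one bin
        post = PosteriorGrid(t1_grid=grid, counts=counts,
                             bin_edges=np.linspace(-0.5, 0.5, 101),
                             b1=1.0, mode="pair", noise_sigma=0.005, n_trials=3500)
        _, sigma, ok = map_estimate(post, 0.005)
        assert ok
        assert sigma == pytest.approx(5.0 / np.sqrt(12), rel=0.01)

    def test_out_of_range_s_invalid(self, low_noise_posterior):
        _, post = low_noise_posterior
        t1, sigma, ok = map_estimate(post, 0.75)
        assert not ok and np.isnan(t1)

    def test_map_agrees_with_point_estimate_up_to_bin_quantization(
            self, protocol, low_noise_posterior):
        """At vanishing noise the MAP and the lookup inversion agree up to
        the S-bin quantization: one 0.01-wide S bin spans several T1 grid
        steps wherever |dS/dT1| < 0.01 / step."""
        cfg, post = low_noise_posterior
        tab = build_lookup(protocol, 1.0)
        grid, s = tab.t1_grid, tab.s_values
        step = grid[1] - grid[0]
        sel = (grid >= 0.5) & (grid <= 3.5)
        ds_dt1 = np.abs(np.gradient(s, grid))
        bin_span_s = 0.01 / ds_dt1  # local T1 width of one S bin
        for t1v, sv, span in zip(grid[sel][::7], s[sel][::7], bin_span_s[sel][::7]):
            t1m, _, ok = map_estimate(post, sv)
            assert ok
            assert abs(t1m - t1v) <= span + 2 * step


class TestMapVolume:
    def test_volume_path_matches_scalar_map_estimate(self, protocol, posterior_cache):
        """The voxelwise volume path reproduces the scalar map_estimate
        applied to each voxel's uniform-image value (recovery accuracy
        itself is exercised by the phantom acceptance test)."""
        cfg = MonteCarloConfig(n_trials=200_000, noise_sigma=0.005, seed=4)
        t1_true = np.linspace(0.9, 2.2, 32).reshape(4, 8, 1)
        sig = mp2rage_signals(t1_true, protocol, 1.0)
        gres = [ComplexGREImage(sig[k] + 0j) for k in range(3)]
        res = map_t1_volume(gres, B1Map(np.ones(t1_true.shape)), protocol, cfg,
                            mode="pair", posterior_cache=posterior_cache)
        assert res.valid_mask.all()
        post = posterior_cache[(1.0, "pair", cfg.config_hash())]
        s12 = uniform_signal(gres[0].data, gres[1].data)
        for idx in np.ndindex(t1_true.shape):
            t1m, sg, ok = map_estimate(post, s12[idx])
            assert ok
            assert res.t1_s[idx] == t1m
            assert res.sigma_t1_s[idx] == sg

    def test_joint_sigma_not_larger_than_pair(self, protocol, posterior_cache):
        cfg = MonteCarloConfig(n_trials=1_000_000, noise_sigma=0.005, seed=4)
        t1_true = np.linspace(0.8, 2.2, 64).reshape(8, 8, 1)
        sig = mp2rage_signals(t1_true, protocol, 1.0)
        gres = [ComplexGREImage(sig[k] + 0j) for k in range(3)]
        b1 = B1Map(np.ones(t1_true.shape))
        pair = map_t1_volume(gres, b1, protocol, cfg, "pair", posterior_cache)
        joint = map_t1_volume(gres, b1, protocol, cfg, "joint", posterior_cache)
        both = pair.valid_mask & joint.valid_mask
        assert both.mean() > 0.9
        assert (np.median(joint.sigma_t1_s[both])
                <= np.median(pair.sigma_t1_s[both]))

    def test_all_zero_gres_invalid(self, protocol):
        cfg = MonteCarloConfig(n_trials=50_000, noise_sigma=0.005, seed=4)
        z = np.zeros((3, 3, 1), complex)
        res = map_t1_volume([ComplexGREImage(z)] * 3, B1Map(np.ones(z.shape)),
                            protocol, cfg, mode="pair")
        assert not res.valid_mask.any()

    def test_b1_mismatch_biases_map_t1(self, protocol, posterior_cache):
        """Data acquired at b1 = 0.8 but decoded with the b1 = 1 posterior
        is biased by at least 3 grid steps at T1 = 1.5 s."""
        cfg = MonteCarloConfig(n_trials=200_000, noise_sigma=0.001, seed=4)
        t1_true = np.full((6, 6, 1), 1.5)
        sig = mp2rage_signals(t1_true, protocol, 0.8)
        gres = [ComplexGREImage(sig[k] + 0j) for k in range(3)]
        res = map_t1_volume(gres, B1Map(np.ones(t1_true.shape)), protocol, cfg,
                            mode="pair", posterior_cache=posterior_cache)
        step = cfg.t1_grid[1] - cfg.t1_grid[0]
        assert np.abs(np.median(res.t1_s[res.valid_mask]) - 1.5) >= 3 * step


class TestUncertaintyMonotonicity:
    def test_median_sigma_increases_with_noise(self, protocol):
        """Posterior width grows with the injected noise level (the
        protocol's noise-level sweep, in reduced-trial mode)."""
        medians = []
        for sigma in (0.001, 0.005, 0.01):
            cfg = MonteCarloConfig(n_trials=200_000, noise_sigma=sigma, seed=6)
            post = run_monte_carlo(protocol, 1.0, cfg)
            _, sig_tab, ok = post.map_tables()
            medians.append(np.median(sig_tab[ok]))
        assert medians[0] < medians[1] < medians[2]


class TestPosteriorIO:
    def test_roundtrip(self, tmp_path, low_noise_posterior):
        _, post = low_noise_posterior
        path = tmp_path / "post.npz"
        save_posterior(post, path)
        loaded = load_posterior(path)
        assert np.array_equal(loaded.counts, post.counts)
        assert loaded.b1 == post.b1
        assert loaded.config_hash == post.config_hash
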
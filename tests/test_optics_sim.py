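"""Forward-model statistics: speckle laws, memory effect, noise, contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import specklemix as sm
from specklemix.optics_sim import substream


class TestPatternGeneration:
    def test_shapes_range_and_reproducibility(self):
        a = sm.generate_random_patterns(32, 100, seed=5)
        b = sm.generate_random_patterns(32, 100, seed=5)
        assert a.phases.shape == (32, 100)
        assert np.all((a.phases >= 0) & (a.phases < 2 * np.pi))
        assert np.array_equal(a.phases, b.phases)

    def test_different_seeds_are_uncorrelated(self):
        a = sm.generate_random_patterns(64, 200, seed=1).phases.ravel()
        b = sm.generate_random_patterns(64, 200, seed=2).phases.ravel()
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.02

    def test_zero_phases_give_unit_fields(self):
        pats = sm.PhasePatternSet(np.zeros((4, 1)))
        assert np.allclose(pats.fields, 1.0)
        assert np.allclose(np.abs(sm.generate_random_patterns(8, 16, 0).fields), 1.0)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            sm.generate_random_patterns(0, 10, 0)
        with pytest.raises(ValueError):
            sm.generate_random_patterns(10, 0, 0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(n=st.integers(1, 32), p=st.integers(1, 32), seed=st.integers(0, 10_000))
    def test_phases_always_in_principal_range(self, n, p, seed):
        phases = sm.generate_random_patterns(n, p, seed).phases
        assert phases.shape == (n, p)
        assert np.all((phases >= 0) & (phases < 2 * np.pi))


class TestFieldTM:
    @staticmethod
    def _pair_tm(d, me_range, seed, n_slm=256):
        cfg = sm.SimulationConfig(
            n_targets=2, n_slm=n_slm, grid_shape=(64, 64), n_patterns=1,
            me_range=me_range, seed=seed,
        )
        emitters = sm.EmitterMap(np.array([[32, 10], [32, 10 + d]]))
        return sm.make_field_tm(cfg, emitters)

    def test_coincident_emitters_share_a_row(self):
        cfg = sm.SimulationConfig(
            n_targets=2, n_slm=64, grid_shape=(32, 32), n_patterns=1, me_range=5.0, seed=3
        )
        tm = sm.make_field_tm(cfg, sm.EmitterMap(np.array([[10, 10], [10, 10]])))
        assert np.allclose(tm.matrix[0], tm.matrix[1])

    def test_memory_effect_correlation_decays_as_gaussian(self):
        """Registered speckle correlation between two emitters follows
        c(d) = exp(-d^2 / 2 sigma^2), hence intensity correlation c(d)^2."""
        me = 8.0
        seps = [0, 4, 8, 16, 32]
        measured = []
        for d in seps:
            vals = [
                self._pair_tm(d, me, seed).registered_row_correlation(0, 1)
                for seed in range(15)
            ]
            measured.append(np.mean(vals))
        expected = [np.exp(-(d**2) / (2 * me**2)) for d in seps]
        assert np.all(np.diff(measured) < 1e-9)  # monotone decay
        np.testing.assert_allclose(measured, expected, atol=0.08)

    def test_distant_pair_decorrelated(self):
        vals = [
            self._pair_tm(48, 6.0, seed).registered_row_correlation(0, 1)
            for seed in range(20)
        ]
        # residual correlation is the O(1/sqrt(n_slm)) sampling floor
        assert np.mean(vals) < 3.0 / np.sqrt(256)

    def test_excitation_intensity_is_exponential(self):
        """Fully developed speckle: |t . E_in|^2 follows an exponential law."""
        cfg = sm.SimulationConfig(
            n_targets=1, n_slm=128, grid_shape=(16, 16), n_patterns=4000,
            me_range=5.0, seed=9,
        )
        tm = sm.make_field_tm(cfg, sm.EmitterMap(np.array([[8, 8]])))
        pats = sm.generate_random_patterns(128, 4000, 9)
        h = tm.excitation_intensity(pats)[0]
        ks = stats.kstest(h / h.mean(), "expon")
        assert ks.pvalue > 0.01
        assert abs(h.std() / h.mean() - 1.0) < 0.1  # contrast -> 1

    def test_emitter_outside_grid_rejected(self):
        cfg = sm.SimulationConfig(
            n_targets=1, n_slm=16, grid_shape=(16, 16), n_patterns=1, me_range=4.0, seed=0
        )
        with pytest.raises(ValueError, match="outside"):
            sm.make_field_tm(cfg, sm.EmitterMap(np.array([[20, 3]])))

    def test_invalid_me_range_rejected(self):
        with pytest.raises(ValueError, match="me_range"):
            sm.SimulationConfig(
                n_targets=1, n_slm=16, grid_shape=(16, 16), n_patterns=1, me_range=0.0
            )


class TestIntensityTM:
    @staticmethod
    def _tm_for(positions, me_range=8.0, seed=5, grid=(64, 64)):
        cfg = sm.SimulationConfig(
            n_targets=len(positions), n_slm=16, grid_shape=grid, n_patterns=1,
            me_range=me_range, seed=seed,
        )
        return sm.make_intensity_tm(cfg, sm.EmitterMap(np.array(positions)))

    def test_coincident_emitters_share_a_column(self):
        tm = self._tm_for([[20, 20], [20, 20]])
        assert np.allclose(tm.matrix[:, 0], tm.matrix[:, 1])

    @pytest.mark.parametrize("shift", [(0, 5), (3, -4), (-6, 2)])
    def test_within_me_shift_planted_exactly(self, shift):
        base = np.array([30, 30])
        tm = self._tm_for([base, base + shift], me_range=10.0)
        u, score = sm.cross_correlate(tm.pattern(0), tm.pattern(1))
        assert tuple(u) == shift
        assert score > 5

    def test_beyond_me_pair_uncorrelated(self):
        scores = []
        for seed in range(8):
            tm = self._tm_for([[14, 14], [50, 50]], me_range=4.0, seed=seed)
            a, b = tm.pattern(0), tm.pattern(1)
            shifted = np.roll(a, (36, 36), axis=(0, 1))
            scores.append(abs(np.corrcoef(shifted.ravel(), b.ravel())[0, 1]))
        assert np.mean(scores) < 0.05

    def test_brightness_scales_columns(self):
        cfg = sm.SimulationConfig(
            n_targets=2, n_slm=16, grid_shape=(32, 32), n_patterns=1, me_range=5.0, seed=7
        )
        em1 = sm.EmitterMap(np.array([[10, 10], [20, 20]]), brightness=[1.0, 1.0])
        em2 = sm.EmitterMap(np.array([[10, 10], [20, 20]]), brightness=[1.0, 3.0])
        w1 = sm.make_intensity_tm(cfg, em1)
        w2 = sm.make_intensity_tm(cfg, em2)
        np.testing.assert_allclose(w2.matrix[:, 1], 3.0 * w1.matrix[:, 1])


class TestAcquisition:
    def test_noiseless_forward_model_is_exact(self, small_sim):
        s = small_sim
        h = s["field_tm"].excitation_intensity(s["patterns"])
        expected = s["intensity_tm"].matrix @ h
        np.testing.assert_allclose(s["stack"].images, expected, rtol=1e-12)

    def test_rank_one_stack_has_identical_frames(self):
        cfg = sm.SimulationConfig(
            n_targets=1, n_slm=32, grid_shape=(24, 24), n_patterns=20, me_range=5.0, seed=2
        )
        em = sm.EmitterMap(np.array([[12, 12]]))
        stack = sm.simulate_acquisition(
            sm.make_field_tm(cfg, em), sm.make_intensity_tm(cfg, em),
            sm.generate_random_patterns(32, 20, 2), cfg,
        )
        corr = np.corrcoef(stack.images.T)
        np.testing.assert_allclose(corr, 1.0, atol=1e-10)

    def test_noiseless_rank_equals_n_targets(self, small_sim):
        sv = np.linalg.svd(small_sim["stack"].images, compute_uv=False)
        assert np.sum(sv > sv[0] * 1e-8) == small_sim["config"].n_targets

    def test_nonsquare_camera_grid_supported(self):
        cfg = sm.SimulationConfig(
            n_targets=2, n_slm=16, grid_shape=(70, 64), n_patterns=4, me_range=5.0, seed=3
        )
        em = sm.EmitterMap(np.array([[30, 30], [40, 40]]))
        stack = sm.simulate_acquisition(
            sm.make_field_tm(cfg, em), sm.make_intensity_tm(cfg, em),
            sm.generate_random_patterns(16, 4, 3), cfg,
        )
        assert stack.images.shape == (70 * 64, 4)
        assert stack.frame(0).shape == (70, 64)

    def test_dimension_mismatch_names_axis(self, small_sim):
        s = small_sim
        bad = sm.generate_random_patterns(32, 10, 0)  # wrong n_slm
        with pytest.raises(ValueError, match="n_slm"):
            sm.simulate_acquisition(s["field_tm"], s["intensity_tm"], bad, s["config"])

    def test_noise_reproducible_and_nonnegative(self):
        cfg = sm.SimulationConfig(
            n_targets=2, n_slm=16, grid_shape=(24, 24), n_patterns=10,
            me_range=5.0, photon_budget=50.0, read_noise_sd=2.0, seed=4,
        )
        em = sm.EmitterMap(np.array([[8, 8], [16, 16]]))
        args = (sm.make_field_tm(cfg, em), sm.make_intensity_tm(cfg, em),
                sm.generate_random_patterns(16, 10, 4), cfg)
        s1 = sm.simulate_acquisition(*args)
        s2 = sm.simulate_acquisition(*args)
        assert np.array_equal(s1.images, s2.images)
        assert np.all(s1.images >= 0)
        assert not np.allclose(
            s1.images, args[1].matrix @ args[0].excitation_intensity(args[2])
        )


class TestContrast:
    def test_constant_image_has_zero_contrast(self):
        assert sm.speckle_contrast(np.full((10, 10), 3.0)) == 0.0

    def test_exponential_speckle_has_unit_contrast(self):
        x = np.random.default_rng(0).exponential(size=100_000)
        assert abs(sm.speckle_contrast(x) - 1.0) < 0.02

    def test_zero_mean_image_rejected(self):
        with pytest.raises(ValueError):
            sm.speckle_contrast(np.zeros((5, 5)))

    @staticmethod
    def _equal_emitter_stack(n, seed, exponent=1, n_patterns=200, grid=(96, 96)):
        cfg = sm.SimulationConfig(
            n_targets=n, n_slm=64, grid_shape=grid, n_patterns=n_patterns,
            me_range=3.0, excitation_exponent=exponent, seed=seed,
        )
        em = sm.random_emitters(grid, n, min_sep=14, rng=substream(seed, "em"), margin=6)
        return sm.simulate_acquisition(
            sm.make_field_tm(cfg, em), sm.make_intensity_tm(cfg, em),
            sm.generate_random_patterns(64, n_patterns, seed), cfg,
        )

    def test_contrast_follows_sqrt_two_over_n(self):
        """Mean frame contrast for N equal emitters scales as sqrt(2/N)."""
        stack = self._equal_emitter_stack(8, seed=21)
        assert abs(sm.stack_contrast(stack) - np.sqrt(2 / 8)) < 0.1 * np.sqrt(2 / 8)

    def test_two_photon_excitation_raises_contrast(self):
        c1 = sm.stack_contrast(self._equal_emitter_stack(6, seed=13, exponent=1))
        c2 = sm.stack_contrast(self._equal_emitter_stack(6, seed=13, exponent=2))
        assert c2 > c1


class TestPolarization:
    @staticmethod
    def _single_speckle_stack(seed, grid=(96, 96), n_patterns=64):
        cfg = sm.SimulationConfig(
            n_targets=1, n_slm=32, grid_shape=grid, n_patterns=n_patterns,
            me_range=4.0, seed=seed,
        )
        em = sm.EmitterMap(np.array([[grid[0] // 2, grid[1] // 2]]))
        return sm.simulate_acquisition(
            sm.make_field_tm(cfg, em), sm.make_intensity_tm(cfg, em),
            sm.generate_random_patterns(32, n_patterns, seed), cfg,
        )

    def test_identical_channels_leave_contrast_unchanged(self):
        a = self._single_speckle_stack(3)
        merged = sm.polarization_channels(a, a)
        assert abs(sm.stack_contrast(merged) - sm.stack_contrast(a)) < 1e-12

    def test_independent_channels_reduce_contrast_by_sqrt2(self):
        a = self._single_speckle_stack(3)
        b = self._single_speckle_stack(104729)
        ratio = sm.stack_contrast(a) / sm.stack_contrast(sm.polarization_channels(a, b))
        assert abs(ratio - np.sqrt(2)) < 0.05

    def test_k_channel_average_scales_as_inverse_sqrt_k(self):
        stacks = [self._single_speckle_stack(s) for s in (11, 211, 3011, 40011)]
        merged2 = sm.polarization_channels(stacks[0], stacks[1])
        merged4 = sm.polarization_channels(merged2, sm.polarization_channels(stacks[2], stacks[3]))
        ratio = sm.stack_contrast(stacks[0]) / sm.stack_contrast(merged4)
        assert abs(ratio - 2.0) < 0.15

    def test_shape_mismatch_rejected(self):
        a = self._single_speckle_stack(3)
        b = self._single_speckle_stack(4, grid=(48, 48))
        with pytest.raises(ValueError, match="shape"):
            sm.polarization_channels(a, b)
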
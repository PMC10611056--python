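"""Tests for noise-mode precomputation, EEMD, and the ICEEMDAN recursion."""

import numpy as np
import pytest

from iceemdan.ensemble import (
    EnsembleConfig,
    RealizationBatch,
    batch_local_mean,
    eemd,
    ensemble_average,
    iceemdan,
    make_realizations,
    noise_amplitude,
    precompute_noise_modes,
)
from iceemdan.envelopes import find_extrema
from iceemdan.metrics import count_zero_crossings, similarity_index
from iceemdan.sifting import SiftConfig, emd, local_mean

from .oracles import iterated_local_mean_decomposition, two_pass_std

SMALL = dict(n_realizations=8, max_modes=6, sift=SiftConfig(n_iterations=5))


class TestNoiseModes:
    def test_same_seed_gives_bitwise_identical_tensors(self):
        cfg = EnsembleConfig(n_realizations=4, max_modes=4, seed=11)
        t1 = precompute_noise_modes(cfg, 256)
        t2 = precompute_noise_modes(cfg, 256)
        assert np.array_equal(t1.values, t2.values)

    def test_realization_streams_independent_of_ensemble_size(self):
        small = precompute_noise_modes(EnsembleConfig(n_realizations=3, max_modes=3, seed=5), 128)
        large = precompute_noise_modes(EnsembleConfig(n_realizations=6, max_modes=3, seed=5), 128)
        assert np.array_equal(small.values, large.values[:, :3, :])

    def test_zero_crossing_count_decreases_with_mode_index(self):
        # dyadic filterbank property of EMD on white noise
        cfg = EnsembleConfig(n_realizations=100, max_modes=5, seed=3)
        tensor = precompute_noise_modes(cfg, 2000)
        mean_zc = [
            np.mean([count_zero_crossings(tensor.values[k, i]) for i in range(100)])
            for k in range(4)
        ]
        assert all(a > b for a, b in zip(mean_zc, mean_zc[1:]))

    def test_first_mode_ensemble_mean_shrinks_like_standard_error(self):
        # averaging I independent noise modes shrinks them like 1/sqrt(I):
        # the per-sample z-score mean/(std/sqrt(I)) should be ~N(0,1)
        cfg = EnsembleConfig(n_realizations=200, max_modes=2, seed=9)
        tensor = precompute_noise_modes(cfg, 2000)
        e1 = tensor.values[0]
        z = np.abs(e1.mean(axis=0)) / (e1.std(axis=0) / np.sqrt(200))
        assert 0.8 <= np.sqrt(np.mean(z**2)) <= 1.2
        assert z.max() <= 5.0  # max of 2000 unit-normal scores


class TestNoiseAmplitude:
    def test_zero_residue(self):
        assert noise_amplitude(np.zeros(10), 0.2) == 0.0

    def test_unit_std_residue_returns_eps0(self):
        r = np.array([1.0, -1.0] * 50)  # population std exactly 1
        assert noise_amplitude(r, 0.2) == pytest.approx(0.2)

    def test_matches_two_pass_oracle(self, rng):
        r = rng.standard_normal(500)
        assert noise_amplitude(r, 0.3) == pytest.approx(0.3 * two_pass_std(r), rel=1e-12)

    def test_normalized_rule_divides_by_noise_std(self, rng):
        r = rng.standard_normal(100)
        beta = noise_amplitude(r, 0.2, "normalized-first-mode", noise_mode_std=2.0)
        assert beta == pytest.approx(0.1 * two_pass_std(r), rel=1e-12)
        with pytest.raises(ValueError, match="noise_mode_std"):
            noise_amplitude(r, 0.2, "normalized-first-mode")

    def test_empty_residue_diagnosed(self):
        with pytest.raises(ValueError, match="empty"):
            noise_amplitude(np.empty(0), 0.2)


class TestRealizationsAndAveraging:
    def test_zero_beta_copies_residue(self, rng):
        r = rng.standard_normal(64)
        batch = make_realizations(r, rng.standard_normal((5, 64)), 0.0)
        assert np.array_equal(batch.values, np.tile(r, (5, 1)))

    def test_single_realization_unit_beta(self, rng):
        r, e = rng.standard_normal(32), rng.standard_normal((1, 32))
        batch = make_realizations(r, e, 1.0)
        assert np.array_equal(batch.values[0], r + e[0])

    def test_matches_elementwise_oracle(self, rng):
        r, e, beta = rng.standard_normal(16), rng.standard_normal((3, 16)), 0.7
        batch = make_realizations(r, e, beta)
        expected = np.array([[ri + beta * eij for ri, eij in zip(r, row)] for row in e])
        assert batch.values == pytest.approx(expected, abs=1e-15)

    def test_shape_mismatch_diagnosed(self, rng):
        with pytest.raises(ValueError, match="incompatible"):
            make_realizations(rng.standard_normal(10), rng.standard_normal((2, 12)), 1.0)

    def test_ensemble_average_trivial_and_oracle(self, rng):
        row = rng.standard_normal(20)
        assert np.array_equal(ensemble_average(row[None, :]), row)
        assert ensemble_average(np.stack([row, -row])) == pytest.approx(np.zeros(20), abs=1e-16)
        m = rng.standard_normal((7, 20))
        expected = np.array([sum(m[:, j]) / 7 for j in range(20)])
        assert ensemble_average(m) == pytest.approx(expected, abs=1e-12)

    def test_batch_local_mean_equals_sequential_loop(self, rng):
        batch = RealizationBatch(rng.standard_normal((50, 128)))
        got = batch_local_mean(batch, SiftConfig(n_iterations=5))
        for i in range(50):
            expected = local_mean(batch.values[i], SiftConfig(n_iterations=5))
            assert np.max(np.abs(got[i] - expected)) <= 1e-12

    def test_batch_of_identical_rows_gives_identical_outputs(self, rng):
        row = rng.standard_normal(128)
        batch = RealizationBatch(np.tile(row, (4, 1)))
        out = batch_local_mean(batch, SiftConfig(n_iterations=3))
        assert np.array_equal(out, np.tile(out[0], (4, 1)))


class TestEEMD:
    def test_no_noise_single_realization_equals_plain_emd(self, tone_1000):
        cfg = EnsembleConfig(n_realizations=1, noise_strength=0.0, max_modes=8)
        got = eemd(tone_1000, cfg)
        expected = emd(tone_1000, max_modes=8)
        assert got.n_modes == expected.n_modes
        for a, b in zip(got.modes, expected.modes):
            assert np.array_equal(a.samples, b.samples)

    def test_dual_tone_components_recovered(self, dual_tone):
        cfg = EnsembleConfig(n_realizations=100, max_modes=10, seed=4)
        dec = eemd(dual_tone.composite, cfg)
        best_s1 = max(similarity_index(m.samples, dual_tone.component_s1) for m in dec.modes)
        best_s2 = max(similarity_index(m.samples, dual_tone.component_s2) for m in dec.modes)
        assert best_s1 >= 0.95 and best_s2 >= 0.95

    def test_reported_decomposition_reconstructs_input(self, dual_tone):
        cfg = EnsembleConfig(n_realizations=10, max_modes=8, seed=2)
        dec = eemd(dual_tone.composite, cfg)
        err = np.max(np.abs(dec.reconstruct() - dual_tone.composite.samples))
        assert err <= 1e-9 * np.max(np.abs(dual_tone.composite.samples))


class TestICEEMDAN:
    def test_completeness_for_arbitrary_input(self, rng):
        x = rng.standard_normal(300)
        res = iceemdan(x, EnsembleConfig(seed=1, **SMALL))
        assert np.max(np.abs(res.reconstruct() - x)) <= 1e-9 * np.max(np.abs(x))

    def test_modes_are_residue_differences(self, rng):
        x = rng.standard_normal(300)
        res = iceemdan(x, EnsembleConfig(seed=1, **SMALL))
        prev = x
        for mode, rk in zip(res.modes, res.residues):
            assert np.array_equal(mode.samples, prev - rk)
            prev = rk

    def test_zero_noise_reduces_to_iterated_local_mean_bitwise(self, rng):
        x = rng.standard_normal(400)
        cfg = EnsembleConfig(n_realizations=5, max_modes=6, noise_strength=0.0, seed=0)
        res = iceemdan(x, cfg)

        def has_oscillation(r):
            ext = find_extrema(r)
            return ext.n_maxima >= 2 and ext.n_minima >= 2

        modes, residue = iterated_local_mean_decomposition(
            x, lambda r: local_mean(r, cfg.sift), cfg.max_modes, has_oscillation
        )
        assert len(modes) == res.n_modes
        for got, expected in zip(res.modes, modes):
            assert np.array_equal(got.samples, expected)
        assert np.array_equal(res.residue, residue)

    def test_full_run_determinism_is_bitwise(self, dual_tone):
        cfg = EnsembleConfig(n_realizations=6, max_modes=5, seed=77)
        r1 = iceemdan(dual_tone.composite, cfg)
        r2 = iceemdan(dual_tone.composite, cfg)
        assert r1.n_modes == r2.n_modes
        assert np.array_equal(r1.mode_matrix(), r2.mode_matrix())
        assert np.array_equal(r1.residue, r2.residue)
        assert r1.betas == r2.betas

    def test_betas_follow_residue_std(self, dual_tone):
        cfg = EnsembleConfig(n_realizations=6, max_modes=4, seed=1, noise_strength=0.25)
        res = iceemdan(dual_tone.composite, cfg)
        assert res.betas[0] == pytest.approx(0.25 * np.std(dual_tone.composite.samples))
        for k in range(1, len(res.betas)):
            assert res.betas[k] == pytest.approx(0.25 * np.std(res.residues[k - 1]))

    def test_mode_frequencies_strictly_decrease_on_dual_tone(self, dual_tone):
        cfg = EnsembleConfig(n_realizations=20, max_modes=8, seed=6)
        res = iceemdan(dual_tone.composite, cfg)
        zc = [count_zero_crossings(m.samples) for m in res.modes if np.ptp(m.samples) > 0]
        assert all(a > b for a, b in zip(zc, zc[1:]))

    def test_normalized_beta_rule_runs_and_reconstructs(self, dual_tone):
        cfg = EnsembleConfig(
            n_realizations=8, max_modes=5, seed=1, beta_rule="normalized-first-mode"
        )
        res = iceemdan(dual_tone.composite, cfg)
        x = dual_tone.composite.samples
        assert np.max(np.abs(res.reconstruct() - x)) <= 1e-9 * np.max(np.abs(x))

    def test_single_precision_pipeline(self, dual_tone):
        cfg = EnsembleConfig(n_realizations=4, max_modes=4, seed=1, precision="single")
        res = iceemdan(dual_tone.composite, cfg)
        assert res.mode_matrix().dtype == np.float32
        x = dual_tone.composite.samples.astype(np.float32)
        assert np.max(np.abs(res.reconstruct() - x)) <= 1e-5 * np.max(np.abs(x))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EnsembleConfig(n_realizations=0)
        with pytest.raises(ValueError):
            EnsembleConfig(noise_strength=-0.1)
        with pytest.raises(ValueError):
            EnsembleConfig(beta_rule="other")
        with pytest.raises(ValueError):
            EnsembleConfig(precision="half")
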
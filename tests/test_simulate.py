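"""Forward Wright-Fisher trait simulator: effect draws, fitness, dynamics."""

import numpy as np
import pytest

from evocompass.simulate import (
    DemographicModel,
    Epoch,
    GWASNoiseParams,
    TraitModelParams,
    add_estimation_noise,
    apply_misorientation,
    draw_effect,
    eyre_walker_mode,
    gaussian_fitness,
    run_forward_simulation,
)


class TestDrawEffect:
    def test_full_bias_gives_all_positive(self, rng):
        params = TraitModelParams(delta=0.999999)
        assert np.all(draw_effect(params, rng, size=1000) > 0)

    def test_sign_frequency_matches_delta(self, rng):
        params = TraitModelParams(delta=0.5)
        draws = draw_effect(params, rng, size=100_000)
        frac = np.mean(draws > 0)
        se = np.sqrt(0.25 / 100_000)
        assert abs(frac - 0.5) < 3 * se

    def test_mean_effect_identity(self, rng):
        """E[β] = (2δ − 1)·E[|β|] for sign-symmetric magnitude draws."""
        params = TraitModelParams(delta=0.4, effect_scale=0.3)
        draws = draw_effect(params, rng, size=100_000)
        expected = (2 * 0.4 - 1) * 0.3
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 4 * se


class TestGaussianFitness:
    def test_maximal_at_optimum(self):
        assert gaussian_fitness(2.0, 2.0, 1.0) == pytest.approx(1.0)
        assert gaussian_fitness(1.9, 2.0, 1.0) < 1.0

    def test_one_sd_displacement(self):
        assert gaussian_fitness(1.0, 0.0, 1.0) == pytest.approx(np.exp(-0.5))
        assert gaussian_fitness(-1.0, 0.0, 1.0) == pytest.approx(np.exp(-0.5))

    def test_symmetry(self, rng):
        a = rng.uniform(0, 3, 20)
        assert np.allclose(gaussian_fitness(1.0 + a, 1.0, 0.7),
                           gaussian_fitness(1.0 - a, 1.0, 0.7))

    def test_requires_positive_width(self):
        with pytest.raises(ValueError):
            gaussian_fitness(0.0, 0.0, 0.0)


class TestDemography:
    def test_constant_model_sizes(self):
        d = DemographicModel.constant(50, 100)
        sizes = d.sizes()
        assert len(sizes) == 10 * 50 + 100
        assert np.all(sizes == 50)

    def test_growth_epoch(self):
        d = DemographicModel((Epoch(10, 10, growth_rate=0.2),), burn_in=0)
        sizes = d.sizes()
        assert sizes[0] == 10
        assert np.all(np.diff(sizes) >= 0)
        assert sizes[-1] == round(10 * np.exp(0.2 * 9))

    def test_gravel_preset_is_multi_epoch(self):
        d = DemographicModel.gravel_european(Q=100)
        sizes = d.sizes()
        assert len(d.epochs) == 3
        assert np.all(sizes >= 2)
        assert sizes[-1] > d.epochs[-1].size  # growth happened

    def test_too_small_sizes_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            DemographicModel.constant(1, 10).sizes()


class TestForwardSimulation:
    def test_no_mutation_means_no_variants(self):
        params = TraitModelParams(mutation_rate=0.0, fitness_width=None, h2=1.0)
        out = run_forward_simulation(params, DemographicModel.constant(20, 20),
                                     seed=0, log_interval=5)
        assert out.n_segregating == 0
        assert np.allclose(out.phi_trajectory[:, 1], 0.0)

    def test_segregating_dafs_strictly_polymorphic(self):
        params = TraitModelParams(mutation_rate=0.2, fitness_width=None)
        out = run_forward_simulation(params, DemographicModel.constant(30, 50),
                                     seed=1)
        assert out.n_segregating > 0
        assert np.all((out.daf > 0) & (out.daf < 1))
        assert out.n_haplotypes == 60

    def test_neutral_unbiased_bin_means_center_on_zero(self):
        """δ = 0.5 with selection off: β̄ ≈ 0 in every frequency bin."""
        rng = np.random.default_rng(42)
        params = TraitModelParams(delta=0.5, fitness_width=None,
                                  mutation_rate=0.2, effect_scale=0.3)
        demog = DemographicModel.constant(40, 80)
        betas = []
        for _ in range(30):
            out = run_forward_simulation(params, demog,
                                         seed=int(rng.integers(2 ** 31)))
            betas.append(out.true_beta)
        pooled = np.concatenate(betas)
        se = pooled.std(ddof=1) / np.sqrt(pooled.size)
        assert abs(pooled.mean()) < 3 * se

    def test_reproducible_with_fixed_seed(self):
        params = TraitModelParams(mutation_rate=0.1, fitness_width=1.0)
        demog = DemographicModel.constant(25, 40)
        a = run_forward_simulation(params, demog, seed=11)
        b = run_forward_simulation(params, demog, seed=11)
        assert np.array_equal(a.true_beta, b.true_beta)
        assert np.array_equal(a.daf, b.daf)

    def test_mean_phenotype_tracks_shifted_optimum(self):
        """After a +2 SD optimum shift the population mean moves toward it."""
        params = TraitModelParams(delta=0.5, dphi=2.0, ts=80,
                                  fitness_width=0.5, mutation_rate=0.3,
                                  effect_scale=0.2, h2=0.8)
        demog = DemographicModel.constant(100, 120, burn_in=800)
        out = run_forward_simulation(params, demog, seed=3, log_interval=5)
        gens = out.phi_trajectory[:, 0]
        means = out.phi_trajectory[:, 1]
        shift_gen = len(demog.sizes()) - 80
        pre = means[gens < shift_gen][-5:].mean()
        post = means[-3:].mean()
        assert post > pre  # moved toward the raised optimum

    def test_gradual_shift_also_moves_mean_toward_optimum(self):
        """A linear ramp of the optimum (instead of a jump) still pulls the
        population mean upward by the end of the ramp."""
        params = TraitModelParams(delta=0.5, dphi=2.0, ts=80,
                                  shift_duration=50, fitness_width=0.5,
                                  mutation_rate=0.3, effect_scale=0.2, h2=0.8)
        demog = DemographicModel.constant(100, 120, burn_in=800)
        out = run_forward_simulation(params, demog, seed=6, log_interval=5)
        gens = out.phi_trajectory[:, 0]
        means = out.phi_trajectory[:, 1]
        shift_gen = len(demog.sizes()) - 80
        pre = means[gens < shift_gen][-5:].mean()
        post = means[-3:].mean()
        assert post > pre

    def test_shift_outside_span_rejected(self):
        params = TraitModelParams(dphi=1.0, ts=10_000)
        with pytest.raises(ValueError, match="outside"):
            run_forward_simulation(params, DemographicModel.constant(10, 10),
                                   seed=0)


class TestEyreWalkerMode:
    def test_tau_zero_gives_unit_magnitudes(self):
        params = eyre_walker_mode(TraitModelParams(), tau=0.0, noise_sd=0.0)
        out = run_forward_simulation(params,
                                     DemographicModel.constant(20, 30), seed=5)
        assert out.n_segregating > 0
        assert np.allclose(np.abs(out.true_beta), 1.0)

    def test_purifying_selection_sign_pattern(self):
        """With δ = 0.4, Sβ(0,1) shares the sign of the overall mean β."""
        from evocompass.sbeta import bin_mean_beta, sbeta
        rng = np.random.default_rng(9)
        params = eyre_walker_mode(
            TraitModelParams(delta=0.4, mutation_rate=0.3, ew_s_mean=0.05),
            tau=0.5, noise_sd=0.1)
        demog = DemographicModel.constant(50, 80)
        betas, dafs = [], []
        for _ in range(25):
            out = run_forward_simulation(params, demog,
                                         seed=int(rng.integers(2 ** 31)))
            betas.append(out.true_beta)
            dafs.append(out.daf)
        beta = np.concatenate(betas)
        daf = np.concatenate(dafs)
        s = sbeta(bin_mean_beta((beta, daf)), 0.0, 1.0)
        assert beta.mean() < 0
        assert np.sign(s) == np.sign(beta.mean())


class TestEstimationNoise:
    def test_large_gwas_recovers_true_effects(self, rng):
        out = run_forward_simulation(
            TraitModelParams(mutation_rate=0.2, fitness_width=None),
            DemographicModel.constant(30, 40), seed=2)
        noisy = add_estimation_noise(out, GWASNoiseParams(n_gwas=10 ** 9), rng)
        assert np.allclose(noisy.beta_hat, noisy.true_beta, atol=1e-3)

    def test_noise_variance_formula(self, rng):
        """Empirical var(β̂ − β) at fixed x matches σ²/(2n·x(1−x))."""
        from evocompass.simulate import SimulationOutput
        x = 0.3
        m = 40_000
        out = SimulationOutput(
            true_beta=np.zeros(m), daf=np.full(m, x),
            origin_generation=np.zeros(m, int), n_haplotypes=100,
            fixed_count=0, lost_count=0, phi_trajectory=np.zeros((0, 2)),
            v_g=0.0, v_p=0.0)
        noise = GWASNoiseParams(n_gwas=1000, residual_var=2.0)
        noisy = add_estimation_noise(out, noise, rng)
        target = 2.0 / (2 * 1000 * x * (1 - x))
        emp = noisy.beta_hat.var()
        assert emp == pytest.approx(target, rel=0.05)
        # variance is minimized at x = 0.5
        assert target > 2.0 / (2 * 1000 * 0.25)


class TestMisorientation:
    def _output(self, beta, daf):
        from evocompass.simulate import SimulationOutput
        beta = np.asarray(beta, float)
        return SimulationOutput(
            true_beta=beta, daf=np.asarray(daf, float),
            origin_generation=np.zeros(beta.size, int), n_haplotypes=100,
            fixed_count=0, lost_count=0, phi_trajectory=np.zeros((0, 2)),
            v_g=0.0, v_p=0.0)

    def test_eps_zero_is_identity(self, rng):
        out = self._output([0.5, -0.2], [0.1, 0.8])
        flipped = apply_misorientation(out, 0.0, rng)
        assert np.array_equal(flipped.true_beta, out.true_beta)
        assert np.array_equal(flipped.daf, out.daf)

    def test_eps_one_is_full_reflection(self, rng):
        out = self._output([0.5, -0.2], [0.1, 0.8])
        flipped = apply_misorientation(out, 1.0, rng)
        assert np.allclose(flipped.true_beta, [-0.5, 0.2])
        assert np.allclose(flipped.daf, [0.9, 0.2])

    def test_constant_beta_attenuates_to_one_minus_two_eps(self, rng):
        """With constant β = c on a frequency-symmetric set, the observed
        mean is (1 − 2ε)·c."""
        m = 100_000
        eps = 0.3
        daf = np.concatenate([rng.uniform(0.05, 0.95, m // 2)] * 2)
        daf[m // 2:] = 1 - daf[m // 2:]
        out = self._output(np.ones(m), daf)
        flipped = apply_misorientation(out, eps, rng)
        se = 1.0 / np.sqrt(m)  # betas are ±1 after flips
        assert abs(flipped.true_beta.mean() - (1 - 2 * eps)) < 4 * se
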
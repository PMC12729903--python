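"""VAE and diffusion generators: latent algebra, noising identity, augmentation."""

import numpy as np
import pytest

from gaitrec.augmentation import (
    DiffusionConfig,
    DiffusionGenerator,
    TimeSeriesVAE,
    VAEConfig,
    augment_cohort,
    forward_noising,
    gaussian_kl,
    linear_beta_schedule,
    reparameterize,
)
from gaitrec.synthetic import CohortSpec, default_archetypes, generate_cohort


class TestReparameterize:
    def test_zero_epsilon_returns_mean(self, rng):
        mu, sigma = rng.normal(size=4), np.abs(rng.normal(size=4)) + 0.1
        assert np.array_equal(reparameterize(mu, sigma, np.zeros(4)), mu)

    def test_hand_example(self):
        z = reparameterize(
            np.array([1.0, -1.0]), np.array([2.0, 3.0]), np.array([0.5, -1.0])
        )
        assert np.array_equal(z, [2.0, -4.0])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            reparameterize(np.zeros(2), np.array([0.0, 1.0]), np.zeros(2))

    def test_identity_z_minus_mu_equals_sigma_epsilon(self, rng):
        mu, sigma = rng.normal(size=6), np.abs(rng.normal(size=6)) + 0.1
        eps = rng.normal(size=6)
        z = reparameterize(mu, sigma, eps)
        assert np.allclose(z - mu, sigma * eps)


class TestGaussianKL:
    def test_zero_iff_standard_normal(self, rng):
        assert gaussian_kl(np.zeros(3), np.ones(3)) == 0.0
        assert gaussian_kl(rng.normal(size=3) + 2.0, np.ones(3)) > 0
        assert gaussian_kl(np.zeros(3), np.full(3, 0.5)) > 0

    def test_matches_monte_carlo_estimate(self, rng):
        mu = rng.normal(size=2)
        sigma = np.abs(rng.normal(size=2)) + 0.5
        draws = mu + sigma * rng.standard_normal((200000, 2))
        logq = -0.5 * (((draws - mu) / sigma) ** 2 + np.log(2 * np.pi * sigma**2)).sum(1)
        logp = -0.5 * (draws**2 + np.log(2 * np.pi)).sum(1)
        mc = float((logq - logp).mean())
        assert gaussian_kl(mu, sigma) == pytest.approx(mc, rel=0.05)


class TestForwardNoising:
    def test_tiny_beta_preserves_signal(self, rng):
        x0 = rng.normal(size=5)
        sched = np.full(10, 1e-6)
        xt = forward_noising(x0, 10, sched, rng.normal(size=5))
        assert np.allclose(xt, x0, atol=1e-2)

    def test_heavy_noise_limit_is_pure_noise(self, rng):
        x0 = rng.normal(size=5)
        eps = rng.normal(size=5)
        sched = np.full(50, 0.5)
        xt = forward_noising(x0, 50, sched, eps)
        assert np.allclose(xt, eps, atol=1e-6)

    def test_single_step_hand_value(self):
        xt = forward_noising(np.array([1.0]), 1, np.array([0.5]), np.array([1.0]))
        assert xt[0] == pytest.approx(np.sqrt(0.5) + np.sqrt(0.5), abs=1e-9)

    def test_out_of_range_t_rejected(self):
        with pytest.raises(ValueError):
            forward_noising(np.zeros(2), 0, np.array([0.1]), np.zeros(2))
        with pytest.raises(ValueError):
            forward_noising(np.zeros(2), 2, np.array([0.1]), np.zeros(2))

    def test_marginal_moments_match_closed_form(self, rng):
        sched = linear_beta_schedule(20, 1e-3, 0.05)
        x0 = np.array([2.0])
        t = 15
        abar = np.prod(1 - sched[:t])
        draws = np.array(
            [forward_noising(x0, t, sched, rng.normal(size=1))[0] for _ in range(10000)]
        )
        se_mean = np.sqrt(1 - abar) / 100
        assert abs(draws.mean() - np.sqrt(abar) * 2.0) < 3 * se_mean
        assert abs(draws.var() - (1 - abar)) < 3 * (1 - abar) * np.sqrt(2 / 9999)


@pytest.fixture(scope="module")
def trained_vae(two_archetype_clean_module):
    cfg = VAEConfig(epochs=600, learning_rate=1e-3, seed=0)
    return TimeSeriesVAE(cfg).fit(two_archetype_clean_module)


@pytest.fixture(scope="module")
def two_archetype_clean_module():
    spec = CohortSpec(
        n_patients=12, archetypes=default_archetypes(2), noise_sd=0.0,
        missingness_profile=None, seed=1,
    )
    return generate_cohort(spec)


class TestVAE:
    def test_missing_data_rejected_with_guidance(self, study_cohort):
        with pytest.raises(ValueError, match="imputation"):
            TimeSeriesVAE(VAEConfig(epochs=1)).fit(study_cohort)

    def test_reconstruction_halves_on_clean_cohort(self, trained_vae):
        hist = trained_vae.recon_history_
        assert hist[-1] <= 0.5 * hist[0]

    def test_seed_determinism(self, two_archetype_clean_module):
        cfg = VAEConfig(epochs=20, seed=3)
        a = TimeSeriesVAE(cfg).fit(two_archetype_clean_module).sample(4, seed=9)
        b = TimeSeriesVAE(cfg).fit(two_archetype_clean_module).sample(4, seed=9)
        assert np.array_equal(a, b)

    def test_sample_shape_and_count(self, trained_vae):
        s = trained_vae.sample(7, seed=0)
        assert s.shape == (7, 8, 600)
        assert np.isfinite(s).all()
        with pytest.raises(ValueError):
            trained_vae.sample(0)

    def test_sampled_mean_curve_near_training_mean(self, trained_vae,
                                                   two_archetype_clean_module):
        s = trained_vae.sample(200, seed=1)
        train = two_archetype_clean_module.values
        gen_sd = s.std(axis=0)
        diff = np.abs(s.mean(axis=0) - train.mean(axis=0))
        # mean curve within 3 generator-SDs elementwise (plus small floor)
        assert (diff <= 3 * gen_sd + 1e-3 * np.abs(train).max()).mean() > 0.99


class TestDiffusion:
    def test_beta_schedule_validation(self):
        with pytest.raises(ValueError):
            DiffusionConfig(n_steps=3, beta_schedule=np.array([0.1, 0.05, 0.2]))
        with pytest.raises(ValueError):
            DiffusionConfig(n_steps=2, beta_schedule=np.array([0.0, 0.5]))

    def test_training_loss_decreases(self, two_archetype_clean_module):
        gen = DiffusionGenerator(DiffusionConfig(epochs=150, seed=0))
        gen.fit(two_archetype_clean_module)
        hist = np.array(gen.loss_history_)
        assert hist[-20:].mean() < hist[:20].mean()

    def test_constant_data_sampling_variance_bounded(self):
        spec = CohortSpec(n_patients=20, archetypes=default_archetypes(1),
                          noise_sd=0.0, missingness_profile=None, seed=3)
        c = generate_cohort(spec)
        noise_sd = 0.5
        c.values[:] = 5.0 + np.random.default_rng(0).normal(0, noise_sd, c.values.shape)
        gen = DiffusionGenerator(DiffusionConfig(epochs=1000, seed=0)).fit(c)
        s = gen.sample(20, seed=1)
        per_elem_sd = s.std(axis=0).mean()
        assert per_elem_sd < 2 * noise_sd

    def test_sample_count_honored(self, two_archetype_clean_module):
        gen = DiffusionGenerator(DiffusionConfig(epochs=20, seed=0))
        gen.fit(two_archetype_clean_module)
        assert gen.sample(5, seed=0).shape[0] == 5


class _IdentityStub:
    """Test generator echoing each source sample once per ratio unit."""

    def augment(self, cohort, ratio, seed=0):
        return np.repeat(cohort.values, ratio, axis=0)


class TestAugmentCohort:
    def test_study_ratio_five_gives_186_samples(self, complete_cohort):
        combined = augment_cohort(complete_cohort, _IdentityStub(), ratio=5)
        assert combined.n_patients == 186
        assert combined.provenance.count("real") == 31
        assert combined.provenance.count("synthetic") == 155

    def test_identity_stub_ratio_one(self, complete_cohort):
        combined = augment_cohort(complete_cohort, _IdentityStub(), ratio=1)
        assert combined.n_patients == 62
        assert np.array_equal(combined.values[31], complete_cohort.values[0])
        assert combined.patient_ids[31] == f"{complete_cohort.patient_ids[0]}_syn0"

    def test_invalid_ratio_and_untrained_generator_rejected(self, complete_cohort):
        with pytest.raises(ValueError):
            augment_cohort(complete_cohort, _IdentityStub(), ratio=0)
        with pytest.raises(RuntimeError):
            augment_cohort(complete_cohort, TimeSeriesVAE(), ratio=2)

    def test_synthetic_samples_have_training_shape(self, complete_cohort):
        vae = TimeSeriesVAE(VAEConfig(epochs=30, seed=0)).fit(complete_cohort)
        combined = augment_cohort(complete_cohort, vae, ratio=1, seed=0)
        assert combined.values.shape == (62, 8, 600)
        assert np.isfinite(combined.values).all()
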
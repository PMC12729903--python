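"""Temporal clustering: soft assignments, target sharpening, planted recovery."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from gaitrec.dtc import (
    DTCConfig,
    TemporalAutoencoder,
    init_centroids,
    kl_clustering_loss,
    reconstruction_loss,
    soft_assign,
    target_distribution,
    train_dtc,
)
from gaitrec.nn import Tensor
from gaitrec.synthetic import CohortSpec, default_archetypes, generate_cohort


class TestAutoencoderShapes:
    @pytest.mark.parametrize("pool", [2, 4, 6, 8])
    def test_roundtrip_shape_and_latent_length(self, pool, rng):
        cfg = DTCConfig(K=2, pool_size=pool, conv_filters=8, kernel_size=3)
        tae = TemporalAutoencoder(24, 8, cfg, rng)
        x = Tensor(rng.normal(size=(5, 8, 24)))
        z = tae.encode(x)
        assert z.shape == (5, -(-8 // pool), 2 * cfg.lstm_hidden_2)
        assert tae.decode(z).shape == (5, 8, 24)

    def test_identical_inputs_give_identical_latents(self, rng):
        cfg = DTCConfig(K=2, conv_filters=8, kernel_size=3)
        tae = TemporalAutoencoder(12, 8, cfg, rng)
        x = rng.normal(size=(1, 8, 12))
        z1 = tae.encode(Tensor(np.vstack([x, x])))
        assert np.allclose(z1.data[0], z1.data[1])


class TestReconstructionLoss:
    def test_perfect_is_zero_and_offset_closed_form(self, rng):
        x = rng.normal(size=(4, 6))
        assert reconstruction_loss(x, x) == 0.0
        assert reconstruction_loss(x, x + 3.0) == pytest.approx(9.0)

    def test_matches_double_loop_oracle(self, rng):
        x, y = rng.normal(size=(5, 7)), rng.normal(size=(5, 7))
        naive = sum((x[i, j] - y[i, j]) ** 2 for i in range(5) for j in range(7)) / 35
        assert reconstruction_loss(x, y) == pytest.approx(naive, abs=1e-10)


class TestInitCentroids:
    def test_k_equals_n_gives_samples(self, rng):
        z = rng.normal(size=(4, 3))
        cents = init_centroids(z, 4)
        assert sorted(map(tuple, cents)) == sorted(map(tuple, z))

    def test_k_one_gives_grand_mean(self, rng):
        z = rng.normal(size=(6, 3))
        assert np.allclose(init_centroids(z, 1)[0], z.mean(axis=0))

    def test_three_blobs_recovered(self, rng):
        means = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        z = np.vstack([m + 0.1 * rng.normal(size=(20, 2)) for m in means])
        cents = init_centroids(z, 3)
        for m in means:
            assert np.linalg.norm(cents - m, axis=1).min() < 0.5

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            init_centroids(rng.normal(size=(2, 2)), 3)


class TestSoftAssign:
    def test_single_centroid_all_ones(self, rng):
        q = soft_assign(rng.normal(size=(5, 2)), rng.normal(size=(1, 2)))
        assert np.allclose(q, 1.0)

    def test_equidistant_point_is_half_half(self):
        q = soft_assign(np.array([[0.0, 0.0]]), np.array([[1.0, 0.0], [-1.0, 0.0]]))
        assert np.allclose(q, [[0.5, 0.5]])

    def test_hand_example_distances_one_and_two(self):
        q = soft_assign(np.array([[0.0]]), np.array([[1.0], [2.0]]))
        assert q[0] == pytest.approx([5.0 / 7.0, 2.0 / 7.0], abs=1e-9)

    def test_matches_scalar_double_loop(self, rng):
        z = rng.normal(size=(7, 3))
        c = rng.normal(size=(4, 3))
        naive = np.zeros((7, 4))
        for i in range(7):
            for j in range(4):
                naive[i, j] = 1.0 / (1.0 + np.sum((z[i] - c[j]) ** 2))
            naive[i] /= naive[i].sum()
        assert np.allclose(soft_assign(z, c), naive, atol=1e-10)

    def test_rows_stochastic(self, rng):
        q = soft_assign(rng.normal(size=(20, 5)), rng.normal(size=(6, 5)))
        assert np.allclose(q.sum(axis=1), 1.0, atol=1e-9)
        assert ((q > 0) & (q < 1)).all()


class TestTargetDistribution:
    def test_one_hot_is_fixed_point(self):
        q = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(target_distribution(q), q)

    def test_uniform_balanced_stays_uniform(self):
        q = np.full((4, 2), 0.5)
        assert np.allclose(target_distribution(q), 0.5)

    def test_hand_example_row(self):
        # row [0.6, 0.4] with unit cluster frequencies
        q = np.array([[0.6, 0.4], [0.4, 0.6]])  # f = [1, 1]
        p = target_distribution(q)
        assert p[0] == pytest.approx([0.36 / 0.52, 0.16 / 0.52], abs=1e-9)

    def test_sharpening_reduces_entropy(self, rng):
        # balanced cluster frequencies: each row appears in all cyclic shifts,
        # the regime in which the squared-membership target provably sharpens
        for _ in range(10):
            base = rng.dirichlet(np.ones(4), size=5)
            q = np.vstack([np.roll(r, s) for r in base for s in range(4)])
            p = target_distribution(q)
            hq = -(q * np.log(q + 1e-12)).sum(axis=1).mean()
            hp = -(p * np.log(p + 1e-12)).sum(axis=1).mean()
            assert hp <= hq + 1e-9
            assert (p.max(axis=1) >= q.max(axis=1) - 1e-9).all()
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)


class TestKLLoss:
    def test_identical_distributions_zero(self, rng):
        q = rng.dirichlet(np.ones(3), size=5)
        assert kl_clustering_loss(q, q) == pytest.approx(0.0, abs=1e-9)

    def test_hand_value_log_two(self):
        assert kl_clustering_loss(
            np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]])
        ) == pytest.approx(np.log(2), abs=1e-6)

    def test_nonnegative(self, rng):
        for _ in range(10):
            p = rng.dirichlet(np.ones(4), size=6)
            q = rng.dirichlet(np.ones(4), size=6)
            assert kl_clustering_loss(p, q) >= -1e-9


class TestTrainDTC:
    def test_two_clean_archetypes_fully_recovered(self, two_archetype_clean):
        cfg = DTCConfig(K=2, epochs_tae=30, epochs_cluster=20, seed=0)
        model = train_dtc(two_archetype_clean, cfg)
        assert adjusted_rand_score(two_archetype_clean.archetype_ids, model.labels) == 1.0

    def test_six_archetypes_recovered_across_seeds(self, six_archetype_cohort):
        for seed in range(3):
            cfg = DTCConfig(K=6, epochs_tae=150, epochs_cluster=100, seed=seed)
            model = train_dtc(six_archetype_cohort, cfg)
            ari = adjusted_rand_score(six_archetype_cohort.archetype_ids, model.labels)
            assert ari >= 0.8

    def test_joint_loss_decreases(self, two_archetype_clean):
        cfg = DTCConfig(K=2, epochs_tae=30, epochs_cluster=30, seed=1)
        model = train_dtc(two_archetype_clean, cfg)
        assert model.joint_loss_history[-1] <= model.joint_loss_history[0]

    def test_soft_assignments_row_stochastic(self, two_archetype_clean):
        cfg = DTCConfig(K=3, epochs_tae=10, epochs_cluster=5, seed=0)
        model = train_dtc(two_archetype_clean, cfg)
        assert np.allclose(model.soft.sum(axis=1), 1.0, atol=1e-9)

    def test_recovery_degrades_with_noise(self):
        aris = []
        for noise in (0.5, 4.0, 12.0):
            level = []
            for seed in range(3):
                spec = CohortSpec(
                    n_patients=24, archetypes=default_archetypes(3),
                    noise_sd=noise, missingness_profile=None, seed=10 + seed,
                )
                c = generate_cohort(spec)
                cfg = DTCConfig(K=3, epochs_tae=30, epochs_cluster=20, seed=seed)
                m = train_dtc(c, cfg)
                level.append(adjusted_rand_score(c.archetype_ids, m.labels))
            aris.append(np.mean(level))
        assert aris[0] >= aris[1] - 0.05
        assert aris[1] >= aris[2] - 0.05
        assert aris[0] > aris[2]

    def test_k_larger_than_n_rejected(self, two_archetype_clean):
        with pytest.raises(ValueError):
            train_dtc(two_archetype_clean, DTCConfig(K=13, epochs_tae=1, epochs_cluster=1))

    def test_incomplete_cohort_rejected(self, study_cohort):
        with pytest.raises(ValueError):
            train_dtc(study_cohort, DTCConfig(K=2, epochs_tae=1, epochs_cluster=1))
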
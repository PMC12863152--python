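import itertools

import numpy as np
import pytest

from ses_microstates.cluster import (aahc, correlation_matrix, gev,
                                     group_templates, group_templates_mean,
                                     spatial_correlation)
from ses_microstates.core import TemplateSet, normalize_map

from conftest import random_maps


def orthogonal_templates(k, n_channels=8):
    """k exactly orthogonal, average-referenced unit maps."""
    base = np.zeros((k, n_channels))
    for i in range(k):
        base[i, 2 * i] = 1.0
        base[i, 2 * i + 1] = -1.0
    return np.stack([normalize_map(m) for m in base])


class TestSpatialCorrelation:
    def test_self_is_one(self, rng):
        a = random_maps(rng, 1)[0]
        assert spatial_correlation(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_invariant(self, rng):
        a = random_maps(rng, 1)[0]
        assert spatial_correlation(a, -a) == pytest.approx(1.0, abs=1e-12)
        assert spatial_correlation(a, -a, polarity_invariant=False) == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_maps(self):
        a = np.array([1.0, -1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, -1.0])
        assert spatial_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_pearson_definition(self, rng):
        a, b = random_maps(rng, 2, 12)
        expected = np.corrcoef(a, b)[0, 1]
        assert spatial_correlation(a, b, polarity_invariant=False) == pytest.approx(expected, abs=1e-12)

    def test_flat_map_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(4), np.array([1.0, -1, 0, 0]))


class TestGev:
    def test_identical_maps_explain_everything(self, rng):
        T = orthogonal_templates(3)
        maps = np.concatenate([T * 2.0, -T])  # scaled and flipped copies
        assignment = np.array([0, 1, 2, 0, 1, 2])
        total, per_class = gev(maps, np.ones(6), T, assignment)
        assert total == pytest.approx(1.0, abs=1e-12)
        assert per_class.sum() == pytest.approx(total, abs=1e-9)

    def test_orthogonal_assignment_explains_nothing(self):
        T = orthogonal_templates(2)
        maps = T[[0]]
        total, _ = gev(maps, np.ones(1), T, np.array([1]))
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_weighting(self):
        # 3 peaks with GFP (1,1,2) and |r| (1,0,1) -> (1+0+4)/(1+1+4) = 5/6
        T = orthogonal_templates(2)
        maps = np.stack([T[0], T[1], T[0]])
        weights = np.array([1.0, 1.0, 2.0])
        assignment = np.array([0, 0, 0])  # middle map orthogonal to its template
        total, per_class = gev(maps, weights, T, assignment)
        assert total == pytest.approx(5 / 6, abs=1e-12)
        assert per_class[0] == pytest.approx(5 / 6, abs=1e-12)
        assert per_class[1] == 0.0


def brute_force_best_gev(maps, weights, K):
    """Exhaustive search over all partitions into exactly K non-empty
    clusters, each scored with its first-principal-direction centroid."""
    n = maps.shape[0]
    best = -1.0
    X = maps - maps.mean(axis=1, keepdims=True)
    for assignment in itertools.product(range(K), repeat=n):
        if len(set(assignment)) != K:
            continue
        a = np.array(assignment)
        centroids = []
        for k in range(K):
            mem = X[a == k]
            S = mem.T @ mem
            w, v = np.linalg.eigh(S)
            centroids.append(v[:, -1])
        total, _ = gev(X, weights, np.stack([normalize_map(c) for c in centroids]), a)
        best = max(best, total)
    return best


class TestAahc:
    def test_exact_recovery_of_duplicated_templates(self):
        T = orthogonal_templates(2)
        maps = np.concatenate([np.tile(T[0], (3, 1)), np.tile(-T[1], (3, 1))])
        fit = aahc(maps, np.ones(6), K=2)
        assert fit.gev_total == pytest.approx(1.0, abs=1e-12)
        R = correlation_matrix(fit.templates.maps, T)
        assert sorted(np.argmax(R, axis=1).tolist()) == [0, 1]
        assert np.allclose(np.max(R, axis=1), 1.0, atol=1e-9)

    def test_k_equals_n_is_perfect(self, rng):
        maps = random_maps(rng, 5)
        fit = aahc(maps, np.ones(5) + rng.random(5), K=5)
        assert fit.gev_total == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_of_four_templates(self, rng):
        T = orthogonal_templates(4, 12)
        truth = rng.integers(0, 4, size=40)
        noise = rng.normal(size=(40, 12)) / np.sqrt(10)  # snr ~ 10
        maps = T[truth] * rng.uniform(1, 2, size=(40, 1)) + noise / np.sqrt(12)
        fit = aahc(maps, np.linalg.norm(maps, axis=1), K=4)
        R = correlation_matrix(fit.templates.maps, T)
        assert sorted(np.argmax(R, axis=1).tolist()) == [0, 1, 2, 3]
        assert np.min(np.max(R, axis=1)) >= 0.99

    def test_matches_exhaustive_partition_search_on_separable_input(self, rng):
        T = orthogonal_templates(2, 6)
        signs = rng.choice([-1.0, 1.0], size=7)[:, None]
        maps = T[[0, 0, 0, 1, 1, 1, 0]] * signs + rng.normal(size=(7, 6)) * 0.02
        weights = rng.uniform(0.5, 2.0, size=7)
        fit = aahc(maps, weights, K=2)
        best = brute_force_best_gev(maps, weights, K=2)
        assert fit.gev_total == pytest.approx(best, abs=1e-9)

    def test_gev_monotone_in_k(self, rng):
        maps = random_maps(rng, 10)
        weights = rng.uniform(0.5, 2.0, size=10)
        gevs = [aahc(maps, weights, K=k).gev_total for k in (2, 3, 4, 5, 6)]
        assert np.all(np.diff(gevs) >= -1e-12)

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            aahc(random_maps(rng, 3), np.ones(3), K=4)


class TestGroupTemplates:
    def make_sets(self, maps, n_subjects):
        tset = TemplateSet(maps=maps, labels=[str(i) for i in range(maps.shape[0])],
                           ch_names=[f"c{i}" for i in range(maps.shape[1])])
        return [tset] * n_subjects

    def test_identical_subjects_recovered(self):
        T = orthogonal_templates(3)
        out = group_templates(self.make_sets(T, 4), K=3)
        R = correlation_matrix(out.maps, T)
        assert np.allclose(np.max(R, axis=1), 1.0, atol=1e-9)
        assert out.level == "group"

    def test_sign_flipped_subjects_give_same_templates(self):
        T = orthogonal_templates(3)
        a = self.make_sets(T, 2)
        b = self.make_sets(-T, 2)
        out_a = group_templates(a + a, K=3)
        out_b = group_templates(a + b, K=3)
        R = correlation_matrix(out_a.maps, out_b.maps)
        assert np.allclose(np.sort(np.max(R, axis=1)), 1.0, atol=1e-9)

    def test_montage_mismatch_rejected(self):
        T = orthogonal_templates(2)
        good = TemplateSet(maps=T, labels=["0", "1"], ch_names=[f"c{i}" for i in range(8)])
        bad = TemplateSet(maps=T, labels=["0", "1"], ch_names=[f"x{i}" for i in range(8)])
        with pytest.raises(ValueError, match="subject index 1"):
            group_templates([good, bad], K=2)


class TestGroupTemplatesMean:
    def test_matches_members_when_identical(self):
        T = orthogonal_templates(3)
        ts = TemplateSet(maps=T, labels=list("ABC"),
                         ch_names=[f"c{i}" for i in range(8)])
        out = group_templates_mean([ts, ts, ts])
        R = correlation_matrix(out.maps, T)
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-9)
        assert out.labels == list("ABC") and out.level == "group"

    def test_polarity_aligned_average_ignores_sign_flips(self):
        T = orthogonal_templates(2)
        a = TemplateSet(maps=T, labels=["A", "B"],
                        ch_names=[f"c{i}" for i in range(8)])
        b = TemplateSet(maps=-T, labels=["A", "B"],
                        ch_names=[f"c{i}" for i in range(8)])
        out = group_templates_mean([a, b])
        R = correlation_matrix(out.maps, T)
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-9)

    def test_label_order_mismatch_rejected(self):
        T = orthogonal_templates(2)
        a = TemplateSet(maps=T, labels=["A", "B"],
                        ch_names=[f"c{i}" for i in range(8)])
        b = TemplateSet(maps=T, labels=["B", "A"],
                        ch_names=[f"c{i}" for i in range(8)])
        with pytest.raises(ValueError, match="label order"):
            group_templates_mean([a, b])
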
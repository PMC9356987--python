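"""Jaccard affinity, Laplacian spectrum, eigengap selection, NJW clustering."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import adjusted_rand_score

from vhlgp import (
    Phenotype,
    PhenotypeSpectralClustering,
    ValidationError,
    VariantType,
    eigengap_k,
    jaccard_affinity,
    profile_clusters,
    spectral_cluster,
)
from vhlgp.clustering import normalized_laplacian, phenotype_matrix


def block_affinity(sizes):
    """Block-diagonal affinity with perfect within-block similarity."""
    n = sum(sizes)
    A = np.zeros((n, n))
    start = 0
    for size in sizes:
        A[start:start + size, start:start + size] = 1.0
        start += size
    return A


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"CHB", "RA"}, {"CHB", "RA"}, 1.0),
            ({"CHB"}, {"PPGL"}, 0.0),
            ({"CHB", "RA"}, {"CHB"}, 0.5),
        ],
    )
    def test_pairwise_values(self, a, b, expected):
        A = jaccard_affinity([a, b])
        assert A[0, 1] == pytest.approx(expected)
        assert A[0, 0] == A[1, 1] == 1.0

    def test_matches_bruteforce_set_arithmetic(self):
        rng = np.random.default_rng(21)
        universe = list("ABCDEFG")
        sets = [
            set(rng.choice(universe, size=int(rng.integers(1, 5)), replace=False))
            for _ in range(12)
        ]
        A = jaccard_affinity(sets)
        for i, si in enumerate(sets):
            for j, sj in enumerate(sets):
                assert A[i, j] == pytest.approx(len(si & sj) / len(si | sj))

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            jaccard_affinity([{"CHB"}, set()])


class TestSpectrum:
    def test_eigenvalues_within_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 30))
            X = (rng.random((n, 5)) < 0.5).astype(float)
            X[X.sum(axis=1) == 0, 0] = 1.0
            A = jaccard_affinity(X)
            ev = np.linalg.eigvalsh(normalized_laplacian(A))
            assert ev.min() >= -1e-9
            assert ev.max() <= 2 + 1e-9

    def test_zero_multiplicity_equals_component_count(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            sizes = rng.integers(2, 8, size=int(rng.integers(1, 5)))
            A = block_affinity(list(sizes))
            n_comp, _ = connected_components(A > 0, directed=False)
            ev = np.linalg.eigvalsh(normalized_laplacian(A))
            assert int(np.sum(ev < 1e-8)) == n_comp


class TestEigengap:
    def test_three_perfect_blocks(self):
        k1, _, ev = eigengap_k(block_affinity([5, 6, 7]))
        assert k1 == 3

    def test_two_perfect_blocks(self):
        k1, _, _ = eigengap_k(block_affinity([8, 5]))
        assert k1 == 2

    def test_too_few_units_rejected(self):
        with pytest.raises(ValidationError):
            eigengap_k(np.eye(2))


class TestSpectralCluster:
    def test_two_blocks_recovered_exactly(self):
        A = block_affinity([6, 9])
        labels = spectral_cluster(A, 2, seed=0)
        truth = [0] * 6 + [1] * 9
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        A = block_affinity([5, 5, 5])
        noise = rng.random((15, 15)) * 0.05
        A = np.clip(A + (noise + noise.T) / 2, 0, 1)
        np.fill_diagonal(A, 1.0)
        labels = spectral_cluster(A, 3, seed=0)
        perm = rng.permutation(15)
        labels_perm = spectral_cluster(A[np.ix_(perm, perm)], 3, seed=0)
        assert adjusted_rand_score(labels[perm], labels_perm) == 1.0

    def test_k_out_of_range(self):
        with pytest.raises(ValidationError):
            spectral_cluster(block_affinity([3, 3]), 6)


class TestEstimator:
    def test_fit_sets_attributes_and_is_deterministic(self):
        X = np.array([[1, 0, 0]] * 5 + [[0, 1, 0]] * 5 + [[0, 0, 1]] * 5, dtype=float)
        model = PhenotypeSpectralClustering(random_state=0).fit(X)
        assert model.k_candidates_[0] == 3
        assert len(set(model.labels_)) == 3
        again = PhenotypeSpectralClustering(random_state=0).fit(X)
        assert np.array_equal(model.labels_, again.labels_)

    def test_fit_predict_matches_labels(self):
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [1, 1]], dtype=float)
        model = PhenotypeSpectralClustering(n_clusters=2, random_state=1)
        labels = model.fit_predict(X)
        assert np.array_equal(labels, model.labels_)

    def test_get_set_params_roundtrip(self):
        model = PhenotypeSpectralClustering(n_clusters=4, k_max=9)
        params = model.get_params()
        clone = PhenotypeSpectralClustering().set_params(**params)
        assert clone.get_params() == params

    def test_empty_phenotype_row_rejected(self):
        X = np.array([[1, 0], [0, 0], [0, 1]], dtype=float)
        with pytest.raises(ValidationError):
            PhenotypeSpectralClustering(n_clusters=2).fit(X)


class TestProfiles:
    def test_all_ppgl_cluster_fraction_one(self, unit_factory):
        units = [unit_factory({Phenotype.PPGL}) for _ in range(4)]
        profiles = profile_clusters([0, 0, 0, 0], units)
        assert profiles[0]["phenotype_fraction"]["PPGL"] == 1.0

    def test_nontruncating_alpha_counts(self, unit_factory):
        units = [
            unit_factory({Phenotype.PPGL}, codon=167),
            unit_factory({Phenotype.PPGL}, codon=170, ref_aa="A", alt_aa="V"),
        ]
        profiles = profile_clusters([1, 1], units)
        assert profiles[1]["group_counts"]["nontruncating"] == 2
        assert profiles[1]["domain_counts"]["alpha"] == 2

    def test_misaligned_labels_rejected(self, unit_factory):
        with pytest.raises(ValidationError):
            profile_clusters([0], [unit_factory({Phenotype.CHB})] * 2)


def test_phenotype_matrix_alignment(unit_factory):
    units = [unit_factory({Phenotype.CHB}), unit_factory({Phenotype.PPGL, Phenotype.CHB})]
    X, ids = phenotype_matrix(units)
    assert X.shape == (2, 7)
    assert X[1].sum() == 2
    assert ids == [u.unit_id for u in units]
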
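"""Phenotype-similarity spectral clustering of patients.

Patients are nodes of a complete weighted graph whose edge weights are the
Jaccard similarity between their phenotype sets, A[i, j] = |Si & Sj| /
|Si | Sj| (patients with no VHL phenotype are excluded upstream, so every
set is non-empty and A[i, i] = 1).  Phenotype sets are tiny, so the full
affinity graph is used without k-nearest-neighbor sparsification.

The number of clusters is estimated by the eigengap heuristic on the
symmetric normalized Laplacian L = I - D^{-1/2} A D^{-1/2}: with
eigenvalues l1 <= ... <= ln, the gaps g_i = l_{i+1} - l_i for i = 2..k_max
are ranked and the positions of the two largest gaps give two candidate
cluster counts (K = 1 is excluded as uninformative; ties break toward the
smaller K).  Clustering itself is the Ng-Jordan-Weiss procedure: the
bottom-K eigenvectors of L, rows renormalized to unit length, then k-means
with a fixed seed and several restarts, so results are deterministic given
(affinity, K, seed).  Genotype information never enters the clustering; it
appears only in the per-cluster profiles computed afterwards.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

from .cohort import AnalysisUnit
from .datamodel import (
    ANALYSIS_PHENOTYPES,
    Phenotype,
    ValidationError,
    VariantGroup,
    annotate_domains,
)

__all__ = [
    "jaccard_affinity",
    "normalized_laplacian",
    "eigengap_k",
    "spectral_cluster",
    "phenotype_matrix",
    "profile_clusters",
    "PhenotypeSpectralClustering",
]


def phenotype_matrix(
    units: Sequence[AnalysisUnit],
    phenotypes: Sequence[Phenotype] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Binary unit x phenotype indicator matrix and the unit ids."""
    if phenotypes is None:
        phenotypes = ANALYSIS_PHENOTYPES
    X = np.array(
        [[p in u.phenotypes for p in phenotypes] for u in units], dtype=float
    )
    return X, [u.unit_id for u in units]


def jaccard_affinity(sets_or_matrix) -> np.ndarray:
    """Pairwise Jaccard similarity.

    Accepts a sequence of phenotype sets or a binary indicator matrix.
    Every row/set must be non-empty.
    """
    if isinstance(sets_or_matrix, np.ndarray):
        X = (sets_or_matrix > 0).astype(float)
    else:
        sets = list(sets_or_matrix)
        universe = sorted({e for s in sets for e in s}, key=str)
        index = {e: i for i, e in enumerate(universe)}
        X = np.zeros((len(sets), len(universe)))
        for i, s in enumerate(sets):
            for e in s:
                X[i, index[e]] = 1.0
    sizes = X.sum(axis=1)
    if np.any(sizes == 0):
        raise ValidationError("empty phenotype set reached the affinity computation")
    inter = X @ X.T
    union = sizes[:, None] + sizes[None, :] - inter
    return inter / union


def normalized_laplacian(affinity: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian I - D^{-1/2} A D^{-1/2}."""
    A = np.asarray(affinity, dtype=float)
    degree = A.sum(axis=1)
    if np.any(degree <= 0):
        raise ValidationError(
            "isolated node (zero degree); remove it before clustering"
        )
    d_inv_sqrt = 1.0 / np.sqrt(degree)
    return np.eye(len(A)) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]


def eigengap_k(
    affinity: np.ndarray, k_max: int = 15
) -> tuple[int, int, np.ndarray]:
    """Two cluster-count candidates from the Laplacian eigengaps.

    Returns (k1, k2, eigenvalues) where k1 carries the largest gap
    g_i = l_{i+1} - l_i over i = 2..k_max and k2 the second largest
    (descending by gap size, ties toward smaller K).
    """
    A = np.asarray(affinity, dtype=float)
    n = len(A)
    if n < 3:
        raise ValidationError("eigengap estimation requires at least 3 units")
    eigenvalues = np.linalg.eigvalsh(normalized_laplacian(A))
    upper = min(k_max, n - 1)
    gaps = eigenvalues[2:upper + 1] - eigenvalues[1:upper]  # K = 2..upper
    ks = np.arange(2, upper + 1)
    order = np.lexsort((ks, -gaps))  # gap descending, then smaller K
    k1, k2 = int(ks[order[0]]), int(ks[order[1]])
    return k1, k2, eigenvalues


def spectral_cluster(
    affinity: np.ndarray,
    n_clusters: int,
    seed: int | None = 0,
    n_init: int = 10,
) -> np.ndarray:
    """Ng-Jordan-Weiss spectral clustering at a fixed K."""
    A = np.asarray(affinity, dtype=float)
    n = len(A)
    if not 2 <= n_clusters <= n - 1:
        raise ValidationError(f"n_clusters={n_clusters} outside 2..{n - 1}")
    L = normalized_laplacian(A)
    _, vectors = np.linalg.eigh(L)
    embedding = vectors[:, :n_clusters]
    norms = np.linalg.norm(embedding, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    embedding = embedding / norms
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    return km.fit_predict(embedding)


class PhenotypeSpectralClustering(BaseEstimator, ClusterMixin):
    """Spectral clustering of patients on Jaccard phenotype similarity.

    Parameters
    ----------
    n_clusters : int or None
        Fixed cluster count; ``None`` selects it by the eigengap heuristic
        (the largest-gap candidate; both candidates are exposed after
        fitting).
    k_max : int
        Largest cluster count considered by the eigengap scan.
    n_init : int
        k-means restarts (best inertia wins).
    random_state : int
        Seed for k-means; fitting is deterministic given data and seed.

    Attributes
    ----------
    affinity_ : ndarray of shape (n_samples, n_samples)
        Jaccard similarity matrix.
    eigenvalues_ : ndarray
        Ascending spectrum of the symmetric normalized Laplacian (all in
        [0, 2]; the multiplicity of 0 equals the number of graph
        components).
    k_candidates_ : tuple of two ints
        The two eigengap candidates (gap-descending).
    labels_ : ndarray of shape (n_samples,)
        Cluster assignment at ``n_clusters`` (or the first candidate).
    labels_by_k_ : dict
        Assignment vectors for every K that was run.

    Examples
    --------
    >>> X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
    >>> model = PhenotypeSpectralClustering(n_clusters=2).fit(X)
    >>> (model.labels_[:2] != model.labels_[2:]).all()
    True
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        k_max: int = 15,
        n_init: int = 10,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a binary unit x phenotype indicator matrix."""
        X = check_array(X, dtype=float)
        if np.any(X.sum(axis=1) == 0):
            raise ValidationError(
                "units without any phenotype must be removed before clustering"
            )
        self.affinity_ = jaccard_affinity(X)
        k1, k2, self.eigenvalues_ = eigengap_k(self.affinity_, k_max=self.k_max)
        self.k_candidates_ = (k1, k2)
        ks = [self.n_clusters] if self.n_clusters is not None else [k1, k2]
        self.labels_by_k_ = {
            k: spectral_cluster(
                self.affinity_, k, seed=self.random_state, n_init=self.n_init
            )
            for k in dict.fromkeys(ks)
        }
        self.labels_ = self.labels_by_k_[ks[0]]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "labels_")


def profile_clusters(
    labels: Sequence[int],
    units: Sequence[AnalysisUnit],
    phenotypes: Sequence[Phenotype] | None = None,
) -> dict[int, dict]:
    """Genotype/phenotype profile of each cluster.

    For every cluster: fraction of patients carrying each phenotype, each
    phenotype's share of all phenotype occurrences, truncating /
    nontruncating counts, alpha / beta / neither domain counts, and the
    per-codon histogram.  Genotype enters only here — never in the
    clustering itself.
    """
    if len(labels) != len(units):
        raise ValidationError("labels and units are not aligned")
    if phenotypes is None:
        phenotypes = ANALYSIS_PHENOTYPES
    profiles: dict[int, dict] = {}
    for label in sorted(set(int(l) for l in labels)):
        members = [u for l, u in zip(labels, units) if int(l) == label]
        n = len(members)
        occurrences = Counter()
        for u in members:
            occurrences.update(p for p in phenotypes if p in u.phenotypes)
        total_occ = sum(occurrences.values())
        group_counts = Counter(u.group.value for u in members)
        domain_counts = {"alpha": 0, "beta": 0, "neither": 0}
        codon_hist: Counter = Counter()
        for u in members:
            v = u.variant
            if v is None or v.codon is None:
                continue
            codon_hist[v.codon] += 1
            flags = annotate_domains(v.codon)
            if flags.in_alpha:
                domain_counts["alpha"] += 1
            elif flags.in_beta:
                domain_counts["beta"] += 1
            else:
                domain_counts["neither"] += 1
        profiles[label] = {
            "n": n,
            "phenotype_fraction": {
                p.value: occurrences.get(p, 0) / n for p in phenotypes
            },
            "phenotype_occurrence_share": {
                p.value: (occurrences.get(p, 0) / total_occ if total_occ else 0.0)
                for p in phenotypes
            },
            "group_counts": {
                g.value: group_counts.get(g.value, 0) for g in VariantGroup
            },
            "domain_counts": domain_counts,
            "codon_histogram": dict(sorted(codon_hist.items())),
        }
    return profiles
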
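"""Beta diversity: Bray-Curtis distances, PCoA, PERMANOVA.

PCoA follows Gower's construction: double-center -D^2/2, eigendecompose,
order axes by eigenvalue and keep the positive ones (negative eigenvalues,
which arise because Bray-Curtis is not Euclidean-embeddable, are reported
but their axes dropped).  PERMANOVA uses the standard pseudo-F on within-
and between-group sums of squared distances with a seeded group-label
permutation null; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError
from .community_tables import AbundanceTable


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ConfigError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ConfigError("distance matrix must be symmetric with zero diagonal")
        self.d = d

    def to_tsv(self) -> str:
        frame = pd.DataFrame(self.d, index=self.labels, columns=self.labels)
        return frame.to_csv(sep="\t")


@dataclass
class PermanovaResult:
    F: float
    R2: float
    p: float
    n_perm: int


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns."""
    X = table.counts.to_numpy(dtype=float).T
    if X.shape[0] < 2:
        raise ConfigError("need at least two samples")
    if (X.sum(axis=1) == 0).any():
        raise ConfigError("all-zero sample column")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(list(table.counts.columns), d)


def pcoa(dm: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Principal coordinate analysis of a distance matrix.

    Returns (coordinates, eigenvalues, proportion_explained).  Coordinates
    span the axes with positive eigenvalue, ordered by decreasing
    eigenvalue; ``eigenvalues`` contains the full sorted spectrum including
    any negative values; proportions are over the positive part.
    """
    n = len(dm.labels)
    if n < 3:
        raise ConfigError("PCoA needs at least three samples")
    d2 = dm.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = 1e-10 * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    proportion = eigvals[positive] / eigvals[positive].sum()
    frame = pd.DataFrame(
        coords,
        index=dm.labels,
        columns=[f"PCo{i + 1}" for i in range(int(positive.sum()))],
    )
    return frame, eigvals, proportion


def _permanova_stats(
    d2: np.ndarray, group_indices: list[np.ndarray]
) -> tuple[float, float]:
    n = d2.shape[0]
    a = len(group_indices)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    F = (ss_among / (a - 1)) / (ss_within / (n - a))
    R2 = ss_among / ss_total
    return F, R2


def permanova(
    dm: DistanceMatrix,
    groups: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``groups`` assigns a label to each sample in ``dm.labels`` order; each
    group needs at least two members.  The permutation p-value is computed
    with a seeded generator and satisfies p >= 1/(n_perm + 1).
    """
    if len(groups) != len(dm.labels):
        raise ConfigError("one group label per sample required")
    labels = np.asarray(groups)
    unique = np.unique(labels)
    if len(unique) < 2:
        raise ConfigError("need at least two groups")
    if any((labels == g).sum() < 2 for g in unique):
        raise ConfigError("every group needs at least two members")
    d2 = dm.d.astype(float) ** 2
    indices = [np.flatnonzero(labels == g) for g in unique]
    F_obs, R2 = _permanova_stats(d2, indices)
    rng = np.random.default_rng(seed)
    hits = 0
    n = len(labels)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        permuted = labels[perm]
        idx = [np.flatnonzero(permuted == g) for g in unique]
        F_perm, _ = _permanova_stats(d2, idx)
        if F_perm >= F_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(F_obs), float(R2), float(p), n_perm)
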
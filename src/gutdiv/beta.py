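"""Community distance matrices and ordination.

Bray-Curtis and weighted UniFrac distances between samples, classical
principal-coordinates analysis (retaining negative eigenvalues, which the
dispersion test needs for its corrected centroid distances), and nonmetric
multidimensional scaling minimising Kruskal stress-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .phylo import BranchMatrix


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    data: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids must match the matrix dimension")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(d, 0.0)
        self.data = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids,
                            columns=self.sample_ids)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("both samples must have positive total reads")
    return float(np.abs(x - y).sum() / (x + y).sum())


def weighted_unifrac(x, y, bm: BranchMatrix, normalized: bool = True) -> float:
    """Weighted UniFrac distance between two count vectors on a shared tree.

    Raw form: sum_b l_b |p_b(x) - p_b(y)| where p_b is the fraction of a
    sample's reads descending from branch b. The normalized form (the
    default) divides by sum_b l_b (p_b(x) + p_b(y)).
    """
    pb = bm.branch_fractions(np.column_stack([x, y]))
    diff = float((bm.lengths * np.abs(pb[:, 0] - pb[:, 1])).sum())
    if not normalized:
        return diff
    denom = float((bm.lengths * (pb[:, 0] + pb[:, 1])).sum())
    if denom == 0:
        return 0.0
    return diff / denom


def distance_matrix(counts: pd.DataFrame, metric: str,
                    bm: BranchMatrix | None = None,
                    normalized: bool = True) -> DistanceMatrix:
    """All pairwise distances of an OTU x sample count table.

    ``metric`` is ``"bray_curtis"`` or ``"weighted_unifrac"``; the latter
    requires a BranchMatrix over the table's OTUs.
    """
    samples = list(counts.columns)
    mat = counts.to_numpy(dtype=float)
    if metric == "bray_curtis":
        d = squareform(pdist(mat.T, metric="braycurtis"))
    elif metric == "weighted_unifrac":
        if bm is None:
            raise ValueError("weighted UniFrac requires a tree (BranchMatrix)")
        pb = bm.branch_fractions(mat)  # (B, S)
        n = len(samples)
        d = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(pb[:, i, None] - pb[:, i + 1:])
            num = (bm.lengths[:, None] * diff).sum(axis=0)
            if normalized:
                den = (bm.lengths[:, None] * (pb[:, i, None] + pb[:, i + 1:])
                       ).sum(axis=0)
                num = np.divide(num, den, out=np.zeros_like(num),
                                where=den > 0)
            d[i, i + 1:] = num
            d[i + 1:, i] = num
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(d, samples)


@dataclass
class PCoAResult:
    """Principal coordinates with positive and negative axes kept apart.

    ``coords`` holds the real coordinates (positive eigenvalues);
    ``neg_coords`` the imaginary-axis magnitudes belonging to negative
    eigenvalues, which enter squared distances with a minus sign.
    """

    coords: np.ndarray
    neg_coords: np.ndarray
    eigenvalues: np.ndarray
    sample_ids: list[str]


def pcoa(dist: DistanceMatrix, eps: float = 1e-10) -> PCoAResult:
    """Classical scaling: eigendecomposition of the Gower-centered matrix."""
    d = dist.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    g = (g + g.T) / 2
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = np.abs(vals).max() if vals.size else 1.0
    pos = vals > eps * max(scale, 1.0)
    neg = vals < -eps * max(scale, 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    neg_coords = vecs[:, neg] * np.sqrt(-vals[neg])
    return PCoAResult(coords, neg_coords, vals, list(dist.sample_ids))


@dataclass
class NMDSResult:
    coords: np.ndarray
    stress: float
    sample_ids: list[str]
    k: int = 2


def nmds(dist: DistanceMatrix, k: int = 2, restarts: int = 20,
         seed: int | None = 0, max_iter: int = 300,
         tol: float = 1e-4) -> NMDSResult:
    """Nonmetric MDS minimising Kruskal stress-1.

    Runs ``restarts`` random SMACOF starts plus one start seeded from the
    PCoA configuration and keeps the lowest-stress solution. Deterministic
    for a fixed seed.
    """
    n = dist.data.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    offdiag = dist.data[np.triu_indices(n, 1)]
    if offdiag.size > 1 and np.allclose(offdiag, offdiag[0]):
        warnings.warn("all pairwise distances are equal; NMDS configuration "
                      "is arbitrary", stacklevel=2)
    best_coords, best_stress = None, np.inf
    common = dict(n_components=k, metric=False, dissimilarity="precomputed",
                  normalized_stress=True, max_iter=max_iter, eps=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if restarts > 0:
            m = MDS(n_init=restarts, random_state=seed, **common)
            c = m.fit_transform(dist.data)
            best_coords, best_stress = c, float(m.stress_)
        # PCoA-seeded start: recovers near-zero stress on embeddable input
        p = pcoa(dist)
        init = np.zeros((n, k))
        take = min(k, p.coords.shape[1])
        init[:, :take] = p.coords[:, :take]
        m = MDS(n_init=1, random_state=seed, **common)
        c = m.fit_transform(dist.data, init=init)
        if float(m.stress_) < best_stress:
            best_coords, best_stress = c, float(m.stress_)
    return NMDSResult(best_coords, best_stress, list(dist.sample_ids), k)
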
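"""Identity-by-state similarity and genetic-ancestry clustering.

IBS similarity between two individuals is the mean, over variants where both
calls are present, of ``1 - |x_j - x_k| / 2`` — i.e. the proportion of alleles
shared by state.  Samples are grouped by average-linkage agglomerative
clustering on the IBS distance ``1 - similarity``, cut at a user-chosen number
of clusters (default 4), with labels reported in decreasing cluster size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dataio import GenotypeCohort

__all__ = ["SimilarityMatrix", "ibs_matrix", "cluster_ibs"]


@dataclass
class SimilarityMatrix:
    """Symmetric n x n IBS-proportion matrix with unit diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("similarity matrix shape does not match sample ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def ibs_matrix(cohort: GenotypeCohort, snp_set=None) -> SimilarityMatrix:
    """Pairwise IBS similarity over (typically LD-pruned) variants.

    Entry (j, k) averages ``1 - |x_j - x_k|/2`` over variants non-missing in
    both samples; a pair sharing no non-missing variant is an error.
    """
    if cohort.n_samples < 2:
        raise ValueError("IBS needs at least two samples")
    idx = np.arange(cohort.n_variants) if snp_set is None else np.asarray(snp_set)
    if idx.size == 0:
        raise ValueError("empty snp_set")
    X = cohort.dosage[:, idx]
    valid = ~np.isnan(X)
    n = cohort.n_samples
    if valid.all():
        # |a-b| = (a-b)^2 - 2*[{a,b} = {0,2}] for dosages; all via matmuls
        Xf = X.astype(np.float64)
        gram = Xf @ Xf.T
        sq = np.einsum("ij,ij->i", Xf, Xf)
        absdiff = sq[:, None] + sq[None, :] - 2.0 * gram
        lo = (X == 0).astype(np.float64)
        hi = (X == 2).astype(np.float64)
        cross = lo @ hi.T
        absdiff -= 2.0 * (cross + cross.T)
        sim = 1.0 - absdiff / (2.0 * idx.size)
        np.fill_diagonal(sim, 1.0)
        return SimilarityMatrix(sim, list(cohort.sample_ids))
    Xz = np.where(valid, X, 0.0)
    sim = np.ones((n, n))
    for j in range(n):
        both = valid[j] & valid[j + 1:]
        counts = both.sum(axis=1)
        if (counts == 0).any():
            k = j + 1 + int(np.argmax(counts == 0))
            raise ValueError(
                f"samples {cohort.sample_ids[j]!r} and {cohort.sample_ids[k]!r} "
                "share no non-missing variants"
            )
        dist = (np.abs(Xz[j] - Xz[j + 1:]) * both).sum(axis=1) / (2.0 * counts)
        sim[j, j + 1:] = sim[j + 1:, j] = 1.0 - dist
    return SimilarityMatrix(sim, list(cohort.sample_ids))


def cluster_ibs(sim: SimilarityMatrix, k: int = 4) -> np.ndarray:
    """Average-linkage agglomerative clustering on IBS distance, cut at k.

    Returns integer labels 0..k-1 ordered by decreasing cluster size
    (ties: smaller first-member index first).
    """
    n = len(sim.sample_ids)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    if k == 1:
        return np.zeros(n, dtype=int)
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    first_member = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_member[lab]))
    remap = {lab: i for i, lab in enumerate(order)}
    return np.array([remap[lab] for lab in raw], dtype=int)
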
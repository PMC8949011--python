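"""Congruence among distance matrices (CADM) via Kendall's W.

Sequence-based and structure-based trees of the same proteins are
compared through their cophenetic matrices: each matrix is unfolded to
its n(n-1)/2 upper-triangle entries, the entries are ranked within each
matrix (mid-ranks for ties, which ultrametric trees always produce), and
Kendall's coefficient of concordance W is computed across matrices.  W
ranges from 0 (no congruence) to 1 (complete congruence).  Significance
comes from a permutation test that jointly permutes object labels of
every matrix except the first (the standard global CADM test), with the
add-one p-value estimator so p is never reported as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix
from scipy.stats import rankdata


@dataclass
class CongruenceResult:
    W: float
    p_value: float
    n_permutations: int
    seed: int
    n_objects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "W": self.W,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_objects": self.n_objects,
        }])


def cophenetic_matrix(t: skbio.TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length (cophenetic) distances of a tree."""
    for node in t.traverse(include_self=False):
        if node.length is None:
            label = node.name or f"internal node above {{{', '.join(x.name for x in node.tips())}}}"
            raise ValueError(f"missing branch length on edge to {label}")
    return t.tip_tip_distances()


def _unfold(matrices: Sequence[DistanceMatrix]) -> tuple[np.ndarray, list[str]]:
    """Stack upper-triangle vectors of matrices re-ordered to common ids."""
    ids = list(matrices[0].ids)
    if len(ids) < 4:
        raise ValueError("need at least 4 objects")
    rows = []
    for dm in matrices:
        if set(dm.ids) != set(ids):
            raise ValueError("matrices cover different id sets")
        data = dm.filter(ids).data
        iu = np.triu_indices(len(ids), k=1)
        rows.append(data[iu])
    return np.asarray(rows), ids


def _w_from_ranks(ranks: np.ndarray, tie_terms: np.ndarray) -> float:
    """Kendall's W from a (p, m) array of per-matrix mid-ranks."""
    p, m = ranks.shape
    R = ranks.sum(axis=0)
    num = 12.0 * np.sum(R ** 2) - 3.0 * p ** 2 * m * (m + 1) ** 2
    den = p ** 2 * (m ** 3 - m) - p * tie_terms.sum()
    return float(num / den)


def _tie_term(vec: np.ndarray) -> float:
    """T = sum(t^3 - t) over tie groups of one unfolded vector."""
    _, counts = np.unique(vec, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kendall_w(matrices: Sequence[DistanceMatrix]) -> float:
    """Kendall's coefficient of concordance across >= 2 distance matrices."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    vecs, _ = _unfold(matrices)
    ranks = np.vstack([rankdata(v) for v in vecs])
    ties = np.array([_tie_term(v) for v in vecs])
    return _w_from_ranks(ranks, ties)


def cadm_test(
    matrices: Sequence[DistanceMatrix],
    n_permutations: int = 999,
    seed: int = 0,
) -> CongruenceResult:
    """Global CADM permutation test of concordance among distance matrices.

    The null is generated by jointly permuting the object labels (rows and
    columns) of every matrix except the first and recomputing W; ranks and
    tie corrections are permutation-invariant, so each permutation only
    re-indexes the precomputed rank vectors.
    """
    if n_permutations < 99:
        warnings.warn("fewer than 99 permutations: p-value resolution is poor")
    vecs, ids = _unfold(matrices)
    n = len(ids)
    p = vecs.shape[0]
    ranks = np.vstack([rankdata(v) for v in vecs])
    ties = np.array([_tie_term(v) for v in vecs])
    w_obs = _w_from_ranks(ranks, ties)

    # pair-index lookup: entry (i, j) -> position in the unfolded vector
    m = n * (n - 1) // 2
    idx = np.zeros((n, n), dtype=int)
    iu = np.triu_indices(n, k=1)
    idx[iu] = np.arange(m)
    idx = idx + idx.T

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        permuted = ranks.copy()
        for k in range(1, p):
            perm = rng.permutation(n)
            pair_perm = idx[np.ix_(perm, perm)][iu]
            permuted[k] = ranks[k, pair_perm]
        if _w_from_ranks(permuted, ties) >= w_obs:
            count += 1
    p_value = (1 + count) / (1 + n_permutations)
    return CongruenceResult(
        W=w_obs, p_value=p_value, n_permutations=n_permutations,
        seed=seed, n_objects=n,
    )
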
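"""Structure-based and sequence-based tree reconstruction.

Structures are compared all-vs-all with the sequence-independent aligner,
scored with the elastic Z-score (symmetrised over alignment direction),
and converted to the pseudo-distance

.. math:: D_{QT} = Z_{QQ} + Z_{TT} - 2 Z_{QT}

which is zero for self-comparisons and grows with structural divergence.
The structural dendrogram is an average-linkage (UPGMA) clustering of the
pseudo-distance matrix.  The sequence tree is a Saitou-Nei neighbour
joining of Needleman-Wunsch alignment distances; externally inferred
trees can be imported through Newick instead.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix
from Bio import Align
from Bio.Align import substitution_matrices

from structphy.daliscore import elastic_raw_score, self_z, z_from_score
from structphy.structio import SequenceRecord, Structure
from structphy.superpose import structural_align

logger = logging.getLogger(__name__)


def pseudo_distance(z_qq: float, z_tt: float, z_qt: float) -> float:
    """Pseudo-distance D = Z_QQ + Z_TT - 2 Z_QT (clamped at 0)."""
    if z_qq <= 0 or z_tt <= 0:
        raise ValueError("self Z-scores must be positive")
    d = z_qq + z_tt - 2.0 * z_qt
    if d < 0:
        warnings.warn(f"negative pseudo-distance {d:.4g} clamped to 0")
        return 0.0
    return float(d)


def zscore_matrix(
    structures: Sequence[Structure], calibration="polynomial"
) -> pd.DataFrame:
    """Symmetric all-vs-all elastic Z matrix with self-scores on the diagonal.

    Off-diagonal entries are the mean of the two alignment directions;
    unalignable pairs are NaN.
    """
    ids = [s.id for s in structures]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate structure ids")
    n = len(structures)
    Z = np.full((n, n), np.nan)
    for i, s in enumerate(structures):
        Z[i, i] = self_z(s, calibration)
    for i, j in itertools.combinations(range(n), 2):
        a, b = structures[i], structures[j]
        rij = structural_align(a, b)
        rji = structural_align(b, a)
        zs = []
        if not rij.unalignable:
            S = elastic_raw_score(a, b, rij.correspondence)
            zs.append(z_from_score(S, len(a), len(b), calibration))
        if not rji.unalignable:
            S = elastic_raw_score(b, a, rji.correspondence)
            zs.append(z_from_score(S, len(b), len(a), calibration))
        if zs:
            Z[i, j] = Z[j, i] = float(np.mean(zs))
        else:
            logger.warning("unalignable pair (%s, %s)", a.id, b.id)
    return pd.DataFrame(Z, index=ids, columns=ids)


def structural_distance_matrix(
    structures: Sequence[Structure], calibration="polynomial"
) -> DistanceMatrix:
    """All-vs-all pseudo-distance matrix over a structure set.

    Unalignable pairs are imputed at 1.5x the largest observed distance.
    """
    if len(structures) < 3:
        raise ValueError("need at least 3 structures")
    Z = zscore_matrix(structures, calibration)
    ids = list(Z.index)
    n = len(ids)
    D = np.zeros((n, n))
    missing = []
    for i, j in itertools.combinations(range(n), 2):
        if np.isnan(Z.iat[i, j]):
            missing.append((i, j))
        else:
            D[i, j] = D[j, i] = pseudo_distance(Z.iat[i, i], Z.iat[j, j], Z.iat[i, j])
    if missing:
        fill = 1.5 * D.max()
        for i, j in missing:
            logger.warning("imputing distance for unalignable pair (%s, %s)", ids[i], ids[j])
            D[i, j] = D[j, i] = fill
    return DistanceMatrix(D, ids)


# ---------------------------------------------------------------------------
# hierarchical clustering (UPGMA family)
# ---------------------------------------------------------------------------

def hierarchical_tree(D: DistanceMatrix, linkage: str = "average") -> skbio.TreeNode:
    """Agglomerative dendrogram of a distance matrix as a rooted tree.

    Merge heights are half the inter-cluster distance, so the tree is
    ultrametric with branch lengths equal to height differences.  Ties
    between equally close cluster pairs are broken by the
    lexicographically smallest member label, making the topology
    deterministic.  ``linkage`` is ``average`` (UPGMA), ``complete`` or
    ``single``.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    ids = list(D.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 leaves")
    dist = {frozenset((i, j)): D[ids[i], ids[j]]
            for i in range(len(ids)) for j in range(i + 1, len(ids))}
    # cluster -> (node, height, size, smallest member label)
    clusters = {
        i: (skbio.TreeNode(name=name), 0.0, 1, name) for i, name in enumerate(ids)
    }
    next_id = len(ids)
    while len(clusters) > 1:
        keys = list(clusters)
        best = None
        for x, y in itertools.combinations(keys, 2):
            d = dist[frozenset((x, y))]
            lab = tuple(sorted((clusters[x][3], clusters[y][3])))
            cand = (d, lab, x, y)
            if best is None or cand < best:
                best = cand
        d, _, x, y = best
        nx, hx, sx, lx = clusters.pop(x)
        ny, hy, sy, ly = clusters.pop(y)
        h = d / 2.0
        nx.length = max(0.0, h - hx)
        ny.length = max(0.0, h - hy)
        parent = skbio.TreeNode(children=[nx, ny])
        for k in list(clusters):
            dxk = dist.pop(frozenset((x, k)))
            dyk = dist.pop(frozenset((y, k)))
            if linkage == "average":
                dnew = (sx * dxk + sy * dyk) / (sx + sy)
            elif linkage == "complete":
                dnew = max(dxk, dyk)
            else:
                dnew = min(dxk, dyk)
            dist[frozenset((next_id, k))] = dnew
        dist.pop(frozenset((x, y)))
        clusters[next_id] = (parent, h, sx + sy, min(lx, ly))
        next_id += 1
    root = next(iter(clusters.values()))[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# sequence distances and neighbour joining
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def pairwise_sequence_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Fraction of identical columns and column count of the NW alignment."""
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns, columns


def sequence_distance_matrix(seqs: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Pairwise alignment distances 1 - identity over aligned columns."""
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    for s in seqs:
        if len(s) < 10:
            warnings.warn(f"{s.id}: sequence shorter than 10 residues")
    n = len(seqs)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ident, _ = pairwise_sequence_identity(seqs[i].sequence, seqs[j].sequence)
        D[i, j] = D[j, i] = 1.0 - ident
    return DistanceMatrix(D, ids)


def nj_tree(D: DistanceMatrix) -> skbio.TreeNode:
    """Saitou-Nei neighbour joining; negative branch lengths clamped to 0."""
    if len(D.ids) < 3:
        raise ValueError("need at least 3 taxa")
    tree = skbio.tree.nj(D)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def conservation_table(seqs: Sequence[SequenceRecord]) -> pd.DataFrame:
    """Per-column conservation (fraction of the most common residue).

    Requires equal-length sequences (e.g. a co-evolved synthetic family);
    an aligned external MSA can be supplied the same way.
    """
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    arr = np.array([list(s.sequence) for s in seqs])
    rows = []
    for col in range(arr.shape[1]):
        letters, counts = np.unique(arr[:, col], return_counts=True)
        k = counts.argmax()
        rows.append({
            "position": col + 1,
            "consensus": letters[k],
            "conservation": counts[k] / arr.shape[0],
        })
    return pd.DataFrame(rows)


def leaf_annotation_table(
    leaf_labels: Sequence[str], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Leaf-label annotation export (family/category rings for tree viewers)."""
    table = annotations.set_index("id")
    missing = [l for l in leaf_labels if l not in table.index]
    if missing:
        raise ValueError(f"unannotated leaves: {missing}")
    return table.loc[list(leaf_labels)].reset_index()
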
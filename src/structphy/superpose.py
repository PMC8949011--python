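"""Rigid-body superposition, TM-score, and sequence-independent alignment.

The TM-score follows the standard definition: for an aligned pair set with
inter-residue distances :math:`d_i` after optimal superposition,

.. math::

    \\mathrm{TM} = \\frac{1}{L_{norm}} \\sum_i \\frac{1}{1 + (d_i/d_0)^2},
    \\qquad d_0 = \\max(0.5,\\ 1.24\\,(L_{norm}-15)^{1/3} - 1.8)

normalised by the reference-structure length when benchmarking a prediction
against its experiment, and by the shorter chain when searching for remote
homologues.  The full-search mode maximises the score over superpositions
seeded from contiguous fragments of the correspondence, iterating a
superpose-on-inliers / rescore loop until the inlier set is stable.

``structural_align`` produces a sequence-independent sequential residue
correspondence between two CA traces by iterative dynamic programming over
TM-style distance scores, seeded from gapless threading offsets and
fragment superpositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from structphy._dp import nw_open_only
from structphy.structio import Structure

#: inlier cutoff for the iterative superposition refinement (Angstrom)
_INLIER_MIN = 4.5
#: gap-open penalty of the structural aligner's DP stage
DEFAULT_GAP_OPEN = 0.6


@dataclass
class Correspondence:
    """An ordered, sequential residue pairing between two structures.

    ``pairs`` is a (k, 2) integer array of 0-based indices; both columns are
    strictly increasing and index-unique.  May be empty only as an explicit
    degenerate value.
    """

    pairs: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if len(self.pairs):
            for col in (0, 1):
                if np.any(np.diff(self.pairs[:, col]) <= 0):
                    raise ValueError("correspondence indices must be strictly increasing")

    @classmethod
    def identity(cls, n: int) -> "Correspondence":
        idx = np.arange(n)
        return cls(np.column_stack([idx, idx]))

    def mirrored(self) -> "Correspondence":
        return Correspondence(self.pairs[:, ::-1])

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    """Outcome of a superposition / alignment.

    The transform maps B onto A: ``x -> rotation @ x + translation``.
    ``tm_score`` is 0 only for the explicit "unalignable" marker.
    """

    correspondence: Correspondence
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    tm_score: float
    n_norm: int

    @property
    def aligned_length(self) -> int:
        return len(self.correspondence)

    @property
    def unalignable(self) -> bool:
        return self.tm_score == 0.0


def kabsch(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation + translation of B onto A, and the RMSD.

    Reflections are corrected via the determinant sign.  All-collinear
    input is flagged with a warning; the transform (non-unique about the
    line) is still returned.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite coordinates")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    P, Q = B - cb, A - ca
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    if S[0] > 0 and S[1] / S[0] < 1e-8:
        warnings.warn("degenerate (collinear) point set: rotation not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / len(A)))
    return R, t, rmsd


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale d0(L), floored at 0.5 A for short chains."""
    return max(0.5, 1.24 * np.cbrt(l_norm - 15.0) - 1.8) if l_norm > 15 else 0.5


def _tm_sum(dists: np.ndarray, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + (dists / d0) ** 2)))


def tm_score(
    A: Structure,
    B: Structure,
    c: Correspondence,
    mode: str = "full-search",
    l_norm: Optional[int] = None,
) -> SuperpositionResult:
    """TM-score of B against A over a given correspondence.

    ``l_norm`` defaults to the length of A (the reference).  In
    ``fixed-frame`` mode the structures are scored in their current
    coordinate frames; ``full-search`` maximises over superpositions seeded
    from contiguous correspondence fragments (lengths L, L/2, L/4, min 4),
    each refined by superposing on the inlier pairs until stable.
    """
    if len(c) == 0:
        raise ValueError("empty correspondence")
    l_norm = int(l_norm if l_norm is not None else len(A))
    if l_norm < 3:
        raise ValueError("normalization length < 3")
    d0 = tm_d0(l_norm)
    a = A.coords[c.pairs[:, 0]]
    b = B.coords[c.pairs[:, 1]]

    if mode == "fixed-frame":
        d = np.linalg.norm(a - b, axis=1)
        tm = _tm_sum(d, d0) / l_norm
        rmsd = float(np.sqrt((d ** 2).mean()))
        return SuperpositionResult(c, np.eye(3), np.zeros(3), rmsd, tm, l_norm)
    if mode != "full-search":
        raise ValueError(f"unknown mode {mode!r}")

    n = len(c)
    cutoff = max(_INLIER_MIN, d0)
    seeds: list[tuple[int, int]] = [(0, n)]  # whole correspondence
    for frag in (max(4, n // 2), max(4, n // 4)):
        if frag >= n:
            continue
        step = max(1, frag // 2)
        for start in range(0, n - frag + 1, step):
            seeds.append((start, start + frag))

    best = None  # (tm, rmsd, start, R, t)
    candidates = []
    # also score the incoming frame so full-search never loses to fixed-frame
    candidates.append((np.eye(3), np.zeros(3), -1))
    for start, stop in seeds:
        if stop - start < 3:
            continue
        R, t, _ = kabsch(a[start:stop], b[start:stop])
        for _ in range(25):
            d = np.linalg.norm(a - (b @ R.T + t), axis=1)
            inliers = d < cutoff
            if inliers.sum() < 3:
                break
            R2, t2, _ = kabsch(a[inliers], b[inliers])
            if np.allclose(R2, R, atol=1e-10) and np.allclose(t2, t, atol=1e-10):
                break
            R, t = R2, t2
        candidates.append((R, t, start))

    for R, t, start in candidates:
        d = np.linalg.norm(a - (b @ R.T + t), axis=1)
        tm = _tm_sum(d, d0) / l_norm
        rmsd = float(np.sqrt((d ** 2).mean()))
        key = (tm, -rmsd, -start)  # higher TM, then lower RMSD, then lower offset
        if best is None or key > best[0]:
            best = (key, tm, rmsd, R, t)
    _, tm, rmsd, R, t = best
    return SuperpositionResult(c, R, t, rmsd, tm, l_norm)


def _threading_seeds(la: int, lb: int, min_overlap: int = 8) -> list[np.ndarray]:
    """Gapless correspondences at all offsets with sufficient overlap."""
    seeds = []
    min_overlap = min(min_overlap, la, lb)
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        i0, j0 = max(0, off), max(0, -off)
        k = min(la - i0, lb - j0)
        if k >= min_overlap:
            idx = np.arange(k)
            seeds.append(np.column_stack([i0 + idx, j0 + idx]))
    return seeds


def structural_align(
    A: Structure,
    B: Structure,
    gap_open: float = DEFAULT_GAP_OPEN,
    max_rounds: int = 30,
) -> SuperpositionResult:
    """Sequence-independent sequential alignment of two CA traces.

    Iterative DP: initial correspondences come from gapless threading at
    all offsets plus fragment-pair superposition seeds; each round
    superposes on the current correspondence, scores every residue pair as
    ``1 / (1 + (d_ij/d0)^2)``, realigns with a global DP (gap-open penalty
    only), and repeats until the correspondence stops changing.  Returns
    the correspondence maximising the TM-score normalised by the shorter
    chain; if nothing of length >= 4 is found, an explicit "unalignable"
    result with TM = 0 is returned.
    """
    la, lb = len(A), len(B)
    if la < 10 or lb < 10:
        raise ValueError("structural_align requires both structures length >= 10")
    l_norm = min(la, lb)
    d0 = tm_d0(l_norm)

    # --- seed correspondences -------------------------------------------
    seed_corrs: list[np.ndarray] = []
    scored = []
    for pairs in _threading_seeds(la, lb):
        a, b = A.coords[pairs[:, 0]], B.coords[pairs[:, 1]]
        R, t, _ = kabsch(a, b)
        d = np.linalg.norm(a - (b @ R.T + t), axis=1)
        scored.append((_tm_sum(d, d0) / l_norm, len(seed_corrs)))
        seed_corrs.append(pairs)
    scored.sort(reverse=True)
    top = [seed_corrs[i] for _, i in scored[:3]]

    best: Optional[SuperpositionResult] = None

    def dp_round(R: np.ndarray, t: np.ndarray) -> np.ndarray:
        bt = B.coords @ R.T + t
        diff = A.coords[:, None, :] - bt[None, :, :]
        dmat = np.sqrt((diff ** 2).sum(axis=2))
        S = 1.0 / (1.0 + (dmat / d0) ** 2)
        return nw_open_only(S, gap_open)

    def refine(pairs: np.ndarray) -> Optional[SuperpositionResult]:
        prev = None
        for _ in range(max_rounds):
            if len(pairs) < 3:
                return None
            R, t, _ = kabsch(A.coords[pairs[:, 0]], B.coords[pairs[:, 1]])
            new = dp_round(R, t)
            if prev is not None and new.shape == pairs.shape and np.array_equal(new, pairs):
                break
            prev, pairs = pairs, new
        if len(pairs) < 4:
            return None
        return tm_score(A, B, Correspondence(pairs), mode="full-search", l_norm=l_norm)

    for pairs in top:
        res = refine(pairs)
        if res is None:
            continue
        if best is None or (res.tm_score, -res.rmsd) > (best.tm_score, -best.rmsd):
            best = res

    # fragment-pair seeds rescue hard cases the threading seeds miss;
    # skipped when threading already found a confident alignment
    if best is None or best.tm_score < 0.6:
        f = min(20, l_norm)
        for i0 in range(0, la - f + 1, max(1, (la - f) // 2 or 1)):
            for j0 in range(0, lb - f + 1, max(1, (lb - f) // 2 or 1)):
                R, t, _ = kabsch(A.coords[i0:i0 + f], B.coords[j0:j0 + f])
                res = refine(dp_round(R, t))
                if res is None:
                    continue
                if best is None or (res.tm_score, -res.rmsd) > (best.tm_score, -best.rmsd):
                    best = res
    if best is None:
        return SuperpositionResult(
            Correspondence(np.empty((0, 2), dtype=int)),
            np.eye(3), np.zeros(3), float("nan"), 0.0, l_norm,
        )
    return best
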
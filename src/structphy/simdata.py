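"""Synthetic protein family generator.

Emulates the study conditions of a desk-scale structural-evolution
analysis of small phage proteins (anti-CRISPR scale, 50-200 residues):

* ``generate_backbone`` builds a compact, self-avoiding CA trace of
  interleaved ideal helices and random coil confined to a protein-like
  globular radius, with a random sequence;
* ``evolve_family`` diverges a root structure + sequence along a known
  tree, accumulating Brownian coordinate noise (displacement RMS =
  rate * sqrt(branch length)), occasional hinge rotations (fold-level
  divergence), and BLOSUM-weighted sequence substitutions;
* ``make_prediction_pair`` fabricates a "predicted" model of a structure
  at a controlled RMSD, with per-residue pLDDT-style confidences that
  decay with the local displacement;
* ``make_homologue_library`` assembles an annotated reference library of
  several functional families plus unrelated decoy chains.

All outputs are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import skbio
from Bio.Align import substitution_matrices

from structphy.structio import AMINO_ACIDS, SequenceRecord, Structure, write_pdb

_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TURN = np.deg2rad(100.0)
_BOND = 3.8
_MIN_SEP = 4.0  # non-consecutive CA clash distance

_CATEGORIES = ("polymerase", "ligase", "nuclease", "regulation", "transport")


@dataclass
class EvolutionParams:
    """Rates of the branch-wise divergence process.

    coordinate_noise_rate is in Angstrom per sqrt(branch-length unit)
    (Brownian scaling: displacement variance accumulates linearly in
    branch length; the realised per-branch displacement field is
    normalised so its RMS equals rate * sqrt(branch) exactly);
    substitution_rate is expected substitutions per site per unit;
    hinge_probability is the per-branch chance of one small domain
    rotation (angle uniform in 5-20 degrees).
    """

    tree: skbio.TreeNode
    coordinate_noise_rate: float = 0.5
    substitution_rate: float = 0.5
    hinge_probability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.coordinate_noise_rate, self.substitution_rate, self.hinge_probability) < 0:
            raise ValueError("rates must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _helix_points(n: int, start: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """n successive CA positions of an ideal helix continuing from start."""
    k = np.arange(1, n + 1)
    local = np.column_stack([
        _HELIX_RADIUS * np.cos(k * _HELIX_TURN) - _HELIX_RADIUS,
        _HELIX_RADIUS * np.sin(k * _HELIX_TURN),
        _HELIX_RISE * k,
    ])
    return start + local @ frame.T


def generate_backbone(length: int, seed: int, helix_fraction: float = 0.5) -> Structure:
    """Compact self-avoiding CA trace of helical and coil segments.

    Consecutive CA-CA distances stay within 3.8 +/- 0.05 A and any two
    non-consecutive CAs are at least 4.0 A apart.  The chain is confined
    to a sphere of radius ``3.0 * length**0.38`` about its running
    centroid, which reproduces the radius-of-gyration scaling of globular
    proteins (Rg ~ 2.2 * L**0.38) rather than an extended random walk;
    dead ends in the growth are resolved by backtracking the last few
    residues.  The sequence is drawn uniformly over the 20 amino acids.
    Deterministic for a fixed seed.
    """
    if not 30 <= length <= 500:
        raise ValueError("length must be in [30, 500]")
    rng = np.random.default_rng(seed)
    r_conf = 3.0 * length ** 0.38
    coords = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    retries = 0
    fail_streak = 0
    helix_left = 0
    coil_left = 0
    frame = np.eye(3)

    def clashes(p: np.ndarray) -> bool:
        if len(coords) < 2:
            return False
        prev = np.asarray(coords[:-1])
        return bool(np.any(np.linalg.norm(prev - p, axis=1) < _MIN_SEP))

    while len(coords) < length:
        centre = np.mean(coords, axis=0)
        if helix_left == 0 and coil_left == 0:
            # segment lengths drawn from matched ranges so the realised
            # helix content tracks helix_fraction on average
            if rng.random() < helix_fraction:
                helix_left = int(rng.integers(5, 12))
                frame = _random_rotation(rng)
            else:
                coil_left = int(rng.integers(5, 12))
        if fail_streak > 100:
            # dead end: back out the last few residues and regrow
            k = min(len(coords) - 1, 5)
            del coords[-k:]
            helix_left = coil_left = fail_streak = 0
            if len(coords) >= 2:
                direction = coords[-1] - coords[-2]
                direction = direction / np.linalg.norm(direction)
            continue
        if helix_left > 0:
            p = _helix_points(1, coords[-1], frame)[0]
            if clashes(p) or np.linalg.norm(p - centre) > r_conf:
                retries += 1
                fail_streak += 1
                if retries > 20000:
                    raise RuntimeError("self-avoidance unsatisfiable after 20000 retries")
                frame = _random_rotation(rng)  # re-orient the helix
                continue
            coords.append(p)
            direction = p - coords[-2]
            direction /= np.linalg.norm(direction)
            helix_left -= 1
            fail_streak = 0
        else:
            step = rng.uniform(3.77, 3.83)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            d = 0.7 * direction + u
            out = coords[-1] - centre
            if np.linalg.norm(out) > 0.8 * r_conf:
                # steer back toward the centroid near the confinement wall
                d = d - 1.2 * out / np.linalg.norm(out)
            d /= np.linalg.norm(d)
            p = coords[-1] + step * d
            if clashes(p) or np.linalg.norm(p - centre) > r_conf:
                retries += 1
                fail_streak += 1
                if retries > 20000:
                    raise RuntimeError("self-avoidance unsatisfiable after 20000 retries")
                continue
            coords.append(p)
            direction = d
            coil_left -= 1
            fail_streak = 0
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return Structure(id=f"bb{seed}", sequence=seq, coords=np.asarray(coords))


# ---------------------------------------------------------------------------
# family evolution
# ---------------------------------------------------------------------------

_B62 = substitution_matrices.load("BLOSUM62")


def _substitution_weights() -> dict[str, np.ndarray]:
    """BLOSUM-weighted replacement distributions, one per residue."""
    weights = {}
    for a in AMINO_ACIDS:
        w = np.array([
            0.0 if b == a else np.exp(_B62[a, b] / 2.0) for b in AMINO_ACIDS
        ])
        weights[a] = w / w.sum()
    return weights


_SUB_WEIGHTS = _substitution_weights()


def _evolve_branch(
    coords: np.ndarray,
    seq: str,
    branch: float,
    params: EvolutionParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str]:
    L = len(seq)
    sd = params.coordinate_noise_rate * np.sqrt(max(branch, 0.0))
    field = rng.normal(size=coords.shape)
    if sd > 0:
        # normalise the realised per-residue displacement RMS to exactly
        # sd: divergence then tracks branch length, not the chance
        # magnitude of one Gaussian draw, keeping short branches reliably
        # shorter than long ones in the realised structures
        field *= sd / np.sqrt((field ** 2).sum(axis=1).mean() / 3.0)
    else:
        field[:] = 0.0
    out = coords + field
    if branch > 0 and rng.random() < params.hinge_probability and L > 10:
        pivot = int(rng.integers(5, L - 5))
        angle = np.deg2rad(rng.uniform(5.0, 20.0))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        K = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        centre = out[pivot]
        out[pivot + 1:] = (out[pivot + 1:] - centre) @ R.T + centre
    p_sub = 1.0 - np.exp(-params.substitution_rate * max(branch, 0.0))
    letters = list(seq)
    hit = rng.random(L) < p_sub
    for i in np.flatnonzero(hit):
        a = letters[i]
        if a in _SUB_WEIGHTS:
            letters[i] = rng.choice(list(AMINO_ACIDS), p=_SUB_WEIGHTS[a])
    return out, "".join(letters)


def evolve_family(
    root: Structure, params: EvolutionParams
) -> list[tuple[Structure, SequenceRecord]]:
    """Diverge a root structure along the params tree; returns the leaves.

    Each branch of length b adds an isotropic Gaussian coordinate noise
    field normalised to RMS coordinate_noise_rate * sqrt(b), may apply
    one hinge rotation,
    and substitutes each site with probability 1 - exp(-rate * b).  Leaves
    are labelled by the tree leaf names.
    """
    rng = np.random.default_rng(params.seed)
    leaves: list[tuple[Structure, SequenceRecord]] = []

    def recurse(node: skbio.TreeNode, coords: np.ndarray, seq: str) -> None:
        for child in node.children:
            b = child.length if child.length is not None else 0.0
            c2, s2 = _evolve_branch(coords, seq, b, params, rng)
            if child.is_tip():
                name = child.name or f"leaf{len(leaves)}"
                leaves.append((
                    Structure(id=name, sequence=s2, coords=c2),
                    SequenceRecord(id=name, sequence=s2),
                ))
            else:
                recurse(child, c2, s2)

    recurse(params.tree, root.coords.copy(), root.sequence)
    return leaves


def random_ultrametric_tree(
    n_leaves: int, seed: int, depth: float = 1.0, names: Optional[list[str]] = None
) -> skbio.TreeNode:
    """Random bifurcating clock-like tree: all leaves at distance ``depth``.

    Built by successive random coalescences.  The n-1 merge heights are a
    rescaled cumulative sum of gaps drawn uniformly in [0.8, 1.2], so
    every internal branch keeps a comparable share of the total depth:
    no split is vanishingly short relative to its neighbours, which makes
    each topology a well-posed reconstruction target.
    """
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"t{i}" for i in range(n_leaves)]
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    gaps = rng.uniform(0.8, 1.2, size=n_leaves - 1)
    heights = depth * np.cumsum(gaps) / gaps.sum()
    nodes = [(skbio.TreeNode(name=n), 0.0) for n in names]
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        a.length = h - ha
        b.length = h - hb
        parent = skbio.TreeNode(children=[a, b])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [(parent, float(h))]
    root = nodes[0][0]
    return root


# ---------------------------------------------------------------------------
# prediction pairs
# ---------------------------------------------------------------------------

def make_prediction_pair(
    experimental: Structure, target_rmsd: float, seed: int
) -> Structure:
    """Fabricate a predicted model at a controlled RMSD from its experiment.

    Per-residue displacement amplitudes follow a gamma profile (some
    regions predicted much worse than others, as in real models), globally
    rescaled so the superposed RMSD lands within 10% of the target.
    Confidence is pLDDT-like: ``clamp(100 * exp(-d_i / 2), 20, 100)`` with
    d_i the final per-residue deviation after superposition.
    """
    from structphy.superpose import kabsch

    if target_rmsd < 0:
        raise ValueError("target RMSD must be >= 0")
    L = len(experimental)
    if target_rmsd == 0:
        return Structure(
            id=experimental.id + "_pred",
            sequence=experimental.sequence,
            coords=experimental.coords.copy(),
            confidence=np.full(L, 100.0),
            resnums=experimental.resnums.copy(),
        )
    rng = np.random.default_rng(seed)
    amps = rng.gamma(shape=2.0, scale=1.0, size=L)
    dirs = rng.normal(size=(L, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    disp = amps[:, None] * dirs
    scale = target_rmsd / np.sqrt((amps ** 2).mean())
    for _ in range(10):
        pred = experimental.coords + scale * disp
        _, _, realized = kabsch(experimental.coords, pred)
        if abs(realized - target_rmsd) <= 0.02 * target_rmsd:
            break
        scale *= target_rmsd / realized
    R, t, _ = kabsch(experimental.coords, pred)
    dev = np.linalg.norm(experimental.coords - (pred @ R.T + t), axis=1)
    plddt = np.clip(100.0 * np.exp(-dev / 2.0), 20.0, 100.0)
    return Structure(
        id=experimental.id + "_pred",
        sequence=experimental.sequence,
        coords=pred,
        confidence=plddt,
        resnums=experimental.resnums.copy(),
    )


# ---------------------------------------------------------------------------
# annotated homologue library
# ---------------------------------------------------------------------------

def make_homologue_library(
    n_families: int,
    members_per_family: int,
    n_decoys: int,
    seed: int,
    length: int = 80,
    coordinate_noise_rate: float = 0.5,
    substitution_rate: float = 0.5,
    hinge_probability: float = 0.1,
    out_dir=None,
) -> tuple[list[Structure], pd.DataFrame]:
    """Annotated reference library: families of related folds plus decoys.

    Each family descends from its own random backbone via
    :func:`evolve_family` and carries one functional-category label;
    decoys are independent chains labelled ``decoy``.  When ``out_dir``
    is given, PDB files and the annotation TSV are written there.
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    rng = np.random.default_rng(seed)
    structures: list[Structure] = []
    rows = []
    for fam in range(n_families):
        root = generate_backbone(length, seed=int(rng.integers(0, 2 ** 31)))
        tree = random_ultrametric_tree(
            members_per_family,
            seed=int(rng.integers(0, 2 ** 31)),
            names=[f"fam{fam}_m{k}" for k in range(members_per_family)],
        )
        params = EvolutionParams(
            tree=tree,
            coordinate_noise_rate=coordinate_noise_rate,
            substitution_rate=substitution_rate,
            hinge_probability=hinge_probability,
            seed=int(rng.integers(0, 2 ** 31)),
        )
        category = _CATEGORIES[fam % len(_CATEGORIES)]
        for st, _ in evolve_family(root, params):
            structures.append(st)
            rows.append({"id": st.id, "category": category, "family": f"fam{fam}"})
    for d in range(n_decoys):
        st = generate_backbone(length, seed=int(rng.integers(0, 2 ** 31)))
        st.id = f"decoy{d}"
        structures.append(st)
        rows.append({"id": st.id, "category": "decoy", "family": "none"})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for st in structures:
            write_pdb(st, out_dir / f"{st.id}.pdb")
        table.to_csv(out_dir / "annotations.tsv", sep="\t", index=False)
    return structures, table
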
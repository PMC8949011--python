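"""File IO and the in-memory CA-trace model.

Every structure handled by the pipeline is reduced to a labelled CA trace:
one coordinate per residue, a one-letter sequence, and (for predicted
models) a per-residue confidence value read from the PDB B-factor column,
where structure predictors store their 0-100 pLDDT estimate.  Residues are
renumbered densely 1..L internally; the author numbering is kept as
metadata so prediction/experiment pairs can still be matched on it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import gemmi
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Seq import Seq as _BioSeq
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA1_TO_3["X"] = "UNK"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FileFormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass
class Structure:
    """A labelled CA trace.

    Parameters
    ----------
    id:
        Structure label (file stem by default).
    sequence:
        One-letter amino-acid sequence, ``X`` for non-standard residues.
    coords:
        ``(L, 3)`` float array of CA coordinates in Angstrom.
    confidence:
        Optional ``(L,)`` array of per-residue confidence values in [0, 100]
        (pLDDT for predicted models); ``None`` when not meaningful.
    resnums:
        Original author residue numbering, kept as metadata.
    """

    id: str
    sequence: str
    coords: np.ndarray
    confidence: Optional[np.ndarray] = None
    resnums: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"{self.id}: coords must be (L, 3)")
        L = self.coords.shape[0]
        if L == 0:
            raise ValueError(f"{self.id}: empty structure")
        if len(self.sequence) != L:
            raise ValueError(f"{self.id}: sequence length {len(self.sequence)} != {L} coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (L,):
                raise ValueError(f"{self.id}: confidence shape mismatch")
            if np.any(self.confidence < 0) or np.any(self.confidence > 100):
                raise ValueError(f"{self.id}: confidence outside [0, 100]")
        if self.resnums is None:
            self.resnums = np.arange(1, L + 1)
        else:
            self.resnums = np.asarray(self.resnums, dtype=int)
            if self.resnums.shape != (L,):
                raise ValueError(f"{self.id}: resnums shape mismatch")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def residues(self):
        """Iterate ``(index, aa, coordinate, confidence)`` tuples."""
        conf = self.confidence if self.confidence is not None else [None] * len(self)
        for i, (aa, xyz, c) in enumerate(zip(self.sequence, self.coords, conf), start=1):
            yield i, aa, xyz, c


@dataclass
class SequenceRecord:
    """A named protein sequence over the 20 amino acids plus X."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"{self.id}: invalid residue letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path, chain: Optional[str] = None, id: Optional[str] = None) -> Structure:
    """Read a CA trace from a PDB file.

    Only MODEL 1 and the first altloc of each residue are used; HETATM
    records are ignored.  The B-factor column is stored as per-residue
    confidence when all values lie in [0, 100] (the pLDDT convention of
    predicted models); otherwise confidence is dropped with a warning,
    since experimental B-factors are not confidences.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) > 1:
        logger.warning("%s: %d models present, reading MODEL 1 only", path, len(st))
    if len(st) == 0:
        raise FileFormatError(f"{path}: no models / no ATOM records")
    model = st[0]
    chains = [model[chain]] if chain is not None else list(model)

    seq, xyz, bfac, nums = [], [], [], []
    for ch in chains:
        for res in ch:
            if res.het_flag != "A":
                continue
            ca = None
            for atom in res:
                if atom.name == "CA":
                    ca = atom  # first altloc wins
                    break
            if ca is None:
                continue
            seq.append(AA3_TO_1.get(res.name, "X"))
            xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
            bfac.append(ca.b_iso)
            nums.append(res.seqid.num)
    if not xyz:
        raise FileFormatError(f"{path}: no CA atoms found in ATOM records")

    conf = np.asarray(bfac, dtype=float)
    if np.any(conf < 0) or np.any(conf > 100):
        warnings.warn(f"{path}: B-factors outside [0, 100]; not treated as confidence")
        conf = None
    elif np.all(conf == 0):
        conf = None  # write_pdb emits 0.00 for absent confidence
    return Structure(
        id=id or path.stem,
        sequence="".join(seq),
        coords=np.asarray(xyz, dtype=float),
        confidence=conf,
        resnums=np.asarray(nums, dtype=int),
    )


def write_pdb(s: Structure, path) -> None:
    """Write a Structure as fixed-column ATOM records (one CA per residue).

    Confidence goes to the B-factor columns (61-66), 0.00 when absent.
    """
    if len(s) == 0:
        raise ValueError("cannot write empty structure")
    conf = s.confidence if s.confidence is not None else np.zeros(len(s))
    lines = []
    for i, (aa, xyz, b, num) in enumerate(zip(s.sequence, s.coords, conf, s.resnums), start=1):
        res3 = AA1_TO_3.get(aa, "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:<3s} A{int(num):4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{b:6.2f}           C"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-FASTA file; IDs are the header up to the first whitespace."""
    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise FileFormatError(f"{path}: duplicate sequence ids {dupes}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    bio = [_BioSeqRecord(_BioSeq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")  # wraps at 60 columns


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path_or_str) -> skbio.TreeNode:
    """Parse a Newick tree, rejecting duplicate leaf labels."""
    try:
        if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
            import io
            tree = skbio.TreeNode.read(io.StringIO(path_or_str), format="newick")
        else:
            tree = skbio.TreeNode.read(str(path_or_str), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError subclasses
        raise FileFormatError(f"invalid Newick: {exc}") from exc
    names = [t.name for t in tree.tips()]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise FileFormatError(f"duplicate leaf labels {dupes}")
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    """Serialize with branch lengths rounded to 6 significant digits."""
    t = tree.copy()
    for node in t.traverse(include_self=True):
        if node.length is not None:
            node.length = float(f"{node.length:.6g}")
    t.write(str(path), format="newick")


def newick_string(tree: skbio.TreeNode) -> str:
    import io

    t = tree.copy()
    for node in t.traverse(include_self=True):
        if node.length is not None:
            node.length = float(f"{node.length:.6g}")
    buf = io.StringIO()
    t.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# TSV matrices and tables
# ---------------------------------------------------------------------------

def write_matrix_tsv(ids: Sequence[str], values: np.ndarray, path) -> None:
    """Write a square matrix with a header row and column of labels."""
    pd.DataFrame(values, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FileFormatError(f"{path}: row and column labels differ")
    return list(df.index), df.to_numpy(dtype=float)


def read_annotation_table(path) -> pd.DataFrame:
    """Read a library annotation table: columns ``id``, ``category`` (+ extras)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "category"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing required column '{col}'")
    return df
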
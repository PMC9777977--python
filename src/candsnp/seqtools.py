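"""Sequence utilities: ORF finding, protein parameters, identity, NJ trees.

Supports the cloning/bioinformatics layer of a candidate-gene study: locate
open reading frames in cloned cDNA, translate them, summarise the protein's
physicochemical profile (molecular weight, pI, charged residues, GRAVY,
instability and aliphatic indices), compute percent-identity matrices over
aligned orthologue sets, and build neighbor-joining trees from distance
matrices.

Coordinates are 0-based half-open on the given strand.  ORF search defaults
to the forward strand (cDNA input); protein parameters follow the ProtParam
conventions (average isotopic masses, Bjellqvist pKa set, Kyte-Doolittle
hydropathy, Guruprasad DIWV instability weights) via Biopython.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

_NT = set("ACGTN")
_AA = set("ACDEFGHIKLMNPQRSTVWY")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ATG..stop reading frame; length includes the stop codon."""

    seq_id: str
    start: int      # 0-based, on the reported strand
    end: int        # half-open
    strand: int     # +1 / -1
    frame: int      # 0..2 on that strand
    length: int     # nucleotides, multiple of 3
    protein: str    # translated product, stop excluded

    def __post_init__(self) -> None:
        assert self.length % 3 == 0 and len(self.protein) == self.length // 3 - 1


def find_orfs(
    seq: str, min_len: int = 30, both_strands: bool = False, seq_id: str = ""
) -> list[OpenReadingFrame]:
    """All ATG-to-stop open reading frames of at least ``min_len`` nt.

    Every in-frame ATG upstream of a stop opens its own ORF (nested starts
    are all reported).  Results are sorted by length, longest first.
    """
    seq = seq.upper()
    bad = set(seq) - _NT
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    if min_len < 6:
        raise ValueError("min_len must be >= 6 (start plus stop codon)")
    orfs: list[OpenReadingFrame] = []
    strands = [(+1, seq)]
    if both_strands:
        strands.append((-1, str(Seq(seq).reverse_complement())))
    for strand, s in strands:
        for frame in range(3):
            starts: list[int] = []
            for pos in range(frame, len(s) - 2, 3):
                codon = s[pos : pos + 3]
                if codon == "ATG":
                    starts.append(pos)
                elif codon in _STOPS:
                    for start in starts:
                        length = pos + 3 - start
                        if length >= min_len:
                            protein = str(Seq(s[start : pos]).translate())
                            orfs.append(
                                OpenReadingFrame(
                                    seq_id=seq_id, start=start, end=pos + 3,
                                    strand=strand, frame=frame, length=length,
                                    protein=protein,
                                )
                            )
                    starts = []
    return sorted(orfs, key=lambda o: (-o.length, o.strand, o.start))


@dataclass(frozen=True)
class ProteinParams:
    """ProtParam-style physicochemical summary of a protein sequence."""

    length: int
    molecular_weight: float   # Da, average isotopic masses
    isoelectric_point: float
    n_negative: int           # Asp + Glu
    n_positive: int           # Arg + Lys
    gravy: float              # mean Kyte-Doolittle hydropathy
    instability_index: float  # Guruprasad DIWV statistic
    aliphatic_index: float
    stability: str            # "stable" | "unstable"  (II > 40 -> unstable)
    hydropathy_class: str     # "hydrophilic" | "hydrophobic"  (GRAVY < 0 -> hydrophilic)


def protein_params(seq: str) -> ProteinParams:
    """Physicochemical parameters of a protein over the 20 standard residues."""
    seq = seq.upper()
    for i, aa in enumerate(seq):
        if aa not in _AA:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
    pa = ProteinAnalysis(seq)
    frac = pa.amino_acids_percent  # mole fractions per residue
    scale = 100.0 / sum(frac.values())  # to mole percent, robust to convention
    aliphatic = scale * (frac["A"] + 2.9 * frac["V"] + 3.9 * (frac["I"] + frac["L"]))
    ii = pa.instability_index()
    gravy = pa.gravy()
    return ProteinParams(
        length=len(seq),
        molecular_weight=pa.molecular_weight(),
        isoelectric_point=pa.isoelectric_point(),
        n_negative=seq.count("D") + seq.count("E"),
        n_positive=seq.count("R") + seq.count("K"),
        gravy=gravy,
        instability_index=ii,
        aliphatic_index=aliphatic,
        stability="unstable" if ii > 40 else "stable",
        hydropathy_class="hydrophilic" if gravy < 0 else "hydrophobic",
    )


# ---------------------------------------------------------------------------
# identity matrices
# ---------------------------------------------------------------------------


def percent_identity(a: str, b: str) -> float:
    """Identity over aligned columns where neither sequence has a gap, x100."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    match = compare = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "-" or y == "-":
            continue
        compare += 1
        if x == y:
            match += 1
    if compare == 0:
        return math.nan
    return 100.0 * match / compare


def identity_matrix(seqs: dict[str, str]) -> "pd.DataFrame":
    """Pairwise percent-identity matrix over equal-length aligned sequences."""
    import pandas as pd

    labels = list(seqs)
    out = pd.DataFrame(np.zeros((len(labels), len(labels))), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            out.iloc[i, j] = 100.0 if i == j else percent_identity(seqs[a], seqs[b])
    return out


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Convenience global alignment (match 2, mismatch -1, gap open -5, extend -0.5)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (node, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dist: np.ndarray, labels: list[str]) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string with lengths.

    Q-matrix ties break on the smallest (row, col) index pair; negative
    branch lengths are clamped to zero with the deficit moved to the sister
    branch, preserving the pair's summed length.
    """
    D = np.asarray(dist, dtype=float).copy()
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if D.shape != (n, n) or np.any(np.abs(D - D.T) > 1e-9):
        raise ValueError("distance matrix must be square and symmetric (tol 1e-9)")
    if np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distances must be non-negative with a zero diagonal")
    nodes = [_Node(label=l) for l in labels]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += -li  # move the deficit to the sister branch
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        u = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    # attach the last edge to the internal node, yielding the standard
    # unrooted (trifurcating) representation
    if nodes[i].children:
        root, other = nodes[i], nodes[j]
    else:
        root, other = nodes[j], nodes[i]
    root.children.append((other, D[i, j]))
    return root.newick() + ";"
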
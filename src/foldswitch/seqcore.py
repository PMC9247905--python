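"""Sequence I/O, pairwise local alignment, identity matrices and clustering.

Every downstream stage of the fold-switch screen is built on the primitives
here: Smith-Waterman local alignment with the affine gap scores used for
CTD registration (match +1, mismatch 0, gap open -1.0, gap extend -0.5),
aligned-identity computation over co-ungapped columns, all-vs-all identity
matrices, and complete-linkage identity clustering (>=78% within-cluster
identity by construction).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from sklearn.cluster import AgglomerativeClustering

logger = logging.getLogger(__name__)

#: canonical one-letter amino-acid codes; X is tolerated but never matches
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = 0.0
DEFAULT_GAP_OPEN = -1.0
DEFAULT_GAP_EXTEND = -0.5


@dataclass(frozen=True)
class Sequence:
    """A protein sequence with an identifier and optional description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )
        if "X" in self.residues:
            logger.warning("sequence %s contains ambiguous residue X", self.id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A local alignment between two sequences.

    ``aligned_a``/``aligned_b`` are equal-length strings over residues plus
    ``-``; ``start_*``/``end_*`` are 0-based half-open coordinates of the
    aligned region in each parent sequence.  An empty alignment (score 0,
    no aligned residues) is represented with empty strings.
    """

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    start_a: int
    start_b: int
    end_a: int
    end_b: int

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def is_empty(self) -> bool:
        return not self.aligned_a

    def columns(self) -> list[tuple[int, int]]:
        """Parent coordinates (i_a, i_b) of every co-ungapped column."""
        out = []
        ia, ib = self.start_a, self.start_b
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != GAP and cb != GAP:
                out.append((ia, ib))
            if ca != GAP:
                ia += 1
            if cb != GAP:
                ib += 1
        return out


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into a list of :class:`Sequence`.

    Lowercase residues are normalised to upper case with a warning; an
    empty file or a record-less file is an error.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seqs = []
    for rec in records:
        residues = str(rec.seq)
        if residues != residues.upper():
            logger.warning("sequence %s: lowercase residues normalised", rec.id)
            residues = residues.upper()
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        seqs.append(Sequence(id=rec.id, residues=residues, description=desc))
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id}" + (f" {s.description}" if s.description else "")
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


def _make_aligner(match: float, mismatch: float,
                  gap_open: float, gap_extend: float) -> PairwiseAligner:
    # X never scores as a match, mirroring ambiguous-residue handling
    mat = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            mat[a, b] = match if (a == b and a != "X") else mismatch
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_ALIGNER_CACHE: dict[tuple[float, float, float, float], PairwiseAligner] = {}


def local_align(a: Sequence, b: Sequence,
                match: float = DEFAULT_MATCH,
                mismatch: float = DEFAULT_MISMATCH,
                gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND) -> PairwiseAlignment:
    """Smith-Waterman local alignment with affine gaps.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``, the convention
    of Biopython's ``localxs``.  The highest-scoring alignment is returned;
    co-optimal alignments are resolved by the aligner's deterministic
    traceback order.  If no positive-scoring alignment exists the empty
    alignment with score 0 is returned.
    """
    key = (match, mismatch, gap_open, gap_extend)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        aligner = _make_aligner(*key)
        _ALIGNER_CACHE[key] = aligner
    alns = aligner.align(a.residues, b.residues)
    if alns.score <= 0 or len(alns) == 0:
        return PairwiseAlignment(a.id, b.id, "", "", 0.0, 0, 0, 0, 0)
    best = alns[0]
    coords = best.coordinates
    return PairwiseAlignment(
        id_a=a.id, id_b=b.id,
        aligned_a=str(best[0]), aligned_b=str(best[1]),
        score=float(alns.score),
        start_a=int(coords[0][0]), start_b=int(coords[1][0]),
        end_a=int(coords[0][-1]), end_b=int(coords[1][-1]),
    )


def pairwise_identity(aligned_a: str | PairwiseAlignment,
                      aligned_b: str | None = None) -> float:
    """Aligned identity: identical co-ungapped columns / co-ungapped columns.

    Accepts either a :class:`PairwiseAlignment` or two equal-length aligned
    strings (e.g. two rows of an MSA).  ``X`` never counts as identical.
    Raises ``ValueError`` when no column has both sequences ungapped.
    """
    if isinstance(aligned_a, PairwiseAlignment):
        sa, sb = aligned_a.aligned_a, aligned_a.aligned_b
    else:
        if aligned_b is None:
            raise TypeError("two aligned strings or one alignment required")
        sa, sb = aligned_a, aligned_b
    if len(sa) != len(sb):
        raise ValueError("aligned strings differ in length")
    both = ident = 0
    for ca, cb in zip(sa, sb):
        if ca != GAP and cb != GAP:
            both += 1
            if ca == cb and ca != "X":
                ident += 1
    if both == 0:
        raise ValueError("identity undefined: no co-ungapped columns")
    return ident / both


@dataclass
class IdentityMatrix:
    """Symmetric all-vs-all identity matrix with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("identity matrix diagonal must be 1")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("identities must lie in [0, 1]")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                row = "\t".join(f"{x:.4f}" for x in self.values[i])
                fh.write(f"{name}\t{row}\n")


def identity_matrix(seqs: TSequence[Sequence] | list[tuple[str, str]],
                    aligned: bool = False) -> IdentityMatrix:
    """All-vs-all identity matrix.

    With ``aligned=True`` the input is MSA rows ``(id, aligned_string)`` and
    identities are computed directly over the rows; otherwise each pair of
    :class:`Sequence` is locally aligned first.  A pair with undefined
    identity gets 0 with a warning.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for an identity matrix")
    if aligned:
        ids = [r[0] for r in seqs]
        rows = [r[1] for r in seqs]
    else:
        ids = [s.id for s in seqs]
    n = len(ids)
    vals = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if aligned:
                    ident = pairwise_identity(rows[i], rows[j])
                else:
                    aln = local_align(seqs[i], seqs[j])
                    if aln.is_empty:
                        raise ValueError("empty alignment")
                    ident = pairwise_identity(aln)
            except ValueError:
                logger.warning("identity undefined for %s/%s; set to 0",
                               ids[i], ids[j])
                ident = 0.0
            vals[i, j] = vals[j, i] = ident
    return IdentityMatrix(ids=ids, values=vals)


@dataclass
class SequenceClusterSet:
    """A partition of sequence ids into identity clusters."""

    clusters: list[frozenset[str]]
    min_within_identity: float

    def cluster_of(self, seq_id: str) -> frozenset[str]:
        for c in self.clusters:
            if seq_id in c:
                return c
        raise KeyError(seq_id)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cluster_id\tmember_id\n")
            for k, c in enumerate(self.clusters):
                for m in sorted(c):
                    fh.write(f"{k}\t{m}\n")


def cluster_by_identity(matrix: IdentityMatrix,
                        min_within_identity: float = 0.78) -> SequenceClusterSet:
    """Complete-linkage agglomerative clustering on distance = 1 - identity.

    Complete linkage guarantees that every pairwise identity within a
    cluster is >= ``min_within_identity`` (inclusive); the invariant is
    asserted after clustering.
    """
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    # threshold nudged up so pairs at exactly the minimum identity merge
    model = AgglomerativeClustering(
        n_clusters=None,
        metric="precomputed",
        linkage="complete",
        distance_threshold=(1.0 - min_within_identity) + 1e-9,
    )
    labels = model.fit_predict(dist)
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    # deterministic order: by first member's input position
    ordered = sorted(groups.values(), key=lambda g: g[0])
    clusters = []
    for g in ordered:
        for i in g:
            for j in g:
                if i < j and matrix.values[i, j] < min_within_identity - 1e-12:
                    raise AssertionError(
                        "within-cluster identity invariant violated")
        clusters.append(frozenset(matrix.ids[i] for i in g))
    return SequenceClusterSet(clusters=clusters,
                              min_within_identity=min_within_identity)


def identity_stats(matrix: IdentityMatrix) -> dict[str, float]:
    """Mean and median identity over the strict upper triangle."""
    n = len(matrix.ids)
    if n < 2:
        raise ValueError("need at least 2 ids")
    iu = np.triu_indices(n, k=1)
    vals = matrix.values[iu]
    return {"mean": float(np.mean(vals)),
            "median": float(statistics.median(vals.tolist()))}
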
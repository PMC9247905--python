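"""Genomic-context validation of NusG annotations.

Query proteins are mapped onto annotated proteomes (best local-alignment
identity strictly above 90%), and each mapped locus is classified by its
proximity to the conserved SecE/RplK/RplA operon markers: a housekeeping
NusG locus is expected within 10 kb of one of them on the same contig.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as TSequence

from .seqcore import Sequence, local_align

logger = logging.getLogger(__name__)

DEFAULT_MARKERS = frozenset({"SecE", "RplK", "RplA", "ribosomal protein L11"})
DEFAULT_WINDOW = 10_000
DEFAULT_MIN_IDENTITY = 0.90

HOUSEKEEPING_CONSISTENT = "housekeeping_consistent"
NOT_HOUSEKEEPING = "not_housekeeping"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval in GTF convention (1-based inclusive coordinates)."""

    contig: str
    start: int
    end: int
    strand: str
    gene_name: str
    protein_id: str = ""
    product: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("gene start must not exceed end")
        if self.start < 1:
            raise ValueError("GTF coordinates are positive")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path, feature: str = "CDS") -> list[GeneRecord]:
    """Read a GTF-like tab-separated gene table.

    Attributes are parsed for gene_name (falling back to gene_id),
    protein_id and product.
    """
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
        contig, _src, feat, start, end, _score, strand, _frame, attrs = parts[:9]
        if feature and feat != feature:
            continue
        a = dict(_ATTR_RE.findall(attrs))
        records.append(GeneRecord(
            contig=contig, start=int(start), end=int(end), strand=strand,
            gene_name=a.get("gene_name", a.get("gene_id", "")),
            protein_id=a.get("protein_id", ""),
            product=a.get("product", "")))
    if not records:
        raise ValueError(f"{path}: no gene records parsed")
    return records


@dataclass
class LocusMapping:
    query_id: str
    matched_protein_id: str | None
    identity: float
    gene: GeneRecord | None


def map_protein(query: Sequence,
                proteome: TSequence[tuple[Sequence, GeneRecord]],
                min_identity: float = DEFAULT_MIN_IDENTITY) -> LocusMapping:
    """Best-identity proteome hit with identity strictly above the threshold.

    Identity uses the full query length as denominator so that partial hits
    score low.  Ties break by longest aligned region, then lexicographic
    protein id.  Below-threshold queries return a mapping with gene None.
    """
    if not proteome:
        raise ValueError("empty proteome")
    best = None   # (identity, aligned_len, protein_id, gene)
    for prot, gene in proteome:
        aln = local_align(query, prot)
        if aln.is_empty:
            continue
        n_ident = sum(1 for ca, cb in zip(aln.aligned_a, aln.aligned_b)
                      if ca == cb and ca not in "-X")
        ident = n_ident / len(query)
        aligned_len = aln.end_a - aln.start_a
        better = (best is None
                  or (ident, aligned_len) > (best[0], best[1])
                  or ((ident, aligned_len) == (best[0], best[1])
                      and gene.protein_id < best[2]))
        if better:
            best = (ident, aligned_len, gene.protein_id, gene)
    if best is None or best[0] <= min_identity:
        return LocusMapping(query_id=query.id, matched_protein_id=None,
                            identity=best[0] if best else 0.0, gene=None)
    return LocusMapping(query_id=query.id, matched_protein_id=best[2],
                        identity=best[0], gene=best[3])


def gene_separation(a: GeneRecord, b: GeneRecord) -> int:
    """Nearest-edge gap in bp between two gene intervals on one contig;
    0 when the intervals overlap or abut."""
    if a.contig != b.contig:
        raise ValueError("genes on different contigs")
    if a.end < b.start:
        return b.start - a.end - 1
    if b.end < a.start:
        return a.start - b.end - 1
    return 0


@dataclass
class ContextAnnotation:
    query_id: str
    nearest_marker: str | None
    separation_bp: int | None
    within_window: bool
    context_class: str


def _matches_marker(gene: GeneRecord, markers: Iterable[str]) -> str | None:
    for m in markers:
        ml = m.lower()
        if ml == gene.gene_name.lower() or (gene.product
                                            and ml in gene.product.lower()):
            return m
    return None


def marker_proximity(locus: GeneRecord, genes: TSequence[GeneRecord],
                     markers: Iterable[str] = DEFAULT_MARKERS,
                     window: int = DEFAULT_WINDOW,
                     query_id: str = "") -> ContextAnnotation:
    """Distance from a locus to the nearest operon marker on its contig.

    Marker matching is a case-insensitive gene-name match or product text
    match; markers on other contigs never count.
    """
    nearest_name, nearest_sep = None, None
    for gene in genes:
        if gene.contig != locus.contig or gene is locus:
            continue
        name = _matches_marker(gene, markers)
        if name is None:
            continue
        sep = gene_separation(locus, gene)
        if nearest_sep is None or sep < nearest_sep:
            nearest_name, nearest_sep = gene.gene_name or name, sep
    within = nearest_sep is not None and nearest_sep <= window
    return ContextAnnotation(
        query_id=query_id,
        nearest_marker=nearest_name,
        separation_bp=nearest_sep,
        within_window=within,
        context_class=HOUSEKEEPING_CONSISTENT if within else NOT_HOUSEKEEPING)


def annotate_context(query: Sequence,
                     proteome: TSequence[tuple[Sequence, GeneRecord]],
                     genes: TSequence[GeneRecord],
                     markers: Iterable[str] = DEFAULT_MARKERS,
                     window: int = DEFAULT_WINDOW,
                     min_identity: float = DEFAULT_MIN_IDENTITY
                     ) -> ContextAnnotation:
    """Map a query protein to a locus, then classify its operon context."""
    mapping = map_protein(query, proteome, min_identity)
    if mapping.gene is None:
        return ContextAnnotation(query_id=query.id, nearest_marker=None,
                                 separation_bp=None, within_window=False,
                                 context_class=UNMAPPED)
    return marker_proximity(mapping.gene, genes, markers, window,
                            query_id=query.id)


def separation_tally(annotations: Iterable[ContextAnnotation],
                     thresholds: TSequence[int] = (270, 1000)) -> dict[int, int]:
    """Count within-window annotations whose separation exceeds each threshold."""
    anns = [a for a in annotations if a.within_window]
    return {t: sum(1 for a in anns if a.separation_bp > t) for t in thresholds}


def write_context_tsv(annotations: Iterable[ContextAnnotation],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tnearest_marker\tseparation_bp\t"
                 "within_window\tcontext_class\n")
        for a in annotations:
            fh.write("\t".join(map(str, (
                a.query_id, a.nearest_marker or "-",
                "-" if a.separation_bp is None else a.separation_bp,
                int(a.within_window), a.context_class))) + "\n")
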
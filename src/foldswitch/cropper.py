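"""Anchor-motif determination of C-terminal domain (CTD) crops.

Housekeeping NusG and fold-switching RfaH share a two-domain architecture;
the screen isolates the C-terminal domain by aligning each query to a
family reference and cropping a fixed-length window starting at the residue
aligned to a 5-residue anchor motif:

* 50-residue crops start at KVIIT (RfaH rule, >=40 accepted when the CTD
  runs short) or EMVRV (NusG rule, full 50 required);
* 40-residue crops start at FQAIF (RfaH) or ADFNG (NusG) and require the
  full 40 residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .seqcore import Sequence, local_align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchorSpec:
    """Family-specific cropping rule anchored at a 5-residue motif."""

    family: str                # "rfah" or "nusg"
    reference_id: str
    anchor_motif: str
    crop_length: int
    min_length: int

    def __post_init__(self):
        if self.family not in ("rfah", "nusg"):
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.anchor_motif) != 5:
            raise ValueError("anchor motif must be 5 residues")
        if self.crop_length not in (40, 50):
            raise ValueError("crop length must be 40 or 50")
        if self.min_length > self.crop_length:
            raise ValueError("min_length must not exceed crop_length")


# The four rules used in the screen.  50-residue crops feed the initial
# predictions; 40-residue crops are the definitive ones (the first 10
# residues of the 50-mers bias the alignments toward the superfamily).
RFAH_50 = AnchorSpec("rfah", "RfaH_ECOLI", "KVIIT", 50, 40)
NUSG_50 = AnchorSpec("nusg", "NUSG_ECOLI", "EMVRV", 50, 50)
RFAH_40 = AnchorSpec("rfah", "RfaH_ECOLI", "FQAIF", 40, 40)
NUSG_40 = AnchorSpec("nusg", "NUSG_ECOLI", "ADFNG", 40, 40)

DEFAULT_SPECS_40 = {"rfah": RFAH_40, "nusg": NUSG_40}
DEFAULT_SPECS_50 = {"rfah": RFAH_50, "nusg": NUSG_50}


@dataclass(frozen=True)
class DomainCrop:
    """A cropped C-terminal domain with provenance coordinates."""

    parent_id: str
    start: int
    end: int
    residues: str
    anchor: AnchorSpec
    truncated: bool

    def __post_init__(self):
        length = self.end - self.start
        if len(self.residues) != length:
            raise ValueError("crop residues do not match coordinates")
        if not (self.anchor.min_length <= length <= self.anchor.crop_length):
            raise ValueError("crop length outside anchor bounds")

    @property
    def id(self) -> str:
        return f"{self.parent_id}|{self.start}:{self.end}"

    def as_sequence(self) -> Sequence:
        return Sequence(id=self.id, residues=self.residues)


def locate_anchor(query: Sequence, reference: Sequence, motif: str) -> int:
    """0-based query index aligned to the first motif residue of the reference.

    The query is locally aligned to the reference; if the anchor column is
    gapped in the query the nearest following co-ungapped column is used.
    """
    count = reference.residues.count(motif)
    if count == 0:
        raise ValueError(f"motif {motif!r} absent from reference {reference.id}")
    if count > 1:
        raise ValueError(f"motif {motif!r} occurs {count} times in reference")
    ref_idx = reference.residues.index(motif)
    aln = local_align(query, reference)
    if aln.is_empty:
        raise ValueError("anchor not covered: no alignment")
    if not (aln.start_b <= ref_idx < aln.end_b):
        raise ValueError("anchor not covered by the aligned region")
    for iq, ir in aln.columns():
        if ir >= ref_idx:
            return iq
    raise ValueError("anchor not covered: anchor column gapped to the end")


def crop_ctd(query: Sequence, spec: AnchorSpec, reference: Sequence) -> DomainCrop:
    """Crop ``spec.crop_length`` residues starting at the anchor position.

    When fewer residues remain the crop is accepted truncated only if the
    rule allows it (RfaH 50-residue rule, minimum 40); otherwise the
    sequence is rejected as having a CTD too short for prediction.
    """
    start = locate_anchor(query, reference, spec.anchor_motif)
    remaining = len(query) - start
    if remaining >= spec.crop_length:
        end = start + spec.crop_length
        truncated = False
    elif remaining >= spec.min_length:
        end = len(query)
        truncated = True
    else:
        raise ValueError(
            f"CTD too short: {remaining} residues after anchor "
            f"(minimum {spec.min_length})")
    return DomainCrop(parent_id=query.id, start=start, end=end,
                      residues=query.residues[start:end], anchor=spec,
                      truncated=truncated)


@dataclass
class BatchCropResult:
    crops: list[DomainCrop]
    exclusions: list[tuple[str, str]]   # (id, reason)
    n_input: int

    @property
    def coverage(self) -> float:
        return len(self.crops) / self.n_input if self.n_input else 0.0

    @property
    def coverage_pct(self) -> int:
        return round(100 * self.coverage)

    def write_exclusions_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\treason\n")
            for sid, reason in self.exclusions:
                fh.write(f"{sid}\t{reason}\n")


def coverage_percent(n_cropped: int, n_total: int) -> int:
    """Crop coverage as a whole-number percentage."""
    if n_total == 0:
        raise ValueError("empty input")
    return round(100 * n_cropped / n_total)


def batch_crop(seqs: Iterable[Sequence],
               annotation: Mapping[str, str],
               specs: Mapping[str, AnchorSpec],
               references: Mapping[str, Sequence]) -> BatchCropResult:
    """Crop every sequence, collecting per-sequence failures into a report.

    ``annotation`` maps sequence id to family ("rfah"/"nusg"); ``specs`` and
    ``references`` map family to its :class:`AnchorSpec` and reference
    sequence.
    """
    seqs = list(seqs)
    crops, excluded = [], []
    for s in seqs:
        fam = annotation.get(s.id)
        if fam is None:
            raise KeyError(f"sequence {s.id} has no family annotation")
        try:
            crops.append(crop_ctd(s, specs[fam], references[fam]))
        except ValueError as exc:
            logger.info("excluding %s: %s", s.id, exc)
            excluded.append((s.id, str(exc)))
    return BatchCropResult(crops=crops, exclusions=excluded, n_input=len(seqs))


def write_crops_fasta(crops: Iterable[DomainCrop], path: str | Path) -> None:
    """Crops as FASTA; headers carry parent id and 0-based coordinates."""
    with open(path, "w") as fh:
        for c in crops:
            fh.write(f">{c.id}\n{c.residues}\n")
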
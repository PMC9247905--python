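"""The fold-switch caller.

A cropped CTD's secondary-structure prediction is reregistered against the
*E. coli* NusG CTD reference prediction through a pairwise local alignment
of the underlying sequences (gap scores -1.0/-0.5), helix<->strand
discrepancies are counted over co-ungapped columns, and the sequence is
called fold-switching when the discrepancy fraction reaches 5% of aligned
positions (inclusive) and the prediction is backed by at least 5 aligned
sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

from .cropper import AnchorSpec, DEFAULT_SPECS_40, DomainCrop, crop_ctd
from .seqcore import Sequence, local_align
from .sspred import SSPrediction

logger = logging.getLogger(__name__)

# E. coli NusG CTD reference predictions (40 states; '-' coil, E strand).
# One per profile database used to build the query predictions.
REFERENCE_STATES = {
    "jpred_db": "---EEEEEEEE----EEEEEEEE------EEEEEEEEE--",
    "uniref90": "---EEEEEEE-----EEEEEEEEE-----EEEEE------",
}

DEFAULT_THRESHOLD = 0.05
DEFAULT_MIN_SUPPORT = 5

FOLD_SWITCHING = "fold_switching"
SINGLE_FOLDING = "single_folding"
LOW_CONFIDENCE = "low_confidence"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class ReferencePrediction:
    database: str
    states: str

    def __post_init__(self):
        if len(self.states) != 40:
            raise ValueError("reference prediction must have 40 states")


REFERENCES = {db: ReferencePrediction(db, s) for db, s in REFERENCE_STATES.items()}


@dataclass
class DiscrepancyResult:
    """Helix<->strand conflict statistics for one query vs one reference."""

    query_id: str
    reference_database: str
    n_aligned: int
    n_H_vs_E: int
    n_E_vs_H: int
    support_depth: int = 1
    call: str | None = None

    @property
    def fraction(self) -> float:
        return (self.n_H_vs_E + self.n_E_vs_H) / self.n_aligned


def reregister(query_pred: SSPrediction, query_seq: Sequence,
               reference_seq: Sequence,
               reference_pred: ReferencePrediction) -> list[tuple[str, str]]:
    """Pair query and reference prediction states through sequence alignment.

    Returns (query_state, reference_state) for every co-ungapped column of
    the local alignment of ``query_seq`` to ``reference_seq``; columns
    gapped on either side are dropped.
    """
    if len(query_pred.states) != len(query_seq):
        raise ValueError("query prediction length does not match sequence")
    if len(reference_pred.states) != len(reference_seq):
        raise ValueError("reference prediction length does not match sequence")
    aln = local_align(query_seq, reference_seq)
    if aln.is_empty:
        raise ValueError("no registration: empty alignment")
    return [(query_pred.states[iq], reference_pred.states[ir])
            for iq, ir in aln.columns()]


def discrepancy(pairs: list[tuple[str, str]], query_id: str = "",
                reference_database: str = "",
                support_depth: int = 1) -> DiscrepancyResult:
    """Count helix-vs-strand conflicts over registered state pairs."""
    if not pairs:
        raise ValueError("no registered columns")
    n_he = sum(1 for q, r in pairs if q == "H" and r == "E")
    n_eh = sum(1 for q, r in pairs if q == "E" and r == "H")
    return DiscrepancyResult(query_id=query_id,
                             reference_database=reference_database,
                             n_aligned=len(pairs), n_H_vs_E=n_he,
                             n_E_vs_H=n_eh, support_depth=support_depth)


def classify(result: DiscrepancyResult,
             threshold: float = DEFAULT_THRESHOLD,
             min_support: int = DEFAULT_MIN_SUPPORT) -> str:
    """Apply the >=5% discrepancy rule with the >=5-sequence confidence gate.

    The threshold is inclusive: a fraction of exactly 0.05 is called
    fold-switching.
    """
    if result.support_depth < min_support:
        result.call = LOW_CONFIDENCE
    elif result.fraction >= threshold:
        result.call = FOLD_SWITCHING
    else:
        result.call = SINGLE_FOLDING
    return result.call


def _aggregate(results: Iterable[DiscrepancyResult]) -> str:
    """Any-database rule: one confident fold-switch call suffices."""
    results = list(results)
    confident = [r for r in results if r.call != LOW_CONFIDENCE]
    if not confident:
        return LOW_CONFIDENCE
    if any(r.call == FOLD_SWITCHING for r in confident):
        return FOLD_SWITCHING
    return SINGLE_FOLDING


@dataclass
class VariantReport:
    """Per-sequence outcome of the variable-length prediction comparison."""

    id: str
    full_length_call: str | None = None
    ctd_call: str | None = None
    aggregate_call: str = EXCLUDED
    full_results: list[DiscrepancyResult] = field(default_factory=list)
    ctd_results: list[DiscrepancyResult] = field(default_factory=list)
    crop: DomainCrop | None = None
    exclusion_reason: str | None = None


# a predictor maps (sequence, database tag) -> SSPrediction
Predictor = Callable[[Sequence, str], SSPrediction]


def run_variant(full_seq: Sequence, family: str, predictor: Predictor,
                reference_seq: Sequence,
                crop_specs: Mapping[str, AnchorSpec] | None = None,
                references: Mapping[str, ReferencePrediction] | None = None,
                family_references: Mapping[str, Sequence] | None = None,
                threshold: float = DEFAULT_THRESHOLD,
                min_support: int = DEFAULT_MIN_SUPPORT) -> VariantReport:
    """Full-vs-cropped comparison for one sequence.

    The CTD is cropped (40-residue rule by default), predictions are
    obtained for the full-length sequence (CTD window extracted) and for
    the isolated crop, both are registered against the NusG reference
    prediction of each database and classified.  A sequence whose CTD
    cannot be cropped is reported as excluded.
    """
    crop_specs = crop_specs or DEFAULT_SPECS_40
    references = references or REFERENCES
    crop_reference = (family_references[family] if family_references
                      else reference_seq)
    report = VariantReport(id=full_seq.id)
    try:
        crop = crop_ctd(full_seq, crop_specs[family], crop_reference)
    except (ValueError, KeyError) as exc:
        logger.info("excluding %s: %s", full_seq.id, exc)
        report.exclusion_reason = str(exc)
        return report
    report.crop = crop
    crop_seq = crop.as_sequence()
    for db, ref_pred in references.items():
        # context: full-length input, CTD window of its prediction
        full_pred = predictor(full_seq, db)
        ctd_of_full = SSPrediction(
            seq_id=full_seq.id,
            states=full_pred.states[crop.start:crop.end],
            source=full_pred.source, support_depth=full_pred.support_depth)
        pairs = reregister(ctd_of_full, crop_seq, reference_seq, ref_pred)
        res = discrepancy(pairs, query_id=full_seq.id, reference_database=db,
                          support_depth=full_pred.support_depth)
        classify(res, threshold, min_support)
        report.full_results.append(res)
        # context: isolated crop
        crop_pred = predictor(crop_seq, db)
        pairs = reregister(crop_pred, crop_seq, reference_seq, ref_pred)
        res = discrepancy(pairs, query_id=crop_seq.id, reference_database=db,
                          support_depth=crop_pred.support_depth)
        classify(res, threshold, min_support)
        report.ctd_results.append(res)
    report.full_length_call = _aggregate(report.full_results)
    report.ctd_call = _aggregate(report.ctd_results)
    report.aggregate_call = report.ctd_call
    return report


def _rate_pct(numerator: int, denominator: int, ndigits: int | None):
    if denominator == 0:
        return None
    pct = 100.0 * numerator / denominator
    return round(pct) if ndigits is None else round(pct, ndigits)


@dataclass
class CohortSummary:
    n_reports: int
    n_confident: int
    fraction_fold_switching: float | None
    fp_rate_housekeeping_pct: float | None     # one decimal
    single_fold_rate_nusg_sp_pct: int | None   # nearest integer
    coverage_pct: int


def cohort_summary(reports: Iterable[VariantReport],
                   labels: Mapping[str, str]) -> CohortSummary:
    """Cohort-level rates from per-sequence reports.

    ``labels`` maps id to "housekeeping", "nusg_sp" or "unknown".  The
    housekeeping false-positive rate is the share of confidently-called
    housekeeping sequences called fold-switching (reported to one decimal);
    the NusG^SP single-fold rate is the analogous share of specialised
    paralogs called single-folding (nearest integer).  Undefined rates
    (zero denominator) are None, never 0.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports")
    confident = [r for r in reports
                 if r.aggregate_call in (FOLD_SWITCHING, SINGLE_FOLDING)]
    n_fs = sum(1 for r in confident if r.aggregate_call == FOLD_SWITCHING)
    hk = [r for r in confident if labels.get(r.id) == "housekeeping"]
    sp = [r for r in confident if labels.get(r.id) == "nusg_sp"]
    hk_fs = sum(1 for r in hk if r.aggregate_call == FOLD_SWITCHING)
    sp_sf = sum(1 for r in sp if r.aggregate_call == SINGLE_FOLDING)
    n_cropped = sum(1 for r in reports if r.aggregate_call != EXCLUDED)
    return CohortSummary(
        n_reports=len(reports),
        n_confident=len(confident),
        fraction_fold_switching=(n_fs / len(confident)) if confident else None,
        fp_rate_housekeeping_pct=_rate_pct(hk_fs, len(hk), 1),
        single_fold_rate_nusg_sp_pct=_rate_pct(sp_sf, len(sp), None),
        coverage_pct=round(100 * n_cropped / len(reports)),
    )


def write_report_tsv(reports: Iterable[VariantReport], path: str | Path) -> None:
    cols = ("id", "database", "n_aligned", "n_H_vs_E", "n_E_vs_H",
            "fraction", "support_depth", "call", "aggregate_call")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rep in reports:
            if not rep.ctd_results:
                fh.write(f"{rep.id}\t-\t0\t0\t0\t-\t0\t{EXCLUDED}\t{EXCLUDED}\n")
                continue
            for res in rep.ctd_results:
                fh.write("\t".join(map(str, (
                    rep.id, res.reference_database, res.n_aligned,
                    res.n_H_vs_E, res.n_E_vs_H, f"{res.fraction:.4f}",
                    res.support_depth, res.call, rep.aggregate_call))) + "\n")
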
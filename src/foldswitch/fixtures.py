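"""Synthetic data generation for every pipeline stage.

Three generators, all deterministic functions of their configuration and
seed:

* :func:`simulate_superfamily` — a toy two-domain superfamily descended
  from one ancestor: an NGN-like N-terminal segment plus a 50-residue CTD
  carrying the EMVRV anchor (ADFNG ten residues in, so both the 50- and
  40-residue cropping rules apply).  Fold-switching members are planted by
  writing an isolated-CTD prediction with a helix block over reference
  strand columns while the full-length-context prediction stays strand/
  coil; ground-truth labels are emitted alongside.
* :func:`simulate_structures` — ideal poly-Ala backbones (alpha-helix at
  phi=-57, psi=-47; antiparallel strand pair at phi=-139, psi=+135) with
  pseudo side chains (CB plus one outer atom), written as PDB text, with
  the true-contact list computed from the geometry.
* :func:`simulate_genome` — toy contigs with a NusG-like gene and operon
  markers at configured separations, with the expected context
  annotations emitted alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .comparator import REFERENCE_STATES, Predictor
from .contacts import Coupling, Structure, parse_structure, true_contact
from .genomics import (ContextAnnotation, GeneRecord, HOUSEKEEPING_CONSISTENT,
                       NOT_HOUSEKEEPING)
from .seqcore import AMINO_ACIDS, Sequence
from .sspred import SSPrediction

FOLD_SWITCHING = "fold_switching"
SINGLE_FOLDING = "single_folding"


# ---------------------------------------------------------------------------
# superfamily generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic superfamily.

    Defaults emulate the screen's setting at desk scale: a handful of
    >=78%-identity clusters descended from a common ancestor, half of the
    members planted as fold switchers, 50-residue CTDs cropped to 40 for
    prediction, and alignment support depths that clear the 5-sequence
    confidence gate.
    """

    seed: int
    n_clusters: int = 4
    cluster_size: int = 25
    fold_switch_fraction: float = 0.5
    ngn_length: int = 110
    ctd_length: int = 50
    founder_mutation_rate: float = 0.30       # NGN segment, between clusters
    ctd_founder_mutation_rate: float = 0.15   # CTD diverges less: it must stay
                                              # registrable against the reference
    member_mutation_rate: float = 0.02
    support_depth_range: tuple[int, int] = (5, 50)
    n_short_ctd: int = 0          # members with a CTD too short to crop

    def __post_init__(self):
        if not (0.0 <= self.fold_switch_fraction <= 1.0):
            raise ValueError("fold_switch_fraction must lie in [0, 1]")
        if not (0.0 <= self.member_mutation_rate <= 1.0
                and 0.0 <= self.founder_mutation_rate <= 1.0):
            raise ValueError("mutation rates must lie in [0, 1]")
        if self.ctd_length != 50:
            raise ValueError("the anchor layout requires a 50-residue CTD")


@dataclass
class GroundTruth:
    labels: dict[str, str]                      # id -> planted call
    fractions: dict[str, dict[str, float]]      # id -> db -> planted fraction


@dataclass
class SuperfamilyData:
    config: SimulationConfig
    sequences: list[Sequence]
    family_map: dict[str, str]
    reference: Sequence                         # ancestor full-length sequence
    reference_ctd: Sequence                     # its 40-residue CTD window
    predictions: dict[tuple[str, str], str]     # (seq or crop id, db) -> states
    support_depths: dict[str, int]
    ground_truth: GroundTruth

    def predictor(self) -> Predictor:
        """Predictor backed by the planted prediction strings."""
        def predict(seq: Sequence, database: str) -> SSPrediction:
            states = self.predictions[(seq.id, database)]
            parent = seq.id.split("|")[0]
            return SSPrediction(seq_id=seq.id, states=states,
                                source="planted",
                                support_depth=self.support_depths[parent])
        return predict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .seqcore import write_fasta
        write_fasta(self.sequences, outdir / "sequences.fasta")
        # full-length reference first, 40-residue reference CTD second,
        # the layout `foldswitch scan --reference-fasta` expects
        write_fasta([self.reference, self.reference_ctd],
                    outdir / "reference.fasta")
        with open(outdir / "family_map.tsv", "w") as fh:
            for sid, fam in self.family_map.items():
                fh.write(f"{sid}\t{fam}\n")
        pred_dir = outdir / "predictions"
        pred_dir.mkdir(exist_ok=True)
        for (sid, db), states in sorted(self.predictions.items()):
            parent = sid.split("|")[0]
            kind = "ctd" if "|" in sid else "full"
            with open(pred_dir / f"{parent}.{kind}.{db}.txt", "w") as fh:
                fh.write(f"#depth={self.support_depths[parent]}\n{states}\n")
        with open(outdir / "ground_truth.tsv", "w") as fh:
            fh.write("id\tlabel\n")
            for sid, lab in self.ground_truth.labels.items():
                fh.write(f"{sid}\t{lab}\n")


def _mutate(rng: np.random.Generator, residues: str, rate: float,
            protected: frozenset[int]) -> str:
    out = list(residues)
    for k in range(len(out)):
        if k in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[k]]
            out[k] = choices[rng.integers(len(choices))]
    return "".join(out)


def _plant_helix_block(reference_states: str, start: int = 3,
                       length: int = 10) -> str:
    states = list(reference_states)
    for k in range(start, start + length):
        states[k] = "H"
    return "".join(states)


def simulate_superfamily(config: SimulationConfig) -> SuperfamilyData:
    """Generate the toy superfamily with planted fold-switch labels.

    All founders descend from one ancestor (substitution-only mutation, the
    EMVRV/ADFNG anchor positions protected) so every CTD registers cleanly
    against the shared reference; members mutate gently from their founder
    so clusters stay above the 78% identity rail.  Planted fold switchers
    get an isolated-CTD prediction whose 10-residue helix block overlaps
    reference strand columns (discrepancy fraction far above the 5% rule);
    everyone's full-length-context CTD prediction equals the reference
    strand pattern.
    """
    rng = np.random.default_rng(config.seed)
    L = config.ngn_length + config.ctd_length
    ctd0 = config.ngn_length
    # anchors: EMVRV at CTD start, ADFNG ten residues in
    ancestor = list(rng.choice(list(AMINO_ACIDS), size=L))
    ancestor[ctd0:ctd0 + 5] = "EMVRV"
    ancestor[ctd0 + 10:ctd0 + 15] = "ADFNG"
    ancestor = "".join(ancestor)
    protected = frozenset(range(ctd0, ctd0 + 5)) | frozenset(
        range(ctd0 + 10, ctd0 + 15))
    reference = Sequence(id="NusG_ref", residues=ancestor)
    reference_ctd = Sequence(id="NusG_ref_ctd",
                             residues=ancestor[ctd0 + 10:ctd0 + 50])

    n_total = config.n_clusters * config.cluster_size
    n_switch = round(n_total * config.fold_switch_fraction)
    statuses = np.array([True] * n_switch + [False] * (n_total - n_switch))
    rng.shuffle(statuses)

    sequences: list[Sequence] = []
    family_map: dict[str, str] = {}
    predictions: dict[tuple[str, str], str] = {}
    depths: dict[str, int] = {}
    labels: dict[str, str] = {}
    fractions: dict[str, dict[str, float]] = {}
    lo, hi = config.support_depth_range
    member_idx = 0
    n_short_left = config.n_short_ctd
    for c in range(config.n_clusters):
        ngn = _mutate(rng, ancestor[:ctd0], config.founder_mutation_rate,
                      frozenset())
        ctd = _mutate(rng, ancestor[ctd0:], config.ctd_founder_mutation_rate,
                      frozenset(k - ctd0 for k in protected))
        founder = ngn + ctd
        for m in range(config.cluster_size):
            sid = f"c{c}m{m}"
            residues = _mutate(rng, founder, config.member_mutation_rate,
                               protected)
            if n_short_left > 0 and m == config.cluster_size - 1:
                # truncate inside the 40-residue window: uncroppable
                residues = residues[:ctd0 + 25]
                n_short_left -= 1
            seq = Sequence(id=sid, residues=residues)
            sequences.append(seq)
            family_map[sid] = "nusg"
            depths[sid] = int(rng.integers(lo, hi + 1))
            is_switcher = bool(statuses[member_idx])
            member_idx += 1
            labels[sid] = FOLD_SWITCHING if is_switcher else SINGLE_FOLDING
            fractions[sid] = {}
            # 40-residue crop window: ADFNG anchor, 10 residues into the CTD
            crop_start, crop_end = ctd0 + 10, ctd0 + 50
            crop_id = f"{sid}|{crop_start}:{crop_end}"
            for db, ref_states in REFERENCE_STATES.items():
                full_states = ["-"] * len(residues)
                end = min(crop_end, len(residues))
                full_states[crop_start:end] = ref_states[:end - crop_start]
                predictions[(sid, db)] = "".join(full_states)
                if is_switcher:
                    ctd_states = _plant_helix_block(ref_states)
                else:
                    ctd_states = ref_states
                predictions[(crop_id, db)] = ctd_states
                n_conflict = sum(1 for q, r in zip(ctd_states, ref_states)
                                 if {q, r} == {"H", "E"})
                fractions[sid][db] = n_conflict / len(ref_states)
    return SuperfamilyData(
        config=config, sequences=sequences, family_map=family_map,
        reference=reference, reference_ctd=reference_ctd,
        predictions=predictions, support_depths=depths,
        ground_truth=GroundTruth(labels=labels, fractions=fractions))


# ---------------------------------------------------------------------------
# ideal-geometry structure fixtures
# ---------------------------------------------------------------------------

# standard backbone geometry (lengths in Angstrom, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_OMEGA = 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural extension reference frame: position atom d from a-b-c."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(n_res: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for an ideal (phi, psi) conformation."""
    residues: list[dict[str, np.ndarray]] = []
    # seed the first residue explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
        c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: anti to the next residue's N
    for i, res in enumerate(residues):
        if i + 1 < len(residues):
            tor = math.degrees(_dihedral(res["N"], res["CA"], res["C"],
                                         residues[i + 1]["N"])) + 180.0
        else:
            tor = psi + 180.0
        res["O"] = _place(res["N"], res["CA"], res["C"],
                          _B_C_O, _A_CA_C_O, tor)
    return residues


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.atan2(y, x)


def _add_sidechain(res: dict[str, np.ndarray]) -> None:
    """Idealised CB from the backbone frame, plus one outer pseudo atom."""
    b = res["CA"] - res["N"]
    c = res["C"] - res["CA"]
    a = np.cross(b, c)
    res["CB"] = res["CA"] - 0.58273431 * a + 0.56802827 * b - 0.54067466 * c
    out = res["CB"] - res["CA"]
    res["CG"] = res["CB"] + 1.5 * out / np.linalg.norm(out)


def _pdb_text(residues: list[dict[str, np.ndarray]], chain: str = "A",
              res_name: str = "ALA", first_number: int = 1) -> str:
    # pseudo side chain: CB + CG outer atom (alanine has no CG in reality;
    # the fixture ships one as the documented pseudo atom)
    lines = []
    serial = 1
    for i, res in enumerate(residues):
        num = first_number + i
        for name in ("N", "CA", "C", "O", "CB", "CG"):
            if name not in res:
                continue
            x, y, z = res[name]
            element = name[0]
            name_field = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name_field} {res_name:<3s} "
                f"{chain}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass
class StructureFixtures:
    helix_pdb: str
    sheet_pdb: str
    helix_structure: Structure
    sheet_structure: Structure
    helix_contacts: list[tuple[int, int]]
    sheet_contacts: list[tuple[int, int]]


def _contact_ground_truth(structure: Structure, n_res: int,
                          cutoff: float = 5.0) -> list[tuple[int, int]]:
    """Residue pairs (|i-j| >= 2) whose minimum heavy-atom distance is
    within the cutoff with a side-chain atom involved."""
    pairs = []
    for i in range(1, n_res + 1):
        for j in range(i + 2, n_res + 1):
            call = true_contact(Coupling(i=i, j=j, probability=1.0),
                                [structure], cutoff=cutoff, exceptions=())
            if call.is_true_positive:
                pairs.append((i, j))
    return pairs


def simulate_structures(n_helix: int = 12, n_strand: int = 8,
                        strand_offset: float = 4.8) -> StructureFixtures:
    """Ideal alpha-helix and antiparallel strand-pair PDB fixtures.

    The helix uses phi=-57, psi=-47; the two strands use phi=-139,
    psi=+135, the second strand being the first rotated 180 degrees about
    the strand axis's normal and offset by the canonical ~4.8 A cross-
    strand spacing (hydrogen-bond registry is not modelled).  The returned
    contact lists are computed from the emitted coordinates with the
    5.0 A / side-chain rule.
    """
    helix = _build_backbone(n_helix, phi=-57.0, psi=-47.0)
    for res in helix:
        _add_sidechain(res)
    helix_pdb = _pdb_text(helix)

    strand_a = _build_backbone(n_strand, phi=-139.0, psi=135.0)
    for res in strand_a:
        _add_sidechain(res)
    # strand axis ~ x after building; rotate the partner 180 deg about x
    # (reverses chain direction: antiparallel) and offset in y
    axis_flip = np.diag([1.0, -1.0, -1.0])
    strand_b = []
    for res in strand_a:
        strand_b.append({name: axis_flip @ xyz + np.array([0.0, strand_offset, 0.0])
                         for name, xyz in res.items()})
    sheet_pdb = (_pdb_text(strand_a, chain="A")[:-len("END\n")]
                 + _pdb_text(strand_b, chain="A",
                             first_number=n_strand + 1))

    helix_structure = _structure_from_text(helix_pdb, "ideal_helix")
    sheet_structure = _structure_from_text(sheet_pdb, "ideal_sheet")
    return StructureFixtures(
        helix_pdb=helix_pdb, sheet_pdb=sheet_pdb,
        helix_structure=helix_structure, sheet_structure=sheet_structure,
        helix_contacts=_contact_ground_truth(helix_structure, n_helix),
        sheet_contacts=_contact_ground_truth(sheet_structure, 2 * n_strand))


def _structure_from_text(pdb_text: str, structure_id: str) -> Structure:
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(pdb_text)
        name = fh.name
    try:
        return parse_structure(name, structure_id=structure_id)
    finally:
        Path(name).unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# toy genome generator
# ---------------------------------------------------------------------------

@dataclass
class GenomeFixture:
    genes: list[GeneRecord]
    proteome: list[tuple[Sequence, GeneRecord]]
    queries: list[Sequence]
    expected: dict[str, ContextAnnotation]

    def gtf_text(self) -> str:
        lines = []
        for g in self.genes:
            attrs = (f'gene_name "{g.gene_name}"; protein_id "{g.protein_id}"; '
                     f'product "{g.product}";')
            lines.append("\t".join(map(str, (
                g.contig, "toy", "CDS", g.start, g.end, ".", g.strand, "0",
                attrs))))
        return "\n".join(lines) + "\n"


DEFAULT_MARKER_SEPARATIONS: Mapping[str, int | None] = {
    "near": 100,          # < 270 bp
    "mid": 300,           # 270-1000 bp
    "far": 2000,          # > 1 kb, within 10 kb
    "outside": 12000,     # beyond the 10 kb window
    "other_contig": None, # marker on a different contig
}


def simulate_genome(marker_separations: Mapping[str, int | None] = DEFAULT_MARKER_SEPARATIONS,
                    seed: int = 0, gene_length: int = 450,
                    protein_length: int = 150,
                    window: int = 10_000) -> GenomeFixture:
    """One contig per scenario: a NusG-like gene plus a SecE marker at the
    configured separation (None puts the marker on a separate contig).

    The expected annotation table is derived directly from the configured
    separations so downstream context classification can be checked
    against it.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    proteome: list[tuple[Sequence, GeneRecord]] = []
    queries: list[Sequence] = []
    expected: dict[str, ContextAnnotation] = {}
    for k, (label, sep) in enumerate(marker_separations.items()):
        contig = f"contig{k + 1}"
        locus = GeneRecord(contig=contig, start=1000,
                           end=1000 + gene_length - 1, strand="+",
                           gene_name=f"nusG_{label}",
                           protein_id=f"NUSG_{label.upper()}",
                           product="transcription termination factor NusG")
        protein = Sequence(
            id=locus.protein_id,
            residues="".join(rng.choice(list(AMINO_ACIDS), size=protein_length)))
        genes.append(locus)
        proteome.append((protein, locus))
        if sep is None:
            marker_contig, start = f"{contig}_other", 2000
        else:
            # nearest-edge gap of exactly `sep` bp (1-based inclusive intervals)
            marker_contig, start = contig, locus.end + sep + 1
        marker = GeneRecord(contig=marker_contig, start=start,
                            end=start + 200, strand="+", gene_name="secE",
                            protein_id=f"SECE_{label.upper()}",
                            product="preprotein translocase subunit SecE")
        genes.append(marker)
        query = Sequence(id=f"query_{label}", residues=protein.residues)
        queries.append(query)
        within = sep is not None and sep <= window
        expected[query.id] = ContextAnnotation(
            query_id=query.id,
            nearest_marker="secE" if sep is not None else None,
            separation_bp=sep,
            within_window=within,
            context_class=(HOUSEKEEPING_CONSISTENT if within
                           else NOT_HOUSEKEEPING))
    return GenomeFixture(genes=genes, proteome=proteome, queries=queries,
                         expected=expected)
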
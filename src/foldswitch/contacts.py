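"""Coevolutionary coupling evaluation against experimental structures.

Couplings (residue pairs with a probability) are judged true positives
when their heavy atoms come within 5.0 A in any provided structure with at
least one side-chain atom involved; the probability threshold is chosen by
maximising the true-positive/false-positive ratio; contacting pairs are
classified geometrically as hydrophobic, Coulombic or helix-capping; and
MSA column pairs are summarised by residue-class fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TSequence

import gemmi
import numpy as np

from . import topology
from .sspred import MSA

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5.0
DEFAULT_CAP_DISTANCE = 4.0
DEFAULT_EXCEPTIONS = frozenset({(140, 151)})


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos)

    @property
    def is_sidechain(self) -> bool:
        return self.name not in topology.BACKBONE_ATOMS


@dataclass
class Residue:
    chain: str
    number: int
    name: str                       # 3-letter code
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """Heavy-atom coordinates of one model, keyed by author residue number.

    ``offset`` aligns author PDB numbering to the coupling (reference
    sequence) numbering: author number = reference position + offset.
    """

    id: str
    residues: dict[tuple[str, int], Residue]
    offset: int = 0

    def get(self, ref_position: int) -> Residue | None:
        num = ref_position + self.offset
        for (chain, n), res in self.residues.items():
            if n == num:
                return res
        return None


def parse_structure(path: str | Path, structure_id: str | None = None,
                    offset: int = 0) -> Structure:
    """Parse a PDB file: first model, HETATM excluded, hydrogens excluded,
    highest-occupancy alternate location kept (ties resolve to the first)."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    residues: dict[tuple[str, int], Residue] = {}
    for chain in model:
        for res in chain:
            if res.het_flag == "H":
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                continue
            key = (chain.name, res.seqid.num)
            residues[key] = Residue(
                chain=chain.name, number=res.seqid.num, name=res.name,
                atoms=[Atom(name=a.name, element=a.element.name.upper(),
                            pos=(a.pos.x, a.pos.y, a.pos.z))
                       for a in best.values()])
    if not residues:
        raise ValueError(f"{path}: no ATOM records")
    return Structure(id=structure_id or Path(path).stem,
                     residues=residues, offset=offset)


@dataclass(frozen=True)
class Coupling:
    """A coevolutionary residue-pair coupling in reference numbering."""

    i: int
    j: int
    probability: float

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("coupling must join two distinct positions")
        if self.i > self.j:
            object.__setattr__(self, "i", self.j)
            object.__setattr__(self, "j", self.i)
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")


def read_couplings_tsv(path: str | Path) -> list[Coupling]:
    """Couplings TSV: columns i, j, probability (header optional)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            i, j, p = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError:
            continue        # header
        out.append(Coupling(i=i, j=j, probability=p))
    if not out:
        raise ValueError(f"{path}: no couplings parsed")
    return out


@dataclass
class ContactCall:
    coupling: Coupling
    is_true_positive: bool
    matched_structure: str | None
    min_heavy_distance: float | None
    sidechain_involved: bool
    exception_applied: bool = False


def _residue_pair_distances(ra: Residue, rb: Residue):
    """All heavy-atom distances between two residues."""
    for a in ra.atoms:
        for b in rb.atoms:
            yield a, b, float(np.linalg.norm(a.xyz - b.xyz))


def true_contact(coupling: Coupling, structures: TSequence[Structure],
                 cutoff: float = DEFAULT_CUTOFF,
                 exceptions: Iterable[tuple[int, int]] = DEFAULT_EXCEPTIONS
                 ) -> ContactCall:
    """True positive iff, in any structure, the minimum heavy-atom distance
    is <= cutoff with a side-chain atom in the pair; exception pairs (by
    default (140, 151), borderline in the NMR ensemble) are true regardless."""
    pair = (coupling.i, coupling.j)
    exception = pair in {tuple(sorted(e)) for e in exceptions}
    best_d, best_struct, best_sc = None, None, False
    tp_struct = None
    sidechain_ok = False
    for st in structures:
        ra, rb = st.get(coupling.i), st.get(coupling.j)
        if ra is None or rb is None:
            continue
        d_min, sc_within = math.inf, False
        for a, b, d in _residue_pair_distances(ra, rb):
            if d < d_min:
                d_min = d
            if d <= cutoff and (a.is_sidechain or b.is_sidechain):
                sc_within = True
        if best_d is None or d_min < best_d:
            best_d, best_struct = d_min, st.id
        if d_min <= cutoff and sc_within and tp_struct is None:
            tp_struct, sidechain_ok = st.id, True
    if best_d is None:
        logger.warning("coupling %s unresolved in all structures", pair)
        return ContactCall(coupling=coupling, is_true_positive=exception,
                           matched_structure=None, min_heavy_distance=None,
                           sidechain_involved=False,
                           exception_applied=exception)
    is_tp = tp_struct is not None or exception
    return ContactCall(coupling=coupling, is_true_positive=is_tp,
                       matched_structure=tp_struct or best_struct,
                       min_heavy_distance=best_d,
                       sidechain_involved=sidechain_ok,
                       exception_applied=exception and tp_struct is None)


def optimize_threshold(couplings: TSequence[Coupling],
                       truth: Mapping[Coupling, bool],
                       candidates: TSequence[float] | None = None) -> float:
    """Probability threshold maximising #TP(p>=t) / #FP(p>=t).

    A zero false-positive count gives an infinite ratio; among thresholds
    achieving the maximal ratio the lowest is returned (retains the most
    couplings).
    """
    if not any(truth[c] for c in couplings):
        raise ValueError("no true positives in the coupling set")
    if candidates is None:
        candidates = sorted({c.probability for c in couplings})
    best_t, best_ratio = None, -math.inf
    for t in sorted(candidates):
        tp = sum(1 for c in couplings if c.probability >= t and truth[c])
        fp = sum(1 for c in couplings if c.probability >= t and not truth[c])
        if tp == 0:
            continue
        ratio = math.inf if fp == 0 else tp / fp
        if ratio > best_ratio:
            best_ratio, best_t = ratio, t
    if best_t is None:
        raise ValueError("no threshold retains a true positive")
    return float(best_t)


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _antecedent_ok(res: Residue, atom: Atom, partner: Atom,
                   min_angle: float = 90.0) -> bool | None:
    """Angle test at a polar atom: (bonded carbon, polar atom, partner).

    None when the antecedent atom is missing from the model.
    """
    ante_name = topology.carbon_antecedent(res.name, atom.name)
    if ante_name is None:
        return None
    ante = res.atom(ante_name)
    if ante is None:
        return None
    return _angle_deg(ante.xyz, atom.xyz, partner.xyz) >= min_angle


def classify_pair_geometry(structure: Structure, i: int, j: int,
                           cutoff: float = DEFAULT_CUTOFF,
                           cap_distance: float = DEFAULT_CAP_DISTANCE,
                           mode: str = "all_pairs") -> set[str]:
    """Geometric categories of a residue pair: subset of
    {hydrophobic, coulombic, helix_cap}.

    ``mode`` 'all_pairs' examines every atom pair within the cutoff;
    'min_pair' only the minimum-distance pair (for the hydrophobic and
    Coulombic tests).  A category whose atoms are missing is skipped.
    """
    ra, rb = structure.get(i), structure.get(j)
    if ra is None or rb is None:
        raise ValueError(f"residues {i},{j} not resolved in {structure.id}")
    pairs = [(a, b, d) for a, b, d in _residue_pair_distances(ra, rb)
             if d <= cutoff]
    categories: set[str] = set()
    if pairs and mode == "min_pair":
        pairs = [min(pairs, key=lambda t: t[2])]
    for a, b, d in pairs:
        if topology.is_apolar(ra.name, a.name) and topology.is_apolar(rb.name, b.name):
            categories.add("hydrophobic")
        pos_neg = ((topology.is_positive(ra.name, a.name)
                    and topology.is_negative(rb.name, b.name))
                   or (topology.is_negative(ra.name, a.name)
                       and topology.is_positive(rb.name, b.name)))
        if pos_neg:
            ok_a = _antecedent_ok(ra, a, b)
            ok_b = _antecedent_ok(rb, b, a)
            if ok_a and ok_b:
                categories.add("coulombic")
    # helix cap: side-chain donor/acceptor of one residue near a backbone
    # N/O of the other, both angle tests >= 90 degrees
    for donor_res, acc_res in ((ra, rb), (rb, ra)):
        for a in donor_res.atoms:
            if not topology.is_sidechain_polar(donor_res.name, a.name):
                continue
            for bb_name in ("O", "N"):
                b = acc_res.atom(bb_name)
                if b is None:
                    continue
                d = float(np.linalg.norm(a.xyz - b.xyz))
                if d > cap_distance:
                    continue
                ok_a = _antecedent_ok(donor_res, a, b)
                ok_b = _antecedent_ok(acc_res, b, a)
                if ok_a and ok_b:
                    categories.add("helix_cap")
    return categories


def backbone_hbond_geometry(structure: Structure, i: int,
                            cap_distance: float = DEFAULT_CAP_DISTANCE,
                            min_angle: float = 90.0) -> bool:
    """i-4 -> i backbone hydrogen-bond geometry (helical capping pattern):
    backbone N(i) within ``cap_distance`` of backbone O(i-4) with the angle
    at the carbonyl oxygen (C-O...N) >= ``min_angle``."""
    ri, rm4 = structure.get(i), structure.get(i - 4)
    if ri is None or rm4 is None:
        return False
    n, o, c = ri.atom("N"), rm4.atom("O"), rm4.atom("C")
    if n is None or o is None or c is None:
        return False
    if float(np.linalg.norm(n.xyz - o.xyz)) > cap_distance:
        return False
    return _angle_deg(c.xyz, o.xyz, n.xyz) >= min_angle


@dataclass
class PairCategoryStats:
    coupling: Coupling
    n_rows: int
    fraction_both_hydrophobic: float
    fraction_one_charged: float
    fraction_cap_capable: float


def pair_category_stats(msa: MSA, couplings: TSequence[Coupling],
                        hydrophobic: set[str] = topology.HYDROPHOBIC_RESIDUES,
                        charged: set[str] = topology.CHARGED_RESIDUES,
                        cap_capable: set[str] = topology.CAP_CAPABLE_RESIDUES
                        ) -> list[PairCategoryStats]:
    """Residue-class fractions per coupling across MSA rows.

    Coupling positions are 1-based MSA column indices.  Per coupling, over
    rows with both columns ungapped: the fraction with both residues
    hydrophobic, with a charged residue in exactly one position, and with
    at least one side chain able to donate/accept a backbone hydrogen bond.
    """
    out = []
    for c in couplings:
        ci, cj = c.i - 1, c.j - 1
        if not (0 <= ci < msa.length and 0 <= cj < msa.length):
            raise ValueError(f"coupling {c.i},{c.j} outside MSA columns")
        both_h = one_c = capable = n = 0
        for _, row in msa.rows:
            a, b = row[ci], row[cj]
            if a == "-" or b == "-":
                continue
            n += 1
            if a in hydrophobic and b in hydrophobic:
                both_h += 1
            if (a in charged) != (b in charged):
                one_c += 1
            if a in cap_capable or b in cap_capable:
                capable += 1
        if n == 0:
            raise ValueError(f"coupling {c.i},{c.j}: no co-ungapped rows")
        out.append(PairCategoryStats(
            coupling=c, n_rows=n,
            fraction_both_hydrophobic=both_h / n,
            fraction_one_charged=one_c / n,
            fraction_cap_capable=capable / n))
    return out


def write_contact_calls_tsv(calls: Iterable[ContactCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tprobability\ttrue_positive\tstructure\t"
                 "min_heavy_distance\tsidechain\texception\n")
        for c in calls:
            d = ("-" if c.min_heavy_distance is None
                 else f"{c.min_heavy_distance:.2f}")
            fh.write("\t".join(map(str, (
                c.coupling.i, c.coupling.j, c.coupling.probability,
                int(c.is_true_positive), c.matched_structure or "-", d,
                int(c.sidechain_involved), int(c.exception_applied)))) + "\n")
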
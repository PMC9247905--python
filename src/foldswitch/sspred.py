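"""Secondary-structure prediction backends and profile transforms.

The neural-network predictor itself (JPred4's jnet) is consumed, never
reimplemented: this module provides (i) the logistic activation transforms
that convert HMM and PSSM profile scores into predictor input, (ii) MSA
depth as N_eff (effective number of non-redundant sequences at a 90%
identity cutoff), (iii) a file adapter for externally produced
three-state prediction strings, and (iv) a self-contained propensity-table
stand-in predictor so the whole pipeline runs offline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .seqcore import Sequence, pairwise_identity

logger = logging.getLogger(__name__)

SS_STATES = set("HE-")


@dataclass(frozen=True)
class SSPrediction:
    """Per-residue three-state prediction: H helix, E strand, '-' coil."""

    seq_id: str
    states: str
    source: str = "external_file"
    support_depth: int = 1

    def __post_init__(self):
        bad = set(self.states) - SS_STATES
        if bad:
            raise ValueError(f"invalid prediction states: {sorted(bad)}")
        if self.support_depth < 1:
            raise ValueError("support_depth must be >= 1")


@dataclass
class MSA:
    """A multiple sequence alignment as (id, aligned string) rows."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("MSA must have at least one row")
        L = len(self.rows[0][1])
        if any(len(r[1]) != L for r in self.rows):
            raise ValueError("MSA rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def depth(self) -> int:
        return len(self.rows)


def read_msa(path: str | Path) -> MSA:
    """Read an aligned FASTA into an MSA (gaps preserved, upper-cased)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return MSA(rows=[(r.id, str(r.seq).upper()) for r in records])


def transform_hmm(x: float) -> float:
    """Logistic activation for HMM profile scores: 1 / (1 + e^(-x/100))."""
    if not math.isfinite(x):
        raise ValueError("profile score must be finite")
    return 1.0 / (1.0 + math.exp(-x / 100.0))


def transform_pssm(x: float) -> float:
    """Logistic activation for PSSM scores: 1 / (1 + e^(-x))."""
    if not math.isfinite(x):
        raise ValueError("profile score must be finite")
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class ProfileMatrix:
    """An L x K profile with its transformed (0,1) representation."""

    kind: str                 # "hmm" or "pssm"
    raw: np.ndarray

    def __post_init__(self):
        if self.kind not in ("hmm", "pssm"):
            raise ValueError("profile kind must be 'hmm' or 'pssm'")
        self.raw = np.asarray(self.raw, dtype=float)
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("profile scores must be finite")

    @property
    def transformed(self) -> np.ndarray:
        scale = 100.0 if self.kind == "hmm" else 1.0
        return 1.0 / (1.0 + np.exp(-self.raw / scale))


@dataclass(frozen=True)
class NeffValue:
    value: float
    identity_cutoff: float = 0.9


def neff(msa: MSA, identity_cutoff: float = 0.9) -> NeffValue:
    """Effective number of non-redundant sequences.

    Each row is weighted by the inverse size of its identity neighbourhood
    (rows with pairwise identity >= cutoff, itself included); N_eff is the
    sum of weights.  Rows with no co-ungapped overlap are never neighbours.
    """
    n = msa.depth
    neighbours = np.ones(n, dtype=int)   # self
    for i in range(n):
        for j in range(i + 1, n):
            try:
                ident = pairwise_identity(msa.rows[i][1], msa.rows[j][1])
            except ValueError:
                continue
            if ident >= identity_cutoff:
                neighbours[i] += 1
                neighbours[j] += 1
    return NeffValue(value=float(np.sum(1.0 / neighbours)),
                     identity_cutoff=identity_cutoff)


def depth_difference(full_msa: MSA, ctd_msa: MSA,
                     identity_cutoff: float = 0.9) -> float:
    """N_eff(full-length MSA) - N_eff(CTD MSA); may be negative."""
    return (neff(full_msa, identity_cutoff).value
            - neff(ctd_msa, identity_cutoff).value)


def read_prediction(path: str | Path, seq: Sequence) -> SSPrediction:
    """Adapter for jnetpred-style prediction string files.

    The file holds one state string (H/E/-/C; C is mapped to coil) and an
    optional ``#depth=N`` comment giving the alignment depth behind the
    prediction.
    """
    depth = 1
    states = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line[1:].strip().lower().startswith("depth="):
                depth = int(line.split("=", 1)[1])
            continue
        if states is not None:
            raise ValueError(f"{path}: multiple prediction lines")
        states = line.replace("C", "-").replace(",", "")
    if states is None:
        raise ValueError(f"{path}: no prediction string found")
    if len(states) != len(seq):
        raise ValueError(
            f"{path}: prediction length {len(states)} does not match "
            f"sequence {seq.id} length {len(seq)}")
    return SSPrediction(seq_id=seq.id, states=states,
                        source="external_file", support_depth=depth)


# Chou-Fasman helix/strand conformational propensities.  The stand-in
# predictor exists so the pipeline runs with no external predictor; it is
# NOT a substitute for a profile-based predictor's accuracy.
HELIX_PROPENSITY = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
    "X": 1.00,
}
STRAND_PROPENSITY = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
    "X": 1.00,
}
COIL_BASELINE = 1.0


def predict_standin(seq: Sequence, window: int = 7) -> SSPrediction:
    """Deterministic propensity-table predictor.

    Helix and strand propensities are smoothed with a centred moving
    average of width ``window``; each position takes the state of the
    largest of (helix, strand, coil baseline), ties resolving to coil.
    Sequences shorter than the window are returned all-coil with a warning.
    """
    n = len(seq)
    if n < window:
        logger.warning("sequence %s shorter than window %d: all-coil",
                       seq.id, window)
        return SSPrediction(seq_id=seq.id, states="-" * n, source="standin")
    h = np.array([HELIX_PROPENSITY[r] for r in seq.residues])
    e = np.array([STRAND_PROPENSITY[r] for r in seq.residues])
    half = window // 2
    states = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        hm, em = float(np.mean(h[lo:hi])), float(np.mean(e[lo:hi]))
        best = max(hm, em, COIL_BASELINE)
        if hm == best and hm > em and hm > COIL_BASELINE:
            states.append("H")
        elif em == best and em > hm and em > COIL_BASELINE:
            states.append("E")
        else:
            states.append("-")
    return SSPrediction(seq_id=seq.id, states="".join(states), source="standin")
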
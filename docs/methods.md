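# Methods

## The fold-switch caller

The method rests on an empirical observation about metamorphic domains:
a secondary-structure predictor fed the full-length sequence of a
fold-switching NusG-family protein sees an alignment dominated by the
β-roll-forming superfamily and predicts strand for the C-terminal domain,
while the same predictor fed only the isolated CTD sees the shallower
subfamily alignment and predicts the alternative α-helical conformation.
Single-folding CTDs predict strand in both contexts. The caller therefore
compares the two predictions position by position.

Pipeline per sequence (`comparator.run_variant`):

1. **Crop the CTD** (`cropper`). The query is locally aligned to the
   family reference and the crop starts at the query position aligned to
   the reference anchor motif. Two rule sets exist: 50-residue crops
   anchored at KVIIT (annotated RfaHs, ≥40 residues accepted when the CTD
   runs short) or EMVRV (everything else, full 50 required), and
   40-residue crops anchored at FQAIF/ADFNG requiring the full window.
   The 40-residue rules are the default: the first ten residues of the
   50-mers are similar enough to housekeeping CTDs to pull the prediction
   alignments back toward the superfamily. If the anchor column is gapped
   in the query, the nearest following co-ungapped column is used, which
   keeps the crop inside the CTD rather than before it.
2. **Predict** both contexts. The predictor is pluggable: a file adapter
   consumes externally produced three-state strings (H/E/−, C mapped to
   coil, with an optional `#depth=N` sidecar giving the alignment depth
   behind the prediction); a deterministic propensity-table stand-in is
   built in so the pipeline runs with no external predictor. The
   full-length prediction contributes its CTD window; the crop is
   predicted in isolation.
3. **Reregister** each prediction against the *E. coli* NusG CTD
   reference prediction of the relevant profile database (two shipped
   40-state reference strings, one from the JPred database profile and
   one from UniRef90). Registration is by Smith–Waterman local alignment
   of the sequences with match +1, mismatch 0, affine gaps −1.0 open /
   −0.5 extend; only co-ungapped columns are kept.
4. **Count and classify.** Helix↔strand conflicts (H over E or E over H)
   are counted over the registered columns; the discrepancy fraction uses
   the co-ungapped column count as denominator (the only denominator
   computable from the registration; configurable). The call is
   fold-switching at fraction ≥ 0.05 — the boundary is inclusive — with a
   confidence gate requiring ≥ 5 sequences behind the prediction.
   Per-database calls are reported individually; the aggregate call is
   fold-switching if any database's confident result crosses the
   threshold, since the screen's purpose is flagging substantial helical
   propensity for follow-up.

Cohort summaries report the share of confidently-called housekeeping
sequences flagged as fold-switching (a false-positive proxy, one decimal),
the share of specialised paralogs called single-folding (nearest integer),
and crop coverage. Zero-denominator rates are `None`, never 0.

## Supporting stages

**Identity machinery** (`seqcore`). Aligned identity = identical
co-ungapped columns / co-ungapped columns; `X` never matches. Alignment is
Biopython's `PairwiseAligner` in local mode (a gap of length L costs
−1.0 − 0.5·(L−1)); scores are cross-checked in the tests against an
independently written Gotoh dynamic program, itself validated against full
alignment-path enumeration on very short strings. Sequence clustering is
complete-linkage agglomerative clustering on distance 1 − identity with
the cut placed so pairs at exactly the minimum identity (default 0.78)
merge; complete linkage is the one standard linkage that guarantees the
within-cluster identity floor, and the invariant is asserted after every
run. Identity summary statistics (mean/median) are taken over the strict
upper triangle of the matrix.

**Profile transforms and MSA depth** (`sspred`). HMM scores map through
1/(1+e^(−x/100)), PSSM scores through 1/(1+e^(−x)); both are strictly
monotone into (0,1) and satisfy `hmm(100x) = pssm(x)`. N_eff uses the
standard inverse-neighbourhood weighting: each row's weight is one over
the number of rows within the identity cutoff (default 0.9, self
included), N_eff is the weight sum. Rows with no co-ungapped overlap are
never neighbours. Note that "adding a duplicate row never raises N_eff"
holds only when the ≥-cutoff neighbourhood relation is transitive on the
alignment; with non-transitive neighbourhoods (A~B, B~C, A≁C) a duplicate
can raise the sum slightly, so the tests pin the transitive cases
(identical rows → 1.0, mutually dissimilar rows → N).

**Stand-in predictor.** Chou–Fasman helix/strand propensities smoothed by
a centred moving average (window 7, clipped at the ends), argmax against a
coil baseline of 1.0 with ties to coil. It is a pure function of the
sequence and exists for offline pipeline runs and smoke tests; it does not
emulate a profile-based predictor's accuracy and the planted-prediction
fixtures, not this predictor, back the comparator's tests.

**Sequence space** (`seqspace`). One node per identity cluster; edges join
node pairs whose mean cross-pair identity is ≥ 0.24; node colour reflects
the share of confident fold-switch calls with the ≥ 50% boundary
inclusive, and nodes without confident calls are a separate
"no_prediction" class. Layout is the networkx Fruchterman–Reingold spring
embedding (k = 0.3, 1000 iterations) with a mandatory seed, normalised to
the unit square for reproducible figures.

**Prediction clustering.** Dissimilarity of two equal-length prediction
strings is summed per position: identical states 0, coil-vs-structure
0.5, helix-vs-strand 10. Affinity propagation (scikit-learn) runs on the
negated dissimilarities with damping 0.99 and up to 10,000 iterations;
preference is the library default (median similarity). Two numerical
choices handle degenerate inputs: a seeded Gaussian jitter of 1e−6 cost
units breaks exact ties (identical prediction strings are common, and
exact ties stall message passing at heavy damping — the jitter is four
orders of magnitude below the smallest real cost step), and the
convergence window is 100 stable iterations because damping 0.99 moves
messages ~1% per step, so a short window declares premature convergence
on transient states. Non-convergence is flagged on the result, not
raised. The cluster containing a named seed sequence (the screen uses the
*E. coli* RfaH prediction) can be extracted for downstream coevolutionary
analysis.

**Contacts** (`contacts`). Structures are parsed with gemmi: first model,
HETATM and hydrogens dropped, highest-occupancy alternate location kept.
A coupling is a true positive when, in any provided structure, the
minimum heavy-atom distance is ≤ 5.0 Å with at least one side-chain atom
in a contacting pair; the pair (140, 151) is accepted by default as an
explicit exception (5.2 Å in the NMR ensemble, within coordinate error of
the cutoff). The probability threshold maximises the TP/FP ratio, with
FP = 0 treated as an infinite ratio and ties resolved toward the lowest
threshold (retains the most couplings); the optimiser is cross-checked
against an exhaustive scan. Geometric classification works from a shipped
heavy-atom topology table of the 20 standard residues: an atom is
hydrophobic when it is carbon or sulfur with no bonded N/O neighbour;
a pair is Coulombic when one atom is in the positive set (Lys NZ, Arg
NE/NH1/NH2, His ND1/NE2 — histidine is counted charged, configurable) and
the other in the negative set (Asp OD1/OD2, Glu OE1/OE2, OXT) with the
angle at each polar atom between its bonded carbon antecedent and the
partner ≥ 90°; a helix cap is a side-chain donor/acceptor within 4.0 Å of
a backbone N/O with both angle tests ≥ 90°. The 4.0 Å cap distance reads
an obvious degree-symbol typo in the source convention as Ångström — a
"4°" distance is dimensionally impossible. By default every atom pair
within the cutoff is examined (a minimum-distance-pair-only mode is
provided). MSA column-pair statistics report, per coupling and over rows
with both columns present, the fractions with both residues hydrophobic
{AVLIMFWCY}, with a charged residue {DEKRH} in exactly one position, and
with at least one side chain able to donate/accept a backbone hydrogen
bond {STNQDEHKRYW}.

**Genomic context** (`genomics`). A query maps to a proteome entry when
the best local-alignment identity — denominator the full query length, so
partial hits score low — is strictly above 0.90. The locus is
housekeeping-consistent when a SecE/RplK/RplA (or "ribosomal protein
L11" by product text) marker lies on the same contig within 10 kb,
distance being the nearest-edge gap between the 1-based inclusive gene
intervals (0 for overlapping or abutting genes, strand-agnostic).
Separation tallies count within-window loci whose gap exceeds given
thresholds (defaults 270 bp and 1 kb).

## The synthetic data

`simulate_superfamily` emulates the screen's inputs at desk scale. All
cluster founders descend from a single random ancestor whose CTD carries
EMVRV at its start and ADFNG ten residues in (both anchor windows are
mutation-protected); founders diverge by substitution at rate 0.30 in the
NGN segment and 0.15 in the CTD, members at 0.02 from their founder.
The two-rate scheme reflects that CTDs must remain registrable against
the shared reference — the homology the real screen relies on — while the
NGN region carries most inter-cluster divergence; purely random founders
would make reference registration meaningless. Defaults: 4 clusters × 25
members, 50% planted fold switchers (exact count, shuffled across
clusters), support depths uniform on [5, 50], seed mandatory. Planted
switchers get an isolated-CTD prediction equal to the database reference
string with a 10-residue helix block from position 3, overlapping 8
(JPred-database) or 7 (UniRef90) reference strand columns — conflict
fractions 0.200/0.175, far above the 5% rule — while everyone's
full-length-context CTD prediction equals the reference string itself.
Prediction strings are planted directly rather than generated by the
stand-in predictor so the comparator tests are predictor-independent.
What the generator does **not** emulate: insertions/deletions,
phylogenetic correlation beyond the two-level cluster structure, realistic
prediction noise near the 5% boundary, or families whose two databases
disagree. Passing the planted-recovery test therefore shows the cropping,
registration, counting and gating machinery is correct — not that the
screen's error rates transfer to real proteomes.

`simulate_structures` builds poly-alanine backbones with standard bond
lengths and angles by natural-extension-reference-frame chaining: an
α-helix at φ = −57°, ψ = −47° and an antiparallel strand pair at
φ = −139°, ψ = +135° (ω = 180° throughout), each residue carrying an
idealised CB plus one outer pseudo side-chain atom — sufficient for the
side-chain-involvement rule. The second strand is the first rotated 180°
about the strand axis and offset by the canonical 4.8 Å cross-strand
spacing; exact hydrogen-bond registry is not modelled. The emitted
contact ground truth is computed from the coordinates with the same
5.0 Å/side-chain rule the evaluator uses. On these fixtures the helix
shows the expected i→i−4 backbone hydrogen-bond geometry at every
interior residue (O(i−4)···N(i) ≈ 3.1 Å) and (i, i±3/4) contacts only;
the strand pair shows exclusively cross-strand contacts and no helix
caps.

`simulate_genome` lays out one contig per scenario with a NusG-like gene
and a SecE marker at configured nearest-edge separations spanning the
bands of interest (<270 bp, 270 bp–1 kb, 1–10 kb, >10 kb, different
contig), emitting the GTF-like table, a proteome whose entries the query
sequences match exactly, and the expected context annotations derived
directly from the configuration.

All three generators are deterministic functions of (configuration,
seed); regenerated outputs are byte-identical.

## Numerical choices and limitations

* Co-optimal local alignments are resolved by the alignment engine's
  deterministic traceback order; when no positive-scoring alignment
  exists an explicit empty alignment (score 0) is returned and dependent
  operations raise rather than guess a registration.
* Identity exactly at a clustering or calling boundary is inclusive
  (≥ 0.78 within clusters, ≥ 0.05 discrepancy, ≥ 0.5 node colouring,
  ≥ 24% edges); locus mapping is the one strict inequality (> 0.90).
* The logistic transforms saturate to exactly 1.0 in double precision
  beyond |x| ≈ 36 (PSSM scale); the open-interval property is
  mathematical, not representational.
* The screen's published error rates derive from counts over external
  predictor runs on the full superfamily; this package reproduces that
  arithmetic and the method, not the 15,516-sequence prediction sweep,
  which requires the external profile databases and predictor.
* Problem sizes in the test suite and acceptance script (100-sequence
  cohorts, 12-residue helices, 8-residue strands, ≤50-coupling threshold
  instances) were chosen as the smallest sizes at which every rule the
  method depends on is exercised.
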
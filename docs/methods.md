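# Methods

## Classification model

Classification is a deterministic decision table over the residues a
query presents at five positions of the pea cytosolic APx1 reference
frame (38, 41, 42, 163, 172), read through a pairwise global alignment:

* **APX** ⇔ exactly (R, W, H, H, R);
* **APX-R** ⇔ R38, F41, H42, H163 all present and 172 ≠ R;
* **APX-L** ⇔ 38 ≠ R, 41 ∉ {W, F}, 42 ≠ H, 163 ≠ H, 172 ≠ R;
* **hybrid** ⇔ any other arrangement;
* **ambiguous** ⇔ an X at any classification position, or reference
  coverage below 0.5.

Three interpretation rules close the gaps the verbal definitions leave
open, and are enforced consistently everywhere:

1. A **deleted** position (aligned to a gap) counts as "another
   residue" — APX-L proteins genuinely lack the sites, and loss of
   His163/Arg172 traces to two short deletions rather than point
   substitutions.  Exception: a deleted *catalytic* position
   (38/41/42/163) disqualifies APX-R, since an active peroxidase cannot
   lack its catalytic residues; such tuples fall to hybrid or APX-L.
2. **Phe41 is family evidence, not decay**: a protein with F at 41 and
   everything else lost is a hybrid, not APX-L, because Trp→Phe at 41
   is the hallmark of APX-R and of class II/III peroxidases.
3. **X never guesses**: ambiguity at any classification position makes
   the whole call ambiguous, and ambiguous calls are excluded from
   prevalence denominators.

These rules make the three family predicates pairwise exclusive (the
41-column alone separates them: W vs F vs neither) and jointly
exhaustive with hybrid; the test suite verifies the partition by
exhaustive sweep of 9⁵ signature tuples against independently coded
predicates.

Hybrid subtypes: `proto-APX-R` ⇔ (R, F, H, H, R) — one mutation away
from APX; `proto-APX-L` ⇔ R38, F41, H163 with 42 ≠ H and 172 ≠ R.  All
other hybrids carry subtype `none`.  Lys30/Cys32 are annotation only.

## Reference and position mapping

All numbering is 1-based on a 250-residue reference modeled on pea
cytosolic APx1.  The bundled sequence is synthetic: it reproduces the
anchors every computation relies on (K30, C32, R38, W41, H42, H163,
R172, and the conserved SGGH proximal-helix context) and provides
realistic background elsewhere; the scheme validates the seven anchors
at load, so a wrong reference file fails fast.  Users may substitute
their own single-entry reference FASTA with the same anchors.

Queries are aligned with the Gotoh affine-gap global algorithm
(biopython's `PairwiseAligner`) under BLOSUM62 with gap open 10 and gap
extend 0.5 — field-standard defaults, exposed in the API and CLI.  A
gap of length k costs `open + (k−1)·extend`.  The first traceback of
the dynamic-programming optimum is taken, which is deterministic; the
score itself is oracle-checked against full alignment enumeration on
short pairs.  Mapping reads, for each reference position, the query
letter in that alignment column.  An externally aligned two-row FASTA
can be supplied instead of the built-in aligner.

Coverage guard: profiles covering less than half the reference are
flagged and classified ambiguous, so database fragments cannot
masquerade as signature-less APX-L through spurious ABSENT calls.

## Curation

Redundancy is resolved within species: a sequence identical to, or an
exact substring of, a longer same-species sequence is dropped; among
equal-length duplicates the lexicographically smallest id survives
(determinism).  The fragment filter discards sequences strictly shorter
than `min_length_fraction` (default 0.5) of the reference length —
"shorter than 50%" read literally, so an exactly-half-length sequence
is kept.  Both rules are conservative, order-preserving and idempotent;
the dedup invariants are tested against a brute-force all-pairs
containment oracle.

## Synthetic-family generator

The generator builds sequences from the reference in four steps, each
recorded in an edit script whose replay on the reference must reproduce
the sequence byte-for-byte (a tested invariant):

1. **Signature planting** — the canonical tuple of the requested
   category: APX (unchanged), APX-R (W41F, R172K), APX-L (R38A, W41L,
   H42N plus proximal deletions), proto-APX-R (W41F), proto-APX-L
   (W41F, H42N, R172G).
2. **Background substitutions** — per site with probability
   `background_substitution_rate` (default 0.2), proposing uniformly
   over the 20 residues; realized changes are therefore uniform over
   the other 19 and occur at 19/20 of the nominal rate.  Windows of
   halfwidth 3 around each signature position are protected unless
   protection is switched off for degradation experiments.
3. **One coordinate-shifting indel** — with probability `indel_rate`
   (default 0.5), an insertion or deletion of length 1–5 at least 10
   residues from every signature position, so classification must
   survive the coordinate shift.
4. **Proximal deletions** (APX-L) — two disjoint windows of 3–8
   residues covering positions 163 and 172 respectively.

The true label is derived from the residues actually planted at the
five positions, so truth and sequence cannot disagree even when
protection is off and a planted signature mutates.

Two constraints exist purely to keep the planted truth *identifiable*
under alignment-based mapping, and were adopted as generator design
(not tuned against any test): the reference carries a second histidine
two helix turns downstream of the proximal one, and affine gap scoring
will merge two nearby deletions into one long gap whenever that saves a
gap-opening penalty — sliding a stranded His onto the vacated proximal
column at no cost.  The deletion operator therefore rejects placements
that leave a His between its two windows, and background protection
covers the whole stretch the operator can reach plus flanks (reference
153–182 at the default halfwidth), because a mutated His/Arg on the
flank of the deleted region slides into the vacated signature column
equally freely.  Without these constraints roughly 1% of APX-L
sequences are genuinely unclassifiable as planted — not a defect of
the classifier but an ambiguity of the simulated molecule itself.

An optional `family_divergence_rate` (default 0) adds founder
substitutions shared by all members of a family, emulating the fact
that real families differ across the whole sequence and not only at
signature sites.  The tree-concordance studies use 0.15 with
per-sequence background 0.02; without founder divergence a distance
tree cannot separate families whose templates differ at two residues
out of 250.

What the generator does **not** emulate: site-rate heterogeneity,
empirical substitution matrices, indel length distributions from real
alignments, compositional drift between lineages, or phylogenetic
autocorrelation within families (members are i.i.d. around the
template).  Passing recovery tests therefore demonstrates correctness
of the mapping/classification machinery under coordinate shifts and
heavy background noise — not performance on real, deeply diverged
proteins, where multiple-alignment quality is the binding constraint.

## Degradation law

With protection off, each classification position of a planted APX
changes independently with probability p = r·19/20 at nominal rate r;
any change leaves the exact APX tuple, so the expected hybrid fraction
is 1 − (1 − p)⁵.  This ignores the small probability (~10⁻³ at r = 0.2)
that changes land exactly on the APX-R pattern — classified APX-R, not
hybrid — which is well inside the 95% binomial confidence band at
n = 500 used by the tests.

## Trees

The concordance surrogate uses p-distances (fraction of mismatched
gap-free aligned columns; pairs with no shared columns get 1.0) and
scikit-bio's neighbor joining with negative branch lengths clamped to
zero.  p-distance is sufficient because only rank-order structure is
needed for the clade test.  Monophyly is assessed on the unrooted tree:
a label forms a clade iff some edge splits exactly its leaves from the
rest, so the result is invariant to rooting (tested).  NJ correctness
is oracle-checked: exhaustive least-squares fitting over all fifteen
unrooted 5-leaf topologies, and closed-form 3-taxon branch lengths.

## Numerical and degenerate-input choices

* Percentages are reported to one decimal; groups whose calls are all
  ambiguous render NA rather than 0.
* Equal-length duplicate ties break on seq_id; NJ ties follow the
  library's deterministic first-minimum rule.
* Empty FASTA curates to an empty output with a zero-count report;
  per-record classification failures degrade to ambiguous rows and
  never abort a batch; only file-level problems exit non-zero.
* All stochastic components run off a single integer seed;
  identical inputs plus seed give byte-identical outputs.

## Problem sizes

The test battery and the acceptance script run the partition sweep at
9⁵ tuples, the alignment oracle on 200 pairs of length ≤ 8, mapping
stability on 500 indels, recovery on 400 planted sequences, the
degradation curve at 500 sequences per rate, NJ recovery on 50
matrices, and monophyly on 40 replicates of 12 sequences — sizes at
which every oracle remains exact and the whole battery completes in
well under a minute on one CPU.

## Known limitations

* Single-reference pairwise mapping stands in for a multiple alignment;
  for deeply diverged queries an external MSA (importable per pair) may
  place gaps better.
* The 50% fragment threshold is measured against the single bundled
  reference, not per-query homologs.
* Non-class-I peroxidases (catalase-peroxidases, cytochrome-c
  peroxidases) are outside the classification's scope; they surface as
  low-coverage ambiguous or hybrid calls rather than being named.
* Prevalence percentages exclude ambiguous calls from denominators, so
  groups dominated by fragments report over few classifiable sequences.
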
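# Methods

## Scope and model

`nmhistone` asks a purely sequence-level question: which catalogued
histone PTM sites, and which Rpb1 CTD heptad repeats, are still present
in a set of divergent proteomes?  The underlying assumption is
asymmetric: conservation of a residue does not prove its modification is
conserved (the local context may be constrained for other reasons), but
*absence* of the residue does prove the modification is lost.  The
pipeline therefore reports binary presence/absence evidence and never
infers modification status.

## The PTM-site catalog

The packaged catalog (`data/ptm_catalog.tsv`) lists 29 functionally
characterised sites — H3: R2, T3, K4, T6, K9, S10, K14, K18, K23, K27,
S28, K36, K56, K64, K79; H4: S1, R3, K5, K8, K12, K16, K20, K31, K91;
H2B: K5, K12, K15, K20, K120 — each assigned to one of five functional
categories (heterochromatin, mitotic phosphorylation, transcription
elongation, promoter definition, activation/repression).  Positions use
mature-protein numbering (initiator methionine stripped, 1-based), the
standard histone-nomenclature convention under which H3K4 is the fourth
residue of ARTK….  Every row is validated on load: the mark label must
parse back to (family, residue, position), and the residue must match
the packaged reference at that position.  Marks referred to in the
literature only as "and others" are deliberately not included; users can
extend the TSV.

## Reference panel

Scoring is anchored on the human references: mature H3.3 (135 aa), H4
(102 aa), H2B (125 aa, the numbering convention under which the FACT-
associated ubiquitination site is K120) and H2A (classification only).
The panel's Rpb1 entry is **synthetic** — a deterministically generated
1,500-residue body followed by 52 consensus YSPTSPS heptads — because
the pipeline only needs it as an alignment anchor for Rpb1
identification and CTD scanning, not as a biological reference; the
FASTA header and filename (`rpb1_synthetic.fasta`) say so explicitly.

## Alignment

Pairwise affine-gap alignment under BLOSUM62 with gap cost
`gap_open + L·gap_extend` for a gap of length L (defaults −10, −1 —
standard protein-alignment practice).  Global mode is true
Needleman–Wunsch with penalised end gaps: a tail truncation is treated
as a deletion, which is exactly how the biology reads it.  Traceback
ties are broken in the fixed order diagonal > up-gap > left-gap, making
every output bit-stable across runs.  The DP fill is a numba kernel
(three-state Gotoh with explicit pointer matrices); an Rpb1-sized
problem (~2,000 × 2,000) fills in well under a second.  Correctness is
established two independent ways in the tests: exhaustive enumeration
of every alignment on short pairs, and score agreement with
`Bio.Align.PairwiseAligner` (note its different gap convention: its
open score is charged on the first gap residue, so open = −11,
extend = −1 reproduces our −10 − L).

Family identification is best-hit **local** alignment against the
panel: a call requires identity ≥ τ = 0.35 over aligned (non-gap)
columns and ≥ 50 aligned columns (≥ 300 for Rpb1, whose great length
makes short spurious local hits otherwise common).  τ = 0.35 sits above
the ~25% twilight zone for unrelated proteins while accepting the
strongly diverged nucleomorph histones.  Identification is pairwise by
design — self-contained and dependency-free; profile-HMM scanning would
be an external adapter, not part of the tested surface.

## Coordinate mapping, indels, tails

The reference→query position map is induced by the global alignment:
reference position *p* maps to the query position in its column, or to
"absent" when the reference residue aligns to a gap.  Mapped positions
are strictly increasing (validated).  Maximal gap runs become indel
blocks: deletions carry the closed reference interval they remove,
insertions the reference position after which they occur (0 = before
position 1).  Blocks are tagged by region using per-family N-tail
bounds — H3 1–38, H4 1–24, H2B 1–34, C-tail = last 5 residues
(configurable; the H3 bound brackets the tail region that is missing in
the chlorarachniophyte proteins).  A block straddling a boundary is
tagged by majority overlap, ties to the more N-terminal region.

## The radius conservation score

For site position *p* and radius *r* ∈ {0, 1, 2}, the window is
[*p*−*r*, *p*+*r*] clipped to the reference (H4S1 at r ≥ 1 keeps only
its C-terminal flank; clipping is flagged per record).  Score 1 requires
all three of: every window position mapped (no deletion touching the
window), mapped positions contiguous (an insertion inside the window
breaks context even when the flanking residues match — "context
conservation" means an intact neighbourhood), and strict residue
identity at every window position.  Conservative substitutions score 0:
the score is deliberately all-or-nothing.  This makes the score
monotone by construction — widening the window can only lose
conservation — which the tests verify over thousands of randomized
queries.  The assembled matrix contains exactly
|species| × 29 sites × 3 radii records; families with no called query
in a species yield `no_homolog` records (this is how the absence of a
nucleomorph-encoded H2B in chlorarachniophyte-like species appears).

One genuine design ambiguity: published figure legends for this kind of
radius score sometimes label the windows inconsistently.  This package
fixes r = number of flanking residues per side (r=0 → 1-aa, r=1 → 3-aa,
r=2 → 5-aa window) and writes the convention into the output metadata.

## CTD heptad scan

Every length-7 window within Hamming distance *m* of the consensus
(default YSPTSPS) is a hit; hits may overlap.  Tandem arrays are chained
greedily left-to-right from hits at exact 7-residue phase spacing, and
windows already covered by a recorded array cannot seed or join another,
keeping arrays disjoint.  `total_in_arrays` (sum of array lengths, with
`min_run` = minimum chained heptads) is the repeat count.  Defaults
m=1, min_run=2 operationalise "repeats are not always perfect matches";
audits always report m=0 alongside.  "Lacks a CTD" is reported as
total_in_arrays = 0 at those defaults — reported, never hard-coded.
Per-hit composition (S/T/Y count, proline count) quantifies the five
phosphosites and two proline-isomerisation sites of the intact
consensus.

## Synthetic data and what passing tests mean

The generator derives queries from the packaged references by planting
substitutions (never no-ops), insertions/deletions (including tail
truncations, encoded as a deletion from position 1), and background
substitution at per-residue rate θ, all driven by one integer seed
(byte-identical reruns).  Ground truth — expected conservation score
per site and radius, expected indel blocks with region tags — is
computed from the event list, never by re-alignment, so it is an
independent oracle for the pipeline.

To keep that oracle exact, background substitutions are excluded from
the radius-2 neighbourhood of every catalogued site and from a
2-residue margin around planted indel boundaries: a substitution at an
indel junction can create score-tied alternative gap placements, after
which no aligner could be expected to return the planted interval.  For
the same reason exact recovery is only guaranteed when planted events
are ≥ 5 reference positions apart (a planted substitution directly
adjacent to a planted deletion can shift the optimal gap by one column).
An unrestricted mode drops the exclusions for stress testing; its
conservation truth remains exact with respect to substitutions, but
indel recovery is then best-effort.

The default six-species study design (two H3/H4-only species — one with
the H3 tail deletion 10–38, one with a 10-residue core insertion after
position 80 — plus four species that also carry H2B, with substitutions
at and around representative PTM sites, θ = 0.05) mirrors the
two-lineage structure of nucleomorph genomes at a realistic divergence.
What passing recovery tests show: the pipeline's bookkeeping
(classification, coordinate mapping, window logic, absence handling) is
exact under separated events.  What they do not show: behaviour on real
proteomes with compound overlapping events, compositional bias, or
paralogy — the generator draws residues uniformly and plants events
independently, with no phylogeny or rate heterogeneity.

## Numerical and procedural choices

* All scores are sums of integer-valued BLOSUM62 entries and integer
  gap costs stored as floats, so score comparisons are exact; no
  tolerances are needed anywhere.
* Duplicate family calls within one species: the audit keeps the
  highest-scoring query and lists the rest as secondary candidates
  (one nucleomorph copy per family is the expected case; paralogs are
  surfaced, not silently dropped).
* Degenerate inputs: empty global alignment partners score as a single
  gap run; sequences shorter than 7 give an empty CTD scan; a query
  with no positive-scoring local alignment to any panel member is
  called `none`.
* Problem sizes in the automated checks — the exhaustive alignment
  oracle on all pairs of length ≤ 3 over a 4-letter alphabet plus tens
  of thousands of sampled longer pairs, 1,000 randomized queries for
  monotonicity, 1,000 random sequences for the motif-count oracle —
  were chosen as the smallest sizes at which each property is exercised
  across its full case structure.

## Known limitations

* Identification is best-hit pairwise, not profile-based; extremely
  diverged histones near τ may be missed where an HMM would succeed.
* The conservation score is strict identity; it cannot distinguish
  "context diverged but biochemically similar" from "context lost".
* H2A is in the panel for classification but carries no catalogued
  sites; linker histones are out of scope.
* GenBank ingestion trusts the annotation: unannotated ORFs are not
  discovered, and partial CDS are skipped with a warning.
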
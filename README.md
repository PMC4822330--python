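# nmhistone

Histone PTM-site conservation scoring and RNA polymerase II CTD heptad
analysis for highly reduced genomes.

## The problem

Nucleomorphs — the relict nuclei that chlorarachniophyte and cryptophyte
algae retain from their eukaryotic endosymbionts — carry tiny, extremely
compact three-chromosome genomes, yet still package their DNA in
nucleosomes.  Whether the **histone code** (the system of
post-translational modifications, PTMs, on histone residues that
regulates heterochromatin, mitosis, transcription initiation and
elongation) survives in such a reduced system is a sequence question:
a modification cannot be deposited on a residue that no longer exists,
so the loss of a catalogued PTM site, or of its local sequence context,
is direct evidence that the corresponding piece of the code is gone.
The same logic applies to the C-terminal domain (CTD) of Rpb1, the
largest RNA Pol II subunit, ancestrally built of tandem **YSPTSPS**
heptads whose phosphorylation cycle coordinates transcription with
mRNA processing.

`nmhistone` turns this analysis into a tested, reusable pipeline for
anyone studying histone or CTD evolution in divergent or reduced
genomes.

## What it computes

Given annotated proteomes (FASTA, or GenBank flat files from which CDS
translations are extracted), the pipeline:

1. **identifies** histone-family and Rpb1 homologs by best-hit local
   alignment (BLOSUM62, affine gaps; gap of length *L* costs
   `gap_open + L·gap_extend`, defaults −10/−1) against a packaged human
   reference panel (H2A, H2B, H3.3, H4, and an Rpb1-like reference),
   accepting a call when identity ≥ τ (default 0.35) over enough aligned
   columns;
2. **maps** each query onto its scoring reference (mature numbering,
   initiator Met stripped — the convention behind names like H3K4) via
   deterministic global alignment, and segments maximal
   insertion/deletion blocks tagged N-tail / core / C-tail;
3. **scores** each of the 29 catalogued PTM sites (15 on H3, 9 on H4,
   5 on H2B) with a binary radius score: at radius *r* ∈ {0, 1, 2} the
   score is 1 iff the window of `2r+1` reference residues centred on the
   site is fully aligned, uninterrupted by indels, and residue-identical
   in the query — i.e. *r* = 0 asks "is the residue there?", *r* = 1 and
   *r* = 2 ask whether the 3- and 5-residue sequence context is intact;
4. **scans** Rpb1 candidates for YSPTSPS heptads with a per-window
   mismatch budget *m*, chaining hits at exact 7-residue phase spacing
   into tandem arrays (the array content is the operational repeat
   count; five S/T/Y phosphosites and two prolines per consensus heptad
   are reported per hit).

A synthetic-data module generates histone- and CTD-like queries from the
packaged references with *planted* substitutions, indels, tail
truncations and background substitution at rate θ, together with the
exact expected conservation scores and indel blocks — so every stage is
verifiable offline, end to end.

## Worked example

```python
import nmhistone as nm
from nmhistone.synthetic_data import MutationSpec, IndelEvent, mutate_reference

panel, catalog = nm.load_panel(), nm.load_catalog()

# a nucleomorph-like H3: tail residues 10-38 deleted, K4 replaced by glycine
spec = MutationSpec(substitutions=((4, "G"),),
                    indels=(IndelEvent(10, "deletion", 29),))
query, truth = mutate_reference("H3", spec, panel, catalog)

call = nm.classify_family(query, panel)
print(call.family, round(call.identity, 3))

aln = nm.align_pair(panel["H3"], query)
for blk in nm.segment_indels(aln, family="H3"):
    print(blk.kind, blk.ref_start, blk.ref_end, blk.length, blk.region)

pmap = nm.map_positions(aln)
site = catalog.lookup("H3", 4)
print([nm.score_site(site, panel["H3"], query, pmap, r) for r in (0, 1, 2)])
```

prints

```
H3 0.952
deletion_in_query 10 38 29 n_tail
[0, 0, 0]
```

— the query is still confidently H3 (95% identical over aligned
columns), the planted tail deletion is recovered with its exact
interval, and H3K4 scores 0 at every radius because the lysine itself
was replaced.  The CTD side:

```python
from nmhistone.ctd_scan import ScanParams
rec = nm.make_ctd(k=5, sub_rate=0.0, seed=1)
res = nm.scan_heptads(rec, params=ScanParams(m=0, min_run=1))
print(nm.heptad_stats("YSPTSPS"), res.total_in_arrays)
```

prints `(5, 2) 5`: the consensus heptad's five phosphosites and two
prolines, and exact recovery of the five planted repeats.

The command line mirrors the library: `nmhistone audit sp1=a.fasta
sp2=b.fasta` runs every stage and writes deterministic TSV/JSON reports
(family calls, indels, the species × site × radius conservation matrix,
CTD summaries, run metadata); `nmhistone identify|conserve|indels|ctd|
simulate|catalog dump` expose single stages.

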
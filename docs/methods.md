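# Methods

This note documents the models, algorithms and parameter choices behind
`evescan`, in the order the pipeline runs them.

## Frameshift-aware translated search

The scanner aligns genomic DNA directly against reference proteins with a
three-frame local dynamic program. State `H[i, j]` is the best local score
with `i` nucleotides and `j` query residues consumed. A codon match advances
3 nt and scores BLOSUM62(translated codon, residue); a frame change advances
2 or 4 nt, scores the codon ending at the same position, and pays a fixed
penalty (default 15 score units per event, the spirit of DIAMOND's
`-F 15`); affine gaps cost `open + k·extend` (11/1 for proteins). With no
frame-change transitions on the optimal path the recurrence collapses
exactly to plain translated Smith–Waterman on one frame, which is how the
test suite checks it against an independent aligner (Biopython
`PairwiseAligner` on each of the six frames).

Search strategy: contigs up to 12 kb are aligned exhaustively against every
query; longer contigs go through an exact amino-acid 6-mer seeding stage —
each seed projects a candidate window covering the whole query plus ~900 nt
slack, overlapping windows are merged, and the same exact dynamic program
runs on each window, with iterative masking so multiple gene copies in one
window are all reported. The exhaustive and seeded paths produce identical
results whenever the optimal alignment contains at least one exact 6-mer
seed; at the ≤5% divergence the simulator emulates, seeds are abundant
(per-position 6-mer survival ≈ 0.8 at 4% amino-acid divergence). Truly
remote homology on megabase contigs is the one regime where seeding can
lose sensitivity relative to the exhaustive mode; the iterative profile
search below, which operates on protein databases, is the intended tool for
remote homologs.

E-values use Karlin–Altschul statistics, `E = K·m·n·exp(−λS)`, with the
standard gapped BLOSUM62(11/1) constants λ = 0.267, K = 0.041 and database
size n = total translated residues (2 × assembly length). They are
internally consistent (monotone in score, linear in search space) but not
bit-compatible with any external tool; the default cutoff 1e-12 and the
23%-identity / 100-aa filters are configuration, not constants.

Range culling keeps one hit per genomic region: hits are taken best score
first (ties: higher identity, then query id) and a hit is dropped when it
overlaps a kept hit by more than half the shorter interval. For mutually
overlapping groups this equals "best hit per group".

## Iterative profile search

Profiles are position-specific half-bit log-odds scores against the
Robinson–Robinson background. Pseudocounts enter as a fixed background
admixture on column frequencies (weight α/(1+α), default α = 1), so
duplicated alignment rows leave the profile unchanged; columns with > 50%
gaps are dropped. The iterative search scores the database with the current
profile, folds sequences at E ≤ 1e-7 back onto the profile columns
(insertions relative to the profile are discarded — a deliberate
simplification versus full profile HMMs), and repeats up to five rounds or
until no new sequence is included. This reproduces the stepping-stone
behaviour that matters operationally: a homolog invisible to the seed
becomes reachable once an intermediate relative joins the profile.

## TIR detection

A terminal-inverted-repeat pair is found by locally aligning the sequence
against its own reverse complement (+2/−3 match/mismatch, 5/2 affine gaps)
and keeping ordered, non-overlapping pairs — which also excludes the
trivial self-palindromic diagonal. End windows up to ~5.5 kb are aligned
exhaustively with iterative masking; whole-locus searches
(`end_window=None`) seed with exact 12-mers between the sequence and its
reverse complement, cluster seeds by diagonal and run the same alignment on
±500 nt candidate windows.

A reported pair must satisfy three conditions: repeat length ≥ 20 bp,
identity ≥ 85% over aligned columns, and alignment score significant at
E ≤ 0.01 under ungapped Karlin–Altschul statistics for the +2/−3 scoring
(λ = 0.63, K = 0.1, search space = the aligned window pair). The
significance floor matters: a 5 kb end-window pair contains ≈ 0.4 expected
chance local optima that pass the literal length/identity rule alone, and
it is the analogue of the minimum-alignment-score setting in the
self-mapping approach this emulates. All planted-TIR regimes the package
guarantees (30/100/500 bp at ≤ 5% divergence) score far above the floor:
a 30 bp repeat with two mismatches scores 50 versus a floor of ≈ 31–39.

## Locus annotation and boundary estimation

Each capsid hit is extended by up to 30 kbp on both sides (truncation at
contig ends is flagged). Hallmark annotation is the same translated search
against the hallmark protein set at E ≤ 1e-4 with ≥ 70% query coverage and
greedy best-hit-per-region semantics. GC deviation is computed in
500 bp windows stepped by 100 bp, N bases excluded from denominators,
relative to the assembly-wide mean — note that in EVE-dense assemblies the
genomic mean itself is pulled toward the element composition, so the
observed per-window delta is element GC minus the blended mean, not the raw
host-versus-element offset.

Boundary estimation prefers structure over composition: if a TIR pair
flanks the capsid gene, the boundaries are the outer TIR coordinates
(method "TIR"); otherwise the longest same-sign run of GC-deviation windows
with |δ| ≥ 0.05 spanning ≥ 5 kbp and containing the capsid gene is used
(method "GC"); runs may bridge at most one window length of sub-threshold
windows, since sampling noise at 500 bp dips below threshold ≈ 1% of the
time even inside a genuinely shifted segment. The 0.05/5 kbp knobs are
free choices exposed in configuration. Boundaries never extend beyond the
locus.

## Census rules

The quality and fragmentation rules are literal, with strict inequalities
at every threshold: high quality ⇔ contig length > 60,000 bp AND capsid
interval > 20,000 bp from both contig ends AND ≥ 3 viral-like genes.
Viral-like genes are counted as the maximum set of pairwise non-overlapping
annotations, the capsid hit included by default (configurable) — counting
non-overlapping intervals avoids double-counting overlapping hits from
homologous queries. Fragment categories: contig < 1,600 bp → lone capsid
fragment; < 25,000 bp → sub-element fragment; else resolved. The
genome-fraction bounds assume one 15–20 kbp element per capsid gene and are
exactly linear in copy number; hit density is hits per Mbp. On published
copy numbers these formulas give 1.27–1.69% for 2,535 capsids in 3 Gbp.
For the parabasalid worked numbers (4,841 capsids, 160 Mbp) the density
formula yields 30.26/Mbp; a published figure of 27/Mbp for that organism is
not reproducible from those two inputs alone and was presumably computed
over a different assembly size — the package implements the formula and
flags the discrepancy here rather than matching the printed value.

## Clustering and the similarity network

Greedy clustering uses incremental MMseqs-style semantics made fully
deterministic: sequences longest-first (ties by id), each joining the first
cluster whose representative it matches. Identity is matches over aligned
(non-gap) columns of a local alignment; coverage is alignment columns over
the shorter sequence length (one of several possible coverage modes; this
one is symmetric and strict for fragment-versus-full comparisons).
Within-genome diversity reports cluster counts at 100% / 98% / 50% identity
over 30% coverage; counts are monotone in the threshold by construction of
the predicate. Per-genome dereplication (90% identity, 80% coverage)
clusters each genome independently and pools representatives under
genome-qualified names, so identical variants in two genomes never merge.

The similarity network aligns all unordered protein pairs (BLOSUM62,
11/1), keeping edges with E ≤ 1e-4 and bit-scale score ≥ 6
(`bits = (λS − ln K)/ln 2`); components come from union-find and are
numbered by smallest member id. Components are verified in the tests
against a brute-force transitive closure of the same edge predicate.

## Synthetic genomes

The generator emulates the statistical structure the analysis assumes,
without modelling reads or coverage:

* **Host**: i.i.d. nucleotides at a configurable GC (default 0.50), 5
  contigs × 2 Mbp by default.
* **Elements**: 3 template families by default, each a random blueprint of
  14–40 kbp with exactly one MCP gene (placed mid-layout so a ±30 kbp
  flank reaches both element ends) plus 4–8 hallmark genes on random
  strands, 100 bp terminal inverted repeats, and a −0.10 GC offset
  realised by the element's own composition. Proteins are drawn from the
  Robinson–Robinson background and reverse-translated with synonymous-codon
  bias calibrated by bisection so coding GC actually hits the target
  (unconstrained bias undershoots by ~0.04 because the code limits
  composition).
* **Families**: star phylogeny — 20 copies per template by default, each
  non-ancestral copy carrying Poisson(0.02 × length) substitutions (and
  optionally single-base indels), TIRs mutating like any other site. A
  star is sufficient for identity-threshold clustering behaviour and keeps
  the ground truth exact; it does not emulate nested subfamilies.
* **Planting**: each copy inserted at a uniform position, extending the
  host contig (no host bases deleted), or — with configurable probability,
  default 0 — emitted as a detached lone-MCP contig (< 1,600 bp) or
  sub-element fragment (< 25,000 bp). A Ty3/Gypsy-like decoy cassette can
  be embedded inside elements at a configurable rate (default 0).
* **Artefacts**: inside planted intervals only, single-base indels
  (frameshifts) and stop-creating substitutions at configurable per-site
  rates (default 0); every edit is logged in final coordinates so the log
  inverts the edits exactly, and truth coordinates are adjusted through
  the indels.
* **Determinism**: one seed; placement, family mutation, host generation
  and artefacts draw from separate spawned streams so changing one rate
  does not reshuffle the rest.

What passing tests on these genomes shows — and does not. The simulator
exercises divergence, artefacts, fragmentation, composition shifts and
repeat structure at realistic magnitudes, so recovery there demonstrates
the machinery end to end. It does not reproduce real-genome features such
as host gene content, repeat families other than the planted decoy,
coverage-dependent assembly behaviour, or element phylogenies deeper than a
star; absolute recall/precision on real assemblies will differ.

## Problem sizes and defaults

The reference simulation used by the acceptance script is the default
configuration: 5 × 2 Mbp contigs, 3 families × 20 copies, 2% divergence —
about 11.6 Mbp of assembly and 60 planted elements, a deliberate
desk-scale stand-in for survey-scale data chosen so a full run completes in
minutes on one CPU. TIR performance is measured on ~100 planted pairs
(30/100/500 bp) in 2 kb cores and 50 random 20 kb sequences; oracle
equivalences use instances within the exhaustive-search regime (≤ 5 kbp ×
≤ 500 aa; clustering n ≤ 50; networks n ≤ 100).

## Known limitations

* The profile model is a PSSM, not a profile HMM: no position-specific gap
  states, and insertions relative to the profile are discarded when
  members are folded in.
* E-values are calibrated analytically, not empirically; absolute values
  differ from BLAST/DIAMOND/HMMER and only thresholds relative to this
  scale are meaningful.
* The frameshift DP treats every frame change identically (penalty per
  event); it does not model the higher plausibility of shifts at
  homopolymer runs.
* Alignment kernels are O(n·m) in time and pointer memory; clustering very
  long sequences (full 40 kbp elements rather than gene-length extracts)
  is correct but slow.
* Translation tables 1, 6 and 11 only; table 6 inputs are handled by
  passing `translation_table: 6` to the scan stage.
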
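# Methods

## The inference problem

Two focal species (nautilus and squid) are represented by assembled
transcript contigs; two reference organisms (human and fly) by protein
sequences, linked pairwise into homologue families.  The pipeline decides,
per contig, which reference lineage it resembles most, and then looks for
two family-level patterns: *duplication* (multiple same-species contigs
sharing one family) and *differential selection* (the nautilus contig
tracking one reference lineage and the squid contig the other, in a region
where the two references disagree enough for the comparison to be
meaningful).

## Search model

Contigs ≤ 100 nt are discarded.  Each remaining contig is translated in six
frames; translations are split into segments at stop codons, and alignments
never cross a stop — a deliberately conservative emulation of translated
BLAST.  Segments are aligned to every reference protein by local alignment
under BLOSUM62 with affine gaps costing `open + (g−1)·extend`
(open 11, extend 1).  Raw scores are converted with the standard gapped
constants λ = 0.267, K = 0.041:

    bits = (λ·raw − ln K) / ln 2,      E = m·n·2^(−bits)

with the plain search space `m·n` (m = contig length, n = total database
residues); e-values here only rank and threshold, so no finite-size or
composition corrections are applied.  Best hits are selected totally and
deterministically: highest bits, then lowest e-value, then lexicographically
smallest subject id.

Two engines share this contract.  The *native* engine computes every score
exactly (pairwise DP via biopython's aligner, with an exact
composition-bound prune: a segment whose residues' best-possible matrix
scores sum below the raw score needed to pass the e-cutoff cannot produce a
reportable hit).  It is quadratic per pair and intended for small inputs and
validation.  The *blastx* engine drives the NCBI BLAST+ tools
(single-threaded, SEG filtering and composition-based statistics disabled,
same matrix and gap costs) and is the default at transcriptome scale; a test
asserts that the two engines assign identical best hits and frames on a
shared dataset.  E-values differ slightly between engines (BLAST applies
length corrections); all pipeline thresholds are calibrated on ranks and
generous cutoffs, not on exact e-values.

## Expression and enrichment

Normalized average coverage is `c̃ = (aligned_bases/length) · T̄/T_s`, where
`T_s` is the sample's total aligned bases and `T̄` the mean over samples;
this preserves total normalized mass and leaves cross-sample fold ratios
invariant under depth changes (absolute values do shift when one sample's
depth changes, since `T̄` moves — the fold-change filter is unaffected).
A contig is up-regulated in a sample iff `c̃ ≥ 10` there (inclusive) and
`c̃ > 2×` the other sample (strict) — the inclusive/strict split mirrors the
wording of the thresholds ("10 or more", "more than two times").

Annotation transfer gives a contig the union of GO terms of all subjects hit
at `E ≤ 10⁻¹⁰`.  Enrichment between the two up-regulated sets is a one-sided
Fisher's exact test per term (both directions computed, the smaller-p
direction reported as over/under), BH-corrected; annotations are used flat
(no GO-graph propagation — upstream annotation augmentation is a curation
step, not reproduced here).  A two-tailed variant sits behind a config
switch because published pipelines differ on this point.

## Eye classification

Reference proteins are eye-related if an annotation carries the explicit eye
flag (synthetic data) or its term name contains one of the configured
keywords (eye, lens, retina, photoreceptor, R1/R6, R2/R5, R3/R4, R7, R8) —
case-insensitive substring match, since real annotations are free text.
Raw eye contigs are those hitting any eye protein at the transfer cutoff;
QC keeps a contig iff its *whole-proteome* best hit is itself eye-related.
A stricter reading — the best hit must be the identical protein found in the
eye-subset search — is available as `qc_strict`; the lenient reading is the
default because ties and near-ties between eye paralogues should not discard
a genuinely eye-related contig.

## Event detection

Same-region: two intervals on a common coordinate frame are "the same
region" iff their overlap covers ≥ 40% of the shorter interval.  The 0.4
default is calibrated on the NF1/Nf1 case study's printed hit intervals: the
starred (same-region) squid pair overlaps by 38 aa against a shorter
interval of 85 aa (fraction 0.447), so any threshold above that breaks the
printed pattern; 0.4 keeps it with margin and is configurable.  The common
frame is the human protein; intervals on the fly homologue are mapped
through the global alignment of the pair, endpoints sliding inward past
gaps.

Duplication: same-species contigs are grouped by the family of their best
hit; a group is a candidate iff it has ≥ 2 members, each > 100 nt, and every
pairwise nucleotide identity is below 95%.  Identity is measured as matched
columns of a free-end-gap global alignment divided by the *shorter contig's
length* — not by the aligned overlap, because for diverged copies the
optimal free-end-gap alignment can collapse to a short perfect overlap and
report near-100% identity, which would veto exactly the duplications the
test is meant to find.  For near-identical fragments (what the 95% rule
screens out) the two definitions coincide.  `dual_origin` is set when the
members' origin labels differ; the same-region flag is evaluated on the
common frame.

Differential selection: a family qualifies iff *exactly one* contig per
species passes the filters — families with two or more same-species contigs
are duplication material and are excluded from pairing (otherwise every
dual-origin duplication would also fire a spurious selection pair).  The
pair is a candidate iff the origin labels differ, the hits are same-region,
and the human/fly identity over the shared window (gap columns counted as
mismatches) is below `conservation_max_identity = 0.60`: in a conserved
window the two references are interchangeable and an origin split carries no
signal.  The 0.60 default sits well below typical within-family human/fly
identity yet above the divergence of a genuinely non-conserved window; it is
reported with every candidate so borderline calls stay auditable.

## Distances and trees

Candidate contigs are trimmed to the translated region of their hit.
Pairwise distances come from global alignments: `d` = mismatches over
gap-free columns, Kimura-corrected `D = −ln(1 − d − 0.2d²)` by default (the
classic protein-distance correction; undefined at `d ≥ 0.85`, in which case
the tree for that candidate falls back to uncorrected distances, logged).
Trees are Saitou–Nei neighbor joining with a total tie-break
(lexicographically smallest cluster-label pair on equal Q) so runs are
reproducible; negative branch estimates are clamped to zero with the deficit
moved to the sibling branch.  Pairwise global alignment stands in for a
progressive MSA because candidates involve at most four short fragments.
For each dual-origin duplication the 4-leaf tree {copy A, copy B, human
homologue, fly homologue} is checked for the expected pattern (each copy
forming a cherry with the reference that seeded it); for each selection pair
the contig–contig path distance is reported.

## The synthetic study

The generator emits the full input bundle (reference FASTAs, contig FASTAs,
homologue map, GO table, coverage table) plus a truth ledger, deterministic
to the byte given a seed.  Default conditions: 200 families of 80–400
residues; human/fly divergence 0.5 substitutions per site (i.i.d., uniform
replacement residue — the detectors respond to identity levels, not to
realistic exchangeabilities); focal contigs at 0.15 from their nearest
reference; 10 duplications (copies resampled into a 70–90% identity band; 3
dual-origin, seeded from the two references over the full interval); 10
selection events with a window of 30% of the family length regenerated
independently in the two references (window identity ≤ 30%) and tracked by
opposite focal species at 5% noise; no indels.  Coverage is generated
directly as aligned bases (read simulation is out of scope): log-normal with
σ = 0.2 around a mean of 50, with differential contigs boosted ≥ 2.5-fold in
their own species' sample.  σ = 0.2 models residual depth noise after
normalization so that a 2.5-fold planted effect reliably clears the strict
2-fold filter while unplanted contigs rarely do; real RNA-seq has far larger
biological dispersion, so the expression-filter performance measured here
speaks to the filter's logic, not to its behaviour on real data — the same
caveat applies to the substitution model and the absence of assembly
artifacts (chimeras, fragments), which the duplication identity and
same-region rules exist to guard against in real data.

GO vocabulary: 32 invented terms, 8 flagged eye-related; every family gets
1–3 terms shared across its four lineage copies (annotation transfer is by
homology), planted-event families always carry an eye term so events survive
the eye-subset workflow, and ~35% of families are eye-flagged overall.  One
background term is planted at a 5-fold contrast between the up-direction
families of the two species (rate 0.7 vs 0.14).  The planted-signal strength
was set by an explicit power analysis over 30 independent seeds: with 40% of
families differential (≈40 up-regulated contigs per side) and the 5-fold
contrast, the term is recovered at FDR < 0.05 in ≈97% of seeds; weaker
settings (30% differential, 0.6 vs 0.12) leave the test underpowered at
these sample sizes against a 31-term BH correction.

Scoring matches candidates to planted events by contig-id set equality;
with zero candidates precision is reported as 1 by convention (warned).

## Numerical and format conventions

Intervals are 1-based inclusive everywhere (protein residues on subjects,
nucleotides on contigs); minus-frame hits report forward-strand coordinates
with the frame sign carrying the strand.  Sequence ids are the FASTA token
before whitespace.  Ties are broken totally at every choice point (best
hits, co-optimal alignments by smallest subject then query start among up to
64 optima, NJ joins).  Distance matrices are validated (symmetric, finite,
zero diagonal) before tree building.  All randomness flows from
`numpy.random.default_rng(seed)`; the BLAST+ backend runs single-threaded
with heuristics that would introduce database-order dependence disabled.

## Problem sizes used by the shipped checks

The test suite runs the full pipeline at the default 200-family conditions
over ten seeds, plus one compact 40-family study shared by unit tests;
`scripts/acceptance.py` uses five seeds plus a determinism re-run.  These
sizes keep a complete from-scratch reproduction within a couple of minutes
on a single CPU while leaving every rate estimate based on ≥ 50 planted
events per detector.

## Known limitations

No indel evolution, codon-usage bias, read/assembly simulation, GO-graph
propagation, or formal selection tests (dN/dS); e-values are ranking
devices, not calibrated significance statements; the conservation and
same-region thresholds are calibrated heuristics, deliberately configurable
and reported with every candidate rather than hidden.
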
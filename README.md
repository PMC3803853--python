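# eyevolve

Comparative homology inference for mollusc developing-eye transcriptomes.

*Nautilus* has a lens-less pinhole eye open to seawater; its close relatives,
the coleoid cephalopods (squids), build a camera-type eye with a lens.
Comparing the transcriptomes of their developing eyes against well-annotated
vertebrate (human) and invertebrate (fly) reference proteomes asks, gene by
gene, which reference lineage each mollusc transcript resembles most — and
whether particular gene families show duplication or lineage-biased
("differentially selected") patterns that could underlie lens evolution.

`eyevolve` implements that analysis as a tested, reusable pipeline:

1. **Translated homology search** — contigs longer than 100 bp are translated
   in six frames (segments split at stop codons) and aligned locally
   (Smith–Waterman, BLOSUM62, affine gaps *o* = 11, *e* = 1) against the
   combined human + fly proteome.  Scores are normalized the Karlin–Altschul
   way, `S' = (λS − ln K)/ln 2`, `E = mn·2^(−S')` (λ = 0.267, K = 0.041).
   A native exact engine and an NCBI BLAST+ (`blastx`) backend share one
   tabular contract; the pipeline uses BLAST+ at transcriptome scale.
2. **Best-hit classification** — each contig's winning hit (bit score, then
   e-value, then subject id) labels it *human-best* or *fly-best*.
3. **Expression filtering** — normalized average coverage
   `c̃ = (aligned bases / length) · T̄/T_s`; contigs with `c̃ ≥ 10` expressed
   *more than* 2-fold between samples are the up-regulated sets.
4. **GO enrichment** — annotations transfer to contigs from hits at
   `E ≤ 10⁻¹⁰`; per-term one-sided Fisher's exact tests between the two
   up-regulated sets, Benjamini–Hochberg FDR < 0.05.
5. **Eye classification** — contigs hitting GO-selected eye-related reference
   proteins, kept only if their whole-proteome best hit is itself eye-related
   (quality control).
6. **Event detection** — *duplication*: ≥ 2 same-species contigs sharing a
   best-hit family, each > 100 bp, pairwise nucleotide identity < 95%;
   *dual-origin* when the copies split between human and fly references over
   the same region.  *Differential selection*: one contig per species with
   opposite origin labels, hits in the same region of the common coordinate
   frame, and that region *not* conserved between the human and fly
   homologues (window identity < 0.60).
7. **Distances and trees** — contigs trimmed to their hit, Kimura-corrected
   protein distances `D = −ln(1 − d − 0.2d²)`, Saitou–Nei neighbor joining,
   and contig–contig path distances per candidate.

Because the original raw reads and contemporaneous databases are not usable
at desk scale, the package ships a first-class synthetic-data module: a
four-lineage family simulator that plants duplications, dual-origin
duplications and selection windows with a machine-readable truth ledger, so
every detector is scored end-to-end (sensitivity and precision) on data with
known answers.

## Worked example

Simulate a 60-family study and run every stage:

```sh
eyevolve all --outdir demo --seed 7 --families 60
```

prints (abridged):

```
eyevolve run report
===================
contigs_total: {'nautilus': 65, 'squid': 65}
hits: {'nautilus': 130, 'squid': 130}
up_regulated: {'nautilus': 15, 'squid': 14}
eye_final: {'nautilus': 26, 'squid': 26}
duplication_candidates: 10
selection_candidates: 10

detection metrics vs truth:
  duplication: {'n_candidates': 10, 'n_recovered': 10, 'n_truth': 10,
                'precision': 1.0, 'sensitivity': 1.0}
  selection:   {'n_candidates': 10, 'n_recovered': 10, 'n_truth': 10,
                'precision': 1.0, 'sensitivity': 1.0}
  dual_origin_trees: {'concordant': 3, 'n': 3}
  origin_accuracy: 1.0
```

All 10 planted duplications (3 of them dual-origin) and all 10 planted
selection events were recovered with no false candidates; every dual-origin
tree pairs each contig with the reference lineage that seeded it, and every
planted ortholog was assigned its true origin.  `demo/selections.tsv` then
holds the per-pair evidence, e.g.

```
family_id  nautilus_contig  squid_contig   ...  overlap_fraction  window_identity  nj_distance
fam0010    naut_fam0010     squid_fam0010  ...  1.0               0.412            0.49894
```

meaning: the two contigs hit the same full-length region of the common frame
(overlap 1.0), that region is only 41% identical between the human and fly
homologues (below the 0.60 conservation bar, so the opposite origin labels
are informative), and the contig–contig neighbor-joining distance is 0.499.

Stages can be re-run individually (`eyevolve search|express|enrich|classify|
detect|tree|score --outdir demo`); all thresholds live in a YAML config
mirroring `eyevolve.config.PipelineConfig`.

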
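# Methods

This note documents the statistical procedures `sigscan` implements, the
design choices made where conventions genuinely diverge, what the
synthetic-data generator does and does not emulate, and known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Variant model and read-support filtering

Input somatic calls (VCF with per-sample `AD`, or a flat TSV) are
normalized to records carrying 1-based coordinates, left-anchored
VCF-style alleles, and read support. Only FILTER-pass records enter;
multi-allelic sites are split into one record per alternate allele (the
alternative — dropping them — discards real signal, and depth fields
remain well defined per allele). The read-support filter keeps records
with `alt_depth ≥ 3`, `total_depth ≥ 10` and `VAF > 0.05`; the VAF rule
is strict, so a record at exactly 0.05 is removed (boundary removals are
logged). Mitochondrial contigs (`chrM`, `MT`, `M` by default) are
excluded from **all** analyses, not only the enrichment score, for
internal consistency; the exclusion set is configurable. Substitutions
whose REF and ALT have equal length > 1 (MNVs) are kept as a distinct
class and excluded from both SBS and indel analyses rather than being
split into per-base events, since per-base independence cannot be
assumed.

## 96-context spectra

Substitutions are expressed on the pyrimidine strand: purine-reference
events are reverse-complemented together with their flanks. Flanking
bases always come from the reference genome, never from annotations in
the input file, and a reference-base mismatch raises an error (it almost
always means the wrong genome build). Sites whose trinucleotide context
contains N, or that sit on a contig edge, are excluded rather than
imputed. Class order for serialization is the conventional catalog
order (C>A, C>G, C>T, T>A, T>C, T>G; flanks lexicographic), so spectrum
matrices align column-by-column with external signature catalogs.

## TCW enrichment score

After four organizing rules — SBS only; C:G reference base; not
mitochondrial; not C→A (equivalently G→T) — each retained record
contributes to four aggregated counts:

* `Mut_C` += 1; `Mut_TCW` += 1 iff the strand-oriented trinucleotide at
  the site is TCA or TCT;
* the 41-base reference window (±20 bp, reverse-complemented for
  G-reference sites so the mutated base is presented as C) contributes
  its motif count to `Con_TCW` and its cytosine count to `Con_C`.

The score is the fold enrichment `(Mut_TCW/Con_TCW)/(Mut_C/Con_C)`;
significance is the one-sided (greater) Fisher exact test on
`[[Mut_TCW, Mut_C−Mut_TCW], [Con_TCW, Con_C−Con_TCW]]`, BH-corrected
once across all samples of a cohort, with ES-high defined as q < 0.1
(strict).

Conventions that required a decision:

* **Motif set.** The motif is TCW = {TCA, TCT} throughout, consistent
  with the deaminase's preference; a strict-TCA variant is available via
  `motif="TCA"`.
* **Strand.** Windows of G-reference sites are reverse-complemented
  before counting, so TCW is always counted on the strand presenting the
  mutated cytosine. Rationale: deamination chemistry acts on C, and the
  C:G / no-C→A rules already imply pyrimidine-strand normalization.
* **Window counting.** Motifs are counted inside the extracted window
  string (a motif must lie fully within the 41-mer); overlapping windows
  of nearby mutations are counted independently, i.e. shared genomic
  bases are counted once per window, matching per-substitution
  aggregation.
* **Edges.** Windows truncated at contig edges are used as-is; this only
  matters on the small synthetic genomes used in testing.
* **Degenerate samples.** A sample with no retained mutated cytosines
  gets an undefined (NaN) score, is excluded from the BH family, and is
  always classed low.

### Known bias of the windowed score under an i.i.d. null

The score is *not* exactly centered at 1 when mutated C sites are drawn
uniformly from the C sites of an i.i.d. random genome. Conditioning on a
mutated C at the window center makes motif centers at the two adjacent
offsets impossible (the center base C cannot serve as the motif's T or
its W flank), so the window-based availability `Con_TCW/Con_C`
systematically under-states the genome-wide TCW fraction among C sites.
Exact site enumeration (`simulate.expected_enrichment_score`) puts the
asymptotic null expectation at ≈ 1.10 for a uniform-composition genome
and 41-base windows; the finite-sample mean is slightly higher still
(Jensen-type bias of the ratio of ratios at a few hundred retained
mutations). The effect shrinks with window length and persists under
every defensible counting convention (both-strand Con counts,
genome-context motif counting at window edges, center exclusion); making
the null exactly 1 would require excluding the mutated trinucleotide
from the Con counts, i.e. changing the statistic. Practical
consequences: scores of background samples hover around 1.0–1.15 rather
than 1.0, and the raw one-sided Fisher false-positive rate is mildly
inflated (measured ≈ 0.06–0.09 at 500 mutations/sample). The
enrichment-high call is driven by the BH-corrected q-value and a planted
signal moves the score several-fold, so the dichotomy is robust to this
bias; quantitative interpretation of scores in the 1.0–1.2 range is
not.

## Signature refitting

A spectrum is normalized to probabilities and decomposed over a catalog
of 96-class signature probability vectors by greedy forward selection:
at each step the candidate signature whose inclusion most reduces the
squared reconstruction error under a non-negative least-squares fit
joins the active set, stopping when the improvement falls below
`tolerance` (default 1e-9, ties broken by catalog order — the procedure
is fully deterministic). Weights are capped to sum ≤ 1; weights below
`weight_floor` (default 0.06, mirroring the widely used refitting tool's
discard rule) are zeroed and the surviving set refit. `unexplained`
is 1 − Σweights and `reconstruction_error` the L2 distance between the
normalized spectrum and the fitted mixture. No trinucleotide-abundance
renormalization between exome/genome spaces is applied — spectra and
catalog must be in the same space. The bundled `toy_signature_catalog()`
is synthetic: five deterministic shapes (APOBEC-like C>T at TCW, its C>G
counterpart, CpG C>T, flat, and a T>G/T>C shape) named after the catalog
signatures they mimic, built for recovery tests and examples, not for
analysis of real data.

## Indel classification

Indels are classified by net length |len(REF) − len(ALT)|: size classes
1–4 and 5+ (5–200 bp; longer events are tallied separately and excluded
from spectra). One-bp events split into T/A vs C/G by the affected base,
which is strand-symmetric by construction. Deletions of ≥ 2 bp carry a
microhomology flag: true iff the deleted sequence and the reference
immediately 3′ of the deletion junction share a common prefix of ≥ 1
base (scanned up to `mh_scan = 10` bases). This is deliberately coarser
than the 83-class indel catalog — no homopolymer/repeat-unit
subclassification — matching the size-plus-microhomology scheme the
analyses need. Complex indels (both alleles > 1 base, unequal lengths)
are classified by net length and never flagged as microhomologous.
Input is assumed left-aligned by the caller, as Mutect2-style output is.

## Replication-timing profiles

A timing track (BED4/5; 0-based half-open, converted at the boundary
from the records' 1-based positions) carries either continuous timing
values — smaller = earlier — or pre-assigned quintile labels 1–5.
Continuous tracks are labeled by a length-weighted quantile cut so each
quintile covers ≈ 20% of tracked bases, ties toward the earlier
quintile. Mutations outside every interval land in an "untracked" bin
that profiles ignore (counted and logged). Group profiles pool records
across a group's samples *before* normalizing to the largest quintile
(per-sample profiles are available via a flag); per-quintile TC→TT
percentages use each quintile's own records only. Because the timing
data source for any particular study is an explicit input, none of the
tests require downloads.

## Synthetic cohorts

`generate_cohort` emits a complete study — FASTA genome, one VCF per
sample, BED timing track, truth TSV — that is byte-stable under a fixed
seed (all sub-generators draw from seeds spawned off one root
`SeedSequence`; no timestamps in any output).

* **Genome**: i.i.d. bases, default 4 × 250 kb at uniform composition —
  a size at which every recovery analysis is exact enough to test while
  the whole suite runs in seconds.
* **SBS**: a mixture of a background process (uniform over all sites,
  uniform non-reference alternate) and an APOBEC process (uniform over
  strand-oriented TCW cytosines, C→T with probability
  `apobec_ct_cg_split`, else C→G) at mixing fraction `apobec_fraction`.
  The split defaults to 1.0, emulating a pure C→T (SBS2-without-SBS13)
  process; 0.5 emulates classic joint SBS2/SBS13 cohorts. Background
  placement is uniform rather than SBS5-like because the enrichment
  null depends only on context proportions, and uniform placement makes
  the closed-form expectation exact.
* **Read support** is synthesized (depth 50, VAF ~ U[0.1, 0.5], alt
  depth rounded) so the filters are exercised, not bypassed.
* **Indels**: lengths drawn per size-category distribution (default
  dominated by 1-bp events, as in real tumors; 5+ uniform on 5–200),
  kind 50/50, placement uniform; with
  `indel_rate_couples_to_apobec` the per-sample count scales as
  `round(n·(1 + 2·apobec_fraction))`, planting the burden–enrichment
  association.
* **Timing**: the genome is tiled, tiles are randomly assigned to five
  equal-coverage quintiles, and biased mode samples mutation sites with
  weights r^(quintile−1), giving the planted geometric profile
  (1, r, r², r³, r⁴).

What the simulator does **not** emulate: mutation clusters
(kataegis/omikli), clonal/subclonal VAF structure, sequence-dependent
background signatures, repeat-context indels, chromatin covariates, or
read-level artifacts. Passing recovery tests therefore demonstrates the
correctness of the implemented statistics on their own assumptions — not
robustness to the full messiness of real tumor genomes.

## Numerical and degenerate-input choices

* Fisher, Mann–Whitney (two-sided, tie-corrected), Pearson/Spearman and
  chi-square come from scipy; BH from statsmodels — each behind the
  package's own validated surface (tests compare against exhaustive
  enumeration or definitional step-up oracles).
* Zero-variance association inputs yield flagged NaN coefficients
  rather than exceptions; empty groups are errors.
* An all-zero spectrum is valid for counting but an error to refit.
* `Con_TCW = 0` with `Mut_TCW > 0` is impossible by construction (every
  full window contains its own site's motif) and raises, as it signals a
  context bug.
* The BH family is all defined samples of one run's manifest — do not
  mix cohorts across runs.

## Scope

Upstream read processing (alignment, duplicate marking, calling),
structural-variant detection, de novo signature extraction, expression
quantification and survival analysis are out of scope; expression
values, SV counts and similar per-sample quantities enter only as
covariate tables for association and group comparison.
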
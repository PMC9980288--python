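# sigscan

APOBEC mutational-signature analysis for somatic variant calls.

APOBEC3 cytidine deaminases (notably APOBEC3A/B) attack single-stranded
DNA at TC dinucleotides, seeding C→T and C→G mutations that appear in
tumor genomes as the SBS2/SBS13 catalog signatures with a strong
preference for the TCW motif (TCA/TCT; W = A/T). `sigscan` implements the
standard desk analysis that establishes such mutagenesis in a tumor
cohort from variant calls and a reference genome:

- **Variant ingest and read-support filtering** — VCF (Mutect2-style) or
  TSV input; keep calls with ≥ 3 variant-supporting reads, ≥ 10 total
  reads, VAF > 0.05; drop mitochondrial sites.
- **96-context SBS spectra** — pyrimidine-strand trinucleotide classes,
  flanks read from the reference.
- **TCW enrichment score** — per sample,

  ```
  E = (Mut_TCW / Con_TCW) / (Mut_C / Con_C)
  ```

  where `Mut_TCW`/`Mut_C` count mutated cytosines in/out of the TCW motif
  (after filtering to C:G substitutions, excluding C→A) and
  `Con_TCW`/`Con_C` count motif and cytosine occurrences aggregated over
  the 41-base windows (±20 bp) around each mutation. Significance is a
  one-sided Fisher exact test on those four counts, Benjamini–Hochberg
  corrected across the cohort; samples with q < 0.1 are called
  enrichment-high (ES-high).
- **Signature refitting** — non-negative decomposition of a spectrum into
  catalog signatures by forward selection with NNLS sub-solves
  (deconstructSigs-style), reporting per-signature percent contributions
  such as %SBS2.
- **Indel spectra** — size classes 1 (split T/A vs C/G), 2, 3, 4 and 5+
  (5–200 bp) for insertions and deletions, with a microhomology flag on
  deletions ≥ 2 bp, plus Spearman association of each class with the
  enrichment score.
- **Replication-timing profiles** — mutation densities across timing
  quintiles normalized to the largest quintile, and per-quintile TC→TT
  percentages.
- **Synthetic cohorts** — a simulator that plants known APOBEC signal
  (mixing fraction, C→T/C→G split, indel rates, timing bias) so every
  stage is validated by parameter recovery; no external data needed.

## Worked example

Simulate a six-sample cohort — three background-only samples and three
with half of their 2000 substitutions planted at TCW cytosines — then
score it:

```python
from sigscan import (ApobecEnrichment, SignatureRefit, SyntheticCohortConfig,
                     apply_filters, build_spectrum, generate_cohort)
from sigscan.simulate import toy_signature_catalog

config = SyntheticCohortConfig(
    seed=11, n_samples=6, sbs_per_sample=2000,
    apobec_fraction=[0.0, 0.0, 0.0, 0.5, 0.5, 0.5],
)
cohort = generate_cohort(config)
records = {s: apply_filters(r) for s, r in cohort.sbs_by_sample.items()}
results = ApobecEnrichment(records, cohort.genome).fit()
print(results.summary())
```

```
APOBEC TCW enrichment (one-sided Fisher, BH-corrected)
samples: 6   motif: TCW   window: 41 bases   enrichment-high (q < 0.1): 3

sample_id  mut_tcw  mut_c  con_tcw  con_c  score      p      q es_class
      S01       77    667      813   7147  1.015 0.4677 0.5612      low
      S02       75    645      780   7038  1.049 0.3563 0.5345      low
      S03       71    655      850   7081  0.903 0.8269 0.8269      low
      S04     1036   1325     2579  14000  4.244      0      0     high
      S05     1048   1354     2629  14270  4.201      0      0     high
      S06     1034   1323     2652  14057  4.143      0      0     high
```

The background samples score near 1 (mutated cytosines use TCW in
proportion to its availability) and are classed low; the planted samples
score ≈ 4.2 — their mutated-cytosine TCW usage (`1036/1325 ≈ 78%`) is
about four times the window availability (`2579/14000 ≈ 18%`) — with
vanishing q-values. Refitting the same samples' spectra against the
bundled toy catalog attributes ≈ 60% of the planted samples' mutations to
the SBS2-like signature and 0% for background samples:

```python
spectra = [build_spectrum(r, cohort.genome, s) for s, r in records.items()]
print(SignatureRefit(spectra, toy_signature_catalog()).fit().percent("SBS2"))
```

```
S01     0.000000
S02     0.000000
S03     0.000000
S04    59.701590
S05    59.965276
S06    59.922956
Name: percent_SBS2, dtype: float64
```

The same pipeline runs from the shell:

```sh
sigscan simulate --seed 11 --out-dir study/
sigscan run --manifest study/manifest.tsv --ref study/genome.fa \
            --track study/timing.bed --out-dir report/
```

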
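# brimmune

Immunogenomic comparison of **primary triple-negative breast cancer (TNBC)
and brain metastases (BrM)**, re-implemented as a tested, reusable Python
pipeline. TNBC has a strong predilection for brain metastasis and a poor
prognosis once BrM develop; characterizing how the mutational and immune
landscape changes between the primary tumor and the metastasis — and which
immune features track with survival — motivates every stage of this
package.

The pipeline covers, end to end:

1. **Consensus somatic filtering** of per-caller variant calls
   (Strelka2, Mutect2, Cadabra). Matched-normal mode retains
   protein-coding calls passing per-caller quality gates (Cadabra indel
   > 10.5; Mutect2 indel > 6.8, SNV > 9.2; Strelka2 indel > 15.2, SNV
   > 19.7), requiring cross-caller corroboration for Cadabra indels with
   quality < 35 and Strelka2 calls with SomaticEVS < 20. Tumor-only mode
   (Mutect2) requires ≥ 5 supporting reads at ≥ 40× depth (≥ 10 reads at
   ≥ 80× when MAF < 5%), drops variants with normal MAF > 5% or any
   subpopulation allele frequency > 1%, and suppresses FFPE deamination
   artifacts by requiring C>T / G>A substitutions to reach MAF ≥ 10%.
2. **Tumor mutational burden**: TMB = retained variants / megabases
   adequately covered, with Wilcoxon comparison of BrM vs primaries and
   exact variant-sharing statistics (Jaccard) for matched pairs.
3. **Neoantigen enumeration**: 8–11-mer candidate peptides from SNVs
   (all mutation-covering windows), frameshift/in-frame indels
   (standard-table translation to the first stop), fusion and splice
   junctions, plus expressed CTA/self, ERV and viral antigen features;
   a pluggable MHC-I affinity interface with a deterministic toy
   predictor; binder classes Kd < 500 nM (positive) and < 50 nM (strong).
4. **Immune gene signatures**: 20M-coding-read QC, upper-quartile
   normalization with log2(x+1), technical-replicate averaging, metagene
   scores as median log2 expression, and Z-transformed Wilcoxon tests
   with Benjamini–Hochberg FDR across the signature family.
5. **TCR/BCR repertoire**: per-chain read counts, clonotype richness,
   Shannon entropy H = −Σ pᵢ ln pᵢ and a Chao–Shen coverage-corrected
   estimator; group tests on log10 read counts and raw entropy.
6. **Survival**: multivariable Cox proportional hazards (Efron ties)
   with stage, age at primary diagnosis and race, signature scores
   entered one at a time, under three time origins (primary diagnosis,
   any metastasis, BrM diagnosis).
7. **Copy-number plumbing**: Sequenza depth-ratio segments converted to
   GISTIC SEG via Seg.CN = log2(depth ratio) − 1 (note: this published
   convention maps a copy-neutral ratio of 1 to −1, not 0).

The real cohort is controlled-access, so the package ships a seeded
**synthetic cohort generator** (`brimmune.synthetic_cohort`) that plants
ground truth for every stage — true variants and FFPE artifacts, caller
scores straddling every gate, signature depression/elevation effects,
site-specific repertoires, covariate-driven hazards — making the whole
pipeline testable offline.

## Worked example

```bash
brimmune run --seed 1 --out run1
```

writes the report tables under `run1/`. Equivalently, the numbered
drivers under `analysis/` run each stage with narrative output:

```text
$ python analysis/02_variant_landscape.py
TMB: BrM median 2.47 vs primary 1.27 mut/Mb (n=19 vs 15, Wilcoxon p=7.56e-07)
matched pairs: median Jaccard 0.124 over 6 pairs
FFPE artifacts surviving tumor-only filtering: 0

$ python analysis/04_immune_signatures.py
32 signatures tested (BrM vs primary)
  depressed in BrM at q<0.05: 9
  elevated in BrM at q<0.05:  ['Wound_Healing_Serum_Response']
  planted effects recovered: 10/11

$ python analysis/05_repertoire_diversity.py
TRB total_reads: lower in BrM (p=7.71e-07)
TRB entropy: lower in BrM (p=7.71e-07)
...
```

Reading these numbers: the metastases carry roughly twice the mutational
burden of the primaries (the planted truth is 3.3 vs 1.8 mutations/Mb;
the filtered estimates are proportionally lower because non-coding and
gate-failing calls are removed on both sides), matched primary/BrM pairs
share only a minority of their variants, immune signatures are broadly
depressed in BrM while the wound-healing signature rises, and T/B-cell
receptor abundance and diversity drop in the metastases — the qualitative
portrait the pipeline is designed to extract.

Stage-level CLIs (`brimmune filter-matched`, `filter-tumor-only`, `tmb`,
`pair-share`, `seg-convert`, `signatures`, `repertoire`, `survival`)
operate on the documented external formats (VCF v4.2, SEG, GMT,
AIRR-style clonotype TSV, clinical CSV) and produce identical outputs to
the orchestrated run.

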
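# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic cohort does and does not emulate, and the
numerical details a user would need to reproduce or modify an analysis.

## Somatic variant consensus filtering

**Matched-normal cascade.** The retained set is the union over callers of
calls that are (R1) protein-coding, (R2) above their per-caller,
per-class quality gate (Cadabra indel > 10.5; Mutect2 indel > 6.8, SNV
> 9.2; Strelka2 indel > 15.2, SNV > 19.7; strict inequalities), and (R3)
corroborated when they fall in one of two low-confidence classes:
Cadabra indels with quality < 35 need a gate-passing Strelka2 or Mutect2
call at the same (chrom, pos, ref, alt), and Strelka2 calls with
SomaticEVS < 20 need a gate-passing Mutect2 or Cadabra match. (R4)
deduplicates by locus/allele, keeping caller provenance. Design choices
a user can override in `FilterConfig`:

* The cascade is a **union of per-caller gate survivors**, not an
  intersection; the published criteria are or-joined per-caller gates.
* Corroborating calls must pass their own gate. The Cadabra clause
  explicitly says "supporting high-quality call"; for the Strelka2
  clause (which says only "matching call") the gate requirement is kept
  for symmetry and exposed as `require_corroborator_gate`.
* The Strelka2 quality gate and the EVS corroboration rule are **both**
  applied — gate first, then corroboration — since they are listed as
  separate criteria.
* Cadabra SNVs have no published gate and are excluded by default (the
  caller is an indel-realignment caller); `cadabra_snv_quality` admits
  them with a user threshold.
* A Strelka2 call without a SomaticEVS annotation is an error, not a
  silent pass.
* Mutect2 calls in matched mode carry no corroboration requirement
  (none is stated).

**Tumor-only cascade** (Mutect2 only). Retained iff protein-coding;
supported by ≥ 5 alt reads at ≥ 40× depth when MAF ≥ 5%, tightened to
≥ 10 reads at ≥ 80× below 5% MAF (the published sentence is ambiguous;
it is resolved as this MAF-conditional branch); normal MAF absent or
≤ 5% (consumed as a pre-computed annotation, no pileup); maximum
subpopulation allele frequency absent or ≤ 1%; and, for literal C>T or
G>A substitutions, MAF ≥ 10% (the FFPE deamination rule — no strand
complement expansion beyond the two printed pairs). The FFPE rule
applies in tumor-only mode by default; `ffpe_in_matched` extends it.

**TMB** divides the retained count by megabases adequately covered.
"Adequately covered" is not defined in the source analysis;
`covered_megabases` counts bases at depth ≥ 20 by default
(`min_depth` configurable). TMB is computed from whichever consensus
set a sample has (matched or tumor-only).

## Copy-number segment conversion

`sequenza_to_gistic_seg` applies Seg.CN = log2(depth ratio) − 1 exactly
as published. Note the convention maps a copy-neutral depth ratio of 1
to −1 rather than 0; downstream consumers that assume Seg.CN = 0 at
neutrality must account for the offset. The function is strictly
increasing in the depth ratio and preserves row order and coordinates
(1-based inclusive throughout the package).

## Neoantigen enumeration and binder classification

Peptide lengths default to 8–11, the standard MHC class I range (no
lengths are published). For SNVs, every k-mer window of the mutant
protein covering the substituted residue is emitted — k windows per
length for interior positions, truncated at sequence ends. Frameshift
(and in-frame) indels translate the mutant CDS with the standard codon
table from its start through the first stop in the shifted frame
(translating to the end with a warning if no stop occurs); emitted
windows contain ≥ 1 residue differing positionally from the reference
protein. Fusions (and splice junctions, which reuse the same machinery
on exon-junction pairs) emit junction-spanning windows, k−1 per length
when both partners suffice. Expressed CTA/self, ERV and viral features
are called per sample when normalized log2 expression exceeds a
threshold (default 1.0; no published value exists, so this is
configuration, not a biological claim), and variant expression is
confirmed by RNA alt-read support ≥ 1 by default.

Affinity prediction is an interface: any `(peptide, allele) -> Kd`
callable. The bundled toy predictor derives an 11×20 position-weight
matrix deterministically from the allele name (CRC32-seeded) and maps
the standardized residue-weight sum s to Kd = 10^(log10 500 + 1.6 s),
clipped to [1, 50000] nM, so random peptide populations straddle the
500 nM threshold. It exists to make the pipeline executable and
testable; an external predictor plugs in through the same interface.
Binder classes use strict inequalities — positive < 500 nM, strong
< 50 nM — on the minimum Kd over a sample's alleles, counting each
distinct (peptide, source class) once, so duplicated predictions and
ordering cannot change counts. Counting is per peptide, matching a
"number of binding peptides" readout, not per antigen.

## Expression normalization and signature testing

Samples with < 20,000,000 coding reads are excluded (a sample exactly at
the cutoff is kept, following the strict "less than" wording). The
normalization order is upper-quartile scaling **on counts first, then**
log2(x+1): each sample's scale factor is its linear-interpolation 75th
percentile of nonzero gene counts, and all samples are scaled to the
geometric mean of those upper quartiles (a fixed reference constant is
configurable). The published sentence does not fix the order;
scale-then-log is the standard reading. After scaling, every sample's
nonzero upper quartile is equal to within numerical precision — a
contract the tests enforce. Technical replicates are averaged gene-wise
on the normalized log2 scale.

A signature's metagene score is the per-sample **median** of log2
expression over the signature's genes (intersection with the matrix;
duplicate symbols and gene order are irrelevant). Group comparison
Z-transforms each signature across all samples (rank tests are invariant
to this, so p-values equal those on the raw scale; the transform fixes
the reported effect scale), applies a two-sided Wilcoxon rank-sum test —
exact for small tie-free samples, otherwise the normal approximation
with mid-ranks and tie-corrected variance, without continuity correction
so identical groups give p = 1 — and controls FDR with
Benjamini–Hochberg within the signature family tested (the 32-signature
family by default; the family is whatever set is passed together).

The exact membership of the study's 32 signatures lives in its
supplementary GMT; the generator emits synthetic signature names and
memberships, and users supply a real GMT for real data.

## Repertoire diversity

Clonotype identity is (chain, CDR3 amino-acid sequence); V/J fields are
ignored. Shannon entropy is reported in nats (base configurable). The
source analysis cites a model-based diversity estimator whose internals
are not specified there; rather than guess, the package reports plug-in
entropy plus a clearly labeled **Chao–Shen** coverage-adjusted
estimator (coverage C = 1 − f₁/n, Horvitz–Thompson reweighting), with
`EntropyEstimator` as the plug-point for alternatives. When every
clonotype is a singleton, C would be 0 and the estimator undefined; the
standard f₁ → n−1 adjustment keeps it finite. Read counts are compared
across groups on the log10(x+1) scale and entropies on the raw scale,
both with two-sided Wilcoxon tests; a chain absent from a group yields
a flagged-missing row, not an error. BCR consensus-contig abundances
are represented through the same clonotype-table abstraction as TCR.

## Survival modeling

Cox proportional-hazards fits use the Efron tie approximation (times
are day-resolution, so ties occur) via lifelines. Stage is encoded
ordinal-linear (I..IV → 1..4; categorical coding available); race is
one-hot with the largest group as reference. Signature covariates enter
**one at a time** beside the clinical base model (stage, age, race),
matching a per-signature forest plot; joint entry is possible by
passing several covariates to `fit_cox`. Three time origins are
supported: primary diagnosis, first metastasis, BrM diagnosis; patients
lacking the origin date are excluded with a logged count, negative
times are an error, and same-day events get half a day. Fewer than two
events or a constant covariate is an error; non-convergence returns
flagged results rather than silent output. TMB or any other per-patient
quantity can be entered as a continuous covariate (no dichotomization).

## Synthetic cohort

Defaults mirror the study's structure: 15 primary and 19 BrM samples
(6 matched pairs, i.e. 28 patients; 2 BrM samples lack a matched
normal and go through the tumor-only cascade), true burdens of 1.8 and
3.3 mutations/Mb over 30 Mb of covered exome, FFPE artifacts at 5/Mb
with MAF drawn in (0.01, 0.09), population contaminants at 1/Mb with
subpopulation AF > 1%, and caller sensitivities of 0.9 with 15% of
detections drawn below their quality gate so every cascade branch
occurs. Matched pairs share 20–60% of the primary's variants.
Expression is negative-binomial (dispersion 0.1) over 2,000 genes with
32 signatures of 25 genes; a sample-level signature latent (SD 0.5
log2 units) carries the planted effects — 10 immune signatures
depressed by 2 SD in BrM and one wound-healing signature elevated by
2 SD — alongside gene-level noise (SD 0.3) and log-normal library-size
factors; three samples get duplicated technical-replicate columns.
Repertoires are Zipf-distributed (exponent 1.1 primary / 1.6 BrM) with
~300 vs ~120 clonotypes and ~3000 vs ~300 reads per chain, giving BrM
lower abundance and entropy. Survival times are exponential with a
baseline median of 440 days after BrM diagnosis and configured
log-hazard-ratios for age, stage and score; 20% of patients are
censored.

Generated quality scores and allele fractions are rounded and nudged at
least 0.005 away from every decision threshold, so 32-bit VCF INFO
storage and text round-trips can never flip a filter comparison, and
"should-pass" labels assigned at generation time by direct clause
checks are exact. Every observable traces to a `GroundTruth` record,
and `evaluate_recovery` scores artifact removal, true-variant
retention, signature detection and Cox convergence against it.

What the generator does **not** emulate: real genome coordinates, gene
annotation or linkage; mutational signatures beyond the FFPE pair;
expression correlation structure between signatures; clonal lineage
structure in repertoires; read-level data. Passing tests therefore
demonstrate the correctness of the pipeline's rules and statistics
under the planted model, not performance on real sequencing data.

## Problem sizes and determinism

The test and acceptance runs use the default cohort (34 tumor samples,
2,000 genes, three chains per sample) and replicate studies of 100–200
runs for the power/coverage checks (TMB direction, signature operating
characteristics, Cox recovery at n = 200), sizes chosen to make
Monte-Carlo rates stable at the asserted margins. All randomness flows
from a single integer seed through `numpy.random.default_rng`; the
orchestrated run writes every input to disk in its external format and
reads it back, so a rerun with the same seed is byte-identical, which
the manifest checksums record.

## Known limitations

* The toy affinity predictor has no biochemical content; absolute
  binder counts are only meaningful relative to it.
* The tumor-only and matched cascades produce systematically different
  retention, so cross-mode TMB comparisons inherit that difference
  (as they would in the real analysis).
* The Chao–Shen estimator stands in for the cited model-based
  diversity method; absolute entropy values differ from that method,
  though group contrasts are preserved under the planted model.
* The segment conversion reproduces the published −1 offset verbatim;
  see above.
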
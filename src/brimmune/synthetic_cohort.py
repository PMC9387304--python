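"""Seeded synthetic cohort generator with planted ground truth.

Produces every input the pipeline consumes — per-caller somatic call
sets, expression counts, clonotype tables, clinical records — for a
cohort of primary triple-negative breast tumors and brain metastases
(BrM), mirroring the statistical structure of the real study cohort:

* higher true SNV/indel burden in BrM than primaries (3.3 vs 1.8
  mutations/Mb over 30 Mb by default);
* FFPE C>T/G>A deamination artifacts planted at low allele fraction,
  plus population-frequent contaminants, in tumor-only call sets;
* caller quality scores drawn to straddle every published filter gate so
  all cascade branches occur;
* negative-binomial expression with immune-signature depression and
  wound-healing-signature elevation in BrM;
* Zipf-distributed clonotype repertoires with lower abundance and
  diversity in BrM;
* survival times from exponential hazards driven by configured log-HRs.

Every generated observable traces to a :class:`GroundTruth` record, and
"should-pass" labels are assigned at generation time by direct clause
checks, so filter behavior can be verified by exact set equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AMINO_ACIDS,
    ClinicalRecord,
    ClonotypeRecord,
    VariantCall,
)
from .variant_filtering import FFPE_PAIRS, VariantKey

_BASES = "ACGT"
_HLA_POOL = (
    "HLA-A*01:01",
    "HLA-A*02:01",
    "HLA-B*07:02",
    "HLA-B*08:01",
    "HLA-C*07:01",
    "HLA-C*07:02",
)

_RACES = ("Caucasian", "African American", "Asian", "Other")
_RACE_PROBS = (0.68, 0.24, 0.04, 0.04)
_STAGE_PROBS = (0.20, 0.48, 0.24, 0.08)

# thresholds used for generation-time should-pass labels; these mirror the
# published filter clauses and are intentionally written as plain literals
_GATES = {
    ("cadabra", "indel"): 10.5,
    ("mutect2", "indel"): 6.8,
    ("mutect2", "snv"): 9.2,
    ("strelka2", "indel"): 15.2,
    ("strelka2", "snv"): 19.7,
}
_ALL_THRESHOLDS = (10.5, 6.8, 9.2, 15.2, 19.7, 35.0, 20.0)


@dataclass(frozen=True)
class CallerSimParams:
    """How one caller's detections and quality scores are simulated."""

    sensitivity: float = 0.9
    p_below_gate: float = 0.15
    quality_spread: float = 15.0


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    TMB rates are true mutations/Mb; signature effects are in units of the
    between-sample score SD (negative = depressed in BrM).
    """

    n_primary: int = 15
    n_brm: int = 19
    fraction_matched_pairs: float = 0.4
    n_tumor_only: int = 2
    tmb_rate_primary: float = 1.8
    tmb_rate_brm: float = 3.3
    covered_mb: float = 30.0
    indel_fraction: float = 0.15
    ffpe_artifact_rate: float = 5.0  # artifacts per Mb, MAF < 0.10
    population_contaminant_rate: float = 1.0  # per Mb, pop AF > 1%
    caller_params: Mapping[str, CallerSimParams] = field(
        default_factory=lambda: {
            "strelka2": CallerSimParams(),
            "mutect2": CallerSimParams(),
            "cadabra": CallerSimParams(),
        }
    )
    # expression
    n_genes: int = 2000
    n_signatures: int = 32
    genes_per_signature: int = 25
    n_affected_signatures: int = 10
    signature_effect_brm: float = -2.0  # SD units
    wound_healing_effect_brm: float = 2.0  # SD units
    signature_noise_sd: float = 0.5  # log2 units, sample-level
    gene_noise_sd: float = 0.3
    nb_dispersion: float = 0.1
    n_replicated_samples: int = 3
    n_qc_fail: int = 0
    # clonotypes
    n_clonotypes_primary: int = 300
    n_clonotypes_brm: int = 120
    reads_scale_primary: float = 3000.0
    reads_scale_brm: float = 300.0
    zipf_exponent_primary: float = 1.1
    zipf_exponent_brm: float = 1.6
    # survival
    baseline_median_days: float = 440.0  # median OS after BrM diagnosis
    log_hrs: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.04, "stage": 0.35, "score": -0.5}
    )
    censoring_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_primary + self.n_brm < 2:
            problems.append("cohort needs at least 2 samples")
        for name in (
            "tmb_rate_primary", "tmb_rate_brm", "ffpe_artifact_rate",
            "population_contaminant_rate",
        ):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not self.covered_mb > 0:
            problems.append("covered_mb must be > 0")
        if not 0 <= self.fraction_matched_pairs <= 1:
            problems.append("fraction_matched_pairs must be in [0, 1]")
        if self.n_tumor_only > self.n_brm:
            problems.append("n_tumor_only cannot exceed n_brm")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))

    @property
    def n_matched_pairs(self) -> int:
        return int(round(self.fraction_matched_pairs * min(self.n_primary, self.n_brm)))

    @property
    def n_patients(self) -> int:
        return self.n_primary + self.n_brm - self.n_matched_pairs


@dataclass
class GroundTruth:
    """Planted truth for every generated observable."""

    seed: int
    true_variants: dict[str, set[VariantKey]] = field(default_factory=dict)
    artifacts: dict[str, set[VariantKey]] = field(default_factory=dict)
    contaminants: dict[str, set[VariantKey]] = field(default_factory=dict)
    matched_should_pass: dict[str, set[VariantKey]] = field(default_factory=dict)
    tumor_only_should_pass: dict[str, set[VariantKey]] = field(default_factory=dict)
    signature_effects: dict[str, float] = field(default_factory=dict)  # SD units
    clonotype_distributions: dict[tuple[str, str], np.ndarray] = field(
        default_factory=dict
    )
    log_hrs: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    """All pipeline inputs for one simulated cohort, plus ground truth."""

    config: CohortConfig
    samples: pd.DataFrame  # sample_id, patient_id, site, mode
    matched_calls: dict[str, list[VariantCall]]
    tumor_only_calls: dict[str, list[VariantCall]]
    variant_context: dict[str, dict[VariantKey, tuple]]
    rna_support: dict[str, dict[VariantKey, int]]
    alleles: dict[str, list[str]]
    counts: pd.DataFrame  # genes x replicate columns
    coding_reads: dict[str, float]
    replicate_map: dict[str, list[str]]
    signatures: dict[str, list[str]]
    antigen_classes: dict[str, str]
    clonotypes: list[ClonotypeRecord]
    clinical: list[ClinicalRecord]
    truth: GroundTruth

    @property
    def site_of(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["site"]))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _away_from(x: float, thresholds: Sequence[float], eps: float = 0.005) -> float:
    """Nudge a value off any decision threshold so that text round-trips
    and 32-bit INFO storage cannot flip a comparison."""
    x = round(float(x), 4)
    for t in thresholds:
        if abs(x - t) < eps:
            x = t + eps if x >= t else t - eps
    return round(x, 4)


def _random_key(rng: np.random.Generator, variant_class: str) -> VariantKey:
    chrom = f"chr{rng.integers(1, 23)}"
    pos = int(rng.integers(1, 100_000_000))
    if variant_class == "snv":
        ref = _BASES[rng.integers(4)]
        alt = _BASES[rng.integers(4)]
        while alt == ref:
            alt = _BASES[rng.integers(4)]
    else:
        anchor = _BASES[rng.integers(4)]
        ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=rng.integers(1, 4)))
        if rng.random() < 0.5:
            ref, alt = anchor, anchor + ins
        else:
            ref, alt = anchor + ins, anchor
    return (chrom, pos, ref, alt)


def _random_snv_key(rng: np.random.Generator, pair: tuple[str, str]) -> VariantKey:
    chrom = f"chr{rng.integers(1, 23)}"
    pos = int(rng.integers(1, 100_000_000))
    return (chrom, pos, pair[0], pair[1])


def _random_peptide_context(
    rng: np.random.Generator, key: VariantKey
) -> tuple:
    """Protein (SNV) or CDS (indel) context for neoantigen enumeration."""
    aas = np.array(list(AMINO_ACIDS))
    if len(key[2]) == 1 and len(key[3]) == 1:
        protein = "".join(rng.choice(aas, size=41))
        position = 20
        alt_aa = str(rng.choice(aas))
        while alt_aa == protein[position]:
            alt_aa = str(rng.choice(aas))
        return ("snv", protein, position, alt_aa)
    # toy CDS: start codon, random body, then stops in all three frames so
    # frameshift translation always terminates
    body = "".join(_BASES[i] for i in rng.integers(0, 4, size=57))
    cds = "ATG" + body + "TAAATAAATAAA"
    position = int(rng.integers(12, 30))
    ref = cds[position]
    alt = ref + _BASES[rng.integers(4)]
    return ("indel", cds, position, ref, alt)


# ---------------------------------------------------------------------------
# generation-time rule checks (should-pass labels)
# ---------------------------------------------------------------------------


def _gate_ok(call: VariantCall) -> bool:
    gate = _GATES.get((call.caller, call.variant_class))
    if gate is None:  # cadabra SNV: no published gate, excluded
        return False
    return call.quality > gate


def _label_matched_should_pass(calls: Sequence[VariantCall]) -> set[VariantKey]:
    """Generation-time evaluation of the matched cascade on planted calls."""
    gated = [c for c in calls if c.coding and _gate_ok(c)]
    keys_by_caller: dict[str, set[VariantKey]] = {}
    for c in gated:
        keys_by_caller.setdefault(c.caller, set()).add(c.key)
    passing = set()
    for c in gated:
        if c.caller == "cadabra" and c.variant_class == "indel" and c.quality < 35.0:
            if not (
                c.key in keys_by_caller.get("strelka2", set())
                or c.key in keys_by_caller.get("mutect2", set())
            ):
                continue
        if c.caller == "strelka2" and (c.somatic_evs or 0.0) < 20.0:
            if not (
                c.key in keys_by_caller.get("mutect2", set())
                or c.key in keys_by_caller.get("cadabra", set())
            ):
                continue
        passing.add(c.key)
    return passing


def _tumor_only_clauses_ok(c: VariantCall) -> bool:
    if not c.coding:
        return False
    if c.maf >= 0.05:
        if c.alt_reads < 5 or c.depth < 40:
            return False
    else:
        if c.alt_reads < 10 or c.depth < 80:
            return False
    if c.normal_maf is not None and c.normal_maf > 0.05:
        return False
    if c.pop_af_max is not None and c.pop_af_max > 0.01:
        return False
    if (c.ref, c.alt) in FFPE_PAIRS and c.maf < 0.10:
        return False
    return True


# ---------------------------------------------------------------------------
# per-stage generators
# ---------------------------------------------------------------------------


def simulate_matched_calls(
    rng: np.random.Generator,
    sample_id: str,
    variant_keys: Sequence[VariantKey],
    caller_params: Mapping[str, CallerSimParams],
) -> list[VariantCall]:
    """Per-caller detections with quality scores straddling every gate."""
    calls: list[VariantCall] = []
    for key in variant_keys:
        chrom, pos, ref, alt = key
        vclass = "snv" if len(ref) == 1 and len(alt) == 1 else "indel"
        coding = rng.random() < 0.85
        for caller in ("strelka2", "mutect2", "cadabra"):
            params = caller_params[caller]
            if caller == "cadabra" and vclass == "snv":
                continue  # realignment caller emits indels only
            if rng.random() > params.sensitivity:
                continue
            gate = _GATES[(caller, vclass)]
            if rng.random() < params.p_below_gate:
                quality = rng.uniform(max(0.5, gate * 0.2), gate)
            else:
                quality = gate + abs(rng.normal(0.0, params.quality_spread)) + 0.1
            quality = _away_from(quality, _ALL_THRESHOLDS)
            evs = None
            if caller == "strelka2":
                evs = _away_from(rng.uniform(5.0, 45.0), (20.0,))
            calls.append(
                VariantCall(
                    sample_id=sample_id,
                    caller=caller,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    variant_class=vclass,
                    coding=coding,
                    quality=quality,
                    somatic_evs=evs,
                )
            )
    return calls


def simulate_tumor_only_calls(
    rng: np.random.Generator,
    sample_id: str,
    config: CohortConfig,
) -> tuple[list[VariantCall], set[VariantKey], set[VariantKey], set[VariantKey]]:
    """Mutect2-only calls: true variants, FFPE artifacts, contaminants.

    Returns (calls, true_keys, artifact_keys, contaminant_keys).
    """
    maf_thresholds = (0.05, 0.10)
    calls: list[VariantCall] = []
    true_keys: set[VariantKey] = set()
    artifact_keys: set[VariantKey] = set()
    contaminant_keys: set[VariantKey] = set()

    def _support(maf: float) -> tuple[int, int]:
        depth = int(rng.integers(30, 300))
        alt_reads = min(depth, max(0, int(round(depth * maf))))
        return alt_reads, depth

    n_true = rng.poisson(config.tmb_rate_brm * config.covered_mb)
    for _ in range(n_true):
        vclass = "indel" if rng.random() < config.indel_fraction else "snv"
        key = _random_key(rng, vclass)
        maf = _away_from(rng.uniform(0.02, 0.6), maf_thresholds)
        alt_reads, depth = _support(maf)
        normal_maf = None
        if rng.random() < 0.1:
            normal_maf = _away_from(rng.uniform(0.06, 0.3), (0.05,))
        pop_af = _away_from(rng.uniform(0.0, 0.009), (0.01,)) if rng.random() < 0.5 else None
        calls.append(
            VariantCall(
                sample_id=sample_id,
                caller="mutect2",
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                variant_class=vclass,
                coding=rng.random() < 0.85,
                quality=_away_from(rng.uniform(10.0, 60.0), _ALL_THRESHOLDS),
                alt_reads=alt_reads,
                depth=depth,
                maf=maf,
                normal_maf=normal_maf,
                pop_af_max=pop_af,
            )
        )
        true_keys.add(key)

    n_artifacts = rng.poisson(config.ffpe_artifact_rate * config.covered_mb)
    pairs = sorted(FFPE_PAIRS)
    for _ in range(n_artifacts):
        pair = pairs[rng.integers(len(pairs))]
        key = _random_snv_key(rng, pair)
        maf = _away_from(rng.uniform(0.01, 0.09), maf_thresholds)
        if maf >= 0.10:  # defensive: artifacts are defined by MAF < 10%
            maf = 0.09
        alt_reads, depth = _support(maf)
        depth = max(depth, 100)  # well-covered loci: only the FFPE rule fires
        alt_reads = max(alt_reads, 10)
        calls.append(
            VariantCall(
                sample_id=sample_id,
                caller="mutect2",
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                variant_class="snv",
                coding=True,
                quality=_away_from(rng.uniform(10.0, 60.0), _ALL_THRESHOLDS),
                alt_reads=alt_reads,
                depth=depth,
                maf=maf,
                pop_af_max=None,
            )
        )
        artifact_keys.add(key)

    n_contam = rng.poisson(config.population_contaminant_rate * config.covered_mb)
    for _ in range(n_contam):
        key = _random_key(rng, "snv")
        maf = _away_from(rng.uniform(0.3, 0.6), maf_thresholds)
        alt_reads, depth = _support(maf)
        calls.append(
            VariantCall(
                sample_id=sample_id,
                caller="mutect2",
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                variant_class="snv",
                coding=True,
                quality=_away_from(rng.uniform(10.0, 60.0), _ALL_THRESHOLDS),
                alt_reads=alt_reads,
                depth=depth,
                maf=maf,
                pop_af_max=_away_from(rng.uniform(0.02, 0.3), (0.01,)),
            )
        )
        contaminant_keys.add(key)
    return calls, true_keys, artifact_keys, contaminant_keys


def simulate_expression(
    rng: np.random.Generator,
    config: CohortConfig,
    site_of: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, str], dict[str, float]]:
    """Negative-binomial counts with planted group effects.

    Returns (counts genes x samples, signatures, antigen gene classes,
    signature effect sizes in SD units keyed by signature name).
    """
    samples = list(site_of)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    n_sig_genes = config.n_signatures * config.genes_per_signature
    if n_sig_genes + 70 > config.n_genes:
        raise ValueError("n_genes too small for the configured signatures")

    signatures: dict[str, list[str]] = {}
    effects: dict[str, float] = {}
    for i in range(config.n_signatures):
        start = i * config.genes_per_signature
        members = genes[start : start + config.genes_per_signature]
        if i == config.n_signatures - 1:
            name = "Wound_Healing_Serum_Response"
            effects[name] = config.wound_healing_effect_brm
        else:
            name = f"Immune_Sig_{i + 1:02d}"
            effects[name] = (
                config.signature_effect_brm if i < config.n_affected_signatures else 0.0
            )
        signatures[name] = members

    antigen_classes: dict[str, str] = {}
    pool = genes[n_sig_genes : n_sig_genes + 70]
    for j, g in enumerate(pool):
        antigen_classes[g] = "cta_self" if j < 30 else ("erv" if j < 60 else "viral")

    log2_mu = rng.normal(5.0, 1.5, size=config.n_genes)
    lib_scale = np.exp(rng.normal(0.0, 0.3, size=len(samples)))
    counts = np.zeros((config.n_genes, len(samples)))
    sig_index = {name: i for i, name in enumerate(signatures)}
    gene_sig = np.full(config.n_genes, -1)
    for name, members in signatures.items():
        for g in members:
            gene_sig[int(g[1:])] = sig_index[name]

    disp = config.nb_dispersion
    for j, s in enumerate(samples):
        is_brm = site_of[s] == "brm"
        eta_sig = rng.normal(0.0, config.signature_noise_sd, size=len(signatures))
        if is_brm:
            for name, eff in effects.items():
                eta_sig[sig_index[name]] += eff * config.signature_noise_sd
        eta = np.where(gene_sig >= 0, eta_sig[np.clip(gene_sig, 0, None)], 0.0)
        eta = eta + rng.normal(0.0, config.gene_noise_sd, size=config.n_genes)
        mu = lib_scale[j] * np.power(2.0, log2_mu + eta)
        n_param = 1.0 / disp
        p_param = n_param / (n_param + mu)
        counts[:, j] = rng.negative_binomial(n_param, p_param)
    df = pd.DataFrame(counts.astype(int), index=pd.Index(genes, name="gene"), columns=samples)
    return df, signatures, antigen_classes, effects


def simulate_clonotypes(
    rng: np.random.Generator,
    config: CohortConfig,
    site_of: Mapping[str, str],
    chains: Sequence[str] = ("TRA", "TRB", "IGH"),
) -> tuple[list[ClonotypeRecord], dict[tuple[str, str], np.ndarray]]:
    """Zipf-abundance clonotype tables with site-specific scale/diversity."""
    records: list[ClonotypeRecord] = []
    distributions: dict[tuple[str, str], np.ndarray] = {}
    aas = np.array(list(AMINO_ACIDS))
    for sample, site in site_of.items():
        is_brm = site == "brm"
        k_mean = config.n_clonotypes_brm if is_brm else config.n_clonotypes_primary
        scale = config.reads_scale_brm if is_brm else config.reads_scale_primary
        a = config.zipf_exponent_brm if is_brm else config.zipf_exponent_primary
        for chain in chains:
            k = max(2, rng.poisson(k_mean))
            ranks = np.arange(1, k + 1, dtype=float)
            p = ranks ** (-a)
            p /= p.sum()
            total = max(k, int(rng.lognormal(math.log(scale), 0.4)))
            counts = rng.multinomial(total, p)
            seen: set[str] = set()
            for count in counts[counts > 0]:
                while True:
                    cdr3 = "C" + "".join(rng.choice(aas, size=int(rng.integers(8, 13)))) + "F"
                    if cdr3 not in seen:
                        seen.add(cdr3)
                        break
                records.append(
                    ClonotypeRecord(
                        sample_id=sample, chain=chain, cdr3=cdr3, read_count=int(count)
                    )
                )
            distributions[(sample, chain)] = counts[counts > 0].astype(float)
    return records, distributions


def simulate_clinical(
    rng: np.random.Generator,
    config: CohortConfig,
    patient_ids: Sequence[str],
    scores: Optional[Mapping[str, float]] = None,
) -> list[ClinicalRecord]:
    """Clinical covariates and survival times from exponential hazards."""
    h0 = math.log(2.0) / config.baseline_median_days
    log_hrs = dict(config.log_hrs)
    records = []
    for pid in patient_ids:
        age = float(np.clip(rng.normal(47.0, 10.0), 29.0, 71.0))
        stage_idx = rng.choice(4, p=_STAGE_PROBS)
        race = _RACES[rng.choice(4, p=_RACE_PROBS)]
        t_primary = 0.0
        t_met = t_primary + rng.exponential(1.8 * 365.0)
        t_brm = t_met + rng.exponential(0.5 * 365.0)
        lp = log_hrs.get("age", 0.0) * (age - 47.0) / 10.0
        lp += log_hrs.get("stage", 0.0) * (stage_idx + 1 - 2)
        if scores is not None and pid in scores:
            lp += log_hrs.get("score", 0.0) * scores[pid]
        delay = rng.exponential(1.0 / (h0 * math.exp(lp)))
        if rng.random() < config.censoring_prob:
            t_event = t_brm + rng.uniform(0.0, max(delay, 1.0))
            event = False
        else:
            t_event = t_brm + delay
            event = True
        records.append(
            ClinicalRecord(
                patient_id=pid,
                age_at_primary_dx=round(age, 1),
                stage=("I", "II", "III", "IV")[stage_idx],
                race=race,
                t_primary_dx=round(t_primary, 1),
                t_met_dx=round(t_met, 1),
                t_brm_dx=round(t_brm, 1),
                t_event=round(t_event, 1),
                event=event,
            )
        )
    return records


def simulate_survival_cohort(
    rng: np.random.Generator,
    n: int = 200,
    true_log_hr: float = math.log(2.0),
    baseline_median_days: float = 500.0,
    censoring_horizon_days: float = 3000.0,
) -> pd.DataFrame:
    """Single-covariate survival cohort for parameter-recovery studies.

    A standard-normal score drives an exponential hazard with the given
    true log hazard ratio; administrative censoring at a fixed horizon.
    """
    score = rng.normal(0.0, 1.0, size=n)
    h0 = math.log(2.0) / baseline_median_days
    times = rng.exponential(1.0 / (h0 * np.exp(true_log_hr * score)))
    event = times <= censoring_horizon_days
    times = np.minimum(times, censoring_horizon_days)
    return pd.DataFrame(
        {
            "patient_id": [f"S{i:04d}" for i in range(n)],
            "time": np.maximum(times, 0.5),
            "event": event.astype(int),
            "score": score,
        }
    )


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(seed=config.seed, log_hrs=dict(config.log_hrs))

    n_pairs = config.n_matched_pairs
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    rows = []
    # first n_pairs patients have both sites; then the remaining primaries,
    # then the remaining BrM (the last n_tumor_only of which lack a normal)
    for i in range(n_pairs):
        rows.append((f"{patients[i]}-PRI", patients[i], "primary", "matched"))
        rows.append((f"{patients[i]}-BRM", patients[i], "brm", "matched"))
    idx = n_pairs
    for _ in range(config.n_primary - n_pairs):
        rows.append((f"{patients[idx]}-PRI", patients[idx], "primary", "matched"))
        idx += 1
    n_brm_only = config.n_brm - n_pairs
    for j in range(n_brm_only):
        mode = "tumor_only" if j >= n_brm_only - config.n_tumor_only else "matched"
        rows.append((f"{patients[idx]}-BRM", patients[idx], "brm", mode))
        idx += 1
    samples = pd.DataFrame(rows, columns=["sample_id", "patient_id", "site", "mode"])

    # --- somatic variants -------------------------------------------------
    matched_calls: dict[str, list[VariantCall]] = {}
    tumor_only_calls: dict[str, list[VariantCall]] = {}
    variant_context: dict[str, dict[VariantKey, tuple]] = {}
    rna_support: dict[str, dict[VariantKey, int]] = {}
    alleles: dict[str, list[str]] = {}

    pair_shared: dict[str, list[VariantKey]] = {}
    for row in samples.itertuples(index=False):
        rate = config.tmb_rate_brm if row.site == "brm" else config.tmb_rate_primary
        alleles[row.sample_id] = sorted(
            rng.choice(_HLA_POOL, size=3, replace=False).tolist()
        )
        if row.mode == "tumor_only":
            calls, true_keys, artifact_keys, contam_keys = simulate_tumor_only_calls(
                rng, row.sample_id, config
            )
            tumor_only_calls[row.sample_id] = calls
            truth.true_variants[row.sample_id] = true_keys
            truth.artifacts[row.sample_id] = artifact_keys
            truth.contaminants[row.sample_id] = contam_keys
            truth.tumor_only_should_pass[row.sample_id] = {
                c.key for c in calls if _tumor_only_clauses_ok(c)
            }
            keys_for_context = truth.tumor_only_should_pass[row.sample_id]
        else:
            n_true = rng.poisson(rate * config.covered_mb)
            keys = []
            if row.patient_id in pair_shared:  # BrM half of a matched pair
                shared = pair_shared[row.patient_id]
                take = int(rng.uniform(0.2, 0.6) * len(shared))
                keys.extend(shared[:take])
            while len(keys) < max(n_true, 1):
                vclass = "indel" if rng.random() < config.indel_fraction else "snv"
                keys.append(_random_key(rng, vclass))
            if row.site == "primary" and (samples["patient_id"] == row.patient_id).sum() > 1:
                pair_shared[row.patient_id] = keys
            calls = simulate_matched_calls(rng, row.sample_id, keys, config.caller_params)
            matched_calls[row.sample_id] = calls
            truth.true_variants[row.sample_id] = set(keys)
            truth.matched_should_pass[row.sample_id] = _label_matched_should_pass(calls)
            keys_for_context = truth.matched_should_pass[row.sample_id]

        ctx = {key: _random_peptide_context(rng, key) for key in sorted(keys_for_context)}
        variant_context[row.sample_id] = ctx
        rna_support[row.sample_id] = {
            key: (int(rng.poisson(10)) + 1 if rng.random() < 0.7 else 0)
            for key in sorted(keys_for_context)
        }

    # --- expression -------------------------------------------------------
    site_of = dict(zip(samples["sample_id"], samples["site"]))
    counts_bio, signatures, antigen_classes, effects = simulate_expression(
        rng, config, site_of
    )
    truth.signature_effects = effects

    replicate_map: dict[str, list[str]] = {}
    rep_samples = list(counts_bio.columns[: config.n_replicated_samples])
    counts_cols = {}
    for s in counts_bio.columns:
        if s in rep_samples:
            base = counts_bio[s].to_numpy(dtype=float)
            for r in (1, 2):
                noisy = rng.poisson(np.maximum(base, 0.0) * rng.uniform(0.9, 1.1))
                counts_cols[f"{s}_r{r}"] = noisy
            replicate_map[s] = [f"{s}_r1", f"{s}_r2"]
        else:
            counts_cols[s] = counts_bio[s].to_numpy()
            replicate_map[s] = [s]
    counts = pd.DataFrame(counts_cols, index=counts_bio.index)

    coding_reads = {}
    cols = list(counts.columns)
    fail = set(cols[: config.n_qc_fail])
    for c in cols:
        if c in fail:
            coding_reads[c] = float(rng.uniform(5e6, 1.9e7))
        else:
            coding_reads[c] = float(rng.uniform(2.1e7, 6e7))

    # --- clonotypes, clinical --------------------------------------------
    clonotypes, distributions = simulate_clonotypes(rng, config, site_of)
    truth.clonotype_distributions = distributions

    clinical = simulate_clinical(rng, config, patients)

    return SyntheticCohort(
        config=config,
        samples=samples,
        matched_calls=matched_calls,
        tumor_only_calls=tumor_only_calls,
        variant_context=variant_context,
        rna_support=rna_support,
        alleles=alleles,
        counts=counts,
        coding_reads=coding_reads,
        replicate_map=replicate_map,
        signatures=signatures,
        antigen_classes=antigen_classes,
        clonotypes=clonotypes,
        clinical=clinical,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------


def evaluate_recovery(outputs: Mapping[str, object], truth: GroundTruth) -> dict:
    """Compare pipeline outputs against planted ground truth.

    ``outputs`` must carry the generating ``seed`` plus any of:
    ``consensus`` (sample -> ConsensusVariantSet), ``signature_results``
    (list of GroupComparisonResult), ``cox_results`` (forest DataFrame).
    """
    if outputs.get("seed") != truth.seed:
        raise ValueError(
            f"outputs generated with seed {outputs.get('seed')} but truth "
            f"has seed {truth.seed}"
        )
    report: dict = {"seed": truth.seed}

    consensus = outputs.get("consensus", {})
    n_artifacts = n_artifacts_retained = 0
    n_should = n_should_retained = 0
    for sample, cvs in consensus.items():
        keys = cvs.keys
        for artifact in truth.artifacts.get(sample, set()):
            n_artifacts += 1
            if artifact in keys:
                n_artifacts_retained += 1
        should = truth.tumor_only_should_pass.get(
            sample, truth.matched_should_pass.get(sample, set())
        )
        n_should += len(should)
        n_should_retained += len(should & keys)
    if n_artifacts:
        report["artifact_removal_rate"] = 1.0 - n_artifacts_retained / n_artifacts
        report["n_planted_artifacts"] = n_artifacts
    if n_should:
        report["true_variant_retention"] = n_should_retained / n_should
        report["n_should_pass"] = n_should

    sig_results = outputs.get("signature_results")
    if sig_results is not None:
        affected = {s for s, e in truth.signature_effects.items() if e != 0.0}
        detected = {r.signature for r in sig_results if r.q < 0.05}
        if affected:
            report["signature_effect_detection_rate"] = len(affected & detected) / len(
                affected
            )
        null = {s for s, e in truth.signature_effects.items() if e == 0.0}
        if null:
            report["signature_false_positive_rate"] = len(null & detected) / len(null)

    cox = outputs.get("cox_results")
    if cox is not None and len(cox):
        report["cox_converged_fraction"] = float(np.mean(cox["converged"]))

    return report
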
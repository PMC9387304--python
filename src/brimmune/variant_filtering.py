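"""Somatic-variant consensus filtering, TMB, and matched-pair sharing.

Two filter cascades are implemented:

* **Matched-normal mode** (:func:`filter_matched`) — the union over
  Strelka2, Mutect2 and Cadabra of protein-coding calls passing per-caller
  quality gates, with cross-caller corroboration required for two
  low-confidence classes (Cadabra indels below quality 35, Strelka2 calls
  with SomaticEVS below 20).

* **Tumor-only mode** (:func:`filter_tumor_only`) — Mutect2 calls filtered
  on coding status, read support conditional on allele fraction, normal
  contamination, population allele frequency, and an FFPE deamination rule
  requiring C>T / G>A substitutions to reach 10% allele fraction.

Tumor mutational burden is the retained variant count divided by the
megabases adequately covered by sequencing reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_formats import VariantCall

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class FilterConfig:
    """All published filter thresholds, overridable per run.

    Quality gates are strict ``>`` comparisons on the caller's own score
    scale; corroboration cutoffs are strict ``<``.
    """

    cadabra_indel_quality: float = 10.5
    mutect2_indel_quality: float = 6.8
    mutect2_snv_quality: float = 9.2
    strelka2_indel_quality: float = 15.2
    strelka2_snv_quality: float = 19.7
    cadabra_corroboration_quality: float = 35.0
    strelka2_corroboration_evs: float = 20.0
    #: corroborating calls must pass their own quality gate
    require_corroborator_gate: bool = True
    #: Cadabra SNVs have no published gate; excluded unless a threshold is set
    cadabra_snv_quality: Optional[float] = None
    # tumor-only clauses
    min_alt_reads: int = 5
    min_depth: int = 40
    low_maf_cutoff: float = 0.05
    low_maf_min_alt_reads: int = 10
    low_maf_min_depth: int = 80
    max_normal_maf: float = 0.05
    max_pop_af: float = 0.01
    ffpe_min_maf: float = 0.10
    #: apply the FFPE C>T/G>A rule in matched mode too
    ffpe_in_matched: bool = False


DEFAULT_FILTER_CONFIG = FilterConfig()

#: literal (ref, alt) pairs subject to the FFPE deamination rule
FFPE_PAIRS = frozenset({("C", "T"), ("G", "A")})


@dataclass
class ConsensusVariantSet:
    """Deduplicated somatic variants surviving a filter cascade.

    ``provenance`` maps each retained (chrom, pos, ref, alt) key to the
    list of (caller, quality) pairs that supported it past their gates.
    """

    sample_id: str
    provenance: dict[VariantKey, list[tuple[str, float]]] = field(default_factory=dict)

    @property
    def keys(self) -> set[VariantKey]:
        return set(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "chrom": k[0],
                "pos": k[1],
                "ref": k[2],
                "alt": k[3],
                "callers": ",".join(c for c, _ in sorted(prov)),
                "qualities": ",".join(f"{q:.6g}" for _, q in sorted(prov)),
            }
            for k, prov in sorted(self.provenance.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["sample_id", "chrom", "pos", "ref", "alt", "callers", "qualities"],
        )


@dataclass(frozen=True)
class TmbResult:
    sample_id: str
    n_variants: int
    covered_mb: float
    tmb: float


@dataclass(frozen=True)
class PairSharing:
    patient_id: str
    n_shared: int
    n_only_a: int
    n_only_b: int
    jaccard: float
    fraction_shared_of_a: float
    fraction_shared_of_b: float


def _passes_gate(call: VariantCall, cfg: FilterConfig) -> bool:
    """Per-caller, per-class quality gate (strict >)."""
    if call.caller == "cadabra":
        if call.variant_class == "indel":
            return call.quality > cfg.cadabra_indel_quality
        if cfg.cadabra_snv_quality is None:
            return False
        return call.quality > cfg.cadabra_snv_quality
    if call.caller == "mutect2":
        gate = (
            cfg.mutect2_indel_quality
            if call.variant_class == "indel"
            else cfg.mutect2_snv_quality
        )
        return call.quality > gate
    # strelka2
    gate = (
        cfg.strelka2_indel_quality
        if call.variant_class == "indel"
        else cfg.strelka2_snv_quality
    )
    return call.quality > gate


def filter_matched(
    calls: Sequence[VariantCall],
    config: FilterConfig = DEFAULT_FILTER_CONFIG,
) -> ConsensusVariantSet:
    """Apply the matched-normal consensus cascade to one tumor's calls.

    Rules, in order: (R1) protein-coding only; (R2) per-caller quality
    gates; (R3) corroboration for low-confidence Cadabra indels
    (quality < 35) and low-EVS Strelka2 calls (SomaticEVS < 20), each
    requiring a gate-passing call from another caller at the same
    (chrom, pos, ref, alt); (R4) deduplication with caller provenance.
    """
    if not calls:
        raise ValueError("no calls supplied")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"calls span multiple samples: {sorted(sample_ids)}")
    (sample_id,) = sample_ids

    for c in calls:
        if c.caller == "strelka2" and c.somatic_evs is None:
            raise ValueError(
                f"strelka2 call {c.chrom}:{c.pos} {c.ref}>{c.alt} missing SomaticEVS"
            )

    coding = [c for c in calls if c.coding]
    gated = [c for c in coding if _passes_gate(c, config)]
    if config.ffpe_in_matched:
        gated = [
            c
            for c in gated
            if (c.ref, c.alt) not in FFPE_PAIRS
            or (c.maf is not None and c.maf >= config.ffpe_min_maf)
        ]

    # corroborator index: keys with a gate-passing (or any coding, if the
    # gate requirement is relaxed) call, per caller
    pool = gated if config.require_corroborator_gate else coding
    keys_by_caller: dict[str, set[VariantKey]] = {}
    for c in pool:
        keys_by_caller.setdefault(c.caller, set()).add(c.key)

    retained: list[VariantCall] = []
    for c in gated:
        if (
            c.caller == "cadabra"
            and c.variant_class == "indel"
            and c.quality < config.cadabra_corroboration_quality
        ):
            supported = c.key in keys_by_caller.get("strelka2", set()) or (
                c.key in keys_by_caller.get("mutect2", set())
            )
            if not supported:
                continue
        if c.caller == "strelka2" and c.somatic_evs < config.strelka2_corroboration_evs:
            supported = c.key in keys_by_caller.get("mutect2", set()) or (
                c.key in keys_by_caller.get("cadabra", set())
            )
            if not supported:
                continue
        retained.append(c)

    result = ConsensusVariantSet(sample_id=sample_id)
    for c in retained:
        result.provenance.setdefault(c.key, []).append((c.caller, c.quality))
    return result


def filter_tumor_only(
    calls: Sequence[VariantCall],
    config: FilterConfig = DEFAULT_FILTER_CONFIG,
) -> ConsensusVariantSet:
    """Apply the tumor-only (Mutect2) filter cascade.

    A call is retained iff all of: protein-coding; read support
    (alt_reads >= 5 and depth >= 40, tightened to 10/80 when MAF < 5%);
    normal MAF absent or <= 5%; max subpopulation allele frequency absent
    or <= 1%; and, for C>T / G>A substitutions, MAF >= 10% (FFPE rule).
    """
    if not calls:
        raise ValueError("no calls supplied")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"calls span multiple samples: {sorted(sample_ids)}")
    (sample_id,) = sample_ids

    result = ConsensusVariantSet(sample_id=sample_id)
    for c in calls:
        if c.caller != "mutect2":
            raise ValueError(
                f"tumor-only mode expects mutect2 calls, got {c.caller!r}"
            )
        if c.alt_reads is None or c.depth is None or c.maf is None:
            raise ValueError(
                f"call {c.chrom}:{c.pos} {c.ref}>{c.alt} missing "
                "alt_reads/depth/maf required for tumor-only filtering"
            )
        if not c.coding:
            continue
        if c.maf >= config.low_maf_cutoff:
            if c.alt_reads < config.min_alt_reads or c.depth < config.min_depth:
                continue
        else:
            if (
                c.alt_reads < config.low_maf_min_alt_reads
                or c.depth < config.low_maf_min_depth
            ):
                continue
        if c.normal_maf is not None and c.normal_maf > config.max_normal_maf:
            continue
        if c.pop_af_max is not None and c.pop_af_max > config.max_pop_af:
            continue
        if (c.ref, c.alt) in FFPE_PAIRS and c.maf < config.ffpe_min_maf:
            continue
        result.provenance.setdefault(c.key, []).append((c.caller, c.quality))
    return result


def compute_tmb(variants: ConsensusVariantSet, covered_mb: float) -> TmbResult:
    """Mutations per megabase of adequately covered sequence."""
    if not covered_mb > 0:
        raise ValueError(f"covered_mb must be > 0, got {covered_mb}")
    n = len(variants)
    return TmbResult(
        sample_id=variants.sample_id,
        n_variants=n,
        covered_mb=covered_mb,
        tmb=n / covered_mb,
    )


def covered_megabases(depth_intervals: pd.DataFrame, min_depth: int = 20) -> float:
    """Megabases with depth >= ``min_depth``.

    ``depth_intervals`` has columns chrom, start, end, depth with 1-based
    inclusive coordinates and a uniform depth per interval.
    """
    required = {"chrom", "start", "end", "depth"}
    missing = required - set(depth_intervals.columns)
    if missing:
        raise ValueError(f"depth summary missing columns {sorted(missing)}")
    if len(depth_intervals) == 0:
        raise ValueError("empty depth-interval list")
    ok = depth_intervals["depth"] >= min_depth
    bases = (
        depth_intervals.loc[ok, "end"] - depth_intervals.loc[ok, "start"] + 1
    ).sum()
    return float(bases) / 1e6


def pair_sharing(
    set_a: ConsensusVariantSet,
    set_b: ConsensusVariantSet,
    patient_id: Optional[str] = None,
) -> PairSharing:
    """Exact variant sharing between two consensus sets keyed on
    (chrom, pos, ref, alt)."""
    a, b = set_a.keys, set_b.keys
    shared = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    union = shared + only_a + only_b
    return PairSharing(
        patient_id=patient_id or f"{set_a.sample_id}|{set_b.sample_id}",
        n_shared=shared,
        n_only_a=only_a,
        n_only_b=only_b,
        jaccard=shared / union if union else 0.0,
        fraction_shared_of_a=shared / len(a) if a else 0.0,
        fraction_shared_of_b=shared / len(b) if b else 0.0,
    )


def gene_mutation_counts(
    consensus_sets: Iterable[ConsensusVariantSet],
    gene_of: Mapping[VariantKey, str],
) -> pd.DataFrame:
    """Per-gene mutated-sample counts (tabular alternative to an oncoprint)."""
    rows = []
    for cvs in consensus_sets:
        genes = {gene_of[k] for k in cvs.keys if k in gene_of}
        rows.extend({"sample_id": cvs.sample_id, "gene": g} for g in genes)
    if not rows:
        return pd.DataFrame(columns=["gene", "n_samples"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("gene")["sample_id"]
        .nunique()
        .rename("n_samples")
        .reset_index()
        .sort_values(["n_samples", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out
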
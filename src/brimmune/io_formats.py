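"""Readers and writers for the external formats the pipeline touches.

Every downstream module consumes only the domain types defined here:
:class:`VariantCall`, :class:`SegmentRecord`, :class:`ClonotypeRecord` and
:class:`ClinicalRecord`, plus plain pandas tables for expression matrices,
gene sets and clinical data.

Conventions
-----------
* Coordinates are 1-based inclusive throughout (VCF convention); SEG output
  is also 1-based inclusive.
* Per-caller VCF quality fields are configuration
  (:class:`CallerFieldMap`), because published thresholds name scores, not
  VCF keys.  Defaults: Strelka2 -> INFO/QSS (plus INFO/SomaticEVS),
  Mutect2 -> INFO/TLOD, Cadabra -> the QUAL column.
* The "coding" flag is read from a single configured annotation key whose
  value is matched against a whitelist of coding consequence terms; no
  annotation engine is embedded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

CALLERS = ("strelka2", "mutect2", "cadabra")
CHAINS = ("TRA", "TRB", "IGH", "IGK", "IGL")
STAGES = ("I", "II", "III", "IV")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: consequence terms treated as protein-coding mutations
CODING_CONSEQUENCES = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "synonymous_variant",
        "protein_altering_variant",
    }
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantCall:
    """One caller's somatic call at a locus with quality/support annotations.

    ``quality`` is the caller-reported score on the caller's own scale
    (unitless); ``somatic_evs`` is present only for Strelka2 calls;
    ``pop_af_max`` is the maximum subpopulation allele frequency over
    gnomAD / 1000 Genomes annotations.
    """

    sample_id: str
    caller: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    coding: bool
    quality: float
    somatic_evs: Optional[float] = None
    alt_reads: Optional[int] = None
    depth: Optional[int] = None
    maf: Optional[float] = None
    normal_maf: Optional[float] = None
    pop_af_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        expected = "snv" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"
        if self.variant_class != expected:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with "
                f"alleles {self.ref}>{self.alt}"
            )
        if (
            self.alt_reads is not None
            and self.depth is not None
            and self.alt_reads > self.depth
        ):
            raise ValueError("alt_reads exceeds depth")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SegmentRecord:
    """A copy-number segment with Sequenza's raw depth ratio."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_markers: int
    depth_ratio: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if not self.depth_ratio > 0:
            raise ValueError(
                f"depth_ratio must be > 0 for segment "
                f"{self.sample_id}:{self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class ClonotypeRecord:
    """One immune-receptor clonotype: chain, CDR3 amino-acid sequence, reads."""

    sample_id: str
    chain: str
    cdr3: str
    read_count: int

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        bad = set(self.cdr3) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"cdr3 contains non-standard residues {sorted(bad)}")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical covariates and event times (day offsets)."""

    patient_id: str
    age_at_primary_dx: float
    stage: str
    race: str
    t_primary_dx: Optional[float]
    t_met_dx: Optional[float]
    t_brm_dx: Optional[float]
    t_event: Optional[float]
    event: bool

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        times = [
            t
            for t in (self.t_primary_dx, self.t_met_dx, self.t_brm_dx, self.t_event)
            if t is not None and not (isinstance(t, float) and math.isnan(t))
        ]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"event times out of order for {self.patient_id}")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CallerFieldMap:
    """Where to find a caller's quality score and annotations in a VCF.

    ``quality_field`` is either the literal string ``"QUAL"`` (the VCF QUAL
    column) or an INFO key.  ``evs_field`` names the Strelka2 empirical
    variant score INFO key, if any.
    """

    quality_field: str
    evs_field: Optional[str] = None
    coding_field: str = "CONSEQ"
    coding_terms: frozenset[str] = CODING_CONSEQUENCES


DEFAULT_FIELD_MAPS: Mapping[str, CallerFieldMap] = {
    "strelka2": CallerFieldMap(quality_field="QSS", evs_field="SomaticEVS"),
    "mutect2": CallerFieldMap(quality_field="TLOD"),
    "cadabra": CallerFieldMap(quality_field="QUAL"),
}

_OPTIONAL_INFO = {
    "alt_reads": ("ALTREADS", int),
    "depth": ("DP", int),
    "maf": ("MAF", float),
    "normal_maf": ("NMAF", float),
    "pop_af_max": ("POPAFMAX", float),
}


def _per_alt(value, i: int, n_alt: int):
    """Pick the i-th element of a per-ALT INFO value, else the scalar."""
    if isinstance(value, (tuple, list, np.ndarray)):
        if len(value) == n_alt:
            return value[i]
        return value[0]
    return value


def read_caller_calls(
    path: str | Path,
    caller: str,
    sample_id: Optional[str] = None,
    field_map: Optional[CallerFieldMap] = None,
) -> list[VariantCall]:
    """Read one caller's VCF into :class:`VariantCall` records.

    Multiallelic records are split into one record per ALT allele.  The
    quality score is taken from the configured per-caller field and the
    coding flag from the configured annotation key.
    """
    if caller not in CALLERS:
        raise ValueError(f"unknown caller {caller!r}")
    fmap = field_map or DEFAULT_FIELD_MAPS[caller]
    path = str(path)
    vcf = VCF(path)
    if sample_id is None:
        sample_id = Path(path).stem.split(".")[0]
    calls: list[VariantCall] = []
    for rec in vcf:
        alts = rec.ALT
        n_alt = len(alts)
        for i, alt in enumerate(alts):
            if fmap.quality_field == "QUAL":
                quality = rec.QUAL
            else:
                quality = rec.INFO.get(fmap.quality_field)
                quality = _per_alt(quality, i, n_alt)
            if quality is None:
                raise ValueError(
                    f"{path}: record {rec.CHROM}:{rec.POS} missing quality "
                    f"field {fmap.quality_field!r} for caller {caller}"
                )
            conseq = rec.INFO.get(fmap.coding_field)
            coding = conseq is not None and str(conseq) in fmap.coding_terms
            evs = None
            if fmap.evs_field is not None:
                evs = rec.INFO.get(fmap.evs_field)
                if evs is not None:
                    evs = float(_per_alt(evs, i, n_alt))
            kwargs = {}
            for attr, (key, cast) in _OPTIONAL_INFO.items():
                val = rec.INFO.get(key)
                if val is not None:
                    kwargs[attr] = cast(_per_alt(val, i, n_alt))
            ref = rec.REF
            vclass = "snv" if len(ref) == 1 and len(alt) == 1 else "indel"
            calls.append(
                VariantCall(
                    sample_id=sample_id,
                    caller=caller,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=ref,
                    alt=alt,
                    variant_class=vclass,
                    coding=coding,
                    quality=float(quality),
                    somatic_evs=evs,
                    **kwargs,
                )
            )
    return calls


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Variant consequence">
##INFO=<ID=QSS,Number=1,Type=Float,Description="Strelka2 somatic SNV/indel quality score">
##INFO=<ID=SomaticEVS,Number=1,Type=Float,Description="Strelka2 empirical variant score">
##INFO=<ID=TLOD,Number=1,Type=Float,Description="Mutect2 tumor log-odds">
##INFO=<ID=ALTREADS,Number=1,Type=Integer,Description="Alt-supporting reads">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Mutant allele fraction">
##INFO=<ID=NMAF,Number=1,Type=Float,Description="Mutant allele fraction in normal">
##INFO=<ID=POPAFMAX,Number=1,Type=Float,Description="Max subpopulation allele frequency">
"""


def write_caller_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    field_map: Optional[CallerFieldMap] = None,
) -> None:
    """Write calls (one caller, one sample) as an uncompressed VCF v4.2."""
    if calls:
        callers = {c.caller for c in calls}
        if len(callers) > 1:
            raise ValueError("write_caller_vcf expects calls from a single caller")
        fmap = field_map or DEFAULT_FIELD_MAPS[calls[0].caller]
    else:
        fmap = field_map or CallerFieldMap(quality_field="QUAL")
    chroms = sorted({c.chrom for c in calls})
    lines = [_VCF_HEADER.rstrip("\n")]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in sorted(calls, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info = [f"CONSEQ={'missense_variant' if c.coding else 'intron_variant'}"]
        qual_col = "."
        if fmap.quality_field == "QUAL":
            qual_col = f"{c.quality:.10g}"
        else:
            info.append(f"{fmap.quality_field}={c.quality:.10g}")
        if c.somatic_evs is not None and fmap.evs_field is not None:
            info.append(f"{fmap.evs_field}={c.somatic_evs:.10g}")
        for attr, (key, _) in _OPTIONAL_INFO.items():
            val = getattr(c, attr)
            if val is not None:
                info.append(f"{key}={val:.10g}" if isinstance(val, float) else f"{key}={val}")
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{qual_col}\tPASS\t"
            + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# variant-call tabular dialect (TSV round trip)
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "sample_id",
    "caller",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "coding",
    "quality",
    "somatic_evs",
    "alt_reads",
    "depth",
    "maf",
    "normal_maf",
    "pop_af_max",
]


def write_variant_calls(calls: Iterable[VariantCall], path: str | Path) -> None:
    rows = [{col: getattr(c, col) for col in _CALL_COLUMNS} for c in calls]
    df = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_variant_calls(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for k in ("somatic_evs", "maf", "normal_maf", "pop_af_max"):
            if pd.isna(d[k]):
                d[k] = None
        for k in ("alt_reads", "depth"):
            d[k] = None if pd.isna(d[k]) else int(d[k])
        d["coding"] = bool(d["coding"])
        d["pos"] = int(d["pos"])
        d["quality"] = float(d["quality"])
        calls.append(VariantCall(**d))
    return calls


# ---------------------------------------------------------------------------
# copy-number segment conversion
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Seg.CN"]


def sequenza_to_gistic_seg(segments: Sequence[SegmentRecord]) -> pd.DataFrame:
    """Convert Sequenza depth-ratio segments to a 6-column SEG table.

    ``Seg.CN = log2(depth_ratio) - 1``, the transformation used to feed
    Sequenza output into GISTIC.  Note this maps a copy-neutral depth ratio
    of 1 to -1 rather than 0; the convention is reproduced exactly as
    published and is flagged in the package docs.
    """
    rows = []
    for s in segments:
        if not s.depth_ratio > 0:  # defensive; the dataclass enforces it
            raise ValueError(
                f"non-positive depth ratio in segment "
                f"{s.sample_id}:{s.chrom}:{s.start}-{s.end}"
            )
        rows.append(
            {
                "Sample": s.sample_id,
                "Chromosome": s.chrom,
                "Start": s.start,
                "End": s.end,
                "Num_Probes": s.n_markers,
                "Seg.CN": math.log2(s.depth_ratio) - 1.0,
            }
        )
    return pd.DataFrame(rows, columns=SEG_COLUMNS)


def read_segments(path: str | Path) -> list[SegmentRecord]:
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "chrom", "start", "end", "n_markers", "depth_ratio"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns {sorted(missing)}")
    return [
        SegmentRecord(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            n_markers=int(r.n_markers),
            depth_ratio=float(r.depth_ratio),
        )
        for r in df.itertuples(index=False)
    ]


def write_segments(segments: Iterable[SegmentRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_markers": s.n_markers,
                "depth_ratio": s.depth_ratio,
            }
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrix / GMT / clonotypes / clinical
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column ``gene``) into a DataFrame.

    Duplicate gene symbols are an error: the matrix contract requires
    unique symbols after load.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("expression matrix missing required column 'gene'")
    df = df.set_index("gene")
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene symbols in expression matrix: {dupes}")
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("gene").to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file; duplicate symbols within a set are dropped
    (first occurrence kept)."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno}: expected name, description, genes")
        name = parts[0]
        genes = list(dict.fromkeys(g for g in parts[2:] if g))
        sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


#: AIRR-style clonotype TSV columns
CLONOTYPE_COLUMNS = ["sample_id", "locus", "junction_aa", "duplicate_count"]


def read_clonotypes(path: str | Path) -> list[ClonotypeRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CLONOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clonotype table missing columns {sorted(missing)}")
    return [
        ClonotypeRecord(
            sample_id=str(r.sample_id),
            chain=str(r.locus),
            cdr3=str(r.junction_aa),
            read_count=int(r.duplicate_count),
        )
        for r in df.itertuples(index=False)
    ]


def write_clonotypes(records: Iterable[ClonotypeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "locus": r.chain,
                "junction_aa": r.cdr3,
                "duplicate_count": r.read_count,
            }
            for r in records
        ],
        columns=CLONOTYPE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


CLINICAL_COLUMNS = [
    "patient_id",
    "age_at_primary_dx",
    "stage",
    "race",
    "t_primary_dx",
    "t_met_dx",
    "t_brm_dx",
    "t_event",
    "event",
]


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns {sorted(missing)}")
    records = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        for k in ("t_primary_dx", "t_met_dx", "t_brm_dx", "t_event"):
            d[k] = None if pd.isna(d[k]) else float(d[k])
        records.append(
            ClinicalRecord(
                patient_id=str(d["patient_id"]),
                age_at_primary_dx=float(d["age_at_primary_dx"]),
                stage=str(d["stage"]),
                race=str(d["race"]),
                t_primary_dx=d["t_primary_dx"],
                t_met_dx=d["t_met_dx"],
                t_brm_dx=d["t_brm_dx"],
                t_event=d["t_event"],
                event=bool(d["event"]),
            )
        )
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "age_at_primary_dx": r.age_at_primary_dx,
                "stage": r.stage,
                "race": r.race,
                "t_primary_dx": r.t_primary_dx,
                "t_met_dx": r.t_met_dx,
                "t_brm_dx": r.t_brm_dx,
                "t_event": r.t_event,
                "event": r.event,
            }
            for r in records
        ],
        columns=CLINICAL_COLUMNS,
    ).to_csv(path, index=False)
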
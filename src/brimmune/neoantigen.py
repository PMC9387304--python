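"""Candidate MHC class I peptide enumeration and binder classification.

Tumor antigen sources span SNVs, indels (frameshift and in-frame), gene
fusions, alternative splice junctions, cancer/testis and overexpressed
self-antigens, endogenous retroviruses, and other viral transcripts.  For
the variant-derived classes, candidate peptides are every 8–11-mer window
of the mutant protein that contains at least one residue absent from the
corresponding position of the normal proteome.

Affinity prediction is a pluggable interface: any callable
``(peptide, allele) -> kd_nm`` can be used.  A deterministic toy
position-weight predictor is bundled so the full pipeline runs and is
testable without an external tool.  Peptides with predicted Kd < 500 nM
are positive binders; Kd < 50 nM are strong binders (strict inequalities).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import AMINO_ACIDS
from .variant_filtering import ConsensusVariantSet, VariantKey

DEFAULT_LENGTHS = (8, 9, 10, 11)

POSITIVE_BINDER_NM = 500.0
STRONG_BINDER_NM = 50.0

SOURCE_CLASSES = ("snv", "indel", "fusion", "splice", "cta_self", "erv", "viral")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class PeptideCandidate:
    """A candidate MHC-I peptide with its antigen source class.

    ``novel_positions`` are 0-based indices within the peptide that differ
    from every window of the normal proteome context (for variant-derived
    classes they are the mutated/novel residues).
    """

    sample_id: str
    source_class: str
    peptide: str
    source_id: str
    novel_positions: frozenset[int]

    def __post_init__(self) -> None:
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(f"unknown source class {self.source_class!r}")
        if not 8 <= len(self.peptide) <= 11:
            raise ValueError(f"peptide length {len(self.peptide)} outside 8-11")
        if self.source_class in ("snv", "indel", "fusion") and not self.novel_positions:
            raise ValueError("variant-derived peptide has no novel positions")


@dataclass(frozen=True)
class AffinityPrediction:
    peptide: str
    allele: str
    kd_nm: float

    def __post_init__(self) -> None:
        if not self.kd_nm > 0:
            raise ValueError("kd_nm must be > 0")


@dataclass(frozen=True)
class BinderCounts:
    """Per-source counts of positive (<500 nM) and strong (<50 nM) binders."""

    sample_id: str
    counts: Mapping[str, tuple[int, int]]  # class -> (n_positive, n_strong)

    def n_positive(self, source_class: str) -> int:
        return self.counts.get(source_class, (0, 0))[0]

    def n_strong(self, source_class: str) -> int:
        return self.counts.get(source_class, (0, 0))[1]


# ---------------------------------------------------------------------------
# peptide enumeration
# ---------------------------------------------------------------------------


def enumerate_snv_peptides(
    protein: str,
    position: int,
    alt_aa: str,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    sample_id: str = "",
    source_id: str = "",
) -> list[PeptideCandidate]:
    """All k-mer windows of the mutant protein covering a substituted residue.

    An interior substitution yields exactly k windows per length k;
    windows are truncated at the sequence ends.
    """
    if not 0 <= position < len(protein):
        raise ValueError(f"position {position} outside protein of length {len(protein)}")
    if alt_aa == protein[position]:
        raise ValueError("alt residue equals reference residue")
    if alt_aa == "*":
        raise ValueError("stop-gain substitutions are handled as truncations")
    if alt_aa not in _AA_INDEX:
        raise ValueError(f"non-standard residue {alt_aa!r}")
    mutant = protein[:position] + alt_aa + protein[position + 1 :]
    out = []
    for k in sorted(set(lengths)):
        lo = max(0, position - k + 1)
        hi = min(position, len(mutant) - k)
        for start in range(lo, hi + 1):
            out.append(
                PeptideCandidate(
                    sample_id=sample_id,
                    source_class="snv",
                    peptide=mutant[start : start + k],
                    source_id=source_id,
                    novel_positions=frozenset({position - start}),
                )
            )
    return out


def _translate(cds: str, to_stop: bool = True, warn_id: str = "") -> str:
    """Standard-table translation of an in-frame CDS prefix."""
    usable = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(usable).translate())
    if to_stop:
        stop = prot.find("*")
        if stop >= 0:
            return prot[:stop]
        warnings.warn(
            f"no stop codon encountered before sequence end ({warn_id}); "
            "translated to end"
        )
    return prot.replace("*", "")


def _novel_windows(
    mutant_protein: str,
    reference_protein: str,
    lengths: Sequence[int],
    sample_id: str,
    source_id: str,
    source_class: str,
) -> list[PeptideCandidate]:
    """k-mers of the mutant protein containing >= 1 residue differing from
    the reference protein at the same index (positions beyond the reference
    end count as novel)."""
    novel = [
        i >= len(reference_protein) or mutant_protein[i] != reference_protein[i]
        for i in range(len(mutant_protein))
    ]
    out = []
    for k in sorted(set(lengths)):
        for start in range(0, len(mutant_protein) - k + 1):
            window_novel = frozenset(
                j for j in range(k) if novel[start + j]
            )
            if window_novel:
                out.append(
                    PeptideCandidate(
                        sample_id=sample_id,
                        source_class=source_class,
                        peptide=mutant_protein[start : start + k],
                        source_id=source_id,
                        novel_positions=window_novel,
                    )
                )
    return out


def enumerate_frameshift_peptides(
    cds: str,
    indel: tuple[int, str, str],
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    sample_id: str = "",
    source_id: str = "",
) -> list[PeptideCandidate]:
    """Peptides from an indel applied to a CDS.

    The mutant CDS is translated from its start through the first stop in
    the (possibly shifted) frame; emitted k-mers contain at least one
    residue not present at the corresponding position of the reference
    protein.  In-frame indels are handled by the same positional
    comparison, which confines windows to the junction.
    """
    position, ref, alt = indel
    if ref == alt:
        raise ValueError("indel with alt identical to ref")
    if not 0 <= position <= len(cds) - len(ref):
        raise ValueError(f"indel position {position} outside CDS")
    if cds[position : position + len(ref)] != ref:
        raise ValueError(
            f"reference allele mismatch at CDS position {position}: "
            f"expected {ref!r}, found {cds[position:position + len(ref)]!r}"
        )
    mutant_cds = cds[:position] + alt + cds[position + len(ref) :]
    ref_protein = _translate(cds, warn_id=f"{source_id} (reference)")
    mut_protein = _translate(mutant_cds, warn_id=source_id)
    return _novel_windows(
        mut_protein, ref_protein, lengths, sample_id, source_id, "indel"
    )


def enumerate_fusion_peptides(
    protein_5p: str,
    protein_3p: str,
    breakpoint_5p: int,
    breakpoint_3p: int,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    sample_id: str = "",
    source_id: str = "",
    source_class: str = "fusion",
) -> list[PeptideCandidate]:
    """Junction-spanning k-mers of a fusion (or splice-junction) protein.

    The chimeric protein is ``protein_5p[:breakpoint_5p] +
    protein_3p[breakpoint_3p:]``; emitted windows contain residues from
    both partners (k-1 windows per length when both partners are long
    enough).  ``novel_positions`` are the 3'-partner residues in the
    window.
    """
    if not 0 < breakpoint_5p <= len(protein_5p):
        raise ValueError(f"5' breakpoint {breakpoint_5p} out of range")
    if not 0 <= breakpoint_3p < len(protein_3p):
        raise ValueError(f"3' breakpoint {breakpoint_3p} out of range")
    if source_class not in ("fusion", "splice"):
        raise ValueError("source_class must be fusion or splice")
    chimera = protein_5p[:breakpoint_5p] + protein_3p[breakpoint_3p:]
    junction = breakpoint_5p  # first index from the 3' partner
    out = []
    for k in sorted(set(lengths)):
        lo = max(0, junction - k + 1)
        hi = min(junction - 1, len(chimera) - k)
        for start in range(lo, hi + 1):
            out.append(
                PeptideCandidate(
                    sample_id=sample_id,
                    source_class=source_class,
                    peptide=chimera[start : start + k],
                    source_id=source_id,
                    novel_positions=frozenset(
                        range(junction - start, k)
                    ),
                )
            )
    return out


def enumerate_self_peptides(
    protein: str,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    sample_id: str = "",
    source_id: str = "",
    source_class: str = "cta_self",
) -> list[PeptideCandidate]:
    """All k-mers of an expressed antigen protein (CTA/self, ERV, viral).

    These classes are tumor-associated rather than mutation-derived, so no
    novelty constraint applies (``novel_positions`` is empty).
    """
    if source_class not in ("cta_self", "erv", "viral"):
        raise ValueError("source_class must be cta_self, erv or viral")
    out = []
    for k in sorted(set(lengths)):
        for start in range(0, len(protein) - k + 1):
            out.append(
                PeptideCandidate(
                    sample_id=sample_id,
                    source_class=source_class,
                    peptide=protein[start : start + k],
                    source_id=source_id,
                    novel_positions=frozenset(),
                )
            )
    return out


# ---------------------------------------------------------------------------
# expression confirmation
# ---------------------------------------------------------------------------


def call_expressed_antigens(
    expression: pd.DataFrame,
    feature_classes: Mapping[str, str],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-sample expressed antigen features (CTA/self, ERV, viral).

    ``expression`` is a normalized log2 genes x samples matrix; a feature
    is called expressed in a sample when its value exceeds ``threshold``.
    Returns a table (sample_id, gene, source_class).
    """
    for cls in feature_classes.values():
        if cls not in ("cta_self", "erv", "viral"):
            raise ValueError(f"unknown antigen feature class {cls!r}")
    genes = [g for g in feature_classes if g in expression.index]
    if not genes:
        raise ValueError("no antigen feature genes present in expression matrix")
    rows = []
    sub = expression.loc[genes]
    for gene in genes:
        for sample in expression.columns:
            if sub.at[gene, sample] > threshold:
                rows.append(
                    {
                        "sample_id": sample,
                        "gene": gene,
                        "source_class": feature_classes[gene],
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "source_class"])


def rna_confirm_variants(
    variants: ConsensusVariantSet,
    rna_support: Mapping[VariantKey, int],
    min_rna_reads: int = 1,
) -> ConsensusVariantSet:
    """Retain variants with RNA alt-read support >= ``min_rna_reads``."""
    confirmed = ConsensusVariantSet(sample_id=variants.sample_id)
    for key, prov in variants.provenance.items():
        if rna_support.get(key, 0) >= min_rna_reads:
            confirmed.provenance[key] = list(prov)
    return confirmed


# ---------------------------------------------------------------------------
# affinity prediction
# ---------------------------------------------------------------------------

AffinityPredictor = Callable[[str, str], float]


def _allele_pwm(allele: str) -> np.ndarray:
    """Deterministic 11 x 20 position-weight matrix derived from the allele
    name (CRC32-seeded)."""
    seed = zlib.crc32(allele.encode("utf-8")) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0, size=(11, 20))


def toy_affinity_kd(peptide: str, allele: str) -> float:
    """Deterministic toy Kd (nM) from a fixed position-weight scheme.

    The score is a standardized sum of allele-specific residue weights;
    Kd = 10**(log10(500) + 1.6 * score), clipped to [1, 50000] nM, so a
    random peptide population spans both sides of the 500 nM threshold.
    """
    return float(predict_batch([peptide], allele)[0])


def predict_batch(peptides: Sequence[str], allele: str) -> np.ndarray:
    """Vectorized toy predictor over many peptides for one allele."""
    pwm = _allele_pwm(allele)
    kd = np.empty(len(peptides))
    for i, pep in enumerate(peptides):
        k = len(pep)
        if not 8 <= k <= 11:
            raise ValueError(f"peptide length {k} outside 8-11: {pep!r}")
        try:
            idx = [_AA_INDEX[aa] for aa in pep]
        except KeyError as exc:
            raise ValueError(f"non-standard residue in peptide {pep!r}") from exc
        score = pwm[np.arange(k), idx].sum() / np.sqrt(k)
        kd[i] = 10.0 ** (np.log10(POSITIVE_BINDER_NM) + 1.6 * score)
    return np.clip(kd, 1.0, 5e4)


def toy_affinity_predictor(peptide: str, allele: str) -> AffinityPrediction:
    return AffinityPrediction(peptide=peptide, allele=allele, kd_nm=toy_affinity_kd(peptide, allele))


def predict_candidates(
    candidates: Sequence[PeptideCandidate],
    alleles: Sequence[str],
    predictor: Optional[AffinityPredictor] = None,
) -> list[AffinityPrediction]:
    """Predict Kd for every (candidate, allele) pair.

    With the default toy predictor the batch path is used; a custom
    predictor callable is invoked per pair.
    """
    peptides = [c.peptide for c in candidates]
    preds: list[AffinityPrediction] = []
    for allele in alleles:
        if predictor is None:
            kds = predict_batch(peptides, allele)
        else:
            kds = [predictor(p, allele) for p in peptides]
        preds.extend(
            AffinityPrediction(peptide=p, allele=allele, kd_nm=float(kd))
            for p, kd in zip(peptides, kds)
        )
    return preds


def classify_binders(
    predictions: Sequence[AffinityPrediction],
    source_class_of: Mapping[str, str],
    sample_id: str,
    positive_nm: float = POSITIVE_BINDER_NM,
    strong_nm: float = STRONG_BINDER_NM,
) -> BinderCounts:
    """Count positive (< 500 nM) and strong (< 50 nM) binders per source.

    A peptide's affinity is the minimum Kd over alleles; each distinct
    (peptide, source_class) pair counts once, so duplicated prediction
    rows and prediction order cannot change the counts.
    """
    best: dict[str, float] = {}
    for p in predictions:
        if p.peptide not in source_class_of:
            raise ValueError(f"prediction for unmapped peptide {p.peptide!r}")
        cur = best.get(p.peptide)
        if cur is None or p.kd_nm < cur:
            best[p.peptide] = p.kd_nm
    counts: dict[str, list[int]] = {}
    for peptide, kd in best.items():
        cls = source_class_of[peptide]
        slot = counts.setdefault(cls, [0, 0])
        if kd < positive_nm:
            slot[0] += 1
            if kd < strong_nm:
                slot[1] += 1
    return BinderCounts(
        sample_id=sample_id,
        counts={cls: (pos, strong) for cls, (pos, strong) in sorted(counts.items())},
    )


def binder_counts_frame(results: Iterable[BinderCounts]) -> pd.DataFrame:
    """Long-format binder-count table (sample, source class, counts)."""
    rows = []
    for r in results:
        for cls in SOURCE_CLASSES:
            pos, strong = r.counts.get(cls, (0, 0))
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "source_class": cls,
                    "n_positive": pos,
                    "n_strong": strong,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "source_class", "n_positive", "n_strong"]
    )
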
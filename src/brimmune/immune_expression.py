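"""Expression QC, normalization, and immune gene-signature scoring.

Samples with fewer than 20 million coding reads are excluded.  Counts are
upper-quartile normalized — each sample scaled so its 75th percentile of
nonzero gene counts equals a common reference (the geometric mean of the
per-sample upper quartiles) — then log2(x+1) transformed.  A signature's
metagene score is the per-sample median of log2 expression over the
signature's genes.  Group comparison Z-transforms each signature across
all samples, applies a two-sided Wilcoxon rank-sum test, and controls the
false discovery rate with Benjamini–Hochberg across the signature family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

QC_MIN_CODING_READS = 20_000_000


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with its normalization state tracked."""

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SignatureScoreTable:
    """Signatures x samples metagene scores plus per-signature Z-scores."""

    scores: pd.DataFrame
    z_scores: pd.DataFrame


@dataclass(frozen=True)
class GroupComparisonResult:
    signature: str
    direction: int  # sign of (group-A median - group-B median)
    p: float
    q: float
    n_a: int
    n_b: int


def qc_filter_samples(
    coding_reads: Mapping[str, float] | pd.Series,
    min_reads: int = QC_MIN_CODING_READS,
) -> list[str]:
    """Samples passing the coding-read depth cutoff.

    Samples with *less than* ``min_reads`` are excluded; a sample exactly
    at the cutoff is retained.
    """
    series = pd.Series(coding_reads)
    if (series < 0).any():
        raise ValueError("negative coding-read counts")
    return [s for s, n in series.items() if n >= min_reads]


def _upper_quartile(col: np.ndarray) -> float:
    """Linear-interpolation 75th percentile of a sample's nonzero counts."""
    nz = col[col > 0]
    if nz.size == 0:
        raise ValueError("sample has all-zero counts")
    return float(np.percentile(nz, 75, method="linear"))


def upper_quartile_scale(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its nonzero upper quartile equals the geometric
    mean of the per-sample upper quartiles (zeros stay zero)."""
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    uqs = {}
    for s in counts.columns:
        try:
            uqs[s] = _upper_quartile(counts[s].to_numpy(dtype=float))
        except ValueError:
            raise ValueError(f"sample {s!r} has all-zero counts") from None
    reference = float(np.exp(np.mean(np.log(list(uqs.values())))))
    scaled = counts.astype(float).copy()
    for s in counts.columns:
        scaled[s] = scaled[s] * (reference / uqs[s])
    return scaled


def upper_quartile_normalize(
    counts: ExpressionMatrix | pd.DataFrame,
    reference_uq: Optional[float] = None,
) -> ExpressionMatrix:
    """Upper-quartile scaling followed by log2(x+1).

    ``reference_uq`` overrides the geometric-mean reference with a fixed
    constant.
    """
    df = counts.values if isinstance(counts, ExpressionMatrix) else counts
    if isinstance(counts, ExpressionMatrix) and counts.normalized:
        raise ValueError("matrix is already normalized")
    scaled = upper_quartile_scale(df)
    if reference_uq is not None:
        # rescale from the geometric-mean reference to the fixed constant
        current = _upper_quartile(scaled.iloc[:, 0].to_numpy(dtype=float))
        scaled = scaled * (reference_uq / current)
    return ExpressionMatrix(values=np.log2(scaled + 1.0), normalized=True)


def average_technical_replicates(
    matrix: ExpressionMatrix,
    replicate_map: Mapping[str, Sequence[str]],
) -> ExpressionMatrix:
    """Collapse technical-replicate columns to their gene-wise mean.

    ``replicate_map`` maps each biological sample id to its replicate
    column names and must partition the matrix's columns.
    """
    cols = [c for group in replicate_map.values() for c in group]
    if sorted(cols) != sorted(matrix.samples):
        raise ValueError("replicate_map does not partition the matrix samples")
    if len(cols) != len(set(cols)):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"replicate groups overlap: {dupes}")
    out = pd.DataFrame(
        {bio: matrix.values[list(group)].mean(axis=1) for bio, group in replicate_map.items()}
    )
    return ExpressionMatrix(values=out, normalized=matrix.normalized)


def metagene_score(
    matrix: ExpressionMatrix, signature: Sequence[str], name: str = ""
) -> pd.Series:
    """Per-sample median log2 expression over the signature's genes."""
    if not matrix.normalized:
        raise ValueError("metagene scores require a normalized matrix")
    genes = sorted(set(signature) & set(matrix.values.index))
    if not genes:
        raise ValueError(f"signature {name or '<unnamed>'} shares no genes with matrix")
    return matrix.values.loc[genes].median(axis=0)


def score_signatures(
    matrix: ExpressionMatrix, signatures: Mapping[str, Sequence[str]]
) -> SignatureScoreTable:
    """Metagene scores for every signature plus per-signature Z-scores."""
    scores = pd.DataFrame(
        {name: metagene_score(matrix, genes, name) for name, genes in signatures.items()}
    ).T
    sd = scores.std(axis=1, ddof=1)
    centered = scores.sub(scores.mean(axis=1), axis=0)
    z = centered.div(sd.where(sd > 0, 1.0), axis=0)
    return SignatureScoreTable(scores=scores, z_scores=z)


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact for small tie-free samples; otherwise the normal approximation
    with mid-ranks and tie-corrected variance, without continuity
    correction (so groups with identical value multisets give p = 1).
    """
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="auto", use_continuity=False
    )
    return float(res.pvalue)


def compare_signature_groups(
    table: SignatureScoreTable,
    labels: Mapping[str, str],
    group_a: str = "A",
    group_b: str = "B",
    alpha: float = 0.05,
) -> list[GroupComparisonResult]:
    """Per-signature two-group comparison with BH FDR control.

    Scores are Z-transformed across all samples before testing (rank
    tests are invariant to this, so p-values match the raw scale; the
    transform standardizes the reported direction/effect scale).
    """
    samples_a = [s for s in table.scores.columns if labels.get(s) == group_a]
    samples_b = [s for s in table.scores.columns if labels.get(s) == group_b]
    if not samples_a or not samples_b:
        raise ValueError(
            f"both groups must be nonempty (|{group_a}|={len(samples_a)}, "
            f"|{group_b}|={len(samples_b)})"
        )
    names, pvals, directions = [], [], []
    for sig in table.z_scores.index:
        za = table.z_scores.loc[sig, samples_a].to_numpy(dtype=float)
        zb = table.z_scores.loc[sig, samples_b].to_numpy(dtype=float)
        pvals.append(wilcoxon_rank_sum(za, zb))
        directions.append(int(np.sign(np.median(za) - np.median(zb))))
        names.append(sig)
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [
        GroupComparisonResult(
            signature=n, direction=d, p=p, q=q, n_a=len(samples_a), n_b=len(samples_b)
        )
        for n, d, p, q in zip(names, directions, pvals, qvals)
    ]


def comparison_frame(results: Sequence[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "signature": r.signature,
                "direction": r.direction,
                "p": r.p,
                "q": r.q,
                "n_a": r.n_a,
                "n_b": r.n_b,
            }
            for r in results
        ],
        columns=["signature", "direction", "p", "q", "n_a", "n_b"],
    )
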
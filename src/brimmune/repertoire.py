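"""TCR/BCR repertoire abundance and diversity.

Diversity is indexed by Shannon entropy over clonotype frequencies
(natural log by default), which jointly reflects richness (the number of
distinct CDR3 sequences per chain) and evenness of the count
distribution.  Because repertoires are typically undersampled, a
Chao–Shen coverage-corrected estimator is also reported; the estimator
interface accepts alternatives.

Group comparisons follow the convention of testing read counts on the
log10(x+1) scale and entropy on its raw scale, both with a two-sided
Wilcoxon rank-sum test (rank tests are unaffected by the monotone log
transform; it is applied for consistency of reported effect scales).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .immune_expression import wilcoxon_rank_sum
from .io_formats import CHAINS, ClonotypeRecord


@dataclass(frozen=True)
class RepertoireSummary:
    sample_id: str
    chain: str
    total_reads: int
    n_clonotypes: int
    entropy: float
    entropy_corrected: float


@dataclass(frozen=True)
class RepertoireComparison:
    chain: str
    metric: str
    direction: int
    p: float
    n_a: int
    n_b: int
    missing: bool = False


def shannon_entropy(counts: Sequence[int] | np.ndarray, base: float = math.e) -> float:
    """Plug-in Shannon entropy of clonotype counts, -sum p ln p."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size <= 1:
        return 0.0
    p = c / c.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def chao_shen_entropy(counts: Sequence[int] | np.ndarray, base: float = math.e) -> float:
    """Chao–Shen coverage-adjusted Shannon entropy.

    Sample coverage is estimated as C = 1 - f1/n (f1 = singleton count);
    abundances are shrunk to C*p and the Horvitz–Thompson correction
    1 - (1 - C p)^n reweights unseen mass.  When every clonotype is a
    singleton C would be 0, so the standard f1 -> n-1 adjustment is
    applied to keep coverage positive.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size <= 1:
        return 0.0
    n = c.sum()
    f1 = float((c == 1.0).sum())
    if f1 == n:
        f1 = n - 1.0
    coverage = 1.0 - f1 / n
    p = coverage * c / n
    ht = 1.0 - (1.0 - p) ** n
    return float(-(p * np.log(p) / ht).sum() / math.log(base))


EntropyEstimator = Callable[[np.ndarray], float]


def summarize_repertoire(
    records: Sequence[ClonotypeRecord],
    sample_id: str,
    chain: str,
    corrected_estimator: EntropyEstimator = chao_shen_entropy,
) -> RepertoireSummary:
    """Reads, richness, and (corrected) Shannon entropy for one
    sample/chain; duplicate CDR3 rows are merged before computing
    frequencies."""
    if chain not in CHAINS:
        raise ValueError(f"unknown chain {chain!r}")
    bad = [r for r in records if r.sample_id != sample_id or r.chain != chain]
    if bad:
        raise ValueError(
            f"records for {bad[0].sample_id}/{bad[0].chain} passed to "
            f"{sample_id}/{chain} summary"
        )
    merged: dict[str, int] = {}
    for r in records:
        merged[r.cdr3] = merged.get(r.cdr3, 0) + r.read_count
    counts = np.array(sorted(merged.values()), dtype=float)
    return RepertoireSummary(
        sample_id=sample_id,
        chain=chain,
        total_reads=int(counts.sum()) if counts.size else 0,
        n_clonotypes=len(merged),
        entropy=shannon_entropy(counts),
        entropy_corrected=corrected_estimator(counts) if counts.size else 0.0,
    )


def summarize_all(
    records: Sequence[ClonotypeRecord],
    corrected_estimator: EntropyEstimator = chao_shen_entropy,
) -> list[RepertoireSummary]:
    """One summary per (sample, chain) present in the records."""
    groups: dict[tuple[str, str], list[ClonotypeRecord]] = {}
    for r in records:
        groups.setdefault((r.sample_id, r.chain), []).append(r)
    return [
        summarize_repertoire(g, sample_id, chain, corrected_estimator)
        for (sample_id, chain), g in sorted(groups.items())
    ]


def compare_repertoire_groups(
    summaries: Sequence[RepertoireSummary],
    labels: Mapping[str, str],
    metric: str,
    group_a: str = "A",
    group_b: str = "B",
    chains: Optional[Sequence[str]] = None,
) -> list[RepertoireComparison]:
    """Per-chain two-group Wilcoxon comparison of a repertoire metric.

    ``total_reads`` is compared on the log10(x+1) scale, entropy metrics
    on their raw scale.  A chain absent from either group yields a result
    flagged ``missing`` rather than an error.
    """
    if metric not in ("total_reads", "entropy", "entropy_corrected"):
        raise ValueError(f"unknown metric {metric!r}")
    chains = list(chains) if chains is not None else sorted({s.chain for s in summaries})
    out = []
    for chain in chains:
        va = [
            getattr(s, metric)
            for s in summaries
            if s.chain == chain and labels.get(s.sample_id) == group_a
        ]
        vb = [
            getattr(s, metric)
            for s in summaries
            if s.chain == chain and labels.get(s.sample_id) == group_b
        ]
        if not va or not vb:
            out.append(
                RepertoireComparison(
                    chain=chain, metric=metric, direction=0, p=float("nan"),
                    n_a=len(va), n_b=len(vb), missing=True,
                )
            )
            continue
        a, b = np.asarray(va, dtype=float), np.asarray(vb, dtype=float)
        if metric == "total_reads":
            a, b = np.log10(a + 1.0), np.log10(b + 1.0)
        out.append(
            RepertoireComparison(
                chain=chain,
                metric=metric,
                direction=int(np.sign(np.median(a) - np.median(b))),
                p=wilcoxon_rank_sum(a, b),
                n_a=len(va),
                n_b=len(vb),
            )
        )
    return out


def summary_frame(summaries: Sequence[RepertoireSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chain": s.chain,
                "total_reads": s.total_reads,
                "n_clonotypes": s.n_clonotypes,
                "entropy": s.entropy,
                "entropy_corrected": s.entropy_corrected,
            }
            for s in summaries
        ],
        columns=[
            "sample_id",
            "chain",
            "total_reads",
            "n_clonotypes",
            "entropy",
            "entropy_corrected",
        ],
    )


def comparison_frame(results: Sequence[RepertoireComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chain": r.chain,
                "metric": r.metric,
                "direction": r.direction,
                "p": r.p,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "missing": r.missing,
            }
            for r in results
        ],
        columns=["chain", "metric", "direction", "p", "n_a", "n_b", "missing"],
    )
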
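"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written rule-by-rule, without reusing any package
code paths, so agreement with the package is a meaningful check.
"""

from __future__ import annotations

import numpy as np

# --- matched-normal cascade, clause by clause ------------------------------


def _gate_passes(call) -> bool:
    if call.caller == "cadabra":
        return call.variant_class == "indel" and call.quality > 10.5
    if call.caller == "mutect2":
        if call.variant_class == "indel":
            return call.quality > 6.8
        return call.quality > 9.2
    if call.caller == "strelka2":
        if call.variant_class == "indel":
            return call.quality > 15.2
        return call.quality > 19.7
    raise AssertionError(call.caller)


def brute_force_matched(calls) -> set:
    """Rule-by-rule reimplementation of the matched cascade; returns the
    retained (chrom, pos, ref, alt) key set."""
    coding = [c for c in calls if c.coding]
    gated = [c for c in coding if _gate_passes(c)]
    retained = set()
    for c in gated:
        ok = True
        if c.caller == "cadabra" and c.variant_class == "indel" and c.quality < 35.0:
            ok = any(
                d.key == c.key and d.caller in ("strelka2", "mutect2") for d in gated
            )
        if ok and c.caller == "strelka2" and c.somatic_evs < 20.0:
            ok = any(
                d.key == c.key and d.caller in ("mutect2", "cadabra") for d in gated
            )
        if ok:
            retained.add(c.key)
    return retained


def brute_force_tumor_only(calls) -> set:
    """Clause-by-clause reimplementation of the tumor-only filter."""
    retained = set()
    for c in calls:
        if not c.coding:
            continue
        if c.maf >= 0.05:
            if not (c.alt_reads >= 5 and c.depth >= 40):
                continue
        else:
            if not (c.alt_reads >= 10 and c.depth >= 80):
                continue
        if c.normal_maf is not None and c.normal_maf > 0.05:
            continue
        if c.pop_af_max is not None and c.pop_af_max > 0.01:
            continue
        if (c.ref, c.alt) in {("C", "T"), ("G", "A")} and c.maf < 0.10:
            continue
        retained.add(c.key)
    return retained


# --- peptide window enumeration --------------------------------------------


def enumerate_windows_covering(sequence: str, index: int, k: int) -> list[str]:
    """Every k-mer of ``sequence`` whose window includes ``index``."""
    return [
        sequence[s : s + k]
        for s in range(0, len(sequence) - k + 1)
        if s <= index <= s + k - 1
    ]


# --- standard-table translation (hard-coded, independent of Biopython) -----

_CODON_TABLE = {}
_BASES = "TCAG"
_AA_ORDER = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AA_ORDER[16 * _i + 4 * _j + _k]


def translate_to_stop(cds: str) -> str:
    """Codon-by-codon translation through the first stop."""
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = _CODON_TABLE[cds[i : i + 3]]
        if aa == "*":
            break
        protein.append(aa)
    return "".join(protein)


def brute_force_frameshift_peptides(cds: str, indel, lengths) -> set:
    """Expected (peptide, novel-position frozenset) pairs for an indel."""
    pos, ref, alt = indel
    mutant = cds[:pos] + alt + cds[pos + len(ref) :]
    ref_prot = translate_to_stop(cds)
    mut_prot = translate_to_stop(mutant)
    expected = set()
    for k in lengths:
        for s in range(0, len(mut_prot) - k + 1):
            novel = frozenset(
                j
                for j in range(k)
                if s + j >= len(ref_prot) or mut_prot[s + j] != ref_prot[s + j]
            )
            if novel:
                expected.add((mut_prot[s : s + k], novel))
    return expected


# --- entropy ----------------------------------------------------------------


def entropy_by_hand(counts) -> float:
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    if len(counts) <= 1:
        return 0.0
    return -sum((c / total) * np.log(c / total) for c in counts)
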
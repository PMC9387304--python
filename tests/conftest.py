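import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from brimmune.io_formats import VariantCall
from brimmune.synthetic_cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 7)."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_call(
    caller="mutect2",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    coding=True,
    quality=50.0,
    sample_id="S1",
    **kwargs,
):
    vclass = "snv" if len(ref) == 1 and len(alt) == 1 else "indel"
    return VariantCall(
        sample_id=sample_id,
        caller=caller,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=vclass,
        coding=coding,
        quality=quality,
        **kwargs,
    )


@pytest.fixture()
def call_factory():
    return make_call


def build_matched_grid():
    """Exhaustive grid of matched-mode scenarios crossing every rule branch.

    Each scenario gets a unique locus; corroborating calls are placed at
    the same locus.  Returns a flat list of VariantCall.
    """
    calls = []
    pos = 0
    quality_bands = {
        ("cadabra", "indel"): [5.0, 10.5, 20.0, 34.9, 35.0, 60.0],
        ("mutect2", "indel"): [3.0, 6.8, 15.0, 40.0],
        ("mutect2", "snv"): [5.0, 9.2, 15.0, 40.0],
        ("strelka2", "indel"): [10.0, 15.2, 25.0, 60.0],
        ("strelka2", "snv"): [12.0, 19.7, 30.0, 60.0],
    }
    corro_options = [
        None,
        ("strelka2", True),
        ("strelka2", False),
        ("mutect2", True),
        ("mutect2", False),
        ("cadabra", True),
        ("cadabra", False),
    ]
    for (caller, vclass), quals in quality_bands.items():
        alleles = ("A", "G") if vclass == "snv" else ("A", "AT")
        for quality in quals:
            for coding in (True, False):
                evs_values = [5.0, 19.9, 20.0, 35.0] if caller == "strelka2" else [None]
                for evs in evs_values:
                    for corro in corro_options:
                        if corro is not None and corro[0] == caller:
                            continue
                        pos += 1
                        calls.append(
                            make_call(
                                caller=caller,
                                chrom="chr1",
                                pos=pos,
                                ref=alleles[0],
                                alt=alleles[1],
                                coding=coding,
                                quality=quality,
                                somatic_evs=evs,
                            )
                        )
                        if corro is not None:
                            other, passes = corro
                            if other == "cadabra" and vclass == "snv":
                                # cadabra emits indels only; place a failing
                                # record anyway to exercise the branch
                                pass
                            gates = {
                                ("cadabra", "snv"): 10.5,  # no published gate
                                ("cadabra", "indel"): 10.5,
                                ("mutect2", "indel"): 6.8,
                                ("mutect2", "snv"): 9.2,
                                ("strelka2", "indel"): 15.2,
                                ("strelka2", "snv"): 19.7,
                            }
                            g = gates[(other, vclass)]
                            q = g + 5.0 if passes else max(0.5, g - 2.0)
                            calls.append(
                                make_call(
                                    caller=other,
                                    chrom="chr1",
                                    pos=pos,
                                    ref=alleles[0],
                                    alt=alleles[1],
                                    coding=True,
                                    quality=q,
                                    somatic_evs=30.0 if other == "strelka2" else None,
                                )
                            )
    return calls


def build_tumor_only_grid():
    """Exhaustive cross of every tumor-only clause value."""
    calls = []
    pos = 0
    for coding in (True, False):
        for ref, alt in (("C", "T"), ("G", "A"), ("A", "G"), ("T", "C")):
            for maf in (0.03, 0.0499, 0.05, 0.08, 0.10, 0.25):
                for alt_reads in (4, 5, 9, 10, 20):
                    for depth in (39, 40, 79, 80, 200):
                        if alt_reads > depth:
                            continue
                        for normal_maf in (None, 0.02, 0.08):
                            for pop_af in (None, 0.005, 0.02):
                                pos += 1
                                calls.append(
                                    make_call(
                                        caller="mutect2",
                                        chrom="chr2",
                                        pos=pos,
                                        ref=ref,
                                        alt=alt,
                                        coding=coding,
                                        quality=30.0,
                                        alt_reads=alt_reads,
                                        depth=depth,
                                        maf=maf,
                                        normal_maf=normal_maf,
                                        pop_af_max=pop_af,
                                    )
                                )
    return calls
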
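import dataclasses

import pandas as pd
import pytest

from brimmune import variant_filtering as vf
from conftest import build_matched_grid, build_tumor_only_grid, make_call
from oracles import brute_force_matched, brute_force_tumor_only


class TestMatchedCascade:
    def test_high_quality_cadabra_indel_retained_without_corroboration(self):
        call = make_call(caller="cadabra", ref="A", alt="AT", quality=40.0)
        result = vf.filter_matched([call])
        assert result.keys == {call.key}

    def test_low_quality_cadabra_indel_needs_corroboration(self):
        call = make_call(caller="cadabra", ref="A", alt="AT", quality=20.0)
        assert len(vf.filter_matched([call])) == 0
        corro = make_call(caller="mutect2", ref="A", alt="AT", quality=10.0)
        assert vf.filter_matched([call, corro]).keys == {call.key}

    def test_corroborator_must_pass_its_own_gate(self):
        call = make_call(caller="cadabra", ref="A", alt="AT", quality=20.0)
        weak = make_call(caller="mutect2", ref="A", alt="AT", quality=5.0)
        assert len(vf.filter_matched([call, weak])) == 0
        relaxed = dataclasses.replace(
            vf.DEFAULT_FILTER_CONFIG, require_corroborator_gate=False
        )
        assert vf.filter_matched([call, weak], relaxed).keys == {call.key}

    def test_noncoding_rejected_regardless_of_quality(self):
        call = make_call(caller="mutect2", coding=False, quality=100.0)
        assert len(vf.filter_matched([call])) == 0

    def test_low_evs_strelka_needs_matching_call(self):
        lone = make_call(caller="strelka2", quality=25.0, somatic_evs=15.0)
        assert len(vf.filter_matched([lone])) == 0
        corro = make_call(caller="mutect2", quality=12.0)
        assert vf.filter_matched([lone, corro]).keys == {lone.key}

    def test_strelka_missing_evs_is_an_error(self):
        call = make_call(caller="strelka2", quality=25.0)
        with pytest.raises(ValueError, match="SomaticEVS"):
            vf.filter_matched([call])

    def test_cadabra_snv_excluded_by_default_but_admittable(self):
        call = make_call(caller="cadabra", ref="A", alt="G", quality=90.0)
        assert len(vf.filter_matched([call])) == 0
        cfg = dataclasses.replace(vf.DEFAULT_FILTER_CONFIG, cadabra_snv_quality=50.0)
        assert vf.filter_matched([call], cfg).keys == {call.key}

    def test_provenance_records_all_supporting_callers(self):
        a = make_call(caller="mutect2", quality=12.0)
        b = make_call(caller="strelka2", quality=25.0, somatic_evs=30.0)
        result = vf.filter_matched([a, b])
        assert len(result) == 1
        callers = {c for c, _ in result.provenance[a.key]}
        assert callers == {"mutect2", "strelka2"}

    def test_grid_matches_brute_force_oracle(self):
        calls = build_matched_grid()
        assert len(calls) >= 800
        assert vf.filter_matched(calls).keys == brute_force_matched(calls)

    @pytest.mark.parametrize(
        "field",
        [
            "cadabra_indel_quality",
            "mutect2_indel_quality",
            "mutect2_snv_quality",
            "strelka2_indel_quality",
            "strelka2_snv_quality",
        ],
    )
    def test_raising_a_gate_never_grows_the_retained_set(self, field):
        calls = build_matched_grid()
        base = vf.filter_matched(calls).keys
        raised = dataclasses.replace(
            vf.DEFAULT_FILTER_CONFIG,
            **{field: getattr(vf.DEFAULT_FILTER_CONFIG, field) + 10.0},
        )
        assert vf.filter_matched(calls, raised).keys <= base
        assert base <= {c.key for c in calls}


class TestTumorOnly:
    def test_ffpe_substitution_below_ten_percent_rejected(self):
        call = make_call(ref="C", alt="T", maf=0.08, alt_reads=12, depth=150)
        assert len(vf.filter_tumor_only([call])) == 0

    def test_low_maf_requires_deeper_support(self):
        call = make_call(ref="A", alt="G", maf=0.04, alt_reads=9, depth=100)
        assert len(vf.filter_tumor_only([call])) == 0
        ok = make_call(ref="A", alt="G", maf=0.04, alt_reads=10, depth=100)
        assert len(vf.filter_tumor_only([ok])) == 1

    def test_population_frequent_variant_rejected(self):
        call = make_call(ref="A", alt="G", maf=0.30, alt_reads=6, depth=45, pop_af_max=0.02)
        assert len(vf.filter_tumor_only([call])) == 0

    def test_every_clause_satisfied_retained(self):
        call = make_call(ref="A", alt="G", maf=0.30, alt_reads=6, depth=45, pop_af_max=0.001)
        assert vf.filter_tumor_only([call]).keys == {call.key}

    def test_missing_support_fields_error_names_variant(self):
        call = make_call(ref="A", alt="G", quality=30.0)
        with pytest.raises(ValueError, match="chr1:100"):
            vf.filter_tumor_only([call])

    def test_non_mutect2_caller_rejected(self):
        call = make_call(
            caller="strelka2", maf=0.3, alt_reads=10, depth=50, somatic_evs=30.0
        )
        with pytest.raises(ValueError, match="mutect2"):
            vf.filter_tumor_only([call])

    def test_grid_matches_brute_force_oracle(self):
        calls = build_tumor_only_grid()
        assert len(calls) >= 2000
        assert vf.filter_tumor_only(calls).keys == brute_force_tumor_only(calls)


class TestTmb:
    def test_arithmetic(self):
        cvs = vf.ConsensusVariantSet("S1")
        for i in range(100):
            cvs.provenance[("chr1", i + 1, "A", "G")] = [("mutect2", 30.0)]
        assert vf.compute_tmb(cvs, 30.0).tmb == pytest.approx(100 / 30, abs=1e-12)

    def test_empty_set(self):
        assert vf.compute_tmb(vf.ConsensusVariantSet("S1"), 30.0).tmb == 0.0

    def test_derived_example(self):
        cvs = vf.ConsensusVariantSet("S1")
        for i in range(57):
            cvs.provenance[("chr1", i + 1, "A", "G")] = [("mutect2", 30.0)]
        assert vf.compute_tmb(cvs, 32.0).tmb == pytest.approx(1.78125, abs=1e-12)

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ValueError):
            vf.compute_tmb(vf.ConsensusVariantSet("S1"), 0.0)

    def test_split_counts_sum_to_pooled(self, rng):
        keys = [("chr1", int(p), "A", "G") for p in rng.choice(10**6, 200, replace=False)]
        pooled = vf.ConsensusVariantSet("S")
        half_a, half_b = vf.ConsensusVariantSet("S"), vf.ConsensusVariantSet("S")
        for i, k in enumerate(keys):
            pooled.provenance[k] = [("mutect2", 1.0)]
            (half_a if i % 2 else half_b).provenance[k] = [("mutect2", 1.0)]
        assert len(half_a) + len(half_b) == len(pooled)


class TestCoverage:
    def test_fully_covered_interval(self):
        df = pd.DataFrame([{"chrom": "chr1", "start": 1, "end": 1_000_000, "depth": 100}])
        assert vf.covered_megabases(df, 20) == pytest.approx(1.0)

    def test_underpowered_interval(self):
        df = pd.DataFrame([{"chrom": "chr1", "start": 1, "end": 1_000_000, "depth": 10}])
        assert vf.covered_megabases(df, 20) == 0.0

    def test_mixed_depths(self):
        df = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 1, "end": 100, "depth": 25},
                {"chrom": "chr1", "start": 101, "end": 300, "depth": 19},
                {"chrom": "chr2", "start": 1, "end": 50, "depth": 20},
            ]
        )
        assert vf.covered_megabases(df, 20) == pytest.approx(150 / 1e6)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vf.covered_megabases(pd.DataFrame(columns=["chrom", "start", "end", "depth"]))


class TestPairSharing:
    @staticmethod
    def _cvs(keys, sample="S"):
        cvs = vf.ConsensusVariantSet(sample)
        for k in keys:
            cvs.provenance[k] = [("mutect2", 1.0)]
        return cvs

    def test_identical_sets(self):
        keys = [("chr1", i + 1, "A", "G") for i in range(10)]
        s = vf.pair_sharing(self._cvs(keys, "A"), self._cvs(keys, "B"))
        assert s.n_shared == 10 and s.jaccard == 1.0

    def test_disjoint_sets(self):
        a = [("chr1", i + 1, "A", "G") for i in range(5)]
        b = [("chr2", i + 1, "A", "G") for i in range(5)]
        s = vf.pair_sharing(self._cvs(a), self._cvs(b))
        assert s.n_shared == 0 and s.jaccard == 0.0

    def test_partial_overlap(self):
        v = [("chr1", i, "A", "G") for i in range(1, 5)]
        s = vf.pair_sharing(self._cvs(v[:3]), self._cvs(v[1:]))
        assert (s.n_shared, s.n_only_a, s.n_only_b) == (2, 1, 1)
        assert s.jaccard == pytest.approx(0.5)
        assert s.fraction_shared_of_a == pytest.approx(2 / 3)
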
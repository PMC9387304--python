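import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brimmune import neoantigen as neo
from brimmune.variant_filtering import ConsensusVariantSet
from oracles import (
    brute_force_frameshift_peptides,
    enumerate_windows_covering,
    translate_to_stop,
)

PROTEIN30 = "MKLVFGAYDQSRTWHENCIPMKLVFGAYDQ"


class TestSnvPeptides:
    def test_interior_position_yields_k_windows(self):
        peps = neo.enumerate_snv_peptides(PROTEIN30, 15, "A", lengths=[9])
        assert len(peps) == 9
        mutant = PROTEIN30[:15] + "A" + PROTEIN30[16:]
        for p in peps:
            (novel,) = p.novel_positions
            assert p.peptide[novel] == "A"
            assert p.peptide in mutant

    def test_left_boundary_single_window(self):
        assert len(neo.enumerate_snv_peptides(PROTEIN30, 0, "A", lengths=[9])) == 1

    def test_all_lengths_interior(self):
        peps = neo.enumerate_snv_peptides(PROTEIN30, 15, "A")
        assert len(peps) == 8 + 9 + 10 + 11

    def test_alt_equal_ref_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            neo.enumerate_snv_peptides(PROTEIN30, 3, PROTEIN30[3])

    def test_stop_gain_routed_elsewhere(self):
        with pytest.raises(ValueError, match="truncation"):
            neo.enumerate_snv_peptides(PROTEIN30, 3, "*")

    @given(
        length=st.integers(min_value=12, max_value=60),
        pos_frac=st.floats(min_value=0.0, max_value=0.999),
        data=st.data(),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_fuzzed_windows_match_enumeration_oracle(self, length, pos_frac, data):
        rng = np.random.default_rng(length * 1000 + int(pos_frac * 1000))
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        position = int(pos_frac * length)
        alt = "W" if protein[position] != "W" else "Y"
        ks = data.draw(
            st.lists(st.integers(8, 11), min_size=1, max_size=4, unique=True)
        )
        got = neo.enumerate_snv_peptides(protein, position, alt, lengths=ks)
        mutant = protein[:position] + alt + protein[position + 1 :]
        expected = []
        for k in ks:
            if k <= length:
                expected.extend(enumerate_windows_covering(mutant, position, k))
        assert sorted(p.peptide for p in got) == sorted(expected)


class TestFrameshiftPeptides:
    # CDS: M A A A A A A A A A A A A A A A A A A A then stops in all frames
    CDS = "ATG" + "GCA" * 19 + "TAAATAAATAAA"

    def test_insertion_matches_independent_translation(self):
        indel = (6, "G", "GT")  # 1-bp insertion after 2 codons
        got = {
            (p.peptide, p.novel_positions)
            for p in neo.enumerate_frameshift_peptides(self.CDS, indel, lengths=[9])
        }
        assert got == brute_force_frameshift_peptides(self.CDS, indel, [9])

    def test_inframe_deletion_windows_span_junction_only(self):
        cds = "ATG" + "GCA" + "TGG" + "CAT" + "GAA" * 16 + "TAA"
        indel = (6, "TGGC", "C")  # removes one codon's worth in-frame
        peps = neo.enumerate_frameshift_peptides(cds, indel, lengths=[8])
        expected = brute_force_frameshift_peptides(cds, indel, [8])
        assert {(p.peptide, p.novel_positions) for p in peps} == expected
        # every emitted window must include a changed residue
        for p in peps:
            assert p.novel_positions

    def test_degenerate_indel_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            neo.enumerate_frameshift_peptides(self.CDS, (6, "G", "G"))

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            neo.enumerate_frameshift_peptides(self.CDS, (6, "T", "TA"))

    def test_no_stop_warns_and_translates_to_end(self):
        cds = "ATG" + "GCA" * 10  # no stop at all
        with pytest.warns(UserWarning, match="no stop"):
            neo.enumerate_frameshift_peptides(cds, (4, "C", "CA"), lengths=[8])

    @pytest.mark.parametrize("seed", range(10))
    def test_fuzzed_cds_against_codon_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        body = "".join(rng.choice(list("ACGT"), size=45))
        cds = "ATG" + body + "TAAATAAATAAA"
        pos = int(rng.integers(6, 30))
        ref = cds[pos]
        alt = ref + str(rng.choice(list("ACGT")))
        got = {
            (p.peptide, p.novel_positions)
            for p in neo.enumerate_frameshift_peptides(cds, (pos, ref, alt), lengths=[8, 9])
        }
        assert got == brute_force_frameshift_peptides(cds, (pos, ref, alt), [8, 9])


class TestFusionPeptides:
    P5 = "MKLVFGAYDQSRTWHENCIP"
    P3 = "WQRSTVAEDGHIKLMNPCYF"

    def test_junction_spanning_nine_mers(self):
        peps = neo.enumerate_fusion_peptides(self.P5, self.P3, 10, 5, lengths=[9])
        assert len(peps) == 8
        chimera = self.P5[:10] + self.P3[5:]
        for p in peps:
            assert p.peptide in chimera
            assert p.novel_positions  # 3' residues present

    def test_single_residue_on_three_prime_side(self):
        peps = neo.enumerate_fusion_peptides(self.P5, self.P3, 10, len(self.P3) - 1, lengths=[9])
        assert len(peps) == 1

    def test_all_lengths_sum(self):
        peps = neo.enumerate_fusion_peptides(self.P5, self.P3, 10, 5)
        assert len(peps) == 7 + 8 + 9 + 10

    def test_out_of_range_breakpoint(self):
        with pytest.raises(ValueError, match="breakpoint"):
            neo.enumerate_fusion_peptides(self.P5, self.P3, 25, 5)


class TestExpressionConfirmation:
    def test_unexpressed_feature_never_called(self):
        expr = pd.DataFrame(
            {"S1": [0.0, 5.0], "S2": [0.0, 5.0]}, index=["ERV1", "CTA1"]
        )
        out = neo.call_expressed_antigens(expr, {"ERV1": "erv", "CTA1": "cta_self"}, 1.0)
        assert set(out["gene"]) == {"CTA1"}

    def test_threshold_selects_expected_samples(self):
        cols = {f"S{i}": [3.0 if i < 3 else 0.5] for i in range(10)}
        expr = pd.DataFrame(cols, index=["ERV1"])
        out = neo.call_expressed_antigens(expr, {"ERV1": "erv"}, 1.0)
        assert sorted(out["sample_id"]) == ["S0", "S1", "S2"]

    def test_infinite_threshold_empty(self):
        expr = pd.DataFrame({"S1": [99.0]}, index=["ERV1"])
        out = neo.call_expressed_antigens(expr, {"ERV1": "erv"}, float("inf"))
        assert out.empty

    def test_empty_intersection_rejected(self):
        expr = pd.DataFrame({"S1": [1.0]}, index=["G1"])
        with pytest.raises(ValueError, match="no antigen feature genes"):
            neo.call_expressed_antigens(expr, {"OTHER": "erv"}, 1.0)

    def test_rna_confirmation_thresholds(self):
        cvs = ConsensusVariantSet("S1")
        keys = [("chr1", i + 1, "A", "G") for i in range(10)]
        for k in keys:
            cvs.provenance[k] = [("mutect2", 1.0)]
        support = {k: (1 if i < 6 else 0) for i, k in enumerate(keys)}
        confirmed = neo.rna_confirm_variants(cvs, support)
        assert len(confirmed) == 6
        assert neo.rna_confirm_variants(cvs, {}, min_rna_reads=1).keys == set()


class TestToyPredictor:
    def test_deterministic(self):
        kd1 = neo.toy_affinity_kd("SIINFEKLM", "HLA-A*02:01")
        kd2 = neo.toy_affinity_kd("SIINFEKLM", "HLA-A*02:01")
        assert kd1 == kd2

    def test_allele_dependence(self):
        kds = {neo.toy_affinity_kd("SIINFEKLM", a) for a in ("HLA-A*02:01", "HLA-B*07:02")}
        assert len(kds) == 2

    def test_distribution_straddles_binder_threshold(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        peptides = ["".join(rng.choice(aas, size=9)) for _ in range(10_000)]
        kds = neo.predict_batch(peptides, "HLA-A*02:01")
        frac_binders = float(np.mean(kds < 500.0))
        assert 0.2 < frac_binders < 0.8
        assert kds.min() >= 1.0 and kds.max() <= 5e4

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            neo.toy_affinity_kd("SIINFEKLX", "HLA-A*02:01")


class TestClassifyBinders:
    @staticmethod
    def _counts(kd):
        pred = neo.AffinityPrediction(peptide="AAAAAAAA", allele="X", kd_nm=kd)
        return neo.classify_binders([pred], {"AAAAAAAA": "snv"}, "S1")

    def test_just_below_strong(self):
        bc = self._counts(49.999)
        assert (bc.n_positive("snv"), bc.n_strong("snv")) == (1, 1)

    def test_exactly_fifty_is_positive_only(self):
        bc = self._counts(50.0)
        assert (bc.n_positive("snv"), bc.n_strong("snv")) == (1, 0)

    def test_just_below_positive(self):
        bc = self._counts(499.999)
        assert (bc.n_positive("snv"), bc.n_strong("snv")) == (1, 0)

    def test_exactly_five_hundred_is_not_positive(self):
        bc = self._counts(500.0)
        assert (bc.n_positive("snv"), bc.n_strong("snv")) == (0, 0)

    def test_min_over_alleles_and_duplication_invariance(self):
        preds = [
            neo.AffinityPrediction("AAAAAAAA", "X", 600.0),
            neo.AffinityPrediction("AAAAAAAA", "Y", 40.0),
        ]
        mapping = {"AAAAAAAA": "erv"}
        a = neo.classify_binders(preds, mapping, "S1")
        b = neo.classify_binders(preds[::-1] + preds, mapping, "S1")
        assert a == b
        assert a.n_strong("erv") == 1

    def test_strong_never_exceeds_positive(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        peptides = ["".join(rng.choice(aas, size=9)) for _ in range(500)]
        preds = [
            neo.AffinityPrediction(p, "A", kd)
            for p, kd in zip(peptides, neo.predict_batch(peptides, "A"))
        ]
        mapping = {p: ("snv" if i % 2 else "erv") for i, p in enumerate(peptides)}
        bc = neo.classify_binders(preds, mapping, "S")
        for cls in ("snv", "erv"):
            assert bc.n_strong(cls) <= bc.n_positive(cls) <= len(peptides)
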
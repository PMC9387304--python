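import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from brimmune import immune_expression as ie
from brimmune.synthetic_cohort import CohortConfig, simulate_expression


class TestQcFilter:
    def test_below_cutoff_excluded(self):
        assert ie.qc_filter_samples({"S1": 19_999_999}) == []

    def test_at_cutoff_included(self):
        assert ie.qc_filter_samples({"S1": 20_000_000}) == ["S1"]

    def test_mixed_fixture(self):
        metrics = {"A": 5e6, "B": 3e7, "C": 1.5e7, "D": 2.5e7, "E": 6e7}
        assert ie.qc_filter_samples(metrics) == ["B", "D", "E"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ie.qc_filter_samples({"S1": -5})


def toy_counts():
    return pd.DataFrame(
        {"S1": [10, 0, 30, 100], "S2": [5, 20, 0, 75], "S3": [1, 2, 3, 4]},
        index=pd.Index(["G1", "G2", "G3", "G4"], name="gene"),
    )


class TestUpperQuartileNormalize:
    def test_identical_samples_stay_identical(self):
        df = pd.DataFrame({"S1": [1, 2, 3, 4], "S2": [1, 2, 3, 4]}, index=list("abcd"))
        norm = ie.upper_quartile_normalize(df)
        pd.testing.assert_series_equal(
            norm.values["S1"], norm.values["S2"], check_names=False
        )

    def test_scale_invariance(self):
        df = pd.DataFrame(
            {"S1": [10, 0, 30, 100], "S2": [20, 0, 60, 200]}, index=list("abcd")
        )
        norm = ie.upper_quartile_normalize(df)
        np.testing.assert_allclose(norm.values["S1"], norm.values["S2"], rtol=1e-12)

    def test_nonzero_upper_quartiles_equalized(self):
        scaled = ie.upper_quartile_scale(toy_counts())
        uqs = [
            np.percentile(scaled[s][scaled[s] > 0], 75, method="linear")
            for s in scaled.columns
        ]
        assert max(uqs) - min(uqs) < 1e-9

    def test_normalized_flag_and_reapplication_rejected(self):
        norm = ie.upper_quartile_normalize(toy_counts())
        assert norm.normalized
        with pytest.raises(ValueError, match="already"):
            ie.upper_quartile_normalize(norm)

    def test_all_zero_sample_named(self):
        df = toy_counts()
        df["S4"] = 0
        with pytest.raises(ValueError, match="S4"):
            ie.upper_quartile_normalize(df)

    @given(
        n_genes=st.integers(5, 30),
        n_samples=st.integers(2, 6),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_fuzzed_matrices_share_upper_quartile(self, n_genes, n_samples, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.poisson(50, size=(n_genes, n_samples)) + 1,
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
        scaled = ie.upper_quartile_scale(counts)
        uqs = {
            s: np.percentile(scaled[s][scaled[s] > 0], 75, method="linear")
            for s in scaled.columns
        }
        vals = list(uqs.values())
        assert max(vals) - min(vals) < 1e-9


class TestReplicateAveraging:
    def test_singleton_groups_unchanged(self):
        norm = ie.upper_quartile_normalize(toy_counts())
        out = ie.average_technical_replicates(
            norm, {s: [s] for s in norm.samples}
        )
        pd.testing.assert_frame_equal(out.values, norm.values[out.samples])

    def test_identical_replicates_collapse_to_same_column(self):
        df = pd.DataFrame({"S1_r1": [1.0, 2.0], "S1_r2": [1.0, 2.0]}, index=["a", "b"])
        m = ie.ExpressionMatrix(df, normalized=True)
        out = ie.average_technical_replicates(m, {"S1": ["S1_r1", "S1_r2"]})
        np.testing.assert_allclose(out.values["S1"], [1.0, 2.0])

    def test_arithmetic_mean(self):
        df = pd.DataFrame({"r1": [1.0], "r2": [3.0]}, index=["g"])
        m = ie.ExpressionMatrix(df, normalized=True)
        out = ie.average_technical_replicates(m, {"S": ["r1", "r2"]})
        assert out.values.loc["g", "S"] == 2.0

    def test_incomplete_partition_rejected(self):
        m = ie.ExpressionMatrix(
            pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"]), normalized=True
        )
        with pytest.raises(ValueError, match="partition"):
            ie.average_technical_replicates(m, {"S": ["a"]})


class TestMetageneScore:
    def _norm(self, df):
        return ie.ExpressionMatrix(df, normalized=True)

    def test_single_gene_signature_is_that_row(self):
        df = pd.DataFrame({"S1": [1.0, 5.0], "S2": [2.0, 6.0]}, index=["G1", "G2"])
        out = ie.metagene_score(self._norm(df), ["G2"])
        np.testing.assert_allclose(out, [5.0, 6.0])

    def test_constant_matrix(self):
        df = pd.DataFrame(np.full((4, 3), 7.5), index=list("abcd"), columns=list("XYZ"))
        out = ie.metagene_score(self._norm(df), list("abcd"))
        np.testing.assert_allclose(out, 7.5)

    def test_median_of_three(self):
        df = pd.DataFrame({"S1": [1.0, 2.0, 9.0]}, index=["G1", "G2", "G3"])
        assert ie.metagene_score(self._norm(df), ["G1", "G2", "G3"])["S1"] == 2.0

    def test_gene_order_and_duplicates_irrelevant(self):
        df = pd.DataFrame({"S1": [1.0, 2.0, 9.0]}, index=["G1", "G2", "G3"])
        a = ie.metagene_score(self._norm(df), ["G3", "G1", "G2"])
        b = ie.metagene_score(self._norm(df), ["G1", "G2", "G3", "G2"])
        pd.testing.assert_series_equal(a, b)

    def test_empty_intersection_names_signature(self):
        df = pd.DataFrame({"S1": [1.0]}, index=["G1"])
        with pytest.raises(ValueError, match="MySig"):
            ie.metagene_score(self._norm(df), ["OTHER"], name="MySig")

    def test_unnormalized_matrix_rejected(self):
        m = ie.ExpressionMatrix(pd.DataFrame({"S1": [1]}, index=["G1"]))
        with pytest.raises(ValueError, match="normalized"):
            ie.metagene_score(m, ["G1"])

    def test_z_scores_standardized(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.normal(5, 1, size=(6, 10)),
            index=[f"G{i}" for i in range(6)],
            columns=[f"S{j}" for j in range(10)],
        )
        table = ie.score_signatures(
            ie.ExpressionMatrix(df, normalized=True),
            {"A": ["G0", "G1", "G2"], "B": ["G3", "G4", "G5"]},
        )
        np.testing.assert_allclose(table.z_scores.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(table.z_scores.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestGroupComparison:
    @staticmethod
    def _table(scores: pd.DataFrame):
        sd = scores.std(axis=1, ddof=1)
        z = scores.sub(scores.mean(axis=1), axis=0).div(sd.where(sd > 0, 1.0), axis=0)
        return ie.SignatureScoreTable(scores=scores, z_scores=z)

    def test_identical_groups_give_p_one(self):
        scores = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
            index=["Sig"],
            columns=[f"S{i}" for i in range(6)],
        )
        labels = {f"S{i}": ("A" if i < 3 else "B") for i in range(6)}
        (res,) = ie.compare_signature_groups(self._table(scores), labels)
        assert res.p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        scores = pd.DataFrame([[1.0, 2.0]], index=["Sig"], columns=["S0", "S1"])
        with pytest.raises(ValueError, match="nonempty"):
            ie.compare_signature_groups(self._table(scores), {"S0": "A", "S1": "A"})

    def test_bh_arithmetic(self):
        _, q, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_z_transform_does_not_change_p(self):
        rng = np.random.default_rng(11)
        scores = pd.DataFrame(
            rng.normal(size=(3, 20)),
            index=["A", "B", "C"],
            columns=[f"S{i}" for i in range(20)],
        )
        labels = {f"S{i}": ("A" if i < 9 else "B") for i in range(20)}
        table = self._table(scores)
        raw_table = ie.SignatureScoreTable(scores=scores, z_scores=scores)
        for sig_res, raw_res in zip(
            ie.compare_signature_groups(table, labels),
            ie.compare_signature_groups(raw_table, labels),
        ):
            assert sig_res.p == pytest.approx(raw_res.p, abs=1e-12)

    def test_planted_shift_detected(self):
        """A 2-SD location shift on 3 of 6 signatures is flagged at q<0.05."""
        rng = np.random.default_rng(5)
        n_a, n_b = 15, 19
        cols = [f"S{i}" for i in range(n_a + n_b)]
        labels = {c: ("A" if i < n_a else "B") for i, c in enumerate(cols)}
        rows = {}
        for s in range(6):
            base = rng.normal(0, 1, size=n_a + n_b)
            if s < 3:
                base[:n_a] -= 2.0
            rows[f"Sig{s}"] = base
        scores = pd.DataFrame(rows, index=cols).T
        results = ie.compare_signature_groups(self._table(scores), labels)
        affected = [r for r in results if r.signature in ("Sig0", "Sig1", "Sig2")]
        assert all(r.q < 0.05 for r in affected)
        assert all(r.direction == -1 for r in affected)

    def test_null_false_positive_rate_controlled(self):
        """Permuted labels keep the q<0.05 rate near or below nominal."""
        cfg = CohortConfig(seed=0, n_genes=800, n_signatures=8,
                           genes_per_signature=20, n_affected_signatures=0,
                           wound_healing_effect_brm=0.0)
        rng = np.random.default_rng(99)
        site_of = {f"S{i}": ("primary" if i < 10 else "brm") for i in range(20)}
        counts, signatures, _, _ = simulate_expression(rng, cfg, site_of)
        norm = ie.upper_quartile_normalize(counts)
        table = ie.score_signatures(norm, signatures)
        n_flagged = n_tests = 0
        for _ in range(60):
            perm = rng.permutation(list(site_of))
            labels = {s: ("A" if i < 10 else "B") for i, s in enumerate(perm)}
            for r in ie.compare_signature_groups(table, labels):
                n_tests += 1
                n_flagged += r.q < 0.05
        assert n_flagged / n_tests <= 0.05 + 0.02
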
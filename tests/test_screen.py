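"""Candidate calling, co-expression, coordination and the differential test."""

import math

import numpy as np
import pandas as pd
import pytest

from pancrna import screen as scr
from pancrna.annotation import define_promoters
from pancrna.quantify import quantify_pairs

from conftest import make_expression_table


@pytest.fixture(scope="module")
def noise_free_expr(noise_free_dataset):
    ds = noise_free_dataset
    promoters = define_promoters(ds.genes, ds.chrom_sizes)
    return quantify_pairs(ds.reads, promoters, ds.genes, ds.samples)


class TestCallPancCandidates:
    def test_noise_free_recovery_of_transcribed_promoters(self, noise_free_dataset, noise_free_expr):
        truth = noise_free_dataset.truth.set_index("gene_id")
        calls = scr.call_panc_candidates(noise_free_expr, "2cell", min_rpkm=1.0)
        expected = set(truth.index[truth["panc_2cell"] >= 1.0])
        assert set(calls.gene_ids) == expected

    def test_infinite_threshold_empty(self, noise_free_expr):
        assert scr.call_panc_candidates(noise_free_expr, "2cell", min_rpkm=math.inf).gene_ids == ()

    def test_all_zero_counts_empty(self):
        expr = make_expression_table({"g1:panc": {"MII": [0.0, 0.0]}, "g1:mRNA": {"MII": [0.0, 0.0]}})
        assert scr.call_panc_candidates(expr, "MII").gene_ids == ()


class TestClassifyCoexpression:
    def test_panc_only_pair(self):
        expr = make_expression_table({"g1:panc": {"MII": [2.0, 2.0]}, "g1:mRNA": {"MII": [0.0, 0.0]}})
        row = scr.classify_coexpression(expr, "MII").loc["g1"]
        assert row["panc_expressed"] and not row["mrna_expressed"] and not row["coexpressed"]

    def test_both_above_threshold_coexpressed(self):
        expr = make_expression_table({"g1:panc": {"MII": [2.0, 2.0]}, "g1:mRNA": {"MII": [3.0, 3.0]}})
        assert scr.classify_coexpression(expr, "MII").loc["g1", "coexpressed"]

    def test_noise_free_flags_match_truth(self, noise_free_dataset, noise_free_expr):
        truth = noise_free_dataset.truth.set_index("gene_id")
        status = scr.classify_coexpression(noise_free_expr, "2cell", expressed_thresh=0.5)
        for gene_id, row in status.iterrows():
            t = truth.loc[gene_id]
            assert row["panc_expressed"] == (t["panc_2cell"] > 0.5), gene_id
            assert row["mrna_expressed"] == (t["mrna_2cell"] > 0.5), gene_id


class TestGroupByPancLevel:
    def test_planted_association_orders_group_medians(self, small_dataset):
        ds = small_dataset
        promoters = define_promoters(ds.genes, ds.chrom_sizes)
        expr = quantify_pairs(ds.reads, promoters, ds.genes, ds.samples)
        groups = scr.group_by_panc_level(expr, "2cell", n=15)
        med = {k: np.median(v) for k, v in groups.mrna_rpkm.items()}
        assert med["C"] > med["A"]
        assert groups.tests[("C", "A")].pvalue < 0.05

    def test_truncation_warns_when_too_few_pairs(self):
        rpkm = {}
        for i in range(5):
            rpkm[f"g{i}:panc"] = {"MII": [float(i + 1)] * 2}
            rpkm[f"g{i}:mRNA"] = {"MII": [10.0] * 2}
        expr = make_expression_table(rpkm)
        with pytest.warns(UserWarning, match="truncated"):
            groups = scr.group_by_panc_level(expr, "MII", n=100)
        assert len(groups.groups["B"]) == 5

    def test_rank_ties_broken_by_gene_id(self):
        rpkm = {}
        for name in ["ga", "gb", "gc", "gd"]:
            rpkm[f"{name}:panc"] = {"MII": [2.0] * 2}  # all tied
            rpkm[f"{name}:mRNA"] = {"MII": [10.0] * 2}
        expr = make_expression_table(rpkm)
        groups = scr.group_by_panc_level(expr, "MII", n=2)
        assert groups.groups["B"] == ["ga", "gb"]
        assert groups.groups["C"] == ["gc", "gd"]


class TestCoordinationStats:
    def _expr(self, lfc_mrna_sign=1.0):
        rpkm = {}
        for i, fc in enumerate([1.0, 2.0, 3.0, 4.0]):
            rpkm[f"g{i}:panc"] = {"MII": [4.0] * 2, "2cell": [4.0 * 2**fc] * 2}
            m_fc = fc * lfc_mrna_sign
            rpkm[f"g{i}:mRNA"] = {"MII": [8.0] * 2, "2cell": [8.0 * 2**m_fc] * 2}
        return make_expression_table(rpkm)

    def test_identical_fold_changes_give_r_one(self):
        res = scr.coordination_stats(self._expr(), "MII", "2cell", pseudo=0.0)
        assert res.r_all == pytest.approx(1.0)
        assert res.n_both_up == 4

    def test_negated_mrna_fold_changes_give_r_minus_one(self):
        res = scr.coordination_stats(self._expr(lfc_mrna_sign=-1.0), "MII", "2cell", pseudo=0.0)
        assert res.r_all == pytest.approx(-1.0)
        assert res.n_both_up == 0

    def test_fewer_than_three_pairs_errors(self):
        expr = make_expression_table(
            {
                "g0:panc": {"MII": [1.0] * 2, "2cell": [2.0] * 2},
                "g0:mRNA": {"MII": [1.0] * 2, "2cell": [2.0] * 2},
            }
        )
        with pytest.raises(ValueError):
            scr.coordination_stats(expr, "MII", "2cell")

    def test_pseudocount_keeps_silent_pairs_finite(self):
        expr = make_expression_table(
            {
                "g0:panc": {"MII": [0.0] * 2, "2cell": [10.0] * 2},
                "g0:mRNA": {"MII": [0.0] * 2, "2cell": [10.0] * 2},
                "g1:panc": {"MII": [1.0] * 2, "2cell": [2.0] * 2},
                "g1:mRNA": {"MII": [1.0] * 2, "2cell": [2.0] * 2},
                "g2:panc": {"MII": [4.0] * 2, "2cell": [1.0] * 2},
                "g2:mRNA": {"MII": [4.0] * 2, "2cell": [1.0] * 2},
            }
        )
        res = scr.coordination_stats(expr, "MII", "2cell", pseudo=0.5)
        assert np.isfinite(res.table.to_numpy()).all()
        assert res.table.loc["g0", "log2fc_panc"] == pytest.approx(math.log2(10.5 / 0.5))


class TestSelectFollowup:
    def _expr(self, mii, two, esc):
        return make_expression_table(
            {
                "g0:panc": {"MII": [mii] * 2, "2cell": [two] * 2, "ESC": [esc] * 2},
                "g0:mRNA": {"MII": [1.0] * 2, "2cell": [1.0] * 2, "ESC": [1.0] * 2},
            }
        )

    def test_silent_in_mii_active_later_selected(self):
        out = scr.select_followup_candidates(self._expr(0.4, 2.0, 3.0))
        assert list(out.index) == ["g0"]

    def test_mii_above_threshold_rejected(self):
        assert scr.select_followup_candidates(self._expr(0.6, 2.0, 3.0)).empty

    def test_low_esc_rejected(self):
        assert scr.select_followup_candidates(self._expr(0.4, 2.0, 0.9)).empty

    def test_ranked_by_esc_ties_by_gene_id(self):
        rpkm = {}
        for name, esc in [("gb", 5.0), ("ga", 5.0), ("gc", 9.0)]:
            rpkm[f"{name}:panc"] = {"MII": [0.0] * 2, "2cell": [2.0] * 2, "ESC": [esc] * 2}
            rpkm[f"{name}:mRNA"] = {"MII": [1.0] * 2, "2cell": [1.0] * 2, "ESC": [1.0] * 2}
        out = scr.select_followup_candidates(make_expression_table(rpkm))
        assert list(out.index) == ["gc", "ga", "gb"]

    def test_missing_stage_errors(self):
        expr = make_expression_table({"g0:panc": {"MII": [0.0] * 2}, "g0:mRNA": {"MII": [1.0] * 2}}, stages=("MII",))
        with pytest.raises(ValueError, match="2cell"):
            scr.select_followup_candidates(expr)

    def test_noise_free_selection_matches_truth(self, noise_free_dataset, noise_free_expr):
        truth = noise_free_dataset.truth.set_index("gene_id")
        out = scr.select_followup_candidates(noise_free_expr)
        has_panc = truth["partnered"] & (truth["excluded"] == "")
        expected = set(
            truth.index[
                has_panc
                & (truth["panc_MII"] < 0.5)
                & (truth["panc_2cell"] > 1.0)
                & (truth["panc_ESC"] > 1.0)
            ]
        )
        assert set(out.index) == expected


def welch_oracle(a, b):
    """Independent textbook Welch computation (t, Welch-Satterthwaite df, p)."""
    from scipy.stats import t as tdist

    a = np.log2(np.asarray(a) + 1.0)
    b = np.log2(np.asarray(b) + 1.0)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


class TestDifferentialTest:
    def test_identical_groups(self):
        t, p = scr.differential_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_equal_means(self):
        _, p = scr.differential_test([5, 5, 5, 5], [5, 5, 5, 5])
        assert p == 1.0

    def test_zero_variance_unequal_means(self):
        t, p = scr.differential_test([5, 5, 5], [7, 7, 7])
        assert p == 0.0 and t == -math.inf

    def test_matches_independent_welch_formula(self):
        a = [1.2, 5.5, 3.3, 8.1]
        b = [10.0, 12.5, 9.7, 15.2, 11.1]
        t, p = scr.differential_test(a, b)
        t0, p0 = welch_oracle(a, b)
        assert t == pytest.approx(t0, abs=1e-9)
        assert p == pytest.approx(p0, abs=1e-9)

    def test_single_replicate_errors(self):
        with pytest.raises(ValueError):
            scr.differential_test([1.0], [1.0, 2.0])


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(scr.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(scr.bh_adjust([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(scr.bh_adjust([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            scr.bh_adjust([0.5, 1.5])

    def test_matches_stepup_formula_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = rng.random(size=rng.integers(2, 30))
            m = len(p)
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(scr.bh_adjust(p), expected, atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(8)
        p = rng.random(50)
        q = scr.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
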
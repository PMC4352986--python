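"""Stranded counting, RPKM and library QC statistics."""

import numpy as np
import pandas as pd
import pytest

from pancrna.annotation import GeneModel, define_promoters
from pancrna.quantify import (
    compute_rpkm,
    count_stranded_reads,
    quantify_pairs,
    replicate_correlation,
    strandedness_qc,
)

from conftest import make_expression_table


def reads_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "sample_id"])


def intervals_df(rows):
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand"])


def brute_force_counts(reads, intervals, samples):
    counts = pd.DataFrame(0, index=intervals["name"], columns=samples, dtype=int)
    for _, r in reads.iterrows():
        for _, iv in intervals.iterrows():
            if (
                r["chrom"] == iv["chrom"]
                and r["strand"] == iv["strand"]
                and iv["start"] <= r["pos"] < iv["end"]
            ):
                counts.loc[iv["name"], r["sample_id"]] += 1
    return counts


class TestCountStrandedReads:
    def test_read_in_window_on_matching_strand_counted(self):
        reads = reads_df([("chr1", 4500, "-", "s1")])
        ivs = intervals_df([("p", "chr1", 4000, 5000, "-")])
        assert count_stranded_reads(reads, ivs).loc["p", "s1"] == 1

    def test_wrong_strand_not_counted(self):
        reads = reads_df([("chr1", 4500, "+", "s1")])
        ivs = intervals_df([("p", "chr1", 4000, 5000, "-")])
        assert count_stranded_reads(reads, ivs, samples=["s1"]).loc["p", "s1"] == 0

    def test_half_open_boundaries(self):
        ivs = intervals_df([("p", "chr1", 100, 200, "+")])
        reads = reads_df([("chr1", 100, "+", "s"), ("chr1", 199, "+", "s"), ("chr1", 200, "+", "s")])
        assert count_stranded_reads(reads, ivs).loc["p", "s"] == 2

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(3)
        reads = reads_df(
            [
                (f"chr{rng.integers(1, 3)}", int(rng.integers(0, 10_000)),
                 "+" if rng.random() < 0.5 else "-", f"s{rng.integers(1, 4)}")
                for _ in range(2000)
            ]
        )
        starts = rng.integers(0, 9000, size=30)
        ivs = intervals_df(
            [
                (f"iv{i}", f"chr{rng.integers(1, 3)}", int(s), int(s + rng.integers(50, 1000)),
                 "+" if rng.random() < 0.5 else "-")
                for i, s in enumerate(starts)
            ]
        )
        samples = sorted(reads["sample_id"].unique())
        fast = count_stranded_reads(reads, ivs, samples=samples)
        slow = brute_force_counts(reads, ivs, samples)
        pd.testing.assert_frame_equal(fast, slow, check_names=False)

    def test_counting_is_permutation_invariant(self):
        rng = np.random.default_rng(4)
        reads = reads_df(
            [("chr1", int(rng.integers(0, 5000)), "+", "s") for _ in range(500)]
        )
        ivs = intervals_df([(f"iv{i}", "chr1", i * 250, i * 250 + 400, "+") for i in range(10)])
        base = count_stranded_reads(reads, ivs, samples=["s"])
        shuffled = count_stranded_reads(
            reads.sample(frac=1, random_state=1).reset_index(drop=True),
            ivs.sample(frac=1, random_state=2).reset_index(drop=True),
            samples=["s"],
        )
        pd.testing.assert_frame_equal(base.sort_index(), shuffled.sort_index(), check_names=False)

    def test_unknown_chromosome_warned_and_skipped(self):
        reads = reads_df([("chrX", 10, "+", "s"), ("chr1", 150, "+", "s")])
        ivs = intervals_df([("p", "chr1", 100, 200, "+")])
        with pytest.warns(UserWarning, match="chrX"):
            counts = count_stranded_reads(reads, ivs, samples=["s"], known_chroms={"chr1"})
        assert counts.loc["p", "s"] == 1


class TestComputeRpkm:
    def test_closed_form(self):
        assert compute_rpkm(10, 1000, 1_000_000) == pytest.approx(10.0)

    def test_zero_count(self):
        assert compute_rpkm(0, 500, 10_000) == 0.0

    def test_random_triples_match_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            c = int(rng.integers(0, 10_000))
            L = int(rng.integers(1, 50_000))
            t = int(rng.integers(1, 10_000_000))
            assert compute_rpkm(c, L, t) == pytest.approx(c / ((L / 1e3) * (t / 1e6)))

    def test_scale_invariance(self):
        assert compute_rpkm(40, 2000, 2_000_000) == pytest.approx(compute_rpkm(20, 2000, 1_000_000))

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            compute_rpkm(1, 1000, 0)


class TestStrandednessQc:
    GENES = [
        GeneModel("a", "chr1", "+", 1000, 2000, 1000),
        GeneModel("b", "chr1", "-", 5000, 6000, 1000),
    ]

    def test_all_correct_gives_one(self):
        reads = reads_df([("chr1", 1500, "+", "s"), ("chr1", 5500, "-", "s")])
        assert strandedness_qc(reads, self.GENES) == 1.0

    def test_all_flipped_gives_zero(self):
        reads = reads_df([("chr1", 1500, "-", "s"), ("chr1", 5500, "+", "s")])
        assert strandedness_qc(reads, self.GENES) == 0.0

    def test_reads_outside_genes_ignored(self):
        reads = reads_df([("chr1", 1500, "+", "s"), ("chr1", 3000, "-", "s")])
        assert strandedness_qc(reads, self.GENES) == 1.0

    def test_reads_in_overlapping_genes_ineligible(self):
        genes = self.GENES + [GeneModel("c", "chr1", "-", 1500, 2500, 1000)]
        reads = reads_df([("chr1", 1600, "+", "s"), ("chr1", 5500, "-", "s")])
        # position 1600 falls in two spans -> excluded; only the read in b counts
        assert strandedness_qc(reads, genes) == 1.0

    def test_no_eligible_reads_errors(self):
        reads = reads_df([("chr1", 9000, "+", "s")])
        with pytest.raises(ValueError):
            strandedness_qc(reads, self.GENES)


class TestReplicateCorrelation:
    def test_duplicate_columns_give_r_one(self):
        expr = make_expression_table(
            {f"g{i}:mRNA": {"MII": [v, v]} for i, v in enumerate([1.0, 4.0, 9.0, 16.0])},
            stages=("MII",),
        )
        corr = replicate_correlation(expr, "MII")
        assert corr.loc["MII_r1", "MII_r2"] == pytest.approx(1.0)

    def test_reflected_columns_give_r_minus_one(self):
        # second replicate = reflection of the first around its mean (log2 scale
        # is monotone, so use values whose log2 is an exact reflection)
        a = np.array([1.0, 3.0, 7.0])  # log2(x+1) = 1, 2, 3
        b = np.array([7.0, 3.0, 1.0])
        expr = make_expression_table(
            {f"g{i}:mRNA": {"MII": [float(a[i]), float(b[i])]} for i in range(3)},
            stages=("MII",),
        )
        corr = replicate_correlation(expr, "MII")
        assert corr.loc["MII_r1", "MII_r2"] == pytest.approx(-1.0)

    def test_nb_replicates_from_identical_means_correlate(self):
        rng = np.random.default_rng(6)
        mu = np.exp2(rng.normal(6, 2.0, size=2000))
        r = 1 / 0.1
        reps = [rng.negative_binomial(r, r / (r + mu)) for _ in range(2)]
        expr = make_expression_table(
            {f"g{i}:mRNA": {"MII": [float(reps[0][i]), float(reps[1][i])]} for i in range(2000)},
            stages=("MII",),
        )
        corr = replicate_correlation(expr, "MII")
        assert corr.loc["MII_r1", "MII_r2"] > 0.9

    def test_zero_variance_reported_as_nan(self):
        expr = make_expression_table(
            {f"g{i}:mRNA": {"MII": [1.0, float(i)]} for i in range(4)},
            stages=("MII",),
        )
        corr = replicate_correlation(expr, "MII")
        assert np.isnan(corr.loc["MII_r1", "MII_r2"])


class TestQuantifyPairs:
    def setup_method(self):
        self.gene = GeneModel("g", "chr1", "+", 5000, 7000, 2000)
        self.promoters = define_promoters([self.gene], {"chr1": 100_000})
        self.samples = pd.DataFrame({"stage": ["MII"], "replicate": [1]}, index=pd.Index(["s1"], name="sample_id"))

    def test_direct_counts(self):
        rows = [("chr1", 4000 + i, "-", "s1") for i in range(5)]  # antisense promoter reads
        rows += [("chr1", 5000 + i, "+", "s1") for i in range(20)]  # sense gene reads
        rows += [("chr1", 50_000 + i, "+", "s1") for i in range(975)]  # filler to total 1000
        expr = quantify_pairs(reads_df(rows), self.promoters, [self.gene], self.samples)
        assert expr.counts.loc["g:panc", "s1"] == 5
        assert expr.counts.loc["g:mRNA", "s1"] == 20
        # RPKM: 5 / (1kb * 1e-3 M) and 20 / (2kb * 1e-3 M)
        assert expr.rpkm.loc["g:panc", "s1"] == pytest.approx(5000.0)
        assert expr.rpkm.loc["g:mRNA", "s1"] == pytest.approx(10_000.0)

    def test_excluded_promoter_has_no_panc_feature(self):
        other = GeneModel("x", "chr1", "-", 4100, 4400, 300)
        promoters = define_promoters([self.gene, other], {"chr1": 100_000})
        reads = reads_df([("chr1", 5100, "+", "s1")])
        expr = quantify_pairs(reads, promoters, [self.gene, other], self.samples)
        assert "g:panc" not in expr.features.index
        assert "g:mRNA" in expr.features.index

    def test_unknown_sample_errors(self):
        reads = reads_df([("chr1", 5100, "+", "mystery")])
        with pytest.raises(ValueError, match="mystery"):
            quantify_pairs(reads, self.promoters, [self.gene], self.samples)

    def test_composition_matches_primitives(self, small_dataset):
        """The full table equals count_stranded_reads + compute_rpkm composed."""
        from pancrna.quantify import count_stranded_reads, compute_rpkm

        ds = small_dataset
        promoters = define_promoters(ds.genes, ds.chrom_sizes)
        expr = quantify_pairs(ds.reads, promoters, ds.genes, ds.samples)
        ivs = []
        for g in ds.genes[:20]:
            ivs.append((f"{g.gene_id}:mRNA", g.chrom, g.start, g.end, g.strand))
        ivs = pd.DataFrame(ivs, columns=["name", "chrom", "start", "end", "strand"])
        samples = list(ds.samples.index)
        counts = count_stranded_reads(ds.reads, ivs, samples=samples)
        totals = ds.reads["sample_id"].value_counts()
        for name in ivs["name"]:
            gene = next(g for g in ds.genes if f"{g.gene_id}:mRNA" == name)
            for s in samples:
                assert expr.counts.loc[name, s] == counts.loc[name, s]
                assert expr.rpkm.loc[name, s] == pytest.approx(
                    compute_rpkm(counts.loc[name, s], gene.exon_lengths_bp, totals[s])
                )
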
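"""Strand-aware read counting, RPKM and library QC.

Directional RNA-seq keeps the strand of origin of every read, which is
what makes pancRNA quantification possible at all: only reads whose 5' end
falls inside the promoter window *and* whose strand is the antisense
(pancRNA) strand are counted.  Assignment uses the 5'-end position alone,
so a 50-bp single-end read at a window boundary is never split between the
promoter and the gene body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, PromoterWindow, PLUS, MINUS

READ_COLUMNS = ["chrom", "pos", "strand", "sample_id"]

PANC_FEATURE_LEN = 1000  # promoter window length: the pancRNA RPKM denominator


@dataclass
class ExpressionTable:
    """RPKM and raw counts for pancRNA and mRNA features across samples.

    ``features`` is indexed by feature_id (``<gene>:panc`` / ``<gene>:mRNA``)
    with columns ``kind``, ``gene_id``, ``length_bp``; ``samples`` is indexed
    by sample_id with columns ``stage``, ``replicate``.  ``counts`` and
    ``rpkm`` are features x samples.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    counts: pd.DataFrame
    rpkm: pd.DataFrame

    def samples_for(self, stage: str) -> list[str]:
        sel = self.samples.index[self.samples["stage"] == stage].tolist()
        if not sel:
            raise KeyError(f"no samples at stage {stage!r}")
        return sel

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.samples["stage"]))

    def mean_rpkm(self, kind: str, stage: str) -> pd.Series:
        """Mean RPKM across replicates at a stage, indexed by gene_id."""
        feats = self.features.index[self.features["kind"] == kind]
        means = self.rpkm.loc[feats, self.samples_for(stage)].mean(axis=1)
        means.index = self.features.loc[feats, "gene_id"]
        return means

    def genes_with(self, kind: str) -> pd.Index:
        return pd.Index(self.features.loc[self.features["kind"] == kind, "gene_id"])

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        self.features.to_csv(outdir / "features.tsv", sep="\t")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t")
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.rpkm.to_csv(outdir / "rpkm.tsv", sep="\t", float_format="%.6g")

    @classmethod
    def load(cls, indir) -> "ExpressionTable":
        indir = Path(indir)
        features = pd.read_csv(indir / "features.tsv", sep="\t", index_col=0)
        samples = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0)
        counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
        rpkm = pd.read_csv(indir / "rpkm.tsv", sep="\t", index_col=0)
        return cls(features, samples, counts, rpkm)


# ---------------------------------------------------------------------------
# Read tables
# ---------------------------------------------------------------------------

def load_read_table(path) -> pd.DataFrame:
    """Read a plain TSV read table: chrom, pos (0-based 5' end), strand, sample_id."""
    reads = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64, "strand": str, "sample_id": str})
    missing = set(READ_COLUMNS) - set(reads.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    bad = ~reads["strand"].isin([PLUS, MINUS])
    if bad.any():
        raise ValueError(f"read table contains invalid strand values: {reads.loc[bad, 'strand'].unique()[:5]}")
    return reads


def load_bam(path, sample_id: str, reverse_stranded: bool = False) -> pd.DataFrame:
    """Extract 5'-end read records from a BAM.

    The 5' end is the first aligned base of the alignment in read
    orientation (``reference_end - 1`` for reverse-strand alignments);
    secondary and supplementary alignments are ignored so every fragment is
    counted once, at its primary alignment.  ``reverse_stranded`` flips the
    read strand for dUTP-style protocols where the read is antisense to the
    transcript.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = MINUS if aln.is_reverse else PLUS
            pos = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            if reverse_stranded:
                strand = PLUS if strand == MINUS else MINUS
            rows.append((aln.reference_name, pos, strand, sample_id))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def _sorted_positions(reads: pd.DataFrame) -> dict[tuple[str, str, str], np.ndarray]:
    """Index read 5' positions by (sample, chrom, strand), sorted for searchsorted."""
    out = {}
    for key, grp in reads.groupby(["sample_id", "chrom", "strand"], sort=True):
        out[key] = np.sort(grp["pos"].to_numpy(dtype=np.int64))
    return out


# ---------------------------------------------------------------------------
# Counting and RPKM
# ---------------------------------------------------------------------------

def count_stranded_reads(
    reads: pd.DataFrame,
    intervals: pd.DataFrame,
    samples: Sequence[str] | None = None,
    known_chroms: set[str] | None = None,
) -> pd.DataFrame:
    """Count reads per interval per sample under the 5'-end + strand rule.

    A read is counted for an interval iff its 5' end lies in the half-open
    interval and its strand equals the interval strand; a read may count
    toward several overlapping intervals.  ``intervals`` needs columns
    name/chrom/start/end/strand; the result is indexed by interval name with
    one column per sample.
    """
    for col in ("name", "chrom", "start", "end", "strand"):
        if col not in intervals.columns:
            raise ValueError(f"intervals table missing column {col!r}")
    if (intervals["end"] <= intervals["start"]).any():
        raise ValueError("degenerate interval (end <= start)")
    if known_chroms is not None:
        unknown = ~reads["chrom"].isin(known_chroms)
        if unknown.any():
            warnings.warn(
                f"skipping {int(unknown.sum())} reads on unknown chromosomes: "
                f"{sorted(reads.loc[unknown, 'chrom'].unique())[:5]}"
            )
            reads = reads.loc[~unknown]
    if samples is None:
        samples = sorted(reads["sample_id"].unique())
    pos_index = _sorted_positions(reads)
    counts = pd.DataFrame(0, index=intervals["name"], columns=list(samples), dtype=np.int64)
    for (chrom, strand), grp in intervals.groupby(["chrom", "strand"], sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        for sample in samples:
            pos = pos_index.get((sample, chrom, strand))
            if pos is None:
                continue
            lo = np.searchsorted(pos, starts, side="left")
            hi = np.searchsorted(pos, ends, side="left")
            counts.loc[grp["name"], sample] = hi - lo
    return counts


def compute_rpkm(count, feature_length_bp, total_mapped_reads):
    """RPKM = count / ((length/1000) * (total/1e6)); accepts scalars or arrays."""
    total = np.asarray(total_mapped_reads, dtype=np.float64)
    length = np.asarray(feature_length_bp, dtype=np.float64)
    if (total < 1).any():
        raise ValueError("total_mapped_reads must be >= 1")
    if (length < 1).any():
        raise ValueError("feature_length_bp must be >= 1")
    out = np.asarray(count, dtype=np.float64) / ((length / 1e3) * (total / 1e6))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

def strandedness_qc(reads: pd.DataFrame, genes: Sequence[GeneModel]) -> float:
    """Fraction of gene-overlapping reads mapped on the annotated strand.

    Only reads whose 5' end falls in exactly one gene span are eligible, so
    ambiguous positions inside overlapping genes never dilute the statistic.
    """
    per_strand: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for strand in (PLUS, MINUS):
        for chrom in {g.chrom for g in genes}:
            spans = [(g.start, g.end) for g in genes if g.chrom == chrom and g.strand == strand]
            if spans:
                starts = np.sort(np.array([s for s, _ in spans], dtype=np.int64))
                ends = np.sort(np.array([e for _, e in spans], dtype=np.int64))
                per_strand[(chrom, strand)] = (starts, ends)

    def containment(chrom: str, strand: str, pos: np.ndarray) -> np.ndarray:
        entry = per_strand.get((chrom, strand))
        if entry is None:
            return np.zeros(len(pos), dtype=np.int64)
        starts, ends = entry
        return np.searchsorted(starts, pos, side="right") - np.searchsorted(ends, pos, side="right")

    eligible = 0
    correct = 0
    for chrom, grp in reads.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        read_strand = grp["strand"].to_numpy()
        c_plus = containment(chrom, PLUS, pos)
        c_minus = containment(chrom, MINUS, pos)
        single = (c_plus + c_minus) == 1
        eligible += int(single.sum())
        gene_strand = np.where(c_plus == 1, PLUS, MINUS)
        correct += int((single & (gene_strand == read_strand)).sum())
    if eligible == 0:
        raise ValueError("strandedness undefined: no reads fall within exactly one gene span")
    return correct / eligible


def replicate_correlation(expr: ExpressionTable, stage: str) -> pd.DataFrame:
    """Pairwise Pearson r between replicates at a stage, on log2(RPKM + 1).

    Zero-variance replicates yield NaN entries (r undefined for that pair);
    the diagonal is 1.0 for well-defined columns.
    """
    cols = expr.samples_for(stage)
    if len(cols) < 2:
        raise ValueError(f"need >= 2 replicates at stage {stage!r}")
    mat = np.log2(expr.rpkm[cols] + 1.0)
    if mat.shape[0] < 3:
        raise ValueError("need >= 3 features for replicate correlation")
    return mat.corr(method="pearson")


# ---------------------------------------------------------------------------
# Pair quantification
# ---------------------------------------------------------------------------

def quantify_pairs(
    reads: pd.DataFrame,
    promoters: Sequence[PromoterWindow],
    genes: Sequence[GeneModel],
    sample_sheet: pd.DataFrame,
) -> ExpressionTable:
    """Count the pancRNA/mRNA feature pair of every gene and fill RPKM.

    The pancRNA feature of a gene is its (non-excluded) promoter window on
    the pancRNA strand; the mRNA feature is the gene span on the gene
    strand.  RPKM denominators: the 1 kb window for pancRNAs and
    ``exon_lengths_bp`` for mRNAs.  The per-sample library size is the total
    number of reads of that sample in the input table.
    """
    unknown = set(reads["sample_id"].unique()) - set(sample_sheet.index)
    if unknown:
        raise ValueError(f"reads contain samples absent from the sample sheet: {sorted(unknown)}")
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for g in genes:
        rows.append((f"{g.gene_id}:mRNA", "mRNA", g.gene_id, g.exon_lengths_bp, g.chrom, g.start, g.end, g.strand))
    for w in promoters:
        if w.is_excluded:
            continue
        if w.gene_id not in by_id:
            raise ValueError(f"promoter for unknown gene {w.gene_id}")
        rows.append((f"{w.gene_id}:panc", "pancRNA", w.gene_id, w.length, w.chrom, w.start, w.end, w.panc_strand))
    table = pd.DataFrame(
        rows, columns=["name", "kind", "gene_id", "length_bp", "chrom", "start", "end", "strand"]
    ).set_index("name", drop=False)
    sample_ids = list(sample_sheet.index)
    counts = count_stranded_reads(reads, table, samples=sample_ids, known_chroms={g.chrom for g in genes})
    totals = reads["sample_id"].value_counts().reindex(sample_ids).fillna(0).astype(np.int64)
    if (totals < 1).any():
        zero = totals.index[totals < 1].tolist()
        raise ValueError(f"samples with zero mapped reads: {zero}")
    rpkm = counts / np.outer(table["length_bp"].to_numpy() / 1e3, totals.to_numpy() / 1e6)
    features = table[["kind", "gene_id", "length_bp"]].copy()
    features.index.name = "feature_id"
    return ExpressionTable(features=features, samples=sample_sheet.copy(), counts=counts, rpkm=rpkm)
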
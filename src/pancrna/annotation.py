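"""Gene models, strand-aware promoter windows and CpG islands.

A pancRNA (promoter-associated noncoding RNA) is transcribed divergently
from the promoter of a partner gene: its reads map to the strand opposite
the mRNA, within the 1 kb immediately upstream of the TSS.  Everything
downstream of this module is anchored on the windows defined here.

Coordinate convention: all internal coordinates are 0-based half-open
``[start, end)``.  GTF input is read as 1-based inclusive; BED output is
written 0-based half-open.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from gffutils.iterators import DataIterator

PLUS = "+"
MINUS = "-"
PROMOTER_LEN = 1000
MOTIF_WINDOW_LEN = 500

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: the anchor for every window in the analysis.

    ``tss`` is the 5'-most transcribed base: ``start`` on the plus strand,
    ``end - 1`` on the minus strand.  ``exon_lengths_bp`` is the length of
    the union of all exons and is the denominator of the mRNA RPKM.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exon_lengths_bp: int

    def __post_init__(self) -> None:
        if self.strand not in (PLUS, MINUS):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end ({self.start}, {self.end})")
        if self.exon_lengths_bp < 1:
            raise ValueError(f"{self.gene_id}: exon_lengths_bp must be >= 1")

    @property
    def tss(self) -> int:
        return self.start if self.strand == PLUS else self.end - 1

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PromoterWindow:
    """The [-1000, -1] window upstream of a TSS, with its pancRNA strand.

    ``panc_strand`` is always opposite the gene strand: divergent
    transcription from a bidirectional promoter runs antisense to the mRNA.
    ``excluded`` carries a machine-readable reason (``overlaps_gene`` or
    ``out_of_bounds``) or ``None`` for usable windows.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    panc_strand: str
    excluded: str | None = None

    @property
    def is_excluded(self) -> bool:
        return self.excluded is not None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionWindows:
    """Promoter [-500, -1] and gene-body [+1, +500] windows of one gene.

    Both intervals are genomic; orientation follows the gene strand, so for
    a minus-strand gene the promoter window lies to the right of the TSS.
    ``truncated`` flags genes shorter than the nominal body window.
    """

    gene_id: str
    chrom: str
    promoter: tuple[int, int]
    body: tuple[int, int]
    truncated: bool = False


@dataclass(frozen=True)
class CpGIsland:
    chrom: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

def _gtf_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            return fh.read()
    if isinstance(source, str):
        return source
    raise TypeError(f"cannot read GTF from {type(source)!r}")


def _validate_gtf(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"malformed GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from exc
        if start < 1 or end < start:
            raise ValueError(f"malformed GTF line {lineno}: invalid interval {start}-{end}")
        if fields[6] not in (PLUS, MINUS, "."):
            raise ValueError(f"malformed GTF line {lineno}: bad strand {fields[6]!r}")


def parse_gene_models(source) -> list[GeneModel]:
    """Parse a GTF (path, text or handle) into one :class:`GeneModel` per gene.

    The gene span is the union of its features; where several transcripts
    exist the 5'-most TSS per gene defines the promoter (the span edge on
    the 5' side).  ``exon_lengths_bp`` is the length of the union of exons.
    Genes with no exon features are skipped with a warning.
    """
    text = _gtf_text(source)
    _validate_gtf(text)
    spans: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for feat in DataIterator(text, from_string=True):
        try:
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValueError(f"feature without gene_id attribute: {feat}") from exc
        start0, end0 = feat.start - 1, feat.end
        rec = spans.get(gene_id)
        if rec is None:
            spans[gene_id] = {"chrom": feat.seqid, "strand": feat.strand, "start": start0, "end": end0}
            order.append(gene_id)
        else:
            if rec["chrom"] != feat.seqid or rec["strand"] != feat.strand:
                raise ValueError(f"gene {gene_id}: inconsistent chrom/strand across features")
            rec["start"] = min(rec["start"], start0)
            rec["end"] = max(rec["end"], end0)
        if feat.featuretype == "exon":
            exons.setdefault(gene_id, []).append((start0, end0))
    genes = []
    for gene_id in order:
        rec = spans[gene_id]
        if gene_id not in exons:
            warnings.warn(f"gene {gene_id} has no exons; skipped")
            continue
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=rec["start"],
                end=rec["end"],
                exon_lengths_bp=_union_length(exons[gene_id]),
            )
        )
    return genes


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def define_promoters(
    genes: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    upstream_len: int = PROMOTER_LEN,
) -> list[PromoterWindow]:
    """Derive the pancRNA quantification window of every gene.

    A plus-strand gene with TSS ``t`` gets ``[t - upstream_len, t)`` with
    pancRNA strand '-'; a minus-strand gene gets ``[t + 1, t + 1 + upstream_len)``
    with pancRNA strand '+'.  A window is excluded (never truncated) when it
    overlaps the span of any *other* gene on either strand -- divergent reads
    there could be mRNA contamination -- or when it does not fit on the
    chromosome, so all usable windows are length-comparable.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrs = {
        chrom: (
            np.array([g.start for g in gs], dtype=np.int64),
            np.array([g.end for g in gs], dtype=np.int64),
            [g.gene_id for g in gs],
        )
        for chrom, gs in by_chrom.items()
    }
    windows = []
    for g in genes:
        if g.strand == PLUS:
            s, e, panc = g.tss - upstream_len, g.tss, MINUS
        else:
            s, e, panc = g.tss + 1, g.tss + 1 + upstream_len, PLUS
        reason = None
        size = chrom_sizes.get(g.chrom)
        if size is None or s < 0 or e > size:
            reason = "out_of_bounds"
        else:
            starts, ends, ids = arrs[g.chrom]
            hit = (starts < e) & (ends > s)
            if any(ids[i] != g.gene_id for i in np.nonzero(hit)[0]):
                reason = "overlaps_gene"
        windows.append(PromoterWindow(g.gene_id, g.chrom, s, e, panc, excluded=reason))
    return windows


def motif_windows(gene: GeneModel, window_len: int = MOTIF_WINDOW_LEN) -> RegionWindows:
    """Promoter [-500, -1] and gene-body [+1, +500] windows for motif scans.

    The body window is truncated to the gene span (and flagged) when the
    gene is shorter than ``window_len``.
    """
    body_len = min(window_len, gene.span_length)
    if gene.strand == PLUS:
        promoter = (gene.tss - window_len, gene.tss)
        body = (gene.tss, gene.tss + body_len)
    else:
        promoter = (gene.tss + 1, gene.tss + 1 + window_len)
        body = (gene.tss + 1 - body_len, gene.tss + 1)
    return RegionWindows(gene.gene_id, gene.chrom, promoter, body, truncated=body_len < window_len)


# ---------------------------------------------------------------------------
# CpG islands
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode_sequence(seq: str) -> np.ndarray:
    """Map ACGTN (case-insensitive) to integers 0..4; other characters error."""
    lut = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
        lut[ord(base.lower())] = idx
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-ACGTN character in sequence: {bad!r}")
    return arr.astype(np.int8)


def _window_stats(is_c, is_g, is_cpg, s: int, e: int) -> tuple[float, float]:
    # cumulative-sum arrays: counts over [s, e)
    length = e - s
    n_c = int(is_c[e] - is_c[s])
    n_g = int(is_g[e] - is_g[s])
    # CpG at position i means seq[i] == C and seq[i+1] == G; count those with i in [s, e-1)
    n_cpg = int(is_cpg[min(e - 1, len(is_cpg) - 1)] - is_cpg[s])
    gc = (n_c + n_g) / length
    oe = (n_cpg * length) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return gc, oe


def detect_cpg_islands(
    seq: str,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    chrom: str = "",
) -> list[CpGIsland]:
    """Detect CpG islands with the classical sliding-window definition.

    Every ``min_len`` window (1-bp step) is tested for G+C fraction
    >= ``min_gc`` and observed/expected CpG >= ``min_oe`` where
    ``obs/exp = (#CpG * L) / (#C * #G)``; windows containing N never pass.
    Overlapping passing windows are merged into maximal islands whose
    statistics are recomputed on the merged interval; a merged interval that
    drops below a threshold is trimmed from the right until it passes again
    (it always contains at least one passing window).
    """
    n = len(seq)
    if n < min_len:
        return []
    arr = encode_sequence(seq)
    is_c = np.concatenate([[0], np.cumsum(arr == 1)])
    is_g = np.concatenate([[0], np.cumsum(arr == 2)])
    is_n = np.concatenate([[0], np.cumsum(arr == 4)])
    cpg = (arr[:-1] == 1) & (arr[1:] == 2)
    is_cpg = np.concatenate([[0], np.cumsum(cpg)])

    n_win = n - min_len + 1
    starts = np.arange(n_win)
    ends = starts + min_len
    c_cnt = is_c[ends] - is_c[starts]
    g_cnt = is_g[ends] - is_g[starts]
    n_cnt = is_n[ends] - is_n[starts]
    cpg_cnt = is_cpg[ends - 1] - is_cpg[starts]
    gc_ok = (c_cnt + g_cnt) >= min_gc * min_len
    denom = (c_cnt * g_cnt).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, cpg_cnt * float(min_len) / denom, 0.0)
    passing = gc_ok & (oe >= min_oe) & (n_cnt == 0)
    if not passing.any():
        return []

    islands = []
    idx = np.nonzero(passing)[0]
    # group window starts into runs whose windows overlap (gap < min_len)
    breaks = np.nonzero(np.diff(idx) >= min_len)[0]
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [len(idx) - 1]])
    for a, b in zip(run_starts, run_ends):
        s, e = int(idx[a]), int(idx[b]) + min_len
        gc, oe_val = _window_stats(is_c, is_g, is_cpg, s, e)
        while (gc < min_gc or oe_val < min_oe) and e - s > min_len:
            e -= 1
            gc, oe_val = _window_stats(is_c, is_g, is_cpg, s, e)
        islands.append(CpGIsland(chrom, s, e, gc, oe_val))
    return islands


def classify_promoter_cpgi(window: PromoterWindow, islands: Iterable[CpGIsland]) -> bool:
    """True iff any CpG island overlaps the promoter window by >= 1 bp."""
    return any(
        isl.chrom == window.chrom and isl.start < window.end and isl.end > window.start
        for isl in islands
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def promoters_to_bed(windows: Sequence[PromoterWindow], path) -> None:
    """BED6 of non-excluded promoters: name=gene_id, score=0, strand=panc_strand."""
    with open(path, "w") as fh:
        for w in windows:
            if not w.is_excluded:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.gene_id}\t0\t{w.panc_strand}\n")


def exclusions_to_tsv(windows: Sequence[PromoterWindow], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\treason\n")
        for w in windows:
            if w.is_excluded:
                fh.write(f"{w.gene_id}\t{w.chrom}\t{w.start}\t{w.end}\t{w.excluded}\n")


def cpg_islands_to_bed(islands: Sequence[CpGIsland], path) -> None:
    with open(path, "w") as fh:
        for i, isl in enumerate(islands):
            name = f"CpGi_{i}"
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\t{name}\t"
                f"{isl.gc_fraction:.3f};{isl.obs_exp_cpg:.3f}\t.\n"
            )


def load_genome_fasta(path) -> dict[str, str]:
    """Read a FASTA into an uppercase in-memory dict (chrom -> sequence)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split("\t")[:2]
                sizes[chrom] = int(size)
    return sizes
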
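"""PWM scanning with min-max identity and strand/region asymmetry profiles.

The asymmetry statistic captures a hallmark of divergent promoters: around
the TSS of a pancRNA-partnered gene, a CT-rich element tends to sit on the
sense strand of the promoter and on the antisense strand of the gene body,
i.e. always upstream of a transcription unit, with the TSS as the switching
point.  Hits are called at a min-max normalized log-probability score
("identity"), so a 0.9 threshold means a window scoring within the top 10%
of the achievable score range of the matrix -- the convention of classical
PWM-matching tools.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    PromoterWindow,
    CpGIsland,
    classify_promoter_cpgi,
    encode_sequence,
    motif_windows,
    reverse_complement,
    PLUS,
    MINUS,
)

BASES = "ACGT"
DEFAULT_MIN_IDENTITY = 0.9

CATEGORIES = ("promoter_sense", "promoter_antisense", "body_sense", "body_antisense")


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position probabilities over A, C, G, T.

    ``probs`` has shape (4, W) with columns summing to 1.  Zero entries are
    allowed at construction (a zero-pseudocount matrix is a legitimate
    description of its sites) but scanning requires strictly positive
    probabilities, i.e. a pseudocount.  ``counts`` records the provenance
    when built from aligned sites or a count matrix.
    """

    probs: np.ndarray
    counts: np.ndarray | None = None
    name: str = "motif"

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != 4 or p.shape[1] < 1:
            raise ValueError("PWM must be a 4 x W matrix")
        if (p < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    start: int  # 0-based genomic/sequence position of the leftmost base
    strand: str
    identity: float


@dataclass(frozen=True)
class RegionMotifProfile:
    """Fractions of genes with >= 1 hit in each strand/region category.

    Strand is re-expressed relative to the mRNA direction of each gene
    (sense = hit strand equals gene strand).  ``hit_counts`` carries the raw
    number of hits per category, since presence fractions and hit counts can
    rank categories differently.
    """

    fractions: dict
    hit_counts: dict
    n_genes: int
    per_gene: pd.DataFrame


def build_pwm(aligned_sites: Sequence[str], pseudocount: float = 0.5, name: str = "motif") -> PWM:
    """Build a PWM from equal-length aligned sites.

    P(base b at column j) = (count_j(b) + pseudocount) / (n + 4 * pseudocount).
    """
    if not aligned_sites:
        raise ValueError("need >= 1 aligned site")
    width = len(aligned_sites[0])
    counts = np.zeros((4, width), dtype=np.float64)
    for site in aligned_sites:
        if len(site) != width:
            raise ValueError(f"sites must be equal length ({len(site)} != {width})")
        for j, base in enumerate(site.upper()):
            idx = BASES.find(base)
            if idx < 0:
                raise ValueError(f"non-ACGT character in site: {base!r}")
            counts[idx, j] += 1
    return pwm_from_counts(counts, pseudocount=pseudocount, name=name)


def pwm_from_counts(counts: np.ndarray, pseudocount: float = 0.5, name: str = "motif") -> PWM:
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("count matrix must be 4 x W (rows A, C, G, T)")
    n = counts.sum(axis=0)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    probs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    return PWM(probs=probs, counts=counts, name=name)


# ---------------------------------------------------------------------------
# JASPAR / MEME I/O (via Bio.motifs)
# ---------------------------------------------------------------------------

def read_pwm(path, pseudocount: float = 0.5) -> PWM:
    """Read a JASPAR-style count matrix or MEME minimal motif file."""
    from Bio import motifs as bio_motifs

    last_error = None
    for fmt in ("jaspar", "minimal"):
        try:
            with open(path) as fh:
                motif = bio_motifs.read(fh, fmt)
            counts = np.array([list(motif.counts[b]) for b in BASES], dtype=np.float64)
            name = motif.name or getattr(motif, "matrix_id", None) or "motif"
            return pwm_from_counts(counts, pseudocount=pseudocount, name=str(name))
        except Exception as exc:  # try the next format
            last_error = exc
    raise ValueError(f"could not parse {path} as JASPAR or MEME minimal: {last_error}")


def write_jaspar(pwm: PWM, path) -> None:
    counts = pwm.counts if pwm.counts is not None else np.round(pwm.probs * 100)
    with open(path, "w") as fh:
        fh.write(f">{pwm.name} {pwm.name}\n")
        for i, base in enumerate(BASES):
            vals = " ".join(f"{v:7.2f}" for v in counts[i])
            fh.write(f"{base} [{vals} ]\n")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _window_identities(seq: str, pwm: PWM) -> np.ndarray:
    """Min-max identity of every window of ``seq`` on the given strand;
    windows containing N are NaN."""
    if (pwm.probs == 0).any():
        raise ValueError("scanning requires strictly positive probabilities; rebuild the PWM with a pseudocount")
    logp = np.log2(pwm.probs)
    arr = encode_sequence(seq)
    W = pwm.width
    n_win = len(arr) - W + 1
    if n_win <= 0:
        return np.empty(0)
    logp_ext = np.vstack([logp, np.zeros((1, W))])  # row 4 = N placeholder
    scores = np.zeros(n_win)
    for j in range(W):
        scores += logp_ext[arr[j : j + n_win], j]
    has_n = np.zeros(n_win, dtype=bool)
    n_pos = np.nonzero(arr == 4)[0]
    for p in n_pos:
        lo = max(0, p - W + 1)
        has_n[lo : min(n_win, p + 1)] = True
    s_min = logp.min(axis=0).sum()
    s_max = logp.max(axis=0).sum()
    identity = (scores - s_min) / (s_max - s_min)
    identity[has_n] = np.nan
    return identity


def scan_pwm(
    seq: str,
    pwm: PWM,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    strands: str = "both",
) -> list[MotifHit]:
    """Scan both strands for windows with identity >= ``min_identity``.

    identity = (s - s_min) / (s_max - s_min) where s is the window's summed
    log2 probability and s_min/s_max are the extreme achievable scores of
    the matrix.  Minus-strand hits come from scanning the reverse
    complement; their ``start`` is the leftmost base on the forward strand.
    Windows containing N are skipped.  Overlapping hits are all reported.
    """
    if len(seq) < pwm.width:
        return []
    hits = []
    eps = 1e-12
    if strands in ("both", PLUS):
        ident = _window_identities(seq, pwm)
        for i in np.nonzero(ident >= min_identity - eps)[0]:
            hits.append(MotifHit(start=int(i), strand=PLUS, identity=float(ident[i])))
    if strands in ("both", MINUS):
        ident = _window_identities(reverse_complement(seq), pwm)
        L, W = len(seq), pwm.width
        for i in np.nonzero(ident >= min_identity - eps)[0]:
            hits.append(MotifHit(start=int(L - W - i), strand=MINUS, identity=float(ident[i])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def hits_to_bed(hits: Iterable[tuple[str, MotifHit]], pwm: PWM, path) -> None:
    """Write (chrom, hit) pairs as BED6; score = identity * 1000, integer."""
    with open(path, "w") as fh:
        for chrom, hit in hits:
            fh.write(
                f"{chrom}\t{hit.start}\t{hit.start + pwm.width}\t{pwm.name}\t"
                f"{int(round(hit.identity * 1000))}\t{hit.strand}\n"
            )


# ---------------------------------------------------------------------------
# Asymmetry and CpGi association
# ---------------------------------------------------------------------------

def region_strand_profile(
    genes: Sequence[GeneModel],
    genome: dict[str, str],
    pwm: PWM,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    window_len: int = 500,
) -> RegionMotifProfile:
    """Per-gene motif presence in promoter/body windows, by relative strand.

    For every gene the [-500, -1] promoter and [+1, +500] body windows are
    scanned on both strands; each hit is assigned sense (hit strand == gene
    strand) or antisense.  Fractions are the share of genes with >= 1 hit in
    each of the four categories.
    """
    if not genes:
        raise ValueError("empty gene set")
    presence_rows = []
    hit_counts = {c: 0 for c in CATEGORIES}
    for gene in genes:
        chrom_seq = genome.get(gene.chrom)
        if chrom_seq is None:
            warnings.warn(f"no sequence for {gene.chrom}; gene {gene.gene_id} skipped")
            continue
        rw = motif_windows(gene, window_len=window_len)
        row = {"gene_id": gene.gene_id, **{c: False for c in CATEGORIES}}
        for region, (s, e) in (("promoter", rw.promoter), ("body", rw.body)):
            if s < 0 or e > len(chrom_seq):
                continue
            for hit in scan_pwm(chrom_seq[s:e], pwm, min_identity=min_identity):
                rel = "sense" if hit.strand == gene.strand else "antisense"
                cat = f"{region}_{rel}"
                row[cat] = True
                hit_counts[cat] += 1
        presence_rows.append(row)
    if not presence_rows:
        raise ValueError("no genes with available sequence")
    per_gene = pd.DataFrame(presence_rows).set_index("gene_id")
    fractions = {c: float(per_gene[c].mean()) for c in CATEGORIES}
    return RegionMotifProfile(
        fractions=fractions, hit_counts=hit_counts, n_genes=len(per_gene), per_gene=per_gene
    )


@dataclass(frozen=True)
class MotifCpgiAssociation:
    """2x2 association of CpG-island promoters with motif presence.

    ``frac_cpgi`` / ``frac_non_cpgi``: share of promoters in each class with
    >= 1 hit in the [-500, -1] window on either strand (NaN when a class is
    empty).
    """

    table: pd.DataFrame  # index cpgi True/False, columns motif True/False
    frac_cpgi: float
    frac_non_cpgi: float


def motif_cpgi_association(
    promoters: Sequence[PromoterWindow],
    genome: dict[str, str],
    pwm: PWM,
    islands: Sequence[CpGIsland],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    window_len: int = 500,
) -> MotifCpgiAssociation:
    """Motif frequency in CpGi-type versus non-CpGi-type promoters."""
    islands_by_chrom: dict[str, list[CpGIsland]] = {}
    for isl in islands:
        islands_by_chrom.setdefault(isl.chrom, []).append(isl)
    counts = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    for w in promoters:
        if w.is_excluded:
            continue
        chrom_seq = genome.get(w.chrom)
        if chrom_seq is None:
            warnings.warn(f"no sequence for {w.chrom}; promoter {w.gene_id} skipped")
            continue
        is_cpgi = classify_promoter_cpgi(w, islands_by_chrom.get(w.chrom, []))
        # the [-500, -1] half of the window is the 500 bp adjacent to the TSS:
        # the right end for plus-strand genes (pancRNA strand '-'), the left
        # end for minus-strand genes.
        if w.panc_strand == MINUS:
            s, e = w.end - window_len, w.end
        else:
            s, e = w.start, w.start + window_len
        has_hit = bool(scan_pwm(chrom_seq[s:e], pwm, min_identity=min_identity))
        counts[(is_cpgi, has_hit)] += 1
    table = pd.DataFrame(
        [[counts[(True, True)], counts[(True, False)]], [counts[(False, True)], counts[(False, False)]]],
        index=pd.Index([True, False], name="cpgi"),
        columns=pd.Index([True, False], name="motif"),
    )
    n_cpgi = table.loc[True].sum()
    n_non = table.loc[False].sum()
    frac_cpgi = float(table.loc[True, True] / n_cpgi) if n_cpgi else float("nan")
    frac_non = float(table.loc[False, True] / n_non) if n_non else float("nan")
    return MotifCpgiAssociation(table=table, frac_cpgi=frac_cpgi, frac_non_cpgi=frac_non)


# ---------------------------------------------------------------------------
# Motif-search input selection
# ---------------------------------------------------------------------------

def select_motif_search_set(
    expr,
    genes: Sequence[GeneModel],
    genome: dict[str, str],
    min_fold: float = 10.0,
    pseudo: float = 0.5,
    stage_from: str = "MII",
    stage_to: str = "2cell",
    seq_len: int = 200,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Strongly upregulated pancRNAs and their [-200, -1] promoter sequences.

    Selects genes whose pancRNA rose >= ``min_fold`` between the two stages
    (pseudocounted fold change) and extracts the ``seq_len`` bp immediately
    upstream of each TSS, oriented in the mRNA direction -- the input a
    de novo motif search would take.
    """
    panc_from = expr.mean_rpkm("pancRNA", stage_from)
    panc_to = expr.mean_rpkm("pancRNA", stage_to)
    lfc = np.log2((panc_to + pseudo) / (panc_from + pseudo))
    selected = lfc[lfc >= np.log2(min_fold)].sort_index()
    by_id = {g.gene_id: g for g in genes}
    seqs = {}
    rows = []
    for gene_id, fc in selected.items():
        gene = by_id.get(gene_id)
        if gene is None:
            continue
        chrom_seq = genome.get(gene.chrom)
        if chrom_seq is None:
            warnings.warn(f"no sequence for {gene.chrom}; gene {gene_id} skipped")
            continue
        if gene.strand == PLUS:
            s, e = gene.tss - seq_len, gene.tss
            if s < 0:
                continue
            seq = chrom_seq[s:e]
        else:
            s, e = gene.tss + 1, gene.tss + 1 + seq_len
            if e > len(chrom_seq):
                continue
            seq = reverse_complement(chrom_seq[s:e])
        seqs[gene_id] = seq
        rows.append({"gene_id": gene_id, "log2fc_panc": float(fc)})
    table = pd.DataFrame(rows, columns=["gene_id", "log2fc_panc"]).set_index("gene_id")
    return table, seqs


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
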
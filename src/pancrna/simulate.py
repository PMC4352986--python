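"""Synthetic genomes, annotations, stranded reads, motifs and bisulfite clones.

The generator emits every input the pipeline consumes, with the statistical
structure the analysis assumes, plus ground-truth tables so each stage can
be tested closed-loop without any external download:

* divergent pancRNA/mRNA transcription from shared promoters -- a fraction
  of genes is "partnered" and emits antisense reads from the 1 kb upstream
  window;
* negative-binomial replicate counts (4 replicates per stage), with
  variance mu + alpha * mu^2;
* coordinated 2-cell upregulation: pancRNA and mRNA log2 fold changes from
  MII to the 2-cell stage are drawn with a configurable correlation;
* a CT-rich consensus planted per strand/region category with the
  TSS-switching asymmetry of divergent promoters;
* CpG-island-type promoters on a CpG-depleted background (the background is
  generated GC-poor with most CpG dinucleotides destroyed, as in vertebrate
  genomes, so the classical island definition is selective);
* bimodal bisulfite methylation: loci highly methylated in oocytes, sperm
  and 1-cell embryos that demethylate by the 2-cell stage.

A fixed seed fully determines every emitted byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, PROMOTER_LEN, MOTIF_WINDOW_LEN, PLUS, MINUS, reverse_complement
from .methylation import BisulfiteCloneSet
from .motif import PWM, build_pwm, write_jaspar

STAGES = ("MII", "2cell", "ESC")
BASES = "ACGT"


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Rates are probabilities in [0, 1].  ``nb_dispersion`` is alpha in
    var = mu + alpha * mu^2; alpha = 0 makes counts deterministic
    (count = round(mu)), which is what the exact closed-loop tests use.
    Expressed features are floored at ``*_floor_rpkm`` so that "on" and
    "off" are well separated from the screening thresholds.
    """

    seed: int = 0
    # genome / annotation
    n_chrom: int = 2
    chrom_length: int = 600_000
    n_genes: int = 400
    gene_length_min: int = 1000
    gene_length_max: int = 2000
    intergenic_gap: int = 1100
    intergenic_gap_jitter: int = 400
    chrom_margin: int = 1500
    frac_panc_partnered: float = 0.30
    frac_overlap_excluded: float = 0.05
    decoy_length: int = 300
    background_gc: float = 0.40
    cpg_depletion: float = 0.85
    # expression truth
    stages: tuple = STAGES
    n_replicates: int = 4
    depth: int = 200_000
    nb_dispersion: float = 0.1
    strand_flip_rate: float = 0.01
    frac_mrna_expressed: float = 0.85
    mrna_log2_mean: float = 3.5
    mrna_log2_sd: float = 1.0
    mrna_floor_rpkm: float = 5.0
    partnered_mrna_boost_log2: float = 1.0
    panc_level_mrna_slope: float = 0.5
    panc_log2_mean: float = 5.0
    panc_log2_sd: float = 1.0
    panc_floor_rpkm: float = 5.0
    frac_panc_mii: float = 0.55
    frac_panc_esc: float = 0.5
    lfc_corr: float = 0.7
    panc_lfc_mean: float = 1.5
    panc_lfc_sd: float = 1.5
    mrna_lfc_mean: float = 1.0
    mrna_lfc_sd: float = 1.5
    nonpartnered_lfc_mean: float = -0.7  # maternal transcript clearance at ZGA
    nonpartnered_lfc_sd: float = 0.7
    # motif planting
    motif_consensus: str = "CTCTCTCC"
    motif_rates_partnered: dict = field(
        default_factory=lambda: {
            "promoter_sense": 0.6,
            "promoter_antisense": 0.1,
            "body_sense": 0.1,
            "body_antisense": 0.5,
        }
    )
    motif_rates_lacking: dict = field(
        default_factory=lambda: {
            "promoter_sense": 0.1,
            "promoter_antisense": 0.4,
            "body_sense": 0.1,
            "body_antisense": 0.4,
        }
    )
    motif_pwm_sites: int = 10
    motif_pwm_pseudocount: float = 0.5
    # CT-rich promoter occurrences are enriched in CpG-island-type promoters:
    # promoter-category planting rates are multiplied by this factor for CpGi
    # genes and divided by it otherwise
    motif_cpgi_factor: float = 1.25
    # CpG islands
    cpgi_rate_partnered: float = 0.7
    cpgi_rate_lacking: float = 0.3
    cpgi_length: int = 300
    cpgi_gc: float = 0.7
    # bisulfite
    bis_stages: tuple = ("MII", "sperm", "1cell", "2cell")
    bis_levels: tuple = (0.85, 0.80, 0.75, 0.10)
    n_bis_loci: int = 3
    bis_clones: int = 24
    bis_cpgs: int = 12
    bis_missing_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "frac_panc_partnered",
            "frac_overlap_excluded",
            "strand_flip_rate",
            "frac_mrna_expressed",
            "frac_panc_mii",
            "frac_panc_esc",
            "cpgi_rate_partnered",
            "cpgi_rate_lacking",
            "bis_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; the generator models {STAGES}")
        for stage in ("MII", "2cell"):
            if stage not in tuple(self.stages):
                raise ValueError(f"stages must include 'MII' and '2cell', got {self.stages}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["bis_stages"] = list(d["bis_stages"])
        d["bis_levels"] = list(d["bis_levels"])
        return json.dumps(d, indent=2, sort_keys=True)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), int(stream)]))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + alpha * mu^2.

    alpha = 0 degenerates to deterministic counts = round(mu), so noise-free
    runs reproduce the truth table exactly.
    """
    mu = np.asarray(mu, dtype=np.float64)
    if alpha == 0.0:
        return np.rint(mu).astype(np.int64)
    r = 1.0 / alpha
    p = r / (r + mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


# ---------------------------------------------------------------------------
# Layout and annotation
# ---------------------------------------------------------------------------

def _promoter_interval(strand: str, tss: int, length: int = PROMOTER_LEN) -> tuple[int, int]:
    if strand == PLUS:
        return tss - length, tss
    return tss + 1, tss + 1 + length


def plan_layout(config: SimulationConfig) -> pd.DataFrame:
    """Place genes and decoys and assign partnered / CpGi / exclusion truth.

    Real genes are laid out with enough clearance that promoters never
    touch a neighboring span; a configured fraction of genes then receives
    a small "decoy" gene inside its promoter window, which triggers the
    promoter-exclusion rule exactly as an overlapping annotation would in a
    real genome.  Exclusion truth is computed here by brute-force interval
    intersection, independently of the annotation module.
    """
    rng = _rng(config.seed, 1)
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    rows = []
    gene_no = 0
    for chrom in chroms:
        pos = config.chrom_margin
        while gene_no < config.n_genes:
            length = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
            gap = config.intergenic_gap + int(rng.integers(0, config.intergenic_gap_jitter + 1))
            if pos + length > config.chrom_length - config.chrom_margin:
                break
            strand = PLUS if rng.random() < 0.5 else MINUS
            gene_no += 1
            rows.append(
                {
                    "gene_id": f"g{gene_no:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "start": pos,
                    "end": pos + length,
                    "role": "gene",
                }
            )
            pos += length + gap
    if gene_no < config.n_genes:
        raise ValueError(
            f"genome too small: placed {gene_no} of {config.n_genes} genes "
            f"on {config.n_chrom} x {config.chrom_length} bp"
        )
    layout = pd.DataFrame(rows)

    # decoys: small genes inside a host promoter, forcing its exclusion
    n_decoys = int(round(config.frac_overlap_excluded * config.n_genes))
    host_idx = rng.choice(len(layout), size=n_decoys, replace=False) if n_decoys else []
    decoys = []
    for i in sorted(host_idx):
        host = layout.iloc[i]
        tss = host["start"] if host["strand"] == PLUS else host["end"] - 1
        ps, pe = _promoter_interval(host["strand"], tss)
        offset = int(rng.integers(0, PROMOTER_LEN - config.decoy_length + 1))
        decoys.append(
            {
                "gene_id": f"{host['gene_id']}ov",
                "chrom": host["chrom"],
                "strand": PLUS if rng.random() < 0.5 else MINUS,
                "start": ps + offset,
                "end": ps + offset + config.decoy_length,
                "role": "decoy",
            }
        )
    if decoys:
        layout = pd.concat([layout, pd.DataFrame(decoys)], ignore_index=True)
    layout = layout.sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)

    # exclusion truth by brute force (independent of the annotation module)
    reasons = []
    for _, g in layout.iterrows():
        tss = g["start"] if g["strand"] == PLUS else g["end"] - 1
        ps, pe = _promoter_interval(g["strand"], tss)
        reason = ""
        if ps < 0 or pe > config.chrom_length:
            reason = "out_of_bounds"
        else:
            same = layout[(layout["chrom"] == g["chrom"]) & (layout["gene_id"] != g["gene_id"])]
            if ((same["start"] < pe) & (same["end"] > ps)).any():
                reason = "overlaps_gene"
        reasons.append(reason)
    layout["excluded"] = reasons

    # partnered status: only real genes with usable promoters can host a pancRNA
    eligible = layout.index[(layout["role"] == "gene") & (layout["excluded"] == "")]
    n_partnered = int(round(config.frac_panc_partnered * config.n_genes))
    n_partnered = min(n_partnered, len(eligible))
    chosen = rng.choice(eligible, size=n_partnered, replace=False) if n_partnered else []
    layout["partnered"] = False
    layout.loc[chosen, "partnered"] = True

    # CpG-island-type promoters (partnered genes more often, as observed)
    cpgi = np.zeros(len(layout), dtype=bool)
    cpgi_start = np.full(len(layout), -1, dtype=np.int64)
    cpgi_end = np.full(len(layout), -1, dtype=np.int64)
    for i, g in layout.iterrows():
        if g["role"] != "gene":
            continue
        rate = config.cpgi_rate_partnered if g["partnered"] else config.cpgi_rate_lacking
        if rng.random() < rate:
            tss = g["start"] if g["strand"] == PLUS else g["end"] - 1
            ps, pe = _promoter_interval(g["strand"], tss)
            if ps < 0 or pe > config.chrom_length:
                continue
            off = (PROMOTER_LEN - config.cpgi_length) // 2
            cpgi[i] = True
            cpgi_start[i] = ps + off
            cpgi_end[i] = ps + off + config.cpgi_length
    layout["cpgi"] = cpgi
    layout["cpgi_start"] = cpgi_start
    layout["cpgi_end"] = cpgi_end
    return layout


def simulate_genome(config: SimulationConfig, layout: pd.DataFrame) -> dict[str, np.ndarray]:
    """CpG-depleted random background with CpG islands planted at promoters.

    Returns mutable per-chromosome integer arrays (0..3 = ACGT) so that
    motif planting can edit them before the FASTA is finalized.
    """
    rng = _rng(config.seed, 2)
    gc = config.background_gc
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms = {}
    for i in range(config.n_chrom):
        chrom = f"chr{i + 1}"
        arr = rng.choice(4, size=config.chrom_length, p=p_bg).astype(np.int8)
        # destroy most CpG dinucleotides: vertebrate genomes are CpG-poor,
        # which is what makes the island definition selective
        cg = np.nonzero((arr[:-1] == 1) & (arr[1:] == 2))[0]
        hit = cg[rng.random(len(cg)) < config.cpg_depletion]
        arr[hit + 1] = np.where(rng.random(len(hit)) < 0.5, 0, 3).astype(np.int8)
        chroms[chrom] = arr
    gci = config.cpgi_gc
    p_isl = np.array([(1 - gci) / 2, gci / 2, gci / 2, (1 - gci) / 2])
    for _, g in layout[layout["cpgi"]].iterrows():
        s, e = int(g["cpgi_start"]), int(g["cpgi_end"])
        chroms[g["chrom"]][s:e] = rng.choice(4, size=e - s, p=p_isl).astype(np.int8)
    return chroms


def simulate_annotation(config: SimulationConfig, layout: pd.DataFrame) -> tuple[list[GeneModel], str]:
    """Gene models (single-exon) and the corresponding GTF text."""
    genes = [
        GeneModel(
            gene_id=g["gene_id"],
            chrom=g["chrom"],
            strand=g["strand"],
            start=int(g["start"]),
            end=int(g["end"]),
            exon_lengths_bp=int(g["end"] - g["start"]),
        )
        for _, g in layout.iterrows()
    ]
    lines = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
        lines.append(
            f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{g.chrom}\tsim\texon\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
    return genes, "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Expression truth
# ---------------------------------------------------------------------------

def simulate_expression_truth(config: SimulationConfig, layout: pd.DataFrame) -> pd.DataFrame:
    """Per-gene true RPKM per stage for mRNA and pancRNA features.

    Expressed values are floored at the configured floors, keeping "on"
    clearly separated from the candidate/expression thresholds; silent
    features are exactly zero.  For partnered genes the MII-to-2-cell log2
    fold changes of pancRNA and mRNA share correlation ``lfc_corr``, and
    the mRNA baseline rises with the pancRNA level (the planted association
    behind the weak/strong pancRNA group comparison).
    """
    rng = _rng(config.seed, 3)
    n = len(layout)
    truth = layout.copy()
    partnered = truth["partnered"].to_numpy()
    is_decoy = (truth["role"] == "decoy").to_numpy()

    z_panc = rng.standard_normal(n)  # pancRNA abundance z-score (partnered only)
    z_shared = rng.standard_normal(n)
    z_mrna_noise = rng.standard_normal(n)
    rho = config.lfc_corr
    lfc_panc = config.panc_lfc_mean + config.panc_lfc_sd * z_shared
    lfc_mrna_part = config.mrna_lfc_mean + config.mrna_lfc_sd * (
        rho * z_shared + np.sqrt(max(0.0, 1 - rho**2)) * z_mrna_noise
    )
    lfc_mrna_other = rng.normal(config.nonpartnered_lfc_mean, config.nonpartnered_lfc_sd, size=n)

    mrna_on = rng.random(n) < config.frac_mrna_expressed
    mrna_on |= is_decoy  # decoys always transcribed so they can contaminate
    base_log2 = rng.normal(config.mrna_log2_mean, config.mrna_log2_sd, size=n)
    base_log2 = np.where(
        partnered,
        base_log2 + config.partnered_mrna_boost_log2 + config.panc_level_mrna_slope * z_panc,
        base_log2,
    )
    base = np.exp2(base_log2)
    floor_m = config.mrna_floor_rpkm

    lfc_mrna = np.where(partnered, lfc_mrna_part, lfc_mrna_other)
    lfc_mrna = np.where(is_decoy, 0.0, lfc_mrna)
    mrna_mii = np.where(mrna_on, np.maximum(base, floor_m), 0.0)
    mrna_2c = np.where(mrna_on, np.maximum(base * np.exp2(lfc_mrna), floor_m), 0.0)
    esc_shift = rng.normal(0.0, 1.0, size=n)
    mrna_esc = np.where(mrna_on, np.maximum(base * np.exp2(np.where(is_decoy, 0.0, esc_shift)), floor_m), 0.0)

    floor_p = config.panc_floor_rpkm
    panc_2c = np.where(
        partnered, np.maximum(np.exp2(config.panc_log2_mean + config.panc_log2_sd * z_panc), floor_p), 0.0
    )
    mii_on = partnered & (rng.random(n) < config.frac_panc_mii)
    panc_mii = np.where(mii_on, np.maximum(panc_2c / np.exp2(lfc_panc), floor_p), 0.0)
    esc_on = partnered & (rng.random(n) < config.frac_panc_esc)
    panc_esc = np.where(esc_on, np.maximum(panc_2c * np.exp2(rng.normal(0.0, 1.0, size=n)), floor_p), 0.0)

    truth["mrna_on"] = mrna_on
    truth["panc_MII"] = panc_mii
    truth["panc_2cell"] = panc_2c
    truth["panc_ESC"] = panc_esc
    truth["mrna_MII"] = mrna_mii
    truth["mrna_2cell"] = mrna_2c
    truth["mrna_ESC"] = mrna_esc

    # RPKM self-consistency: in any real table sum(RPKM * length_kb) over the
    # transcriptome equals 1e6 (the counts sum to the library).  Rescaling
    # each stage to that identity makes the realized RPKM of the simulated
    # reads agree with the truth values, not just rank with them.  With only
    # a few hundred genes the rescaled values are large -- a small synthetic
    # transcriptome concentrates the per-million denominator.
    mrna_kb = (truth["end"] - truth["start"]).to_numpy() / 1e3
    has_panc = (truth["partnered"] & (truth["excluded"] == "")).to_numpy()
    panc_kb = np.where(has_panc, 1.0, 0.0)
    for stage in STAGES:
        s_total = float(
            (truth[f"mrna_{stage}"] * mrna_kb).sum() + (truth[f"panc_{stage}"] * panc_kb).sum()
        )
        if s_total > 0:
            factor = 1e6 / s_total
            truth[f"mrna_{stage}"] *= factor
            truth[f"panc_{stage}"] *= factor

    truth["lfc_panc_true"] = np.where(
        mii_on,
        np.log2(np.maximum(truth["panc_2cell"], 1e-300) / np.maximum(truth["panc_MII"], 1e-300)),
        np.nan,
    )
    truth["lfc_mrna_true"] = np.where(
        mrna_on,
        np.log2(np.maximum(truth["mrna_2cell"], 1e-300) / np.maximum(truth["mrna_MII"], 1e-300)),
        np.nan,
    )
    return truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{stage}_r{rep}", "stage": stage, "replicate": rep}
        for stage in config.stages
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_reads(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Stranded 5'-end read records for every sample.

    Per feature and replicate, count ~ NB(mu = RPKM x length_kb x
    depth_millions, alpha); 5' positions are uniform within the feature on
    the correct strand and each read's strand is flipped with the
    configured strandedness error rate.
    """
    rng = _rng(config.seed, 4)
    depth_m = config.depth / 1e6
    flip = {PLUS: MINUS, MINUS: PLUS}
    features = []  # (chrom, start, end, strand, rpkm_by_stage)
    for _, g in truth.iterrows():
        rpkms = {stage: g[f"mrna_{stage}"] for stage in STAGES}
        features.append((g["chrom"], int(g["start"]), int(g["end"]), g["strand"], rpkms))
        if g["partnered"] and g["excluded"] == "":
            tss = int(g["start"]) if g["strand"] == PLUS else int(g["end"]) - 1
            ps, pe = _promoter_interval(g["strand"], tss)
            panc_strand = flip[g["strand"]]
            rpkms = {stage: g[f"panc_{stage}"] for stage in STAGES}
            features.append((g["chrom"], ps, pe, panc_strand, rpkms))
    chunks = []
    for stage in config.stages:
        for rep in range(1, config.n_replicates + 1):
            sample_id = f"{stage}_r{rep}"
            for chrom, s, e, strand, rpkms in features:
                mu = rpkms[stage] * ((e - s) / 1e3) * depth_m
                count = int(_nb_counts(rng, np.array([mu]), config.nb_dispersion)[0])
                if count == 0:
                    continue
                pos = rng.integers(s, e, size=count)
                strands = np.full(count, strand, dtype=object)
                if config.strand_flip_rate > 0:
                    flipped = rng.random(count) < config.strand_flip_rate
                    strands[flipped] = flip[strand]
                chunks.append(
                    pd.DataFrame(
                        {"chrom": chrom, "pos": pos, "strand": strands, "sample_id": sample_id}
                    )
                )
    if not chunks:
        raise ValueError("simulation produced no reads; raise depth or expression levels")
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

_ENC = {b: i for i, b in enumerate(BASES)}


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC[b] for b in seq], dtype=np.int8)


def plant_motif(
    config: SimulationConfig,
    chrom_arrays: dict[str, np.ndarray],
    truth: pd.DataFrame,
) -> tuple[pd.DataFrame, PWM]:
    """Write the consensus into promoter/body windows at per-category rates.

    Categories follow the asymmetry profile: strand is expressed relative
    to the mRNA (sense = gene strand).  Plantings that would collide with a
    previous one are redrawn a bounded number of times, then skipped; every
    planting is recorded with its genomic position and strand, and the
    generating PWM is returned for closed-loop scanning.
    """
    rng = _rng(config.seed, 5)
    consensus = config.motif_consensus.upper()
    W = len(consensus)
    fwd = _encode(consensus)
    rev = _encode(reverse_complement(consensus))
    flip = {PLUS: MINUS, MINUS: PLUS}
    planted: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_arrays}
    records = []
    for _, g in truth.iterrows():
        if g["role"] != "gene":
            continue
        rates = config.motif_rates_partnered if g["partnered"] else config.motif_rates_lacking
        tss = int(g["start"]) if g["strand"] == PLUS else int(g["end"]) - 1
        if g["strand"] == PLUS:
            prom = (tss - MOTIF_WINDOW_LEN, tss)
            body = (tss, min(tss + MOTIF_WINDOW_LEN, int(g["end"])))
        else:
            prom = (tss + 1, tss + 1 + MOTIF_WINDOW_LEN)
            body = (max(tss + 1 - MOTIF_WINDOW_LEN, int(g["start"])), tss + 1)
        windows = {"promoter": prom, "body": body}
        for category, rate in rates.items():
            if category.startswith("promoter") and config.motif_cpgi_factor != 1.0:
                factor = config.motif_cpgi_factor if g["cpgi"] else 1.0 / config.motif_cpgi_factor
                rate = min(1.0, rate * factor)
            if rng.random() >= rate:
                continue
            region, rel = category.split("_")
            ws, we = windows[region]
            strand = g["strand"] if rel == "sense" else flip[g["strand"]]
            ok = False
            pos = -1
            for _attempt in range(10):
                pos = int(rng.integers(ws, we - W + 1))
                if all(pos + W <= s or pos >= e for s, e in planted[g["chrom"]]):
                    ok = True
                    break
            if ok:
                arr = chrom_arrays[g["chrom"]]
                arr[pos : pos + W] = fwd if strand == PLUS else rev
                planted[g["chrom"]].append((pos, pos + W))
            records.append(
                {
                    "gene_id": g["gene_id"],
                    "category": category,
                    "chrom": g["chrom"],
                    "pos": pos if ok else -1,
                    "strand": strand,
                    "planted": ok,
                }
            )
    motif_truth = pd.DataFrame(
        records, columns=["gene_id", "category", "chrom", "pos", "strand", "planted"]
    )
    pwm = build_pwm(
        [consensus] * config.motif_pwm_sites,
        pseudocount=config.motif_pwm_pseudocount,
        name="CT-rich",
    )
    return motif_truth, pwm


# ---------------------------------------------------------------------------
# Bisulfite clones
# ---------------------------------------------------------------------------

def simulate_bisulfite(config: SimulationConfig) -> tuple[dict[str, BisulfiteCloneSet], pd.DataFrame]:
    """Clone sets per locus x stage with the planted methylation levels.

    Calls are independent Bernoulli(level) per CpG per clone; a small
    fraction of calls is missing.  The planted stage profile is high
    methylation in MII/sperm/1-cell and near-complete demethylation at the
    2-cell stage.
    """
    rng = _rng(config.seed, 6)
    clone_sets = {}
    rows = []
    for locus_i in range(1, config.n_bis_loci + 1):
        locus = f"locus{locus_i}"
        positions = tuple(100 + 17 * k for k in range(config.bis_cpgs))
        for stage, level in zip(config.bis_stages, config.bis_levels):
            key = f"{locus}_{stage}"
            clones = []
            for c in range(config.bis_clones):
                meth = rng.random(config.bis_cpgs) < level
                missing = rng.random(config.bis_cpgs) < config.bis_missing_rate
                calls = np.where(missing, ".", np.where(meth, "M", "U"))
                clones.append("".join(calls))
            clone_sets[key] = BisulfiteCloneSet(
                locus_id=key,
                cpg_positions=positions,
                clone_ids=tuple(f"{key}_c{j + 1}" for j in range(config.bis_clones)),
                clones=tuple(clones),
            )
            rows.append({"locus": locus, "stage": stage, "true_level": level})
    return clone_sets, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration and output
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    gtf_text: str
    truth: pd.DataFrame
    samples: pd.DataFrame
    reads: pd.DataFrame
    pwm: PWM
    motif_truth: pd.DataFrame
    bisulfite: dict[str, BisulfiteCloneSet]
    bisulfite_truth: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["genome"] = outdir / "genome.fa"
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths["chrom_sizes"] = outdir / "chrom.sizes"
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        paths["gtf"] = outdir / "annotation.gtf"
        paths["gtf"].write_text(self.gtf_text)
        paths["reads"] = outdir / "reads.tsv"
        self.reads.to_csv(paths["reads"], sep="\t", index=False)
        paths["samples"] = outdir / "samples.tsv"
        self.samples.to_csv(paths["samples"], sep="\t")
        paths["pwm"] = outdir / "pwm.jaspar"
        write_jaspar(self.pwm, paths["pwm"])
        paths["clones"] = outdir / "bisulfite_clones.tsv"
        with open(paths["clones"], "w") as fh:
            fh.write("locus_id\tclone_id\tcalls\n")
            for key in self.bisulfite:
                cs = self.bisulfite[key]
                for cid, calls in zip(cs.clone_ids, cs.clones):
                    fh.write(f"{key}\t{cid}\t{calls}\n")
        paths["truth_genes"] = outdir / "truth_genes.tsv"
        self.truth.to_csv(paths["truth_genes"], sep="\t", index=False, float_format="%.6g")
        paths["truth_motif"] = outdir / "truth_motif.tsv"
        self.motif_truth.to_csv(paths["truth_motif"], sep="\t", index=False)
        paths["truth_bisulfite"] = outdir / "truth_bisulfite.tsv"
        self.bisulfite_truth.to_csv(paths["truth_bisulfite"], sep="\t", index=False)
        paths["config"] = outdir / "config.json"
        paths["config"].write_text(self.config.to_json())
        return paths


def simulate(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Run the full generator: genome, annotation, reads, motif, bisulfite."""
    config = config or SimulationConfig()
    layout = plan_layout(config)
    chrom_arrays = simulate_genome(config, layout)
    truth = simulate_expression_truth(config, layout)
    motif_truth, pwm = plant_motif(config, chrom_arrays, truth)
    genes, gtf_text = simulate_annotation(config, layout)
    reads = simulate_reads(config, truth)
    samples = sample_sheet(config)
    clone_sets, bis_truth = simulate_bisulfite(config)
    base_lut = np.array(list(BASES))
    genome = {chrom: "".join(base_lut[arr]) for chrom, arr in chrom_arrays.items()}
    chrom_sizes = {chrom: len(seq) for chrom, seq in genome.items()}
    return SimulatedDataset(
        config=config,
        genome=genome,
        chrom_sizes=chrom_sizes,
        genes=genes,
        gtf_text=gtf_text,
        truth=truth,
        samples=samples,
        reads=reads,
        pwm=pwm,
        motif_truth=motif_truth,
        bisulfite=clone_sets,
        bisulfite_truth=bis_truth,
    )
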
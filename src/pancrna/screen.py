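"""The pancRNA screen: candidate calling, co-expression and coordination.

Mirrors the discovery logic applied to preimplantation directional RNA-seq:
call promoters with detectable antisense transcription as pancRNA
candidates, flag pancRNA/mRNA pairs co-expressed at a stage, compare the
mRNA levels of genes with weak vs strong pancRNAs, measure how pancRNA and
mRNA fold changes between stages co-vary, and select follow-up candidates
that are silent in oocytes but active after zygotic gene activation.

Differential expression between replicate groups is a Welch t-test on
log2(RPKM + 1) with Benjamini-Hochberg adjustment -- a deliberately simple,
fully testable replacement for an external differential-expression tool.
All numeric thresholds are keyword arguments with the defaults used
throughout the package; ties on any numeric key are broken by gene_id so
every selection is deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

from .methylation import mann_whitney_u, MannWhitneyResult

DEFAULT_MIN_RPKM = 1.0
DEFAULT_EXPRESSED_RPKM = 0.5
DEFAULT_PSEUDO_RPKM = 0.5


@dataclass(frozen=True)
class PancCallSet:
    """pancRNA candidates at one stage: mean RPKM >= ``min_rpkm``."""

    stage: str
    min_rpkm: float
    gene_ids: tuple[str, ...]
    rpkm: pd.Series  # mean pancRNA RPKM of the candidates, indexed by gene_id


@dataclass(frozen=True)
class GroupComparison:
    """Expression-level grouping: mRNA levels of genes without pancRNAs (A)
    versus partners of the n weakest (B) and n strongest (C) pancRNAs."""

    stage: str
    n: int
    groups: dict  # name -> list of gene_ids
    mrna_rpkm: dict  # name -> np.ndarray of mRNA mean RPKM
    tests: dict  # (name_hi, name_lo) -> MannWhitneyResult, one-sided greater


@dataclass(frozen=True)
class CoordinationResult:
    """Per-pair log2 fold changes between two stages plus their Pearson r.

    ``r_all``/``n_all`` cover every scored pair; the ``upregulated`` slice
    restricts to pairs whose mRNA rose by at least ``min_fold``, the subset
    on which coordinated upregulation is usually quoted.
    """

    table: pd.DataFrame  # gene_id, log2fc_panc, log2fc_mrna
    r_all: float
    n_all: int
    n_both_up: int
    min_fold: float
    r_upregulated: float
    n_upregulated: int
    n_both_up_upregulated: int


def _mean_rpkm_or_empty(expr, kind: str, stage: str) -> pd.Series:
    means = expr.mean_rpkm(kind, stage)
    return means.groupby(level=0).mean() if means.index.has_duplicates else means


def call_panc_candidates(expr, stage: str, min_rpkm: float = DEFAULT_MIN_RPKM) -> PancCallSet:
    """Genes whose mean pancRNA RPKM across replicates reaches ``min_rpkm``.

    Genes with excluded promoters carry no pancRNA feature and can never be
    called.
    """
    means = _mean_rpkm_or_empty(expr, "pancRNA", stage)
    called = means[means >= min_rpkm].sort_index()
    return PancCallSet(stage=stage, min_rpkm=min_rpkm, gene_ids=tuple(called.index), rpkm=called)


def classify_coexpression(
    expr, stage: str, expressed_thresh: float = DEFAULT_EXPRESSED_RPKM
) -> pd.DataFrame:
    """Per-gene expressed flags for pancRNA and mRNA, and co-expression.

    A feature is "expressed" when its mean RPKM exceeds ``expressed_thresh``;
    a pair is co-expressed iff both members are.  Genes without a pancRNA
    feature (excluded promoter) have ``panc_present == False``.
    """
    mrna = _mean_rpkm_or_empty(expr, "mRNA", stage)
    panc = _mean_rpkm_or_empty(expr, "pancRNA", stage)
    out = pd.DataFrame(index=mrna.index.sort_values())
    out.index.name = "gene_id"
    out["panc_present"] = out.index.isin(panc.index)
    out["panc_rpkm"] = panc.reindex(out.index).fillna(0.0)
    out["mrna_rpkm"] = mrna.reindex(out.index)
    out["panc_expressed"] = out["panc_rpkm"] > expressed_thresh
    out["mrna_expressed"] = out["mrna_rpkm"] > expressed_thresh
    out["coexpressed"] = out["panc_expressed"] & out["mrna_expressed"]
    return out


def group_by_panc_level(
    expr,
    stage: str,
    n: int = 100,
    expressed_thresh: float = DEFAULT_EXPRESSED_RPKM,
) -> GroupComparison:
    """Compare mRNA levels across pancRNA strength groups (A / B / C).

    Group A: expressed mRNAs with no expressed pancRNA.  Groups B and C:
    partners of the ``n`` most weakly / strongly expressed pancRNAs among
    co-expressed pairs, ranked by pancRNA mean RPKM with ties broken by
    gene_id.  One-sided Mann-Whitney tests ask whether C sits above A and B.
    """
    status = classify_coexpression(expr, stage, expressed_thresh)
    co = status[status["coexpressed"]]
    if len(co) < n:
        warnings.warn(f"only {len(co)} co-expressed pairs; groups truncated to that size")
        n = len(co)
    # stable sort on a gene_id-sorted frame: ties broken lexically by gene_id
    ranked = co.sort_index().sort_values("panc_rpkm", kind="mergesort")
    group_b = ranked.head(n)
    group_c = ranked.tail(n)
    group_a = status[status["mrna_expressed"] & ~status["panc_expressed"]]
    groups = {
        "A": group_a.index.tolist(),
        "B": group_b.index.tolist(),
        "C": group_c.index.tolist(),
    }
    mrna = {k: status.loc[v, "mrna_rpkm"].to_numpy() for k, v in groups.items()}
    tests = {}
    for hi, lo in (("C", "A"), ("C", "B")):
        if len(mrna[hi]) and len(mrna[lo]):
            tests[(hi, lo)] = mann_whitney_u(mrna[hi], mrna[lo], alternative="greater")
    return GroupComparison(stage=stage, n=n, groups=groups, mrna_rpkm=mrna, tests=tests)


def coordination_stats(
    expr,
    stage_from: str,
    stage_to: str,
    pseudo: float = DEFAULT_PSEUDO_RPKM,
    gene_ids: Sequence[str] | None = None,
    min_fold: float = 2.0,
) -> CoordinationResult:
    """How pancRNA and mRNA fold changes between two stages co-vary.

    log2FC = log2((RPKM_to + pseudo) / (RPKM_from + pseudo)) per feature;
    the pseudocount keeps pairs silent at one stage finite.  Scored over
    pairs with a pancRNA feature (optionally restricted to ``gene_ids``).
    """
    panc_from = _mean_rpkm_or_empty(expr, "pancRNA", stage_from)
    panc_to = _mean_rpkm_or_empty(expr, "pancRNA", stage_to)
    mrna_from = _mean_rpkm_or_empty(expr, "mRNA", stage_from)
    mrna_to = _mean_rpkm_or_empty(expr, "mRNA", stage_to)
    genes = panc_from.index.intersection(mrna_from.index)
    if gene_ids is not None:
        genes = genes.intersection(pd.Index(gene_ids))
    genes = genes.sort_values()
    if len(genes) < 3:
        raise ValueError(f"need >= 3 pairs to estimate coordination, got {len(genes)}")
    lfc_panc = np.log2((panc_to[genes] + pseudo) / (panc_from[genes] + pseudo))
    lfc_mrna = np.log2((mrna_to[genes] + pseudo) / (mrna_from[genes] + pseudo))
    table = pd.DataFrame(
        {"gene_id": genes, "log2fc_panc": lfc_panc.to_numpy(), "log2fc_mrna": lfc_mrna.to_numpy()}
    ).set_index("gene_id")
    r_all = _pearson(table["log2fc_panc"], table["log2fc_mrna"])
    both_up = (table["log2fc_panc"] > 0) & (table["log2fc_mrna"] > 0)
    up = table[table["log2fc_mrna"] >= math.log2(min_fold)]
    r_up = _pearson(up["log2fc_panc"], up["log2fc_mrna"]) if len(up) >= 3 else float("nan")
    return CoordinationResult(
        table=table,
        r_all=r_all,
        n_all=len(table),
        n_both_up=int(both_up.sum()),
        min_fold=min_fold,
        r_upregulated=r_up,
        n_upregulated=len(up),
        n_both_up_upregulated=int(((up["log2fc_panc"] > 0) & (up["log2fc_mrna"] > 0)).sum()),
    )


def _pearson(x: pd.Series, y: pd.Series) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def select_followup_candidates(
    expr,
    mii_max: float = 0.5,
    twocell_min: float = 1.0,
    esc_min: float = 1.0,
    stage_mii: str = "MII",
    stage_twocell: str = "2cell",
    stage_esc: str = "ESC",
) -> pd.DataFrame:
    """pancRNAs silent in oocytes but active at the 2-cell stage and in ESCs.

    Selection: pancRNA RPKM < ``mii_max`` in MII, > ``twocell_min`` in
    2-cell embryos and > ``esc_min`` in ESCs; ranked by descending ESC
    pancRNA RPKM with ties broken by gene_id.
    """
    for stage in (stage_mii, stage_twocell, stage_esc):
        if stage not in set(expr.samples["stage"]):
            raise ValueError(f"stage {stage!r} missing from the expression table")
    mii = _mean_rpkm_or_empty(expr, "pancRNA", stage_mii)
    two = _mean_rpkm_or_empty(expr, "pancRNA", stage_twocell)
    esc = _mean_rpkm_or_empty(expr, "pancRNA", stage_esc)
    table = pd.DataFrame({"rpkm_mii": mii, "rpkm_2cell": two, "rpkm_esc": esc})
    keep = (table["rpkm_mii"] < mii_max) & (table["rpkm_2cell"] > twocell_min) & (table["rpkm_esc"] > esc_min)
    out = table[keep].sort_index().sort_values("rpkm_esc", ascending=False, kind="mergesort")
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# Differential test
# ---------------------------------------------------------------------------

def differential_test(reps_a: Sequence[float], reps_b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sided t-test on log2(RPKM + 1) between two replicate groups.

    When both groups have zero variance the t distribution degenerates: the
    p-value is 1 if the means are equal and 0 otherwise.
    """
    a = np.log2(np.asarray(list(reps_a), dtype=np.float64) + 1.0)
    b = np.log2(np.asarray(list(reps_b), dtype=np.float64) + 1.0)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    with warnings.catch_warnings():
        # scipy warns about precision loss on nearly identical groups; the
        # resulting p ~ 1 is exactly the right answer there
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = _scipy_stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(list(pvals), dtype=np.float64)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(expr, stage_a: str, stage_b: str, kind: str | None = None) -> pd.DataFrame:
    """Per-feature Welch test between two stages with BH-adjusted q-values."""
    cols_a = expr.samples_for(stage_a)
    cols_b = expr.samples_for(stage_b)
    feats = expr.features.index
    if kind is not None:
        feats = feats[expr.features["kind"] == kind]
    rows = []
    for fid in feats:
        a = expr.rpkm.loc[fid, cols_a].to_numpy(dtype=np.float64)
        b = expr.rpkm.loc[fid, cols_b].to_numpy(dtype=np.float64)
        t, p = differential_test(a, b)
        rows.append(
            {
                "feature_id": fid,
                f"mean_log2_{stage_a}": float(np.log2(a + 1.0).mean()),
                f"mean_log2_{stage_b}": float(np.log2(b + 1.0).mean()),
                "t": t,
                "pvalue": p,
            }
        )
    table = pd.DataFrame(rows).set_index("feature_id")
    table["qvalue"] = bh_adjust(table["pvalue"].to_numpy())
    return table
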
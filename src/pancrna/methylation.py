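"""Bisulfite subclone methylation levels and the Mann-Whitney U test.

Each subclone is one PCR molecule from bisulfite-converted DNA; its string
of per-CpG calls (M methylated / U unmethylated / '.' missing) is one
independent observation.  Methylation levels between conditions are
compared with a Mann-Whitney U test on per-clone methylated fractions:
clone counts are small and the fractions are bounded and tied, so a rank
test is the appropriate choice.
"""

from __future__ import annotations

import io
import itertools
import math
import os
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats as _scipy_stats

VALID_CALLS = frozenset("MU.")


@dataclass(frozen=True)
class BisulfiteCloneSet:
    """Per-clone per-CpG methylation calls at one locus (one condition)."""

    locus_id: str
    cpg_positions: tuple[int, ...]
    clone_ids: tuple[str, ...]
    clones: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError(f"{self.locus_id}: clone set needs >= 1 clone")
        n = len(self.cpg_positions)
        for cid, calls in zip(self.clone_ids, self.clones):
            if len(calls) != n:
                raise ValueError(
                    f"{self.locus_id}/{cid}: call string length {len(calls)} != {n} CpGs"
                )
            bad = set(calls) - VALID_CALLS
            if bad:
                raise ValueError(f"{self.locus_id}/{cid}: invalid calls {sorted(bad)}")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def n_clones(self) -> int:
        return len(self.clones)


@dataclass(frozen=True)
class MethylationProfile:
    """Methylated fractions per CpG, per clone, and overall.

    Missing calls are excluded from both numerator and denominator; a CpG or
    clone with no informative call is NaN.
    """

    per_cpg: np.ndarray
    per_clone: np.ndarray
    overall: float


class MannWhitneyResult(NamedTuple):
    U: float
    pvalue: float
    method: str


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_bisulfite_clones(source) -> dict[str, BisulfiteCloneSet]:
    """Parse a clone TSV (locus_id, clone_id, calls) into per-locus sets.

    CpG positions are not part of the TSV; they default to 0..n-1 per locus.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = str(source).splitlines()
    loci: dict[str, list[tuple[str, str]]] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[:3] == ["locus_id", "clone_id", "calls"]:
            continue
        if len(fields) < 3:
            raise ValueError(f"clone TSV line {lineno}: expected 3 columns")
        locus_id, clone_id, calls = fields[0], fields[1], fields[2]
        bad = set(calls) - VALID_CALLS
        if bad:
            raise ValueError(f"clone {clone_id}: invalid call characters {sorted(bad)}")
        loci.setdefault(locus_id, []).append((clone_id, calls))
    if not loci:
        raise ValueError("no clones in input")
    out = {}
    for locus_id, recs in loci.items():
        n = len(recs[0][1])
        out[locus_id] = BisulfiteCloneSet(
            locus_id=locus_id,
            cpg_positions=tuple(range(n)),
            clone_ids=tuple(cid for cid, _ in recs),
            clones=tuple(calls for _, calls in recs),
        )
    return out


# ---------------------------------------------------------------------------
# Levels
# ---------------------------------------------------------------------------

def methylation_level(clones: BisulfiteCloneSet) -> MethylationProfile:
    """Methylated fraction per CpG, per clone, and over all informative calls."""
    mat = np.array([[c for c in calls] for calls in clones.clones])
    meth = mat == "M"
    informative = mat != "."
    if not informative.any():
        raise ValueError(f"{clones.locus_id}: all calls missing")
    with np.errstate(invalid="ignore"):
        per_cpg = np.where(
            informative.sum(axis=0) > 0,
            meth.sum(axis=0) / np.maximum(informative.sum(axis=0), 1),
            np.nan,
        )
        per_clone = np.where(
            informative.sum(axis=1) > 0,
            meth.sum(axis=1) / np.maximum(informative.sum(axis=1), 1),
            np.nan,
        )
    overall = float(meth.sum() / informative.sum())
    return MethylationProfile(per_cpg=per_cpg, per_clone=per_clone, overall=overall)


def lollipop(clones: BisulfiteCloneSet) -> str:
    """Text rendering of the clone set: one row per clone, ● methylated,
    ○ unmethylated, · missing -- the standard bisulfite figure, in ASCII art."""
    glyph = {"M": "●", "U": "○", ".": "·"}
    lines = [f"# {clones.locus_id} ({clones.n_clones} clones x {clones.n_cpgs} CpGs)"]
    for cid, calls in zip(clones.clone_ids, clones.clones):
        lines.append(f"{cid}\t" + "".join(glyph[c] for c in calls))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x (midrank ties): number of (x_i, y_j) pairs with x_i > y_j,
    counting ties as 1/2."""
    pooled = np.concatenate([x, y])
    ranks = _scipy_stats.rankdata(pooled)
    n = len(x)
    return float(ranks[:n].sum() - n * (n + 1) / 2.0)


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float, alternative: str) -> float:
    """Exact p by full enumeration of the C(n+m, n) group labelings of the
    pooled data; ties are carried through the enumeration via midranks."""
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _scipy_stats.rankdata(pooled)
    offset = n * (n + 1) / 2.0
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in itertools.combinations(range(n + m), n)]
    )
    total = len(us)
    eps = 1e-9
    ge = np.sum(us >= u_obs - eps) / total
    le = np.sum(us <= u_obs + eps) / total
    if alternative == "greater":
        return float(ge)
    if alternative == "less":
        return float(le)
    return float(min(1.0, 2.0 * min(ge, le)))


def _normal_p(x: np.ndarray, y: np.ndarray, u_obs: float, alternative: str) -> float:
    """Normal approximation with tie-corrected variance and continuity correction."""
    n, m = len(x), len(y)
    N = n + m
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        # all pooled values identical: U is exactly nm/2, no evidence either way
        return 1.0
    mu = n * m / 2.0
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (u_obs - mu - 0.5) / sd
        return float(_scipy_stats.norm.sf(z))
    if alternative == "less":
        z = (u_obs - mu + 0.5) / sd
        return float(_scipy_stats.norm.cdf(z))
    z = (abs(u_obs - mu) - 0.5) / sd
    if z <= 0:
        return 1.0
    return float(min(1.0, 2.0 * _scipy_stats.norm.sf(z)))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    mode: str = "auto",
    exact_max: int = 12,
) -> MannWhitneyResult:
    """Mann-Whitney U test with midrank ties.

    ``mode='auto'`` enumerates all C(n+m, n) labelings exactly (ties
    included) when n + m <= ``exact_max`` and otherwise uses the normal
    approximation with tie-corrected variance and continuity correction.
    The two-sided p is min(1, 2 * one-sided).  Returns (U, p, method) where
    U counts (x, y) pairs with x > y (ties as 1/2).
    """
    x = np.asarray(list(x), dtype=np.float64)
    y = np.asarray(list(y), dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("samples must not contain NaN")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    u_obs = _u_statistic(x, y)
    if mode == "auto":
        mode = "exact" if len(x) + len(y) <= exact_max else "normal"
    if mode == "exact":
        p = _exact_p(x, y, u_obs, alternative)
    elif mode == "normal":
        p = _normal_p(x, y, u_obs, alternative)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MannWhitneyResult(U=u_obs, pvalue=p, method=mode)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def methylation_report(
    clone_sets: dict[str, BisulfiteCloneSet],
    groups: dict[str, Sequence[str]] | None = None,
):
    """Per-locus methylation levels plus all pairwise Mann-Whitney tests.

    ``groups`` maps a comparison label (e.g. a locus) to the clone-set keys
    belonging to it; within each group all key pairs are tested and labelled
    explicitly.  Returns (summary, tests) DataFrames; ``tests`` is empty
    when no groups are given.
    """
    import pandas as pd

    rows = []
    for key, cs in clone_sets.items():
        prof = methylation_level(cs)
        rows.append(
            {
                "clone_set": key,
                "n_clones": cs.n_clones,
                "n_cpgs": cs.n_cpgs,
                "overall_methylation": prof.overall,
            }
        )
    summary = pd.DataFrame(rows).set_index("clone_set")
    tests = []
    for label, keys in (groups or {}).items():
        for a, b in itertools.combinations(keys, 2):
            fa = methylation_level(clone_sets[a]).per_clone
            fb = methylation_level(clone_sets[b]).per_clone
            res = mann_whitney_u(fa[~np.isnan(fa)], fb[~np.isnan(fb)])
            tests.append(
                {
                    "group": label,
                    "a": a,
                    "b": b,
                    "level_a": float(np.nanmean(fa)),
                    "level_b": float(np.nanmean(fb)),
                    "U": res.U,
                    "pvalue": res.pvalue,
                    "method": res.method,
                }
            )
    tests_df = pd.DataFrame(tests, columns=["group", "a", "b", "level_a", "level_b", "U", "pvalue", "method"])
    return summary, tests_df
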
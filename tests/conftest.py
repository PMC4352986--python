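"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pancrna.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced dataset: same architecture as the default conditions but
    fewer genes and lower depth, for fast per-module tests."""
    return SimulationConfig(seed=11, n_genes=120, chrom_length=220_000, depth=50_000)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Deterministic counts, no strand flips: the exact-recovery regime."""
    cfg = SimulationConfig(
        seed=13, n_genes=120, chrom_length=220_000, depth=50_000,
        nb_dispersion=0.0, strand_flip_rate=0.0,
    )
    return simulate(cfg)


def make_expression_table(rpkm: dict[str, dict[str, list[float]]], stages=("MII", "2cell", "ESC"), n_reps=2):
    """Build a tiny ExpressionTable directly from per-feature per-stage RPKM lists.

    ``rpkm`` maps feature_id (``g:panc`` / ``g:mRNA``) to {stage: [per-replicate rpkm]}.
    """
    from pancrna.quantify import ExpressionTable

    feature_ids = list(rpkm)
    samples = pd.DataFrame(
        [
            {"sample_id": f"{st}_r{r}", "stage": st, "replicate": r}
            for st in stages
            for r in range(1, n_reps + 1)
        ]
    ).set_index("sample_id")
    mat = pd.DataFrame(0.0, index=feature_ids, columns=samples.index)
    for fid, by_stage in rpkm.items():
        for st, vals in by_stage.items():
            for r, v in enumerate(vals, start=1):
                mat.loc[fid, f"{st}_r{r}"] = v
    features = pd.DataFrame(
        {
            "kind": ["pancRNA" if f.endswith(":panc") else "mRNA" for f in feature_ids],
            "gene_id": [f.rsplit(":", 1)[0] for f in feature_ids],
            "length_bp": 1000,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    counts = (mat * 0).astype(int)
    return ExpressionTable(features=features, samples=samples, counts=counts, rpkm=mat)
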
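import numpy as np
import pandas as pd
import pytest

from kbcascade.genome import GeneModels
from kbcascade.simulate import SimulationConfig, generate_gene_models, make_truth


@pytest.fixture(scope="session")
def kb_pwms():
    from kbcascade.motifs import load_kb_pwms
    return load_kb_pwms()


@pytest.fixture(scope="session")
def noise_free_study():
    """A 200-gene study in the deterministic (noise-free) configuration."""
    from kbcascade.simulate import (simulate_expression, simulate_peaks,
                                    simulate_interactions)
    cfg = SimulationConfig(n_genes=200, seed=11, count_noise="none",
                           replicate_reproducibility=1.0,
                           subthreshold_fraction=0.0)
    gm = generate_gene_models(cfg)
    truth = make_truth(gm, cfg)
    return {
        "config": cfg, "gene_models": gm, "truth": truth,
        "expression": simulate_expression(gm, truth, cfg),
        "peaks": simulate_peaks(gm, truth, cfg),
        "interactions": simulate_interactions(gm, truth, cfg),
    }


def toy_gene_models(rows, exons=None, chrom_sizes=None):
    """Hand-built gene models from (gene_id, chrom, start, end, strand[, u5, u3])."""
    recs = []
    for r in rows:
        rec = dict(zip(["gene_id", "chrom", "start", "end", "strand",
                        "utr5_len", "utr3_len"], list(r) + [0, 0][:7 - len(r)]))
        recs.append(rec)
    ex = pd.DataFrame(exons, columns=["gene_id", "start", "end"]) if exons else None
    return GeneModels(pd.DataFrame(recs), ex, chrom_sizes)


def make_peaks(rows):
    """Peak frame from (chrom, start, end, score) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    df["name"] = [f"p{i}" for i in range(len(df))]
    return df
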
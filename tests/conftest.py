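import numpy as np
import pandas as pd
import pytest

from hgtenrich import SimConfig
from hgtenrich import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_bacteria=30, n_archaea=6, seed=7)


@pytest.fixture(scope="session")
def small_community(small_config):
    genomes, _ = sd.generate_community(small_config)
    return genomes


@pytest.fixture(scope="session")
def gene_level_sim():
    """A mid-sized community with full gene-level tables, shared across tests.

    Large enough for direction-ratio and COG statistics, small enough to
    generate once per session.
    """
    cfg = SimConfig(n_bacteria=80, n_archaea=8, seed=5)
    genomes, _ = sd.generate_community(cfg)
    matrix, truth = sd.generate_rbh_matrix(genomes, cfg)
    hits, genes, lpi, cog = sd.generate_gene_tables(genomes, matrix, truth, cfg)
    pairs = pd.DataFrame(
        {
            "gene_b": lpi["gene_id"][lpi["gene_id"].str.endswith("b")],
        }
    )
    sizes = pd.Series({g.id: float(g.n_genes) for g in genomes})
    return {
        "config": cfg,
        "genomes": genomes,
        "matrix": matrix,
        "truth": truth,
        "hits": hits,
        "genes": genes,
        "lpi": lpi,
        "cog": cog,
        "sizes": sizes,
    }


@pytest.fixture(scope="session")
def gene_level_pairs(gene_level_sim):
    """True RBH pairs of the gene-level community, straight from the hit table."""
    hits = gene_level_sim["hits"]
    fwd = hits.loc[
        hits["query_id"].str.endswith("b")
        & hits["subject_id"].str.endswith("a")
        & (hits["evalue"] <= 1e-10)
    ]
    return pd.DataFrame(
        {
            "gene_b": fwd["query_id"].to_numpy(),
            "gene_a": fwd["subject_id"].to_numpy(),
            "bacterium": fwd["query_genome"].to_numpy(),
            "archaeon": fwd["subject_genome"].to_numpy(),
        }
    )
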
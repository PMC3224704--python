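import numpy as np
import pandas as pd
import pytest

from cistronet.compendium import ExpressionDataset
from cistronet.features import GeneRecord


def make_dataset(values, gene_ids, sample_ids, mask=None, platform="cDNA_gDNA"):
    vals = pd.DataFrame(np.asarray(values, dtype=float), index=gene_ids, columns=sample_ids)
    if mask is None:
        mask = np.zeros(vals.shape, dtype=bool)
    m = pd.DataFrame(np.asarray(mask, dtype=bool), index=gene_ids, columns=sample_ids)
    vals = vals.mask(m)
    return ExpressionDataset(platform, vals, m)


@pytest.fixture
def toy_genes():
    """Four genes on one contig: two plus-strand then two minus-strand."""
    return [
        GeneRecord("g1", "chr", 100, 400, "+"),
        GeneRecord("g2", "chr", 450, 800, "+"),
        GeneRecord("g3", "chr", 900, 1300, "-"),
        GeneRecord("g4", "chr", 1350, 1700, "-"),
    ]


@pytest.fixture(scope="session")
def default_synthetic():
    """Generator outputs at default scale, shared across recovery tests."""
    from cistronet.synth import (SyntheticConfig, generate_annotations,
                                 generate_expression, generate_genome,
                                 generate_promoters, generate_training_set)

    cfg = SyntheticConfig()
    seed = 202
    genes, truth = generate_genome(cfg, seed)
    genes, conservation, dag, namespaces = generate_annotations(genes, truth, cfg, seed)
    datasets = generate_expression(truth, cfg, seed)
    genome = generate_promoters(genes, truth, cfg, seed)
    labels = generate_training_set(genes, truth, cfg, seed)
    return dict(cfg=cfg, seed=seed, genes=genes, truth=truth,
                conservation=conservation, dag=dag, namespaces=namespaces,
                datasets=datasets, genome=genome, labels=labels)
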
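import numpy as np
import pandas as pd
import pytest

from circdm import synthetic as syn
from circdm.data_model import (
    CircCatalog,
    CircRecord,
    GeneModel,
    GenomicInterval,
    JunctionCounts,
    SampleMeta,
    parse_locus,
)


@pytest.fixture(scope="session")
def toy_gene():
    """Five-exon gene with regular introns on a small chromosome."""
    exons = tuple(
        GenomicInterval("chrT", s, s + 100) for s in (1000, 1500, 2000, 2500, 3000)
    )
    return GeneModel(gene_id="geneT", name="GENET", exons=exons)


@pytest.fixture(scope="session")
def small_annotation():
    return syn.make_annotation(n_genes=8, seed=11)


@pytest.fixture(scope="session")
def small_catalog(small_annotation):
    genes, _ = small_annotation
    catalog, gene_map = syn.make_catalog(genes, n_top_mcg=1, seed=12)
    return catalog, gene_map


@pytest.fixture(scope="session")
def small_dataset(small_annotation, small_catalog):
    """Counts + metadata for 6v6 samples over the small catalog."""
    catalog, _ = small_catalog
    design = syn.SimDesign(n_control=6, n_dm=6, seed=13)
    counts, meta, truth = syn.simulate_counts(catalog, design)
    return counts, meta, truth


def make_counts(bsj_rows, sample_ids, linear_rows=None, groups=None, libsize=1_000_000):
    """Small JunctionCounts with metadata from plain nested lists."""
    circ_ids = [f"c{i}" for i in range(len(bsj_rows))]
    bsj = pd.DataFrame(bsj_rows, index=circ_ids, columns=sample_ids)
    linear = pd.DataFrame(
        linear_rows if linear_rows is not None else np.zeros_like(bsj_rows),
        index=circ_ids,
        columns=sample_ids,
    )
    groups = groups or ["control"] * len(sample_ids)
    meta = [
        SampleMeta(sample_id=s, group=g, mappable_reads=libsize)
        for s, g in zip(sample_ids, groups)
    ]
    return JunctionCounts(bsj, linear, samples=meta), meta
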
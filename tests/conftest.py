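import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for the _oracles helper

from mxescan import PredictionParams, predict_genome
from mxescan.simulate import (IsoformPattern, PlantSpec, filter_demo_fixture,
                              generate_planted_genome)


@pytest.fixture(scope="session")
def filter_demo():
    """The worked three-exon gene with a planted cluster of four MXEs."""
    return filter_demo_fixture()


@pytest.fixture(scope="session")
def filter_demo_run(filter_demo):
    """Gene models plus the relaxed store-stage candidate set for the fixture."""
    dataset, expected = filter_demo
    genes = dataset.gene_models()
    cands = predict_genome(genes, dataset.genome, PredictionParams.store())
    return genes, cands, expected


@pytest.fixture(scope="session")
def planted_ds():
    """12 genes, one internal planted cluster each at 80% identity."""
    spec = PlantSpec.one_internal_cluster_per_gene(12, 0.8, seed=42)
    return generate_planted_genome(spec)


@pytest.fixture(scope="session")
def planted_run(planted_ds):
    genes = planted_ds.gene_models()
    store = predict_genome(genes, planted_ds.genome, PredictionParams.store())
    return genes, store


@pytest.fixture(scope="session")
def swapped_exon_genes():
    """Four two-isoform genes with annotated mutually exclusive exon pairs.

    Three pairs are similar enough to be cross-predicted at default
    parameters; in the fourth the variant is degraded below the default
    score threshold.
    """
    patterns = {g: IsoformPattern("annotated_mxe", 2, identity=0.85,
                                  ensure_score_above=25.0)
                for g in range(3)}
    patterns[3] = IsoformPattern("annotated_mxe", 2, identity=0.15,
                                 ensure_score_below=14.0)
    spec = PlantSpec(genes=4, seed=5, isoform_patterns=patterns)
    return generate_planted_genome(spec)
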
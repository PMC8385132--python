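import numpy as np
import pandas as pd
import pytest

from ldcoloc.genetic_map import GeneticMap
from ldcoloc.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic study conditions (seed 1), shared read-only."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced scenario for the expression-heavy pipeline tests."""
    cfg = ScenarioConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length_bp=12e6,
        n_true_loci=6,
        n_decoys=6,
        genes_per_mb=6.0,
        n_noncis_eqtl=20,
        studies=(("adipose", 2), ("muscle", 1)),
        samples_per_study=24,
        probes_per_gene_max=2,
        n_sets=6,
        set_size=15,
        n_enriched_sets=2,
    )
    return generate_scenario(cfg)


@pytest.fixture
def block_step_map():
    """A hand-built map: 200-kb flat block, sharp 3-LDU step, flat tail.

    A +/-1-LDU window centred in the block spans the whole block; centred
    inside the step it spans only ~667 bp.
    """
    return GeneticMap("1", [0, 200_000, 201_000, 400_000], [0.0, 0.0, 3.0, 3.0])


def random_map(rng, n_anchors=30, chromosome="1"):
    """Random monotone block/step map for property tests."""
    gaps = rng.integers(1, 50_000, size=n_anchors - 1)
    positions = np.cumsum(np.concatenate([[1], gaps]))
    rises = np.where(rng.random(n_anchors - 1) < 0.5, 0.0, rng.exponential(1.0, n_anchors - 1))
    ldu = np.concatenate([[0.0], np.cumsum(rises)])
    return GeneticMap(chromosome, positions, ldu)


@pytest.fixture
def annotation_grid():
    """60 genes on one chromosome, evenly spaced 500 kb apart."""
    starts = np.arange(60) * 500_000 + 10_000
    return pd.DataFrame(
        {
            "chrom": "1",
            "start": starts,
            "end": starts + 20_000,
            "gene_id": [f"G{i:03d}" for i in range(60)],
            "hgnc": [f"G{i:03d}" for i in range(60)],
        }
    )
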
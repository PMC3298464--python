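"""Shared fixtures: hand-built toy annotations and a small simulated study."""

import numpy as np
import pytest

from medipseq.genome import GeneModel, GenomeAnnotation, RepeatElement
from medipseq.simulate import SimulationConfig, simulate_study


@pytest.fixture
def toy_annotation():
    """Two chromosomes, two genes (one per strand), one repeat."""
    plus = GeneModel(
        id="gA", chrom="chr1", strand="+", tx_start=5000, tx_end=8000,
        exons=[(5000, 5600), (6200, 7100), (7500, 8000)],
        utr5=(5000, 5300), utr3=(7700, 8000),
    )
    minus = GeneModel(
        id="gB", chrom="chr2", strand="-", tx_start=5000, tx_end=8000,
        exons=[(5000, 6000), (7000, 8000)],
        utr5=(7600, 8000), utr3=(5000, 5400),
    )
    return GenomeAnnotation(
        chrom_lengths={"chr1": 20000, "chr2": 9000},
        genes=[plus, minus],
        repeats=[RepeatElement("chr1", 12000, 12500, "LTR-gypsy")],
        organelle_names=set(),
    )


@pytest.fixture(scope="session")
def small_sim_config():
    return SimulationConfig(seed=11, reads_per_sample=6000)


@pytest.fixture(scope="session")
def small_study(small_sim_config):
    return simulate_study(small_sim_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120117)
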
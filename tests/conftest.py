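import numpy as np
import pytest

from skimloci.pipeline import _consensus_all, assemble_matrix
from skimloci.read_mapping import ReferenceSet, build_index, compute_pileup, map_library
from skimloci.skim_simulator import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated skim: 6 taxa, 5 loci of 240 bp, expected depth 6."""
    config = SimulationConfig(
        n_taxa=6, n_loci=5, locus_length=240, target_depth=6.0,
        sequencing_error_rate=0.001, seed=101,
    )
    refs, libraries, truth = generate_dataset(config)
    return config, refs, libraries, truth


@pytest.fixture(scope="session")
def small_pileups(small_dataset):
    """Mapped pileups per sample for the small dataset."""
    config, refs, libraries, truth = small_dataset
    refset = ReferenceSet(refs)
    index = build_index(refset, config.read_length // 5)
    pileups = {
        sid: compute_pileup(map_library(reads, index, refset), refset)
        for sid, reads in libraries.items()
    }
    return refset, pileups


def assemble(refset, pileups, min_depth=2, min_coverage=0.1, **kwargs):
    calls = _consensus_all(pileups, min_depth, kwargs.pop("het_fraction", 0.25))
    return assemble_matrix(calls, refset, min_coverage, **kwargs)
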
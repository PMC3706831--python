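import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from flsmethylome.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, fully-featured cohort for structural and unit checks."""
    config = SimConfig(
        n_loci=3000,
        n_genes=300,
        n_pathways=20,
        genes_per_pathway=15,
        group_sizes=(5, 5, 4),
        p5_replicate_lines=2,
        seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the full study conditions (20k loci, 11/11/6 lines)."""
    return simulate_cohort(SimConfig(seed=5))
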
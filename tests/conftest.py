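import pytest

from cernet.simulate import SimulationConfig, simulate_bundle
from cernet.targeting import build_target_map


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic fixture: 30 coding genes, 10 true lncRNAs,
    5 single-fault decoys, 158 miRNAs, 10 planted triplets, 18 samples."""
    return simulate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_target_map(default_bundle):
    """MRE scan of all miRNAs against the true lncRNAs and all mRNAs."""
    b = default_bundle
    ids = list(b.truth.mrna_ids) + sorted(b.truth.true_lncrna_ids)
    return build_target_map(b.mirnas, {k: b.sequences[k] for k in ids})


@pytest.fixture(scope="session")
def small_config_dict():
    """A reduced configuration for fast CLI round-trips."""
    return {
        "n_coding_genes": 8,
        "n_intergenic": 3,
        "n_intronic": 1,
        "n_antisense": 1,
        "n_mirnas": 20,
        "n_planted_triplets": 3,
    }
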
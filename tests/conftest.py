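import pytest

from hicut import (
    AnalysisParams,
    SimulationConfig,
    bin_pairs,
    call_interactions,
    canonicalize_all,
    deduplicate,
    filter_pairs,
    kr_balance,
    simulate,
)


@pytest.fixture(scope="session")
def params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic dataset (seed 7), shared across tests."""
    return simulate(SimulationConfig())


@pytest.fixture(scope="session")
def default_calls(default_bundle, params):
    prepped = filter_pairs(
        deduplicate(canonicalize_all(default_bundle.pairs)), params
    )
    return call_interactions(prepped, default_bundle.peaks, params)


@pytest.fixture(scope="session")
def decay_only_bundle():
    """Loop-free, trans-free, duplicate-free draw: decay background only."""
    cfg = SimulationConfig(
        n_loops=0, trans_fraction=0.0, duplicate_fraction=0.0, seed=11
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_matrices(default_bundle):
    """Balanced 5 kb contact matrices of the default dataset."""
    mats = bin_pairs(
        canonicalize_all(default_bundle.pairs),
        5_000,
        chrom_sizes=default_bundle.config.chrom_sizes,
    )
    for cm in mats.values():
        kr_balance(cm)
    return mats
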
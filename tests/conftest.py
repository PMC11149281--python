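import numpy as np
import pytest

from regmap import abc_map
from regmap.synthetic import SimConfig, simulate_all


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic study at seed 1 (shared, read-only)."""
    return simulate_all(SimConfig(seed=1))


@pytest.fixture(scope="session")
def powerlaw_fit(dataset):
    cfg = dataset.config
    return abc_map.fit_powerlaw(
        dataset.contacts, cfg.bin_size_bp, n_bins=cfg.chrom_len_bp // cfg.bin_size_bp
    )


@pytest.fixture(scope="session")
def abc_nt(dataset, powerlaw_fit):
    """ABC map for the stimulated non-treated condition at 24 h."""
    cfg = dataset.config
    activity = abc_map.condition_activity(
        dataset.atac, dataset.h3k27ac, dataset.design, "NT_24h"
    )
    return abc_map.build_abc_map(
        dataset.elements,
        dataset.genes,
        activity,
        dataset.contacts,
        cfg.bin_size_bp,
        condition="NT_24h",
        powerlaw=powerlaw_fit,
    )


@pytest.fixture(scope="session")
def strong_effect_dataset():
    """A study with an exaggerated drug effect, for testing call logic
    where per-feature significance must be near-certain."""
    return simulate_all(SimConfig(seed=3, drug_effect=-3.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
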
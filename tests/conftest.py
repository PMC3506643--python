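"""Shared fixtures: the standard synthetic datasets and derived panels.

Simulation and AMid computation are session-scoped so the heavier
datasets (20,000-40,000 SNPs) are generated once per run.
"""

import numpy as np
import pytest
from hypothesis import settings

import ancestrymapper as am

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def std_fixtures():
    return am.make_standard_fixtures()


@pytest.fixture(scope="session")
def continental(std_fixtures):
    return std_fixtures["continental"]


@pytest.fixture(scope="session")
def continental_panel(continental):
    return am.build_panel(continental.genotypes)


@pytest.fixture(scope="session")
def continental_profiles(continental, continental_panel):
    return am.compute_amids(continental.genotypes, continental_panel)


@pytest.fixture(scope="session")
def tiny(std_fixtures):
    return std_fixtures["tiny"]


@pytest.fixture(scope="session")
def tiny_panel(tiny):
    return am.build_panel(tiny.genotypes)


@pytest.fixture(scope="session")
def tiny_profiles(tiny, tiny_panel):
    return am.compute_amids(tiny.genotypes, tiny_panel, min_overlap=10)


@pytest.fixture(scope="session")
def admixed(std_fixtures):
    return std_fixtures["admixed"]


@pytest.fixture(scope="session")
def admixed_panel(admixed):
    """Panel from the unadmixed source populations only."""
    gm = admixed.genotypes
    unadmixed = [s for s in gm.sample_ids
                 if admixed.metadata.loc[s, "region"] != "ADMIXED"]
    return am.build_panel(gm.subset_samples(unadmixed))


@pytest.fixture(scope="session")
def admixed_profiles(admixed, admixed_panel):
    return am.compute_amids(admixed.genotypes, admixed_panel)


@pytest.fixture(scope="session")
def stability_dataset():
    """Deeper SNP set (40,000) so 20,000-SNP subsamples are non-trivial."""
    cfg = am.SimulationConfig(
        n_continents=3, pops_per_continent=2, inds_per_pop=10, n_snps=40_000,
        F_continent=0.10, F_population=0.05, missing_rate=0.002, seed=11,
    )
    ds = am.simulate(cfg)
    return ds, am.build_panel(ds.genotypes)


@pytest.fixture(scope="session")
def serial_founder():
    ds = am.simulate_serial_founder(seed=7)
    panel = am.build_panel(ds.genotypes)
    profiles = am.compute_amids(ds.genotypes, panel)
    return ds, panel, profiles


def naive_rms_distance(g, r):
    """Independent per-position oracle for the RMS genotype distance."""
    total, n = 0.0, 0
    for x, y in zip(g, r):
        if not (np.isnan(x) or np.isnan(y)):
            total += (x - y) ** 2
            n += 1
    if n == 0:
        return np.nan, 0
    return float(np.sqrt(total / n)), n
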
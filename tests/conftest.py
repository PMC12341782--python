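import numpy as np
import pandas as pd
import pytest

import longreadage as lra
from longreadage.types import sites_index


@pytest.fixture(scope="session")
def sim_reference():
    """A cohort-scale simulated reference dataset with its generating truth."""
    cfg = lra.SimulationConfig(seed=11, n_reference_samples=519, n_sites=2000)
    dataset, truth = lra.simulate_reference(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def sim_model(sim_reference):
    _, dataset, _ = sim_reference
    return lra.fit_reference(dataset)


@pytest.fixture(scope="session")
def sim_atlas():
    """Atlas sample set + ground-truth marker mean table (separation 0.5)."""
    cfg = lra.SimulationConfig(seed=3, ineligible_fraction=0.0)
    samples, truth = lra.simulate_atlas_samples(cfg)
    return cfg, samples, truth


def make_model(rows):
    """Hand-built reference model from (chrom, pos, slope, intercept, r, n) rows."""
    tab = pd.DataFrame(
        rows, columns=["chrom", "pos", "slope", "intercept", "pearson_r", "n_samples"]
    ).set_index(["chrom", "pos"])
    return lra.ReferenceAgingModel.from_table(tab)


def make_profile(entries):
    """Profile from (chrom, pos, beta[, coverage]) tuples."""
    idx = sites_index([(e[0], e[1]) for e in entries])
    beta = pd.Series([e[2] for e in entries], index=idx, dtype=float)
    cov = pd.Series([e[3] if len(e) > 3 else 1 for e in entries], index=idx, dtype=int)
    return lra.MethylationProfile(beta=beta, coverage=cov)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
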
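import numpy as np
import pandas as pd
import pytest

from epiconcord import simulate
from epiconcord.methylome import Methylome


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_world(sim_config):
    """(genome, truth, tss) for the default simulation."""
    return simulate.build_truth(sim_config)


@pytest.fixture(scope="session")
def rod_cone_methylomes(sim_config, sim_world):
    """Two replicates each for rodlike, conelike, hybrid."""
    _, truth, _ = sim_world
    return {
        name: [
            simulate.simulate_methylome(truth, name, sim_config, rep)
            for rep in range(sim_config.n_replicates)
        ]
        for name in ("rodlike", "conelike", "hybrid")
    }


@pytest.fixture(scope="session")
def rod_cone_accessibility(sim_config, sim_world):
    """{profile: [(fragments, peaks) per replicate]}."""
    _, truth, _ = sim_world
    return {
        name: [
            simulate.simulate_accessibility(truth, name, sim_config, rep)
            for rep in range(sim_config.n_replicates)
        ]
        for name in ("rodlike", "conelike", "hybrid")
    }


def make_methylome(
    positions, levels, cov=20, chrom="chr1", seed=0, context="CG", label="m",
    lambda_nc=0.0, exact=False,
):
    """Small hand-built methylome: binomial counts (or exact rounded counts)
    around the given per-site levels."""
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions)
    levels = np.asarray(levels, dtype=float)
    cov_arr = np.full(len(positions), cov, dtype=np.int64)
    if exact:
        mc = np.round(levels * cov_arr).astype(np.int64)
    else:
        mc = rng.binomial(cov_arr, levels)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "strand": "+",
            "context": context,
            "mc": mc,
            "cov": cov_arr,
        }
    )
    return Methylome(df, sample_label=label, lambda_nc=lambda_nc)
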
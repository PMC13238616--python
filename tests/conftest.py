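import numpy as np
import pandas as pd
import pytest

from abalonepg import simdata
from abalonepg.core import GenotypeMatrix


def make_gm(
    G,
    positions=None,
    scaffold="s1",
    locations=None,
    groups=None,
    depth=None,
    scaffold_length=None,
    tag="full",
):
    """Build a GenotypeMatrix from a plain (sites x samples) list/array."""
    G = np.asarray(G, dtype=np.int8)
    n_sites, n_samples = G.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {"scaffold": scaffold, "pos": positions, "ref": "A", "alt": "C"}
    )
    samples = pd.DataFrame(
        {
            "sample": [f"ind{i}" for i in range(n_samples)],
            "location": locations or ["loc1"] * n_samples,
            "group": groups or ["g1"] * n_samples,
        }
    )
    lengths = {scaffold: scaffold_length or int(max(positions)) + 100}
    return GenotypeMatrix(
        sites=sites, G=G, samples=samples,
        depth=None if depth is None else np.asarray(depth),
        tag=tag, scaffold_lengths=lengths,
    )


@pytest.fixture(scope="session")
def two_deme_result():
    """Two demes, selection concentrated on scaffold_1 (preset conditions)."""
    return simdata.simulate_population(simdata.two_deme_selection_config(seed=2))


@pytest.fixture(scope="session")
def constant_result():
    """Neutral constant N=500 single deme (preset conditions)."""
    return simdata.simulate_population(simdata.constant_config(N=500, seed=3))


@pytest.fixture(scope="session")
def bottleneck_result():
    """Long-term expansion + severe recent bottleneck + partial recovery."""
    return simdata.simulate_population(simdata.bottleneck_config(seed=4))


@pytest.fixture(scope="session")
def bottleneck_control_result():
    """Constant-size control paired with the bottleneck run (same seed)."""
    cfg = simdata.bottleneck_config(seed=4)
    return simdata.simulate_population(
        simdata.SimConfig(
            scaffolds=cfg.scaffolds,
            schedule=[(0, (2000,))],
            n_generations=40,
            mu=cfg.mu,
            recomb=cfg.recomb,
            sample_sizes=cfg.sample_sizes,
            group_names=("all",),
            seed=4,
        )
    )


@pytest.fixture(scope="session")
def roh_planted():
    """Dense-SNP simulation with 10 planted homozygous tracts >= 150 kb."""
    res = simdata.simulate_population(simdata.roh_config(seed=7))
    rng = np.random.default_rng(7)
    samples = list(res.gm.samples["sample"])
    # one tract per individual: tracts in the same sample and scaffold
    # would merge into a single detected segment
    chosen = rng.choice(samples, size=10, replace=False)
    tracts = []
    for k, sample in enumerate(chosen):
        scaffold = f"scaffold_{k % 2 + 1}"
        length = int(rng.integers(150_000, 250_000))
        start = int(rng.integers(50_000, 1_000_000 - length - 50_000))
        simdata.plant_roh(res, str(sample), scaffold, start, start + length)
        tracts.append((str(sample), scaffold, start, start + length))
    return res, tracts


@pytest.fixture(scope="session")
def small_sim():
    """Tiny fast simulation for I/O round trips and generic smoke tests."""
    cfg = simdata.SimConfig(
        scaffolds=[("scaffold_1", 200_000), ("scaffold_2", 150_000)],
        schedule=[(0, (60, 60))],
        n_generations=10,
        mu=2e-7,
        recomb=1e-7,
        migration=0.05,
        sample_sizes=(8, 8),
        seed=5,
    )
    return simdata.simulate_population(cfg)
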
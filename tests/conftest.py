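import numpy as np
import pandas as pd
import pytest

import poolgwas as pg


def standard_assignment(libraries):
    return {lib: ("D" if lib.startswith("D") else "ND") for lib in libraries}


def run_pipeline(config, k=None):
    """Simulation -> phenotyping -> extreme selection -> pooled sequencing."""
    pop = pg.simulate_strains(config)
    flies = pg.simulate_phenotypes(pop)
    profiles = pg.compute_dormancy_levels(flies)
    groups = pg.select_extreme_groups(profiles, k=k or config.pool_strains)
    sync, truth = pg.generate_pool_counts(pop, groups.dormant_strains,
                                          groups.nondormant_strains)
    return pop, flies, profiles, groups, sync, truth


@pytest.fixture(scope="session")
def small_config():
    return pg.SimulationConfig(n_strains=60, n_sites=400, pool_strains=10,
                               chrom_lengths={"2L": 1500, "2R": 1500},
                               seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    pop, flies, profiles, groups, sync, truth = run_pipeline(small_config)
    return {"pop": pop, "flies": flies, "profiles": profiles,
            "groups": groups, "sync": sync, "truth": truth}


@pytest.fixture()
def merged_small(small_study):
    sync = small_study["sync"]
    return pg.merge_groups(sync, standard_assignment(sync.libraries))


@pytest.fixture()
def toy_sync():
    """Hand-built 2-library sync with known counts."""
    chrom = np.array(["2R", "2R", "3L"], dtype=object)
    pos = np.array([100, 101, 5], dtype=np.int64)
    ref = np.array(["A", "T", "C"], dtype=object)
    counts = np.array([
        [[10, 0, 2, 0, 0, 0], [8, 0, 4, 0, 0, 0]],
        [[0, 12, 0, 3, 0, 1], [0, 9, 0, 6, 1, 0]],
        [[5, 5, 0, 0, 0, 0], [5, 5, 0, 0, 0, 0]],
    ], dtype=np.int64)
    return pg.SyncData(chrom, pos, ref, counts, ["D", "ND"])


def make_flies(rows):
    """rows: (strain, temperature, dormant, eggs) tuples."""
    return pd.DataFrame(rows, columns=["strain", "temperature", "dormant", "eggs"])
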
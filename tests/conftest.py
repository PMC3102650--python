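import numpy as np
import pandas as pd
import pytest

import surrosel as ss
from surrosel.solvers import AnnealSchedule


def make_matrix(vals, species=None, cells=None) -> ss.PresenceAbsence:
    vals = np.asarray(vals, dtype=bool)
    if species is None:
        species = [f"s{i}" for i in range(vals.shape[0])]
    if cells is None:
        cells = list(range(vals.shape[1]))
    return ss.PresenceAbsence(vals, species, cells)


def random_instance(rng, max_cells=12, max_species=10, p=0.3):
    """Small random solvable instance (every species occupies >= 1 cell)."""
    n_c = int(rng.integers(4, max_cells + 1))
    n_s = int(rng.integers(3, max_species + 1))
    vals = rng.random((n_s, n_c)) < p
    for r in range(n_s):
        if not vals[r].any():
            vals[r, rng.integers(n_c)] = True
    return make_matrix(vals)


@pytest.fixture(scope="session")
def reduced_configs():
    return ss.default_paired_configs("reduced")


@pytest.fixture(scope="session")
def small_assemblage():
    """One quickly generated small region with all group kinds present."""
    orders = {"Alpha": 20, "Beta": 24, "Gamma": 18, "Delta": 6, "Epsilon": 4}
    cfg = ss.AssemblageConfig(n_rows=10, n_cols=10, order_sizes=orders)
    return ss.generate_hotspot(cfg, "small", np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_pipeline(reduced_configs):
    """A full paired analysis at reduced scale with few runs (shared)."""
    cfg_a, cfg_b = reduced_configs
    return ss.run_pipeline(cfg_a, cfg_b, seed=5, n_runs=5)


FAST_SCHEDULE = AnnealSchedule(iterations=2_000, restarts=2)
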
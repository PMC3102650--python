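import math
from collections import deque

import numpy as np
import pytest

import surrosel as ss
from surrosel import AssemblageConfig, generate_hotspot, generate_paired_hotspots, make_grid
from surrosel.synthetic import spread_dye_range


def bfs_connected(grid, cells) -> bool:
    """Independent rook-connectivity oracle by breadth-first traversal."""
    cells = set(cells)
    start = next(iter(cells))
    seen = {start}
    queue = deque([start])
    while queue:
        c = queue.popleft()
        for nb in grid.neighbors(c):
            if nb in cells and nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return seen == cells


class TestSpreadDye:
    def test_target_one_returns_seed_only(self):
        g = make_grid(4, 4)
        assert spread_dye_range(g, 1, 5, np.random.default_rng(0)) == {5}

    def test_saturation_fills_grid(self):
        g = make_grid(3, 3)
        assert spread_dye_range(g, 50, 0, np.random.default_rng(0)) == set(range(9))

    def test_invalid_seed_rejected(self):
        g = make_grid(3, 3)
        with pytest.raises(ValueError):
            spread_dye_range(g, 2, 9, np.random.default_rng(0))
        with pytest.raises(ValueError):
            spread_dye_range(g, 0, 1, np.random.default_rng(0))

    @pytest.mark.parametrize("trial", range(20))
    def test_ranges_rook_connected_on_5x5(self, trial):
        g = make_grid(5, 5)
        rng = np.random.default_rng(trial)
        size = int(rng.integers(1, 26))
        seed = int(rng.integers(25))
        cells = spread_dye_range(g, size, seed, rng)
        assert len(cells) == size
        assert seed in cells
        assert bfs_connected(g, cells)


def _tiny_config(**kw):
    defaults = dict(
        n_rows=6,
        n_cols=6,
        order_sizes={"A": 6, "B": 4},
        endemic_fraction=0.3,
        threatened_fraction=0.3,
    )
    defaults.update(kw)
    return AssemblageConfig(**defaults)


class TestGenerateHotspot:
    def test_forced_single_cell_occupancy(self):
        # log-normal pushed far left: every species occupies exactly 1 cell
        cfg = _tiny_config(occupancy_mu=math.log(1e-6), occupancy_sigma=0.01)
        asm = generate_hotspot(cfg, "r", np.random.default_rng(3))
        assert (asm.matrix.occupancy() == 1).all()

    def test_all_endemic_seeds_confined_to_zone(self):
        cfg = _tiny_config(
            endemic_fraction=1.0,
            endemic_zone_fraction=0.25,
            occupancy_mu=math.log(1e-6),
            occupancy_sigma=0.01,
        )
        asm = generate_hotspot(cfg, "r", np.random.default_rng(4))
        zone = set(cfg.endemic_zone_cells(asm.grid))
        # size-1 ranges equal their seed cells
        occupied = set(np.flatnonzero(asm.matrix.values.any(axis=0)))
        assert occupied <= zone
        assert asm.metadata["endemic"].all()

    def test_occupancy_right_skewed_at_stated_parameters(self):
        # 200 species on 20x15, lognormal(log 0.05, 1): median < mean
        cfg = AssemblageConfig(
            n_rows=20,
            n_cols=15,
            order_sizes={"O": 200},
            occupancy_mu=math.log(0.05),
            occupancy_sigma=1.0,
        )
        hits = 0
        for seed in range(50):
            asm = generate_hotspot(cfg, "r", np.random.default_rng(seed))
            occ = asm.matrix.occupancy()
            hits += float(occ.median()) < float(occ.mean())
        assert hits >= 0.95 * 50

    def test_every_species_occupies_at_least_one_cell(self, small_assemblage):
        assert (small_assemblage.matrix.occupancy() >= 1).all()

    def test_deterministic_given_seed(self):
        cfg = _tiny_config()
        a1 = generate_hotspot(cfg, "r", np.random.default_rng(42))
        a2 = generate_hotspot(cfg, "r", np.random.default_rng(42))
        assert a1 == a2


def centroid_spread(asm, ids):
    grid = asm.grid
    df = asm.matrix.to_frame()
    cents = []
    for s in ids:
        cells = np.flatnonzero(df.loc[s].to_numpy())
        rc = np.array([divmod(int(c), grid.n_cols) for c in cells], dtype=float)
        cents.append(rc.mean(axis=0))
    cents = np.array(cents)
    d = [
        abs(cents[i] - cents[j]).sum()
        for i in range(len(cents))
        for j in range(i + 1, len(cents))
    ]
    return float(np.mean(d))


def test_endemic_ranges_clumped_relative_to_random_subset(reduced_configs):
    """Endemics (zone-seeded) sit closer together than a size-matched
    random non-endemic subset in the vast majority of realizations."""
    cfg, _ = reduced_configs
    wins = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        asm = generate_hotspot(cfg, "r", rng)
        md = asm.metadata
        end = list(md.index[md["endemic"]])
        non = list(md.index[~md["endemic"]])
        if len(end) < 3:
            wins += 1  # too few endemics to compare; not a clumping failure
            continue
        pick = list(rng.choice(non, size=len(end), replace=False))
        wins += centroid_spread(asm, end) < centroid_spread(asm, pick)
    assert wins >= 0.90 * 50


class TestPairedHotspots:
    def test_mismatched_order_lists_rejected(self):
        cfg_a = _tiny_config()
        cfg_b = _tiny_config(order_sizes={"A": 6, "C": 4})
        with pytest.raises(ValueError, match="order list"):
            generate_paired_hotspots(cfg_a, cfg_b, np.random.default_rng(0))

    def test_cell_counts_follow_grid_dimensions(self):
        cfg_a = _tiny_config(n_rows=26, n_cols=26)
        cfg_b = _tiny_config(n_rows=22, n_cols=21)
        a, b = generate_paired_hotspots(cfg_a, cfg_b, np.random.default_rng(0))
        assert (a.n_cells, b.n_cells) == (676, 462)
        assert a.region != b.region

    def test_pair_reproducible_from_master_seed(self):
        cfg_a, cfg_b = _tiny_config(), _tiny_config(n_rows=5, n_cols=7)
        p1 = generate_paired_hotspots(cfg_a, cfg_b, np.random.default_rng(9))
        p2 = generate_paired_hotspots(cfg_a, cfg_b, np.random.default_rng(9))
        assert p1[0] == p2[0] and p1[1] == p2[1]


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        AssemblageConfig(n_rows=3, n_cols=3, order_sizes={"A": 0})
    with pytest.raises(ValueError):
        AssemblageConfig(n_rows=3, n_cols=3, order_sizes={"A": 2}, endemic_fraction=1.5)
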
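"""Central-place harvest: trip rule, patch selection, depletion, season."""

import numpy as np
import pytest

from woodhaul import (
    Forager,
    HarvestParams,
    harvest_trip,
    run_harvest_year,
    select_patch,
    trip_status_rule,
)
from woodhaul.errors import ConfigError, HarvestContractError
from woodhaul.harvest import ANY, DEAD_ONLY, NearestPatchIndex
from woodhaul.landscape import GridSpec

from conftest import make_landscape

P = 0  # pinyon species code
J = 1


def forager(home=(0, 0), demand=7.0, adherence=1.0):
    return Forager(home=home, annual_demand=demand, adherence=adherence)


class TestTripStatusRule:
    def test_full_adherence_always_dead_only(self, rng):
        f = forager(adherence=1.0)
        assert all(trip_status_rule(f, rng) == DEAD_ONLY for _ in range(1000))

    def test_zero_adherence_always_any(self, rng):
        f = forager(adherence=0.0)
        assert all(trip_status_rule(f, rng) == ANY for _ in range(1000))

    def test_half_adherence_is_a_fair_coin(self, rng):
        f = forager(adherence=0.5)
        draws = [trip_status_rule(f, rng) == DEAD_ONLY for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.015)

    def test_adherence_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            forager(adherence=1.2)
        with pytest.raises(ConfigError):
            forager(adherence=-0.1)
        with pytest.raises(ConfigError):
            forager(demand=-1.0)


class TestSelectPatch:
    def test_dead_tree_in_home_cell_is_nearest(self, rng):
        grid = GridSpec(nx=5, ny=5, cell_km=1.0)
        ls = make_landscape(grid, [(P, 100, 300.0, False, 2, 2)])
        f = forager(home=(2, 2))
        assert select_patch(f, ls, DEAD_ONLY, rng=rng) == (2, 2)

    def test_dead_only_ignores_live_trees(self, rng):
        grid = GridSpec(nx=5, ny=5, cell_km=1.0)
        ls = make_landscape(grid, [(P, 100, 300.0, True, 2, 2)])
        f = forager(home=(2, 2))
        assert select_patch(f, ls, DEAD_ONLY, rng=rng) is None
        assert select_patch(f, ls, ANY, rng=rng) == (2, 2)

    def test_saplings_are_not_harvestable(self, rng):
        grid = GridSpec(nx=3, ny=3, cell_km=1.0)
        ls = make_landscape(grid, [(P, 2, 20.0, False, 1, 1)])  # below 50 kg
        assert select_patch(forager(home=(1, 1)), ls, DEAD_ONLY, rng=rng) is None

    def test_equidistant_ties_broken_uniformly(self):
        grid = GridSpec(nx=5, ny=5, cell_km=1.0)
        stems = [(P, 100, 300.0, False, 0, 4), (P, 100, 300.0, False, 4, 0)]
        f = forager(home=(0, 0))
        picks = []
        rng = np.random.default_rng(5)
        ls = make_landscape(grid, stems)
        for _ in range(1000):
            picks.append(select_patch(f, ls, DEAD_ONLY, rng=rng))
        frac = np.mean([p == (0, 4) for p in picks])
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_out_of_radius_stock_invisible(self, rng):
        grid = GridSpec(nx=40, ny=1, cell_km=10.0)
        ls = make_landscape(grid, [(P, 100, 300.0, False, 30, 0)])  # 300 km out
        f = forager(home=(0, 0))
        params = HarvestParams(max_radius_km=120.0)
        assert select_patch(f, ls, DEAD_ONLY, params, rng) is None

    def test_matches_exhaustive_scan(self):
        # nearest-first oracle: 1000 randomized queries against a brute
        # force distance scan over all stocked cells
        rng = np.random.default_rng(99)
        grid = GridSpec(nx=15, ny=15, cell_km=3.0)
        params = HarvestParams(max_radius_km=40.0)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            stems = [
                (
                    int(rng.integers(0, 2)),
                    int(rng.integers(10, 300)),
                    float(rng.uniform(60, 500)),
                    bool(rng.integers(0, 2)),
                    int(rng.integers(0, 15)),
                    int(rng.integers(0, 15)),
                )
                for _ in range(n)
            ]
            ls = make_landscape(grid, stems)
            for _ in range(20):
                home = (int(rng.integers(0, 15)), int(rng.integers(0, 15)))
                f = forager(home=home)
                status = DEAD_ONLY if rng.random() < 0.5 else ANY
                got = select_patch(f, ls, status, params, rng)
                # brute force: qualifying cells and their distances
                best = None
                for x in range(15):
                    for y in range(15):
                        c = grid.cell_id(x, y)
                        t = ls.trees
                        m = (t.cell == c) & (t.biomass >= params.min_stem_kg)
                        if status == DEAD_ONLY:
                            m = m & ~t.alive
                        if not m.any():
                            continue
                        d = grid.distance_km(home, (x, y))
                        if d <= params.max_radius_km and (best is None or d < best):
                            best = d
                if best is None:
                    assert got is None
                else:
                    assert got is not None
                    assert grid.distance_km(home, got) == pytest.approx(best)


class TestHarvestTrip:
    def test_full_load_leaves_remainder(self, rng):
        grid = GridSpec(nx=3, ny=3, cell_km=1.0)
        ls = make_landscape(
            grid,
            [(P, 200, 800.0, False, 1, 1), (P, 150, 700.0, False, 1, 1)],
        )
        f = forager(home=(1, 1))
        taken = harvest_trip(f, ls, (1, 1), DEAD_ONLY, HarvestParams(), rng)
        assert taken == pytest.approx(1000.0)
        assert f.loads_acquired == pytest.approx(1.0)
        # 1500 kg present, 1000 taken: 500 remains (oldest stem went first)
        assert ls.trees.biomass.sum() == pytest.approx(500.0)
        assert ls.trees.age.tolist() == [150]

    def test_partial_load(self, rng):
        grid = GridSpec(nx=3, ny=3, cell_km=1.0)
        ls = make_landscape(grid, [(P, 200, 400.0, False, 1, 1)])
        f = forager(home=(1, 1))
        taken = harvest_trip(f, ls, (1, 1), DEAD_ONLY, HarvestParams(), rng)
        assert taken == pytest.approx(400.0)
        assert f.loads_acquired == pytest.approx(0.4)
        assert len(ls.trees) == 0

    def test_hand_worked_mixed_patch(self, rng):
        # 2 dead (200 kg each) + 3 live (300, 450, 500 kg), allowed any,
        # load 1000: dead go first (oldest first), then live smallest-first:
        # 200 + 200 + 300 = 700, then 300 kg taken from the 450 kg stem,
        # leaving it alive at 150 kg (>= the 50 kg whole-stem threshold)
        grid = GridSpec(nx=3, ny=3, cell_km=1.0)
        ls = make_landscape(
            grid,
            [
                (P, 180, 200.0, False, 1, 1),
                (J, 220, 200.0, False, 1, 1),
                (P, 90, 450.0, True, 1, 1),
                (J, 80, 300.0, True, 1, 1),
                (P, 120, 500.0, True, 1, 1),
            ],
        )
        f = forager(home=(1, 1))
        taken = harvest_trip(f, ls, (1, 1), ANY, HarvestParams(), rng)
        assert taken == pytest.approx(1000.0)
        remaining = sorted(ls.trees.biomass.tolist())
        assert remaining == pytest.approx([150.0, 500.0])
        assert ls.trees.alive.all()

    def test_residual_below_threshold_taken_whole(self, rng):
        grid = GridSpec(nx=3, ny=3, cell_km=1.0)
        ls = make_landscape(grid, [(P, 200, 1030.0, False, 1, 1)])
        f = forager(home=(1, 1))
        taken = harvest_trip(f, ls, (1, 1), DEAD_ONLY, HarvestParams(), rng)
        # residual 30 kg < 50 kg threshold: whole stem goes into the load
        assert taken == pytest.approx(1030.0)
        assert len(ls.trees) == 0

    def test_trip_against_empty_patch_is_contract_violation(self, rng):
        grid = GridSpec(nx=3, ny=3, cell_km=1.0)
        ls = make_landscape(grid, [(P, 100, 300.0, True, 1, 1)])
        with pytest.raises(HarvestContractError):
            harvest_trip(
                forager(home=(1, 1)), ls, (1, 1), DEAD_ONLY, HarvestParams(), rng
            )

    def test_round_trip_distance_accrues(self, rng):
        grid = GridSpec(nx=9, ny=1, cell_km=2.0)
        ls = make_landscape(grid, [(P, 100, 300.0, False, 5, 0)])
        f = forager(home=(0, 0))
        harvest_trip(f, ls, (5, 0), DEAD_ONLY, HarvestParams(), rng)
        assert f.distance_travelled_km == pytest.approx(20.0)


class TestHarvestYear:
    def test_vacuous_with_zero_foragers(self, small_grid, rng):
        ls = make_landscape(small_grid, [(P, 100, 300.0, False, 5, 5)])
        stats = run_harvest_year([], ls, HarvestParams(), rng)
        assert stats.prop_meeting_need == 1.0
        assert stats.total_biomass_removed_kg == 0.0

    def test_abundant_home_stock_means_no_travel(self, small_grid, rng):
        stems = [(P, 100 + i, 900.0, False, 5, 5) for i in range(5)]
        ls = make_landscape(small_grid, stems)
        f = forager(home=(5, 5), demand=2.0)
        stats = run_harvest_year([f], ls, HarvestParams(), rng)
        assert stats.prop_meeting_need == 1.0
        assert stats.mean_distance_km == 0.0
        assert f.loads_acquired >= 2.0

    def test_two_foragers_one_load_hand_trace(self, small_grid, rng):
        # one 1000 kg dead stem: whoever goes first takes the full load,
        # the other comes back empty
        ls = make_landscape(small_grid, [(P, 100, 1000.0, False, 5, 5)])
        fs = [forager(home=(5, 5), demand=1.0), forager(home=(5, 5), demand=1.0)]
        stats = run_harvest_year(fs, ls, HarvestParams(), rng)
        assert stats.prop_meeting_need == pytest.approx(0.5)
        assert sorted(f.loads_acquired for f in fs) == pytest.approx([0.0, 1.0])
        assert stats.dead_trees_harvested == 1

    def test_taboo_full_adherence_never_touches_live_wood(self, small_grid, rng):
        stems = [(P, 100, 400.0, False, 5, 5)] + [
            (J, 90, 350.0, True, x, y) for x in range(10) for y in range(10)
        ]
        ls = make_landscape(small_grid, stems)
        live_before = ls.live_biomass_kg()
        fs = [forager(home=(5, 5), demand=3.0, adherence=1.0) for _ in range(4)]
        stats = run_harvest_year(fs, ls, HarvestParams(), rng)
        assert stats.live_trees_harvested == 0
        assert ls.live_biomass_kg() == live_before

    def test_biomass_conservation_is_exact(self, small_grid):
        rng = np.random.default_rng(31)
        stems = [
            (
                int(rng.integers(0, 2)),
                int(rng.integers(20, 300)),
                float(rng.uniform(60, 600)),
                bool(rng.integers(0, 2)),
                int(rng.integers(0, 10)),
                int(rng.integers(0, 10)),
            )
            for _ in range(400)
        ]
        ls = make_landscape(small_grid, stems)
        before = ls.trees.biomass.sum()
        fs = [forager(home=(5, 5), demand=5.0, adherence=0.3) for _ in range(6)]
        stats = run_harvest_year(fs, ls, HarvestParams(), rng)
        after = ls.trees.biomass.sum()
        assert before - after == pytest.approx(stats.total_biomass_removed_kg, abs=1e-6)
        loads_sum = sum(f.loads_acquired for f in fs) * 1000.0
        assert loads_sum == pytest.approx(stats.total_biomass_removed_kg, abs=1e-6)

    def test_radius_never_exceeded(self):
        rng = np.random.default_rng(77)
        grid = GridSpec(nx=30, ny=2, cell_km=10.0)
        stems = [(P, 100, 900.0, False, x, 0) for x in range(30)]
        ls = make_landscape(grid, stems)
        params = HarvestParams(max_radius_km=120.0)
        f = forager(home=(0, 0), demand=30.0, adherence=1.0)
        run_harvest_year([f], ls, HarvestParams(max_trips_per_year=60), rng)
        # cells beyond 120 km (x > 12) keep their stock
        far = ls.biomass_by_cell("dead")[
            [grid.cell_id(x, 0) for x in range(13, 30)]
        ]
        assert (far == 900.0).all()

    def test_travel_distance_grows_under_live_harvest(self):
        # without the dead-wood rule, depletion radiates outward and the
        # across-replicate mean distance rises through the years
        from scipy import stats as sstats

        from woodhaul import (
            DemographyParams,
            generate_suitability,
            populate_woodland,
            stationary_density,
            step_demography,
        )

        grid = GridSpec(nx=11, ny=11, cell_km=4.0, central_places=((5, 5),))
        params = DemographyParams()
        density = stationary_density(params)
        years = 20
        acc = np.zeros(years)
        for seed in range(20):
            suit = generate_suitability(grid, 8.0, seed)
            ls = populate_woodland(grid, suit, density, seed, demography=params)
            rng = np.random.default_rng(seed)
            fs = [
                forager(home=(5, 5), demand=10.5, adherence=0.0) for _ in range(8)
            ]
            for t in range(years):
                step_demography(ls, params, None, 2020 + t, rng)
                stats = run_harvest_year(fs, ls, HarvestParams(), rng)
                acc[t] += stats.mean_distance_km
        rho, p = sstats.spearmanr(np.arange(years), acc / 20.0)
        assert rho > 0 and p < 0.05


class TestTripLog:
    def test_log_rows_match_stats(self, small_grid, rng):
        stems = [(P, 100 + i, 900.0, False, 5, 5) for i in range(8)]
        ls = make_landscape(small_grid, stems)
        fs = [forager(home=(5, 5), demand=3.0), forager(home=(5, 5), demand=2.0)]
        log = []
        stats = run_harvest_year(fs, ls, HarvestParams(), rng, trip_log=log, year=2020)
        assert len(log) == stats.n_trips
        assert sum(r["kg"] for r in log) == pytest.approx(
            stats.total_biomass_removed_kg
        )
        assert {r["forager"] for r in log} <= {0, 1}
        assert all(r["year"] == 2020 for r in log)
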
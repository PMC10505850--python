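"""Central-place firewood foraging under an Indigenous harvest rule.

Households are foragers tied to a home central place. Each year a forager
makes truckload trips until its annual demand (in loads) is met, a trip
finds nothing within range, or its trip cap is reached. Before each trip
the forager draws whether the trip is restricted to dead wood: with
probability equal to its *adherence* the trip is ``dead_only`` (the
dead-wood-only rule — "we don't bother the live trees"), otherwise ``any``.

A trip targets the patch nearest to home (straight-line, cell centres)
holding harvestable wood of the allowed status, ties broken uniformly at
random. Within a patch, dead stems are taken first (oldest first); live
stems (smallest first) are touched only on ``any`` trips once the patch's
dead stock is gone — even non-adherent harvesters take the easiest wood
first. Stems below ``min_stem_kg`` are not harvestable firewood (saplings),
which keeps regrowing patches out of the trip rotation until stems reach
usable size.

Foragers take turns trip-by-trip in a per-year shuffled round-robin, so
depletion of the shared woodland is spread across households rather than
granting a season-long first-mover advantage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, HarvestContractError
from .landscape import SPECIES, GridSpec, Landscape

DEAD_ONLY = "dead_only"
ANY = "any"

_EPS = 1e-9


@dataclass
class Forager:
    """One wood-hauling household."""

    home: tuple[int, int]
    annual_demand: float  # truckloads per year
    adherence: float  # probability a trip is restricted to dead wood
    loads_acquired: float = 0.0
    distance_travelled_km: float = 0.0  # round-trip sum, this year

    def __post_init__(self) -> None:
        if not (0.0 <= self.adherence <= 1.0):
            raise ConfigError(
                f"adherence must lie in [0, 1], got {self.adherence}"
            )
        if self.annual_demand < 0:
            raise ConfigError("annual_demand must be >= 0")

    def reset_year(self) -> None:
        self.loads_acquired = 0.0
        self.distance_travelled_km = 0.0

    @property
    def met_demand(self) -> bool:
        return self.loads_acquired >= self.annual_demand - _EPS


@dataclass(frozen=True)
class HarvestParams:
    """Trip mechanics shared by all foragers.

    ``max_trips_per_year=None`` means four times the annual demand (rounded
    up), so partial loads can be made up: once nearby stock is reduced to
    the annual deadwood input, a typical trip returns well under a full
    load, and a tighter cap would ration households that ample supply could
    serve. ``min_stem_kg`` is the smallest
    stem counted as harvestable firewood; ``removal_threshold_kg`` is the
    residual below which a partially harvested stem is taken whole (so the
    biomass removed from the landscape always equals the load exactly).
    """

    load_kg: float = 1000.0
    max_radius_km: float = 120.0
    max_trips_per_year: int | None = None
    n_foragers: int = 25
    min_stem_kg: float = 50.0
    removal_threshold_kg: float = 50.0

    def __post_init__(self) -> None:
        if self.load_kg <= 0:
            raise ConfigError("load_kg must be positive")
        if self.max_radius_km <= 0:
            raise ConfigError("max_radius_km must be positive")
        if self.n_foragers < 0:
            raise ConfigError("n_foragers must be >= 0")

    def trips_cap(self, annual_demand: float) -> int:
        if self.max_trips_per_year is not None:
            cap = self.max_trips_per_year
        else:
            cap = math.ceil(4.0 * annual_demand)
        if cap < math.ceil(annual_demand):
            raise ConfigError(
                "max_trips_per_year must be at least ceil(annual_demand)"
            )
        return cap


@dataclass
class AnnualHarvestStats:
    """One simulated year's harvest outcomes, aggregated over foragers."""

    prop_meeting_need: float
    mean_distance_km: float
    live_trees_harvested: int
    dead_trees_harvested: int
    biomass_removed_kg: dict = field(default_factory=dict)  # (species, status) -> kg
    n_trips: int = 0

    @property
    def total_biomass_removed_kg(self) -> float:
        return float(sum(self.biomass_removed_kg.values()))


def trip_status_rule(forager: Forager, rng: np.random.Generator) -> str:
    """Draw the status restriction for one trip.

    ``dead_only`` with probability ``adherence``, else ``any``. Full
    adherence (1.0) therefore never permits live harvest; zero adherence
    never restricts.
    """
    if forager.adherence >= 1.0:
        return DEAD_ONLY
    if forager.adherence <= 0.0:
        return ANY
    return DEAD_ONLY if rng.random() < forager.adherence else ANY


class NearestPatchIndex:
    """Cells within range of one home, grouped by increasing distance.

    Queries scan distance groups outward and pick uniformly among the
    qualifying cells of the nearest non-empty group. The caller may pass
    back the returned group index as ``start_group`` on later queries in
    the same harvest season (stocks only shrink within a season), which
    makes the amortised scan cost per season linear in the cell count.
    """

    def __init__(self, grid: GridSpec, home: tuple[int, int], max_radius_km: float):
        d = grid.distances_from(home)
        within = np.flatnonzero(d <= max_radius_km + _EPS)
        order = within[np.argsort(d[within], kind="stable")]
        dsort = d[order]
        breaks = np.flatnonzero(np.diff(dsort) > 1e-9) + 1
        self.order = order
        self.starts = np.concatenate(([0], breaks, [order.size]))
        self.group_distance = dsort[self.starts[:-1]] if order.size else np.empty(0)
        self.n_groups = self.starts.size - 1

    def query(
        self, stock: np.ndarray, rng: np.random.Generator, start_group: int = 0
    ) -> tuple[int | None, int, float]:
        """Nearest stocked cell; returns (cell, group index, distance km)."""
        for g in range(start_group, self.n_groups):
            cells = self.order[self.starts[g]: self.starts[g + 1]]
            avail = cells[stock[cells] > _EPS]
            if avail.size == 1:
                return int(avail[0]), g, float(self.group_distance[g])
            if avail.size > 1:
                pick = avail[rng.integers(avail.size)]
                return int(pick), g, float(self.group_distance[g])
        return None, self.n_groups, float("nan")


def select_patch(
    forager: Forager,
    landscape: Landscape,
    allowed_status: str,
    params: HarvestParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, int] | None:
    """The nearest in-range patch with harvestable wood of the allowed status.

    ``dead_only`` counts dead stems only; ``any`` counts dead plus live.
    Returns the patch's ``(x, y)`` or ``None`` when nothing qualifies
    within ``max_radius_km`` (a legal "failed trip" signal). Ties at equal
    distance are broken uniformly at random with the run RNG.
    """
    if allowed_status not in (DEAD_ONLY, ANY):
        raise ConfigError(f"allowed_status must be {DEAD_ONLY!r} or {ANY!r}")
    params = params or HarvestParams()
    rng = rng if rng is not None else np.random.default_rng()
    stock = landscape.biomass_by_cell("dead", params.min_stem_kg)
    if allowed_status == ANY:
        stock = stock + landscape.biomass_by_cell("live", params.min_stem_kg)
    index = NearestPatchIndex(landscape.grid, forager.home, params.max_radius_km)
    cell, _, _ = index.query(stock, rng)
    if cell is None:
        return None
    return landscape.grid.cell_xy(cell)


def _removal_order(trees, idx: np.ndarray, allowed_status: str, min_stem_kg: float):
    """Harvest order within a patch: dead oldest-first, then live smallest."""
    b = trees.biomass[idx]
    harvestable = b >= max(min_stem_kg, _EPS)
    dead = idx[harvestable & ~trees.alive[idx]]
    dead = dead[np.argsort(-trees.age[dead], kind="stable")]
    if allowed_status == ANY:
        live = idx[harvestable & trees.alive[idx]]
        live = live[np.argsort(trees.biomass[live], kind="stable")]
        return np.concatenate([dead, live])
    return dead


def _take_from_patch(trees, order: np.ndarray, load_kg: float, threshold_kg: float):
    """Remove up to ``load_kg`` following ``order``; mutates tree biomass.

    Returns ``(taken_kg, removed_indices, touched_indices)``. When a
    partial harvest would leave a residual below ``threshold_kg`` the whole
    stem goes into the load, so the biomass removed from the landscape is
    exactly the load taken.
    """
    remaining = load_kg
    taken = 0.0
    removed: list[int] = []
    touched: list[int] = []
    for i in order:
        b = float(trees.biomass[i])
        take = min(remaining, b)
        if b - take < threshold_kg:
            take = b
        trees.biomass[i] = b - take
        touched.append(int(i))
        if trees.biomass[i] <= _EPS:
            removed.append(int(i))
        taken += take
        remaining -= take
        if remaining <= _EPS:
            break
    return taken, removed, touched


def harvest_trip(
    forager: Forager,
    landscape: Landscape,
    patch: tuple[int, int],
    allowed_status: str,
    params: HarvestParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Execute one truckload trip against ``patch``; returns kg taken.

    The patch must have been returned by :func:`select_patch` for this
    ``allowed_status``; issuing a trip against a patch with no harvestable
    wood of that status is a caller bug and raises
    :class:`HarvestContractError`. Fully harvested stems are deleted from
    the landscape; the forager's distance (round trip) and load accounts
    are updated.
    """
    grid = landscape.grid
    cell = grid.cell_id(*patch)
    trees = landscape.trees
    idx = np.flatnonzero(trees.cell == cell)
    order = _removal_order(trees, idx, allowed_status, params.min_stem_kg)
    if order.size == 0:
        raise HarvestContractError(
            f"patch {patch} has no harvestable {allowed_status} wood"
        )
    taken, removed, _ = _take_from_patch(
        trees, order, params.load_kg, params.removal_threshold_kg
    )
    if removed:
        keep = np.ones(len(trees), bool)
        keep[removed] = False
        landscape.trees = trees.select(keep)
    forager.distance_travelled_km += 2.0 * grid.distance_km(forager.home, patch)
    forager.loads_acquired += taken / params.load_kg
    return taken


def run_harvest_year(
    foragers: list[Forager],
    landscape: Landscape,
    params: HarvestParams,
    rng: np.random.Generator,
    trip_log: list | None = None,
    year: int | None = None,
) -> AnnualHarvestStats:
    """Simulate one harvest season and aggregate the outcomes.

    Foragers take turns in a shuffled round-robin, one trip per round; a
    forager leaves the rotation when its demand is met, a trip comes back
    empty, or its trip cap is hit. With no foragers the season is vacuous
    and ``prop_meeting_need`` is 1.0 by convention.

    When ``trip_log`` is a list, one dict per executed trip is appended
    (year, forager id, trip number, patch x/y, allowed status, kg taken,
    round-trip km) — the raw material for a delimited harvest log.
    """
    for f in foragers:
        f.reset_year()
    biomass_removed = {
        (sp, status): 0.0 for sp in SPECIES for status in ("live", "dead")
    }
    if not foragers:
        return AnnualHarvestStats(1.0, 0.0, 0, 0, biomass_removed, 0)

    grid = landscape.grid
    trees = landscape.trees
    dead_stock = landscape.biomass_by_cell("dead", params.min_stem_kg)
    any_stock = dead_stock + landscape.biomass_by_cell("live", params.min_stem_kg)

    # per-cell tree index (counting sort by cell)
    perm = np.argsort(trees.cell, kind="stable")
    counts = np.bincount(trees.cell, minlength=grid.n_cells)
    starts = np.concatenate(([0], np.cumsum(counts)))
    removed_mask = np.zeros(len(trees), bool)

    indexes: dict[tuple[int, int], NearestPatchIndex] = {}
    hints: dict[tuple[tuple[int, int], str], int] = {}
    live_count = 0
    dead_count = 0
    n_trips = 0

    forager_ids = {id(f): i for i, f in enumerate(foragers)}
    order = [foragers[i] for i in rng.permutation(len(foragers))]
    active = [
        (f, params.trips_cap(f.annual_demand))
        for f in order
        if not f.met_demand and params.trips_cap(f.annual_demand) > 0
    ]

    while active:
        next_round = []
        for f, trips_left in active:
            status = trip_status_rule(f, rng)
            kind = DEAD_ONLY if status == DEAD_ONLY else ANY
            stock = dead_stock if kind == DEAD_ONLY else any_stock
            if f.home not in indexes:
                indexes[f.home] = NearestPatchIndex(
                    grid, f.home, params.max_radius_km
                )
            hint_key = (f.home, kind)
            cell, g, dist = indexes[f.home].query(
                stock, rng, hints.get(hint_key, 0)
            )
            hints[hint_key] = g
            if cell is None:
                continue  # failed trip: forager is done for the year
            idx = perm[starts[cell]: starts[cell + 1]]
            idx = idx[~removed_mask[idx]]
            tree_order = _removal_order(trees, idx, status, params.min_stem_kg)
            if tree_order.size == 0:  # stock array said otherwise: caller bug
                raise HarvestContractError(
                    f"inconsistent stock bookkeeping at cell {cell}"
                )
            pre_alive = trees.alive[tree_order].copy()
            pre_biomass = trees.biomass[tree_order].copy()
            taken, removed, touched = _take_from_patch(
                trees, tree_order, params.load_kg, params.removal_threshold_kg
            )
            removed_mask[removed] = True
            n_trips += 1
            # per-(species, status) tallies and stock bookkeeping
            for pos, i in enumerate(tree_order[: len(touched)]):
                got = pre_biomass[pos] - float(trees.biomass[i])
                if got <= 0:
                    continue
                sp = SPECIES[trees.species[i]]
                if pre_alive[pos]:
                    st = "live"
                    live_count += 1
                else:
                    st = "dead"
                    dead_count += 1
                biomass_removed[(sp, st)] += got
                # a residual below min_stem_kg leaves the harvestable pool
                post = float(trees.biomass[i])
                pool_red = got if post >= params.min_stem_kg else got + post
                if st == "dead":
                    dead_stock[cell] = max(0.0, dead_stock[cell] - pool_red)
                any_stock[cell] = max(0.0, any_stock[cell] - pool_red)
            f.distance_travelled_km += 2.0 * dist
            f.loads_acquired += taken / params.load_kg
            trips_left -= 1
            if trip_log is not None:
                x, y = grid.cell_xy(cell)
                trip_log.append(
                    {
                        "year": year,
                        "forager": forager_ids[id(f)],
                        "trip": params.trips_cap(f.annual_demand) - trips_left,
                        "x": x,
                        "y": y,
                        "status": status,
                        "kg": taken,
                        "km": 2.0 * dist,
                    }
                )
            if not f.met_demand and trips_left > 0:
                next_round.append((f, trips_left))
        active = next_round

    if removed_mask.any():
        landscape.trees = trees.select(~removed_mask)

    prop = float(np.mean([f.met_demand for f in foragers]))
    mean_dist = float(np.mean([f.distance_travelled_km for f in foragers]))
    return AnnualHarvestStats(
        prop_meeting_need=prop,
        mean_distance_km=mean_dist,
        live_trees_harvested=live_count,
        dead_trees_harvested=dead_count,
        biomass_removed_kg=biomass_removed,
        n_trips=n_trips,
    )
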
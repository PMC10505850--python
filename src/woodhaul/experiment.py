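"""Factorial scenario experiment: IEK adherence x demand x climate supply.

The experiment crosses three levels of adherence to the dead-wood-only rule
(full, partial, none), three household demand levels (low, current, high
relative to the seven-truckload baseline) and three climate-driven supply
scenarios (stable, low emissions, high emissions) — 27 cells, each run with
seeded replicates. One run is: generate a landscape, spin it up to
quasi-equilibrium under neutral climate with no harvest, then step through
the 2020-2100 calendar applying demography followed by the harvest season,
recording the response variables each year.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import SimulationConfig, default_config
from .demography import stationary_density, spin_up, step_demography
from .errors import ConfigError, EquilibriumWarning, ExperimentError
from .forcing import ClimateForcing, calibrate_forcing, stable_forcing
from .harvest import Forager, run_harvest_year
from .landscape import SPECIES, Landscape, generate_suitability, populate_woodland

IEK_LEVELS = ("full", "partial", "none")
DEMAND_LEVELS = ("low", "current", "high")
SUPPLY_LEVELS = ("stable", "low_emissions", "high_emissions")

#: Fixed output schema of the experiment table.
RECORD_COLUMNS = [
    "iek",
    "demand",
    "supply",
    "replicate",
    "year",
    "prop_meeting_need",
    "mean_distance",
    "pinyon_biomass",
    "juniper_biomass",
    "pinyon_mean_age",
    "juniper_mean_age",
    "live_trees_harvested",
    "dead_trees_harvested",
]


@dataclass(frozen=True)
class ScenarioCell:
    """One cell of the 3 x 3 x 3 factorial grid."""

    iek: str
    demand: str
    supply: str

    def __post_init__(self) -> None:
        if self.iek not in IEK_LEVELS:
            raise ConfigError(f"unknown IEK level {self.iek!r}")
        if self.demand not in DEMAND_LEVELS:
            raise ConfigError(f"unknown demand level {self.demand!r}")
        if self.supply not in SUPPLY_LEVELS:
            raise ConfigError(f"unknown supply level {self.supply!r}")

    def label(self) -> str:
        return f"{self.iek}/{self.demand}/{self.supply}"


def full_grid() -> list[ScenarioCell]:
    """All 27 scenario cells in fixed (iek, demand, supply) order."""
    return [
        ScenarioCell(i, d, s)
        for i, d, s in itertools.product(IEK_LEVELS, DEMAND_LEVELS, SUPPLY_LEVELS)
    ]


@dataclass(frozen=True)
class AnnualRecord:
    """One simulated year's response variables for one run."""

    cell: ScenarioCell
    replicate: int
    year: int
    prop_meeting_need: float
    mean_distance: float
    pinyon_biomass: float
    juniper_biomass: float
    pinyon_mean_age: float
    juniper_mean_age: float
    live_trees_harvested: int
    dead_trees_harvested: int

    def to_row(self) -> list:
        return [
            self.cell.iek,
            self.cell.demand,
            self.cell.supply,
            self.replicate,
            self.year,
            self.prop_meeting_need,
            self.mean_distance,
            self.pinyon_biomass,
            self.juniper_biomass,
            self.pinyon_mean_age,
            self.juniper_mean_age,
            self.live_trees_harvested,
            self.dead_trees_harvested,
        ]


def replicate_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-run seed derived from the experiment base seed."""
    ss = np.random.SeedSequence((int(base_seed), int(cell_index), int(replicate)))
    return int(ss.generate_state(1)[0])


def get_forcing(
    supply: str, config: SimulationConfig, cache: dict | None = None
) -> ClimateForcing:
    """Calibrated forcing for a supply scenario, optionally memoised."""
    if cache is not None and supply in cache:
        return cache[supply]
    cal = config.calendar
    if supply == "stable":
        f = stable_forcing(cal.start_year, cal.horizon_year)
    else:
        f = calibrate_forcing(
            supply,
            config.demography,
            start_year=cal.start_year,
            horizon_year=cal.horizon_year,
            spin_up_years=cal.spin_up_years,
            dead_fraction=config.landscape.dead_fraction,
            density=config.landscape.density,
            targets=config.forcing.targets,
            rel_tol=config.forcing.rel_tol,
        )
    if cache is not None:
        cache[supply] = f
    return f


def _build_landscape(config: SimulationConfig, suit_seed: int, pop_seed: int) -> Landscape:
    suit = generate_suitability(
        config.grid, config.landscape.correlation_length_km, suit_seed
    )
    density = config.landscape.density or stationary_density(config.demography)
    return populate_woodland(
        config.grid,
        suit,
        density,
        pop_seed,
        demography=config.demography,
        dead_fraction=config.landscape.dead_fraction,
        age_init=config.landscape.age_init,
        age_init_mean=config.landscape.age_init_mean,
        max_per_cell=config.landscape.max_per_cell,
    )


def run_simulation(
    cell: ScenarioCell,
    replicate_seed: int,
    config: SimulationConfig | None = None,
    forcing: ClimateForcing | None = None,
    replicate: int = 0,
) -> list[AnnualRecord]:
    """One seeded scenario run; fully deterministic given its arguments.

    Independent RNG streams are spawned for the suitability field, the
    initial stocking, the demography and the harvest season, so e.g. a
    zero-forager run reproduces the pure-demography trajectory of the same
    seed record-for-record.
    """
    config = config or default_config()
    ss = np.random.SeedSequence(int(replicate_seed))
    suit_ss, pop_ss, demog_ss, harv_ss = ss.spawn(4)
    landscape = _build_landscape(
        config,
        int(suit_ss.generate_state(1)[0]),
        int(pop_ss.generate_state(1)[0]),
    )
    demog_rng = np.random.default_rng(demog_ss)
    harvest_rng = np.random.default_rng(harv_ss)

    with warnings.catch_warnings():
        # short settling spin-ups from the stationary start are intentional
        warnings.simplefilter("ignore", EquilibriumWarning)
        spin_up(landscape, config.demography, config.calendar.spin_up_years, demog_rng)

    if forcing is None:
        forcing = get_forcing(cell.supply, config)

    adherence = config.levels.iek[cell.iek]
    demand = config.levels.baseline_demand_loads * config.levels.demand[cell.demand]
    foragers = [
        Forager(home=cp, annual_demand=demand, adherence=adherence)
        for cp in config.grid.central_places
        for _ in range(config.harvest.n_foragers)
    ]

    records: list[AnnualRecord] = []
    for year in config.calendar.years:
        step_demography(landscape, config.demography, forcing, year, demog_rng)
        stats = run_harvest_year(foragers, landscape, config.harvest, harvest_rng)
        records.append(
            AnnualRecord(
                cell=cell,
                replicate=replicate,
                year=year,
                prop_meeting_need=stats.prop_meeting_need,
                mean_distance=stats.mean_distance_km,
                pinyon_biomass=landscape.live_biomass_kg("pinyon"),
                juniper_biomass=landscape.live_biomass_kg("juniper"),
                pinyon_mean_age=landscape.mean_live_age("pinyon"),
                juniper_mean_age=landscape.mean_live_age("juniper"),
                live_trees_harvested=stats.live_trees_harvested,
                dead_trees_harvested=stats.dead_trees_harvested,
            )
        )
    return records


def run_experiment(
    cells: list[ScenarioCell] | None = None,
    replicates: int = 10,
    base_seed: int = 0,
    config: SimulationConfig | None = None,
    out_dir=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every cell x replicate and assemble the experiment table.

    Replicate seeds derive deterministically from ``base_seed``, the cell
    index and the replicate number, so two invocations with the same
    arguments produce byte-identical output files. When ``out_dir`` is
    given, writes ``experiment.csv`` plus a ``metadata.json`` sidecar
    (config hash, seeds, version).
    """
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    config = config or default_config()
    cells = list(cells) if cells is not None else full_grid()

    forcing_cache: dict[str, ClimateForcing] = {}
    seeds_used: dict[str, int] = {}
    rows = []
    for ci, cell in enumerate(cells):
        forcing = get_forcing(cell.supply, config, forcing_cache)
        for rep in range(replicates):
            seed = replicate_seed(base_seed, ci, rep)
            seeds_used[f"{cell.label()}#{rep}"] = seed
            try:
                recs = run_simulation(
                    cell, seed, config, forcing=forcing, replicate=rep
                )
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise ExperimentError(
                    f"run failed for cell {cell.label()} replicate {rep}"
                ) from exc
            rows.extend(r.to_row() for r in recs)
            if progress:
                print(f"done {cell.label()} replicate {rep}", flush=True)
    if len(set(seeds_used.values())) != len(seeds_used):
        raise ExperimentError("replicate seed collision; change base_seed")

    table = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "experiment.csv", index=False)
        meta = {
            "version": _version,
            "base_seed": int(base_seed),
            "replicates": int(replicates),
            "n_cells": len(cells),
            "config_hash": config.config_hash(),
            "seeds": seeds_used,
        }
        (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return table
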
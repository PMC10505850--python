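"""Synthetic pinyon-juniper woodland landscapes.

The simulated arena is a regular grid of square patches. Each patch carries a
suitability value in [0, 1] that scales both the initial stocking and the
annual recruitment of the two harvested taxa (pinyon, juniper). Households
live at one or more *central places* (grid cells) from which all harvest
trips depart and to which they return.

Everything here is seeded: the same :class:`GridSpec`, parameters and seed
always reproduce the same landscape, byte-for-byte in serialised form.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import ConfigError

#: The two harvested taxa, in fixed code order (0 = pinyon, 1 = juniper).
SPECIES = ("pinyon", "juniper")

#: Tree status labels used in serialised tables.
STATUS = ("live", "dead")

_EPS = 1e-12


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the simulation arena.

    Parameters
    ----------
    nx, ny:
        Cell counts along x and y. Must be at least 1.
    cell_km:
        Edge length of a (square) cell in km.
    central_places:
        One or more ``(x, y)`` cell coordinates where households live.
        Distances are measured between cell centres (straight-line, km).
    """

    nx: int
    ny: int
    cell_km: float
    central_places: tuple[tuple[int, int], ...] = ((0, 0),)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ConfigError(f"grid dimensions must be >= 1, got {self.nx}x{self.ny}")
        if self.cell_km <= 0:
            raise ConfigError(f"cell_km must be positive, got {self.cell_km}")
        cps = tuple((int(x), int(y)) for x, y in self.central_places)
        if not cps:
            raise ConfigError("at least one central place is required")
        for x, y in cps:
            if not (0 <= x < self.nx and 0 <= y < self.ny):
                raise ConfigError(f"central place ({x}, {y}) lies outside the grid")
        object.__setattr__(self, "central_places", cps)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_id(self, x: int, y: int) -> int:
        """Flatten ``(x, y)`` to a scalar cell index (row-major in x)."""
        return int(x) * self.ny + int(y)

    def cell_xy(self, cell: int) -> tuple[int, int]:
        return divmod(int(cell), self.ny)

    def distance_km(self, a: tuple[int, int], b: tuple[int, int]) -> float:
        """Euclidean distance between two cell centres, in km."""
        return float(np.hypot(a[0] - b[0], a[1] - b[1]) * self.cell_km)

    def distances_from(self, origin: tuple[int, int]) -> np.ndarray:
        """Distances (km) from ``origin``'s centre to every cell centre."""
        xs, ys = np.meshgrid(
            np.arange(self.nx), np.arange(self.ny), indexing="ij"
        )
        return (np.hypot(xs - origin[0], ys - origin[1]) * self.cell_km).ravel()


@dataclass(frozen=True)
class SuitabilityField:
    """A per-cell habitat suitability surface in [0, 1].

    ``values`` has shape ``(nx, ny)``. The field is fully determined by the
    grid, the correlation length and the seed, so serialising the three
    scalars is enough to reproduce it exactly.
    """

    values: np.ndarray
    correlation_length_km: float
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.min() < -_EPS or v.max() > 1 + _EPS:
            raise ConfigError("suitability values must lie in [0, 1]")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()


def generate_suitability(
    grid: GridSpec, correlation_length_km: float, seed: int
) -> SuitabilityField:
    """Generate a patchy suitability surface.

    White Gaussian noise is convolved with an isotropic Gaussian kernel whose
    scale is set so that the autocorrelation of the smoothed field decays by
    a factor *e* at roughly ``correlation_length_km``, then min-max rescaled
    to [0, 1]. ``correlation_length_km = 0`` yields independent cells.
    """
    if correlation_length_km < 0:
        raise ConfigError("correlation_length_km must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((grid.nx, grid.ny))
    if correlation_length_km > 0:
        # Gaussian kernel sigma (cells): autocorr of the smoothed field is
        # exp(-d^2 / (4 sigma^2)), so the e-folding distance is 2 sigma.
        sigma = correlation_length_km / (2.0 * grid.cell_km)
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    lo, hi = float(noise.min()), float(noise.max())
    if hi - lo < 1e-12:  # degenerate (e.g. 1x1 grid): flat mid-scale field
        values = np.full_like(noise, 0.5)
    else:
        values = (noise - lo) / (hi - lo)
    return SuitabilityField(values, float(correlation_length_km), int(seed))


@dataclass
class TreeTable:
    """Column-oriented store of individual trees.

    One row per stem: species code (index into :data:`SPECIES`), age in
    years, biomass in kg dry wood, live/dead status and the flat cell index
    of the patch the stem occupies.
    """

    species: np.ndarray  # uint8 codes
    age: np.ndarray  # int32 years
    biomass: np.ndarray  # float64 kg
    alive: np.ndarray  # bool
    cell: np.ndarray  # int64 flat cell index

    @classmethod
    def empty(cls) -> "TreeTable":
        return cls(
            species=np.empty(0, np.uint8),
            age=np.empty(0, np.int32),
            biomass=np.empty(0, np.float64),
            alive=np.empty(0, bool),
            cell=np.empty(0, np.int64),
        )

    @classmethod
    def concat(cls, parts: list["TreeTable"]) -> "TreeTable":
        return cls(
            species=np.concatenate([p.species for p in parts]),
            age=np.concatenate([p.age for p in parts]),
            biomass=np.concatenate([p.biomass for p in parts]),
            alive=np.concatenate([p.alive for p in parts]),
            cell=np.concatenate([p.cell for p in parts]),
        )

    def select(self, mask: np.ndarray) -> "TreeTable":
        return TreeTable(
            species=self.species[mask],
            age=self.age[mask],
            biomass=self.biomass[mask],
            alive=self.alive[mask],
            cell=self.cell[mask],
        )

    def __len__(self) -> int:
        return self.species.size


@dataclass
class Landscape:
    """A gridded woodland: geometry, suitability and the stems on it."""

    grid: GridSpec
    suitability: SuitabilityField
    trees: TreeTable = field(default_factory=TreeTable.empty)

    def live_biomass_kg(self, species: str | None = None) -> float:
        """Total live biomass (kg), optionally for one species."""
        m = self.trees.alive
        if species is not None:
            m = m & (self.trees.species == SPECIES.index(species))
        return float(self.trees.biomass[m].sum())

    def mean_live_age(self, species: str) -> float:
        """Mean age of live trees of one species (NaN if none)."""
        m = self.trees.alive & (self.trees.species == SPECIES.index(species))
        if not m.any():
            return float("nan")
        return float(self.trees.age[m].mean())

    def biomass_by_cell(self, status: str, min_stem_kg: float = 0.0) -> np.ndarray:
        """Per-cell biomass (kg) of live or dead stems at least ``min_stem_kg``."""
        if status not in STATUS:
            raise ValueError(f"status must be one of {STATUS}")
        m = self.trees.alive if status == "live" else ~self.trees.alive
        if min_stem_kg > 0:
            m = m & (self.trees.biomass >= min_stem_kg)
        return np.bincount(
            self.trees.cell[m],
            weights=self.trees.biomass[m],
            minlength=self.grid.n_cells,
        )

    def counts_by_cell(self) -> np.ndarray:
        return np.bincount(self.trees.cell, minlength=self.grid.n_cells)


def populate_woodland(
    grid: GridSpec,
    suitability: SuitabilityField,
    density_params: dict[str, float],
    seed: int,
    demography=None,
    dead_fraction: float = 0.10,
    age_init: str = "stationary",
    age_init_mean: float = 80.0,
    max_per_cell: int | None = None,
) -> Landscape:
    """Stock a landscape with trees.

    Per cell and species, the stem count is Poisson with mean
    ``density × suitability``. Ages are drawn either from the demographic
    stationary age distribution implied by the background mortality
    (``age_init="stationary"``, the default, so short spin-ups suffice) or
    from a truncated exponential with mean ``age_init_mean``
    (``age_init="exponential"``). Initial biomass follows the growth curve at
    the drawn age, and a fraction ``dead_fraction`` of stems starts dead
    (standing deadwood) so that dead-wood-only harvest is feasible at t0.

    ``demography`` is a :class:`~woodhaul.demography.DemographyParams`; the
    package default is used when omitted.
    """
    from . import demography as _demog  # local import avoids a module cycle

    params = demography if demography is not None else _demog.DemographyParams()
    if not (0.0 <= dead_fraction <= 1.0):
        raise ConfigError("dead_fraction must lie in [0, 1]")
    if age_init not in ("stationary", "exponential"):
        raise ConfigError(f"unknown age_init {age_init!r}")

    rng = np.random.default_rng(seed)
    suit = suitability.flat
    remaining_cap = (
        None
        if max_per_cell is None
        else np.full(grid.n_cells, int(max_per_cell), dtype=np.int64)
    )
    parts: list[TreeTable] = []
    for si, sp in enumerate(SPECIES):
        dens = float(density_params[sp])
        if dens < 0:
            raise ConfigError(f"density for {sp} must be >= 0")
        counts = rng.poisson(dens * suit)
        if remaining_cap is not None:
            counts = np.minimum(counts, remaining_cap)
            remaining_cap -= counts
        cells = np.repeat(np.arange(grid.n_cells, dtype=np.int64), counts)
        n = cells.size
        sp_par = params.species(sp)
        if age_init == "stationary":
            probs = _demog.stationary_age_distribution(sp_par)
            ages = rng.choice(probs.size, size=n, p=probs).astype(np.int32)
        else:
            draw = rng.exponential(age_init_mean, size=n)
            ages = np.minimum(draw, sp_par.max_age - 1).astype(np.int32)
        biomass = _demog.biomass_at_age(sp, ages, params)
        alive = rng.random(n) >= dead_fraction
        parts.append(
            TreeTable(
                species=np.full(n, si, np.uint8),
                age=ages,
                biomass=np.asarray(biomass, dtype=np.float64),
                alive=alive,
                cell=cells,
            )
        )
    return Landscape(grid=grid, suitability=suitability, trees=TreeTable.concat(parts))


# ---------------------------------------------------------------------------
# Serialisation: '#'-prefixed YAML header describing the geometry and the
# suitability spec, followed by one CSV row per tree. Round-trips exactly.
# ---------------------------------------------------------------------------

def save_landscape(landscape: Landscape, path) -> None:
    header = {
        "nx": landscape.grid.nx,
        "ny": landscape.grid.ny,
        "cell_km": landscape.grid.cell_km,
        "central_places": [list(cp) for cp in landscape.grid.central_places],
        "suitability": {
            "correlation_length_km": landscape.suitability.correlation_length_km,
            "seed": landscape.suitability.seed,
        },
    }
    t = landscape.trees
    xy = np.array([landscape.grid.cell_xy(c) for c in t.cell], dtype=int).reshape(-1, 2)
    df = pd.DataFrame(
        {
            "species": [SPECIES[s] for s in t.species],
            "age": t.age,
            "biomass": t.biomass,
            "status": np.where(t.alive, "live", "dead"),
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    buf = io.StringIO()
    for line in yaml.safe_dump(header, sort_keys=True).splitlines():
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_landscape(path) -> Landscape:
    header_lines = []
    with open(path) as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("# "):
            header_lines.append(line[2:])
        else:
            body_lines.append(line)
    header = yaml.safe_load("\n".join(header_lines))
    grid = GridSpec(
        nx=header["nx"],
        ny=header["ny"],
        cell_km=header["cell_km"],
        central_places=tuple(tuple(cp) for cp in header["central_places"]),
    )
    suit = generate_suitability(
        grid,
        header["suitability"]["correlation_length_km"],
        header["suitability"]["seed"],
    )
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    trees = TreeTable(
        species=np.array([SPECIES.index(s) for s in df["species"]], np.uint8),
        age=df["age"].to_numpy(np.int32),
        biomass=df["biomass"].to_numpy(np.float64),
        alive=(df["status"] == "live").to_numpy(),
        cell=np.array(
            [grid.cell_id(x, y) for x, y in zip(df["x"], df["y"])], np.int64
        ),
    )
    if trees.cell.size and (
        trees.cell.min() < 0 or trees.cell.max() >= grid.n_cells
    ):
        raise ConfigError("serialised tree lies outside the grid")
    return Landscape(grid=grid, suitability=suit, trees=trees)
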
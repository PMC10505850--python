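"""Annual woodland demography: recruitment, growth, mortality, decay.

The woodland advances in one-year steps with a fixed sub-step order —
recruit, grow, kill, decay — so that runs are reproducible draw-for-draw:

1. *Recruitment*: per cell and species, a Poisson number of age-0 recruits
   with mean ``recruitment_rate × suitability × recruitment-multiplier``.
2. *Growth*: every live tree (including this year's recruits) ages one year
   and its biomass increases by the growth-curve increment for its new age,
   scaled by the climate growth multiplier. Growth is deterministic given
   the multiplier, which keeps the mean-field recursion exact.
3. *Mortality*: each live tree dies with probability
   ``background_mortality × mortality-multiplier``; trees reaching
   ``max_age`` die with certainty. Dead trees keep their current biomass
   and become standing deadwood.
4. *Decay*: each dead tree is removed from the landscape with probability
   ``deadwood_decay`` (fall-down and rot, i.e. wood lost to harvesters).

The growth curve is logistic in age:
``B(a) = max_biomass / (1 + exp(-growth_rate (a - inflection_age)))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, EquilibriumWarning
from .landscape import SPECIES, Landscape, TreeTable


@dataclass(frozen=True)
class SpeciesParams:
    """Demographic parameters for one taxon.

    Units: biomass kg dry wood, ages and rates per year; probabilities are
    annual. ``recruitment_rate`` is the expected number of recruits per cell
    per year at suitability 1.
    """

    max_biomass_kg: float = 500.0
    growth_rate: float = 0.06
    inflection_age: float = 60.0
    max_age: int = 400
    recruitment_rate: float = 3.2
    background_mortality: float = 0.01
    deadwood_decay: float = 0.04

    def __post_init__(self) -> None:
        if self.max_biomass_kg <= 0:
            raise ConfigError("max_biomass_kg must be positive")
        if self.growth_rate <= 0:
            raise ConfigError("growth_rate must be positive")
        if self.max_age < 1:
            raise ConfigError("max_age must be >= 1")
        if self.recruitment_rate < 0:
            raise ConfigError("recruitment_rate must be >= 0")
        for name in ("background_mortality", "deadwood_decay"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class DemographyParams:
    """Per-species demographic parameters (pinyon and juniper)."""

    pinyon: SpeciesParams = SpeciesParams(max_biomass_kg=500.0)
    juniper: SpeciesParams = SpeciesParams(max_biomass_kg=400.0)

    def species(self, name: str) -> SpeciesParams:
        return getattr(self, name)

    def arr(self, attr: str) -> np.ndarray:
        """Attribute values as an array indexed by species code."""
        return np.array([getattr(self.species(sp), attr) for sp in SPECIES])


def _logistic(max_biomass, growth_rate, inflection_age, age):
    age = np.asarray(age, dtype=float)
    return max_biomass / (1.0 + np.exp(-growth_rate * (age - inflection_age)))


class _StepTables:
    """Cached per-species vectors for the annual step (keyed on params)."""

    def __init__(self, params: "DemographyParams"):
        self.max_age = params.arr("max_age").astype(np.int64)
        self.mort = params.arr("background_mortality")
        self.decay = params.arr("deadwood_decay")
        self.recruit = params.arr("recruitment_rate")
        a_hi = int(self.max_age.max()) + 2
        self.curve = np.zeros((len(SPECIES), a_hi))
        for si, sp in enumerate(SPECIES):
            p = params.species(sp)
            self.curve[si] = _logistic(
                p.max_biomass_kg, p.growth_rate, p.inflection_age, np.arange(a_hi)
            )


_STEP_CACHE: dict = {}


def _tables(params: "DemographyParams") -> "_StepTables":
    tab = _STEP_CACHE.get(params)
    if tab is None:
        if len(_STEP_CACHE) > 32:
            _STEP_CACHE.clear()
        tab = _STEP_CACHE[params] = _StepTables(params)
    return tab


def biomass_at_age(species, age, params: DemographyParams):
    """Biomass (kg) on the growth curve at a given age.

    ``species`` is a name from :data:`~woodhaul.landscape.SPECIES` or an
    array of species codes; ``age`` may be scalar or array. Negative ages
    raise ``ValueError``.
    """
    if np.any(np.asarray(age) < 0):
        raise ValueError("age must be >= 0")
    if isinstance(species, str):
        p = params.species(species)
        out = _logistic(p.max_biomass_kg, p.growth_rate, p.inflection_age, age)
    else:
        code = np.asarray(species)
        out = _logistic(
            params.arr("max_biomass_kg")[code],
            params.arr("growth_rate")[code],
            params.arr("inflection_age")[code],
            age,
        )
    if np.isscalar(age) or np.asarray(age).ndim == 0:
        return float(out)
    return out


def stationary_age_distribution(p: SpeciesParams) -> np.ndarray:
    """Stationary live age distribution under background mortality.

    Probability mass proportional to survival ``(1 - m)^a`` over ages
    ``0 .. max_age - 1`` (trees die with certainty at ``max_age``).
    """
    ages = np.arange(p.max_age)
    w = (1.0 - p.background_mortality) ** ages
    return w / w.sum()


def stationary_density(params: DemographyParams) -> dict[str, float]:
    """Expected stationary stems per cell at suitability 1, per species.

    Recruitment rate times the expected stem lifetime under background
    mortality and the max-age cutoff. Used as the default initial stocking
    so that populated landscapes start near demographic equilibrium.
    """
    out = {}
    for sp in SPECIES:
        p = params.species(sp)
        lifetime = ((1.0 - p.background_mortality) ** np.arange(p.max_age)).sum()
        out[sp] = p.recruitment_rate * float(lifetime)
    return out


def step_demography(
    landscape: Landscape,
    params: DemographyParams,
    forcing,
    year: int,
    rng: np.random.Generator,
) -> Landscape:
    """Advance the woodland by one year, in place; returns the landscape.

    ``forcing`` is a :class:`~woodhaul.forcing.ClimateForcing` or ``None``
    (neutral). A stable forcing and ``None`` produce identical draws, so
    stable-scenario runs are tree-for-tree identical to unforced runs with
    the same seed.
    """
    if forcing is not None:
        g_mult, m_mult, r_mult = forcing.multipliers(year)
    else:
        g_mult, m_mult, r_mult = 1.0, 1.0, 1.0

    suit = landscape.suitability.flat
    n_cells = landscape.grid.n_cells
    tab = _tables(params)

    # 1. recruitment
    parts = [landscape.trees]
    for si, sp in enumerate(SPECIES):
        lam = tab.recruit[si] * r_mult * suit
        counts = rng.poisson(lam)
        cells = np.repeat(np.arange(n_cells, dtype=np.int64), counts)
        n = cells.size
        parts.append(
            TreeTable(
                species=np.full(n, si, np.uint8),
                age=np.zeros(n, np.int32),
                biomass=np.full(n, tab.curve[si, 0], np.float64),
                alive=np.ones(n, bool),
                cell=cells,
            )
        )
    t = TreeTable.concat(parts)

    # 2. growth (live trees only; dead wood neither ages nor grows)
    live = np.flatnonzero(t.alive)
    sp_live = t.species[live]
    old_age = t.age[live]
    new_age = old_age + 1
    delta = tab.curve[sp_live, new_age] - tab.curve[sp_live, old_age]
    t.age[live] = new_age
    t.biomass[live] += delta * g_mult

    # 3. mortality (background x climate, plus certain death at max_age)
    p_die = np.clip(tab.mort[sp_live] * m_mult, 0.0, 1.0)
    u = rng.random(live.size)
    dies = (u < p_die) | (new_age >= tab.max_age[sp_live])
    t.alive[live[dies]] = False

    # 4. deadwood decay
    dead = np.flatnonzero(~t.alive)
    u2 = rng.random(dead.size)
    decays = u2 < tab.decay[t.species[dead]]
    keep = np.ones(len(t), bool)
    keep[dead[decays]] = False
    landscape.trees = t.select(keep)
    return landscape


def spin_up(
    landscape: Landscape,
    params: DemographyParams,
    years: int,
    rng: np.random.Generator,
    trend_tol: float = 0.002,
    return_series: bool = False,
):
    """Run the woodland to quasi-equilibrium under neutral climate, no harvest.

    After ``years`` annual steps, the live-biomass series over the final 25%
    of the spin-up is checked for drift: if the absolute linear-trend slope
    exceeds ``trend_tol`` (fraction of the window mean per year) an
    :class:`~woodhaul.errors.EquilibriumWarning` is issued with diagnostics
    — a warning, not an error, because short exploratory spin-ups are legal.
    """
    if years < 0:
        raise ConfigError("spin-up years must be >= 0")
    series = np.empty(years, dtype=float)
    for i in range(years):
        step_demography(landscape, params, None, 0, rng)
        series[i] = landscape.trees.biomass[landscape.trees.alive].sum()
    window = series[-max(2, years // 4):] if years >= 2 else series
    if window.size >= 2 and window.mean() > 0:
        slope = np.polyfit(np.arange(window.size), window, 1)[0]
        rel = abs(slope) / window.mean()
        if rel > trend_tol:
            warnings.warn(
                f"spin-up trend {rel:.4%}/yr over final {window.size} years "
                f"exceeds {trend_tol:.2%}/yr (mean live biomass "
                f"{window.mean():.3e} kg)",
                EquilibriumWarning,
                stacklevel=2,
            )
    if return_series:
        return landscape, series
    return landscape
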
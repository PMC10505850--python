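"""Climate forcing: scenario schedules and their biomass-target calibration.

Climate stress enters the demography through three annual multipliers that
ramp linearly from neutral at the simulation start to full strength at the
horizon. With ramp ``r(year)`` rising 0 to 1 and intensity ``lambda``:

* growth multiplier      ``max(0, 1 - lambda r)``
* mortality multiplier   ``1 + lambda r``
* recruitment multiplier ``max(0, 1 - lambda r)``

A single intensity keeps calibration one-dimensional: ``lambda`` is found by
bisection on a deterministic mean-field reduction of the demography (an
expected-value recursion over the age distribution, no sampling noise) so
that no-harvest live biomass at the horizon equals ``1 - target_reduction``
times live biomass at the start year. The low- and high-emissions scenarios
target 13% and 21% end-of-century losses of live biomass respectively; the
stable scenario is exactly neutral (``lambda = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import DemographyParams, _logistic, stationary_density
from .errors import CalibrationError, ConfigError
from .landscape import SPECIES

SUPPLY_SCENARIOS = ("stable", "low_emissions", "high_emissions")

#: Default end-of-horizon live-biomass reduction targets per scenario.
DEFAULT_TARGETS = {"stable": 0.0, "low_emissions": 0.13, "high_emissions": 0.21}


@dataclass(frozen=True)
class ClimateForcing:
    """A calibrated annual schedule of demographic multipliers."""

    scenario: str
    target_reduction: float
    intensity: float  # the calibrated scalar lambda >= 0
    start_year: int
    horizon_year: int

    def __post_init__(self) -> None:
        if self.scenario not in SUPPLY_SCENARIOS:
            raise ConfigError(f"unknown supply scenario {self.scenario!r}")
        if not (0.0 <= self.target_reduction <= 1.0):
            raise ConfigError("target_reduction must lie in [0, 1]")
        if self.intensity < 0:
            raise ConfigError("forcing intensity must be >= 0")
        if self.scenario == "stable" and self.intensity != 0.0:
            raise ConfigError("stable scenario requires intensity 0")
        if self.horizon_year <= self.start_year:
            raise ConfigError("horizon_year must exceed start_year")

    def ramp(self, year: int) -> float:
        """Linear forcing ramp, clipped to [0, 1]."""
        r = (year - self.start_year) / (self.horizon_year - self.start_year)
        return float(np.clip(r, 0.0, 1.0))

    def multipliers(self, year: int) -> tuple[float, float, float]:
        """(growth, mortality, recruitment) multipliers for one year."""
        lr = self.intensity * self.ramp(year)
        return max(0.0, 1.0 - lr), 1.0 + lr, max(0.0, 1.0 - lr)

    def schedule(self) -> pd.DataFrame:
        """The full multiplier schedule as a table, for inspection/export."""
        years = np.arange(self.start_year, self.horizon_year + 1)
        rows = [self.multipliers(int(y)) for y in years]
        g, m, r = zip(*rows)
        return pd.DataFrame(
            {"year": years, "growth_mult": g, "mort_mult": m, "recruit_mult": r}
        )


def stable_forcing(start_year: int, horizon_year: int) -> ClimateForcing:
    return ClimateForcing("stable", 0.0, 0.0, start_year, horizon_year)


def _meanfield_series(
    params: DemographyParams,
    forcing: ClimateForcing | None,
    spin_up_years: int,
    start_year: int,
    horizon_year: int,
    dead_fraction: float,
    density: dict[str, float] | None = None,
) -> pd.Series:
    """Deterministic expected live biomass per year, start..horizon.

    Runs ``spin_up_years`` neutral steps from the stationary-age initial
    state, then the forced period, mirroring the stochastic simulator's
    sub-step order in expectation. Totals are per unit of summed landscape
    suitability; only ratios of the series are meaningful, which is all
    calibration needs.
    """
    from .demography import stationary_age_distribution

    dens = density if density is not None else stationary_density(params)
    states = []
    for sp in SPECIES:
        p = params.species(sp)
        a_max = p.max_age
        n = np.zeros(a_max + 1)
        n[:a_max] = dens[sp] * (1.0 - dead_fraction) * stationary_age_distribution(p)
        ages = np.arange(a_max + 1)
        curve = _logistic(p.max_biomass_kg, p.growth_rate, p.inflection_age, ages)
        b = curve.copy()
        delta = np.diff(curve)
        states.append({"p": p, "n": n, "b": b, "b0": curve[0], "delta": delta})

    def step(mults):
        g, m, r = mults
        for st in states:
            p = st["p"]
            n, b = st["n"], st["b"]
            # recruit at age 0, then every live cohort ages one year; the
            # recruits land at age 1 with biomass b0 + delta(1) * g, exactly
            # as in the stochastic sub-step order
            n[1:] = n[:-1]
            n[0] = 0.0
            b[1:] = b[:-1] + st["delta"] * g
            b[0] = st["b0"]
            n[1] += p.recruitment_rate * r
            # mortality: background x climate, plus certain death at max_age
            n *= 1.0 - min(1.0, p.background_mortality * m)
            n[p.max_age] = 0.0

    def total():
        return float(sum((st["n"] * st["b"]).sum() for st in states))

    for _ in range(spin_up_years):
        step((1.0, 1.0, 1.0))
    years = np.arange(start_year, horizon_year + 1)
    out = np.empty(years.size)
    for i, y in enumerate(years):
        mults = forcing.multipliers(int(y)) if forcing is not None else (1.0, 1.0, 1.0)
        step(mults)
        out[i] = total()
    return pd.Series(out, index=years, name="live_biomass")


def meanfield_live_biomass(
    params: DemographyParams,
    forcing: ClimateForcing | None,
    spin_up_years: int,
    start_year: int,
    horizon_year: int,
    dead_fraction: float = 0.10,
    density: dict[str, float] | None = None,
) -> pd.Series:
    """Public wrapper for the mean-field live-biomass recursion."""
    return _meanfield_series(
        params, forcing, spin_up_years, start_year, horizon_year,
        dead_fraction, density,
    )


def calibrate_forcing(
    scenario: str,
    params: DemographyParams,
    start_year: int = 2020,
    horizon_year: int = 2100,
    spin_up_years: int = 30,
    dead_fraction: float = 0.10,
    density: dict[str, float] | None = None,
    targets: dict[str, float] | None = None,
    rel_tol: float = 1e-3,
    max_intensity: float = 64.0,
) -> ClimateForcing:
    """Find the forcing intensity matching a scenario's biomass target.

    Bisection on the mean-field recursion: the returned intensity makes the
    no-harvest expected live biomass at ``horizon_year`` equal
    ``(1 - target) x`` the start-year value to relative tolerance
    ``rel_tol``. The stable scenario returns the neutral forcing
    immediately. If the target is unreachable even with growth and
    recruitment floored at zero, a :class:`CalibrationError` names it.
    """
    if scenario not in SUPPLY_SCENARIOS:
        raise ConfigError(f"unknown supply scenario {scenario!r}")
    tgt_map = dict(DEFAULT_TARGETS)
    if targets:
        tgt_map.update(targets)
    target = float(tgt_map[scenario])
    if not (0.0 <= target <= 1.0):
        raise ConfigError(f"target reduction {target} outside [0, 1]")
    if scenario == "stable" or target == 0.0:
        return stable_forcing(start_year, horizon_year)

    def reduction(lam: float) -> float:
        f = ClimateForcing(scenario, target, lam, start_year, horizon_year)
        s = _meanfield_series(
            params, f, spin_up_years, start_year, horizon_year,
            dead_fraction, density,
        )
        return 1.0 - s.loc[horizon_year] / s.loc[start_year]

    lo, hi = 0.0, 1.0
    while reduction(hi) < target:
        hi *= 2.0
        if hi > max_intensity:
            raise CalibrationError(
                f"target reduction {target:.3f} for scenario {scenario!r} is "
                f"unreachable with intensity <= {max_intensity}"
            )
    lam = hi
    for _ in range(100):
        lam = 0.5 * (lo + hi)
        red = reduction(lam)
        if abs(red - target) <= rel_tol * target:
            break
        if red < target:
            lo = lam
        else:
            hi = lam
    else:
        raise CalibrationError(
            f"bisection did not converge for scenario {scenario!r}"
        )
    return ClimateForcing(scenario, target, lam, start_year, horizon_year)
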
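"""Reduce experiment tables to per-cell summaries and qualitative checks.

The per-cell summary of a response is its *yearly mean over all runs*: the
grand mean over every (year, replicate) row of the cell — identical to the
mean of per-replicate means because the runner guarantees balanced panels.
The ordering checks encode the qualitative patterns a sound run of the
model is expected to show: meeting household need gets no easier as demand
rises, full adherence to the dead-wood rule leaves more live biomass than
no adherence, and ignoring the rule deforests outward from the central
place so travel distances lengthen through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ConfigError
from .experiment import DEMAND_LEVELS, IEK_LEVELS, SUPPLY_LEVELS, full_grid

FACTORS = ["iek", "demand", "supply"]

#: The six response variables of the experiment.
RESPONSES = [
    "prop_meeting_need",
    "mean_distance",
    "pinyon_biomass",
    "juniper_biomass",
    "pinyon_mean_age",
    "juniper_mean_age",
]


def _check_schema(table: pd.DataFrame) -> None:
    missing = [c for c in FACTORS + ["replicate", "year"] + RESPONSES
               if c not in table.columns]
    if missing:
        raise ValueError(f"experiment table is missing columns: {missing}")


def _missing_cells(table: pd.DataFrame) -> list[str]:
    have = set(map(tuple, table[FACTORS].drop_duplicates().to_numpy()))
    return [
        c.label()
        for c in full_grid()
        if (c.iek, c.demand, c.supply) not in have
    ]


def summarize_cells(
    table: pd.DataFrame, require_full_grid: bool = False
) -> pd.DataFrame:
    """Per-cell response means plus across-replicate standard deviations.

    Each response column gains a ``<name>_sd`` companion: the standard
    deviation, across replicates, of the per-replicate yearly means. With
    ``require_full_grid`` the call fails loudly when any of the 27 factor
    combinations is absent, listing the missing ones.
    """
    _check_schema(table)
    if require_full_grid:
        absent = _missing_cells(table)
        if absent:
            raise ValueError(f"experiment table is missing cells: {absent}")
    grand = table.groupby(FACTORS, sort=False)[RESPONSES].mean()
    per_rep = table.groupby(FACTORS + ["replicate"], sort=False)[RESPONSES].mean()
    sd = per_rep.groupby(FACTORS, sort=False).std(ddof=1)
    sd.columns = [f"{c}_sd" for c in sd.columns]
    return grand.join(sd).reset_index()


@dataclass
class OrderingReport:
    """Booleans for the qualitative response patterns, with diagnostics."""

    need_nonincreasing_in_demand: bool
    biomass_full_ge_none: bool
    need_full_ge_none: bool
    distance_increasing_without_iek: bool
    min_need_low_demand: float
    spearman_rho: float
    spearman_p: float
    violations: dict = field(default_factory=dict)

    @property
    def all_hold(self) -> bool:
        return (
            self.need_nonincreasing_in_demand
            and self.biomass_full_ge_none
            and self.need_full_ge_none
            and self.distance_increasing_without_iek
        )


def ordering_checks(
    table: pd.DataFrame, alpha: float = 0.05, atol: float = 1e-3
) -> OrderingReport:
    """Evaluate the qualitative orderings on a full 27-cell experiment.

    ``atol`` absorbs replicate-level jitter when two cells are effectively
    tied (e.g. both at a meeting-need proportion of ~1.0). Aborts rather
    than passing vacuously when the grid is incomplete.
    """
    _check_schema(table)
    absent = _missing_cells(table)
    if absent:
        raise ValueError(
            f"ordering checks need the full 27-cell grid; missing: {absent}"
        )
    summ = summarize_cells(table).set_index(FACTORS)
    violations: dict = {}

    # (a) meeting need is non-increasing in demand within each (iek, supply)
    a_ok = True
    for iek in IEK_LEVELS:
        for sup in SUPPLY_LEVELS:
            vals = [
                summ.loc[(iek, d, sup), "prop_meeting_need"] for d in DEMAND_LEVELS
            ]
            if any(vals[i + 1] > vals[i] + atol for i in range(len(vals) - 1)):
                a_ok = False
                violations.setdefault("need_vs_demand", []).append(
                    (iek, sup, [float(v) for v in vals])
                )

    # (b) live biomass: full adherence >= none, every (demand, supply)
    b_ok = True
    for d in DEMAND_LEVELS:
        for sup in SUPPLY_LEVELS:
            total = {
                iek: summ.loc[(iek, d, sup), "pinyon_biomass"]
                + summ.loc[(iek, d, sup), "juniper_biomass"]
                for iek in ("full", "none")
            }
            if total["full"] < total["none"] * (1 - 1e-6):
                b_ok = False
                violations.setdefault("biomass_full_vs_none", []).append(
                    (d, sup, {k: float(v) for k, v in total.items()})
                )

    # (c) meeting need: full adherence >= none, every (demand, supply)
    c_ok = True
    for d in DEMAND_LEVELS:
        for sup in SUPPLY_LEVELS:
            pf = summ.loc[("full", d, sup), "prop_meeting_need"]
            pn = summ.loc[("none", d, sup), "prop_meeting_need"]
            if pf < pn - atol:
                c_ok = False
                violations.setdefault("need_full_vs_none", []).append(
                    (d, sup, float(pf), float(pn))
                )

    # (d) without the dead-wood rule, travel distance rises through time
    sub = table[table["iek"] == "none"]
    yearly = sub.groupby("year")["mean_distance"].mean()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # constant series yields NaN rho
        rho, p = sstats.spearmanr(yearly.index.to_numpy(), yearly.to_numpy())
    d_ok = bool(np.isfinite(rho) and rho > 0 and p < alpha)

    low = summ.xs("low", level="demand")["prop_meeting_need"]
    return OrderingReport(
        need_nonincreasing_in_demand=a_ok,
        biomass_full_ge_none=b_ok,
        need_full_ge_none=c_ok,
        distance_increasing_without_iek=d_ok,
        min_need_low_demand=float(low.min()),
        spearman_rho=float(rho),
        spearman_p=float(p),
        violations=violations,
    )


def plot_response_grid(
    summaries: pd.DataFrame, response_name: str, output_path
) -> dict:
    """Write a three-panel response grid and return its value mapping.

    One panel per IEK level; demand varies on the x-axis, supply on the
    y-axis, and cell values are colour-encoded on a shared scale normalised
    over the whole response. Returns metadata including the colour-scale
    limits and each cell's normalised value, so the mapping can be audited
    without re-reading the image.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if response_name not in RESPONSES:
        raise ConfigError(
            f"unknown response {response_name!r}; valid: {RESPONSES}"
        )
    for col in FACTORS + [response_name]:
        if col not in summaries.columns:
            raise ValueError(f"summaries table is missing column {col!r}")

    s = summaries.set_index(FACTORS)[response_name]
    vmin, vmax = float(s.min()), float(s.max())
    span = vmax - vmin
    degenerate = span <= 0

    fig, axes = plt.subplots(1, len(IEK_LEVELS), figsize=(11, 3.6), sharey=True)
    normalized: dict = {}
    for ax, iek in zip(np.atleast_1d(axes), IEK_LEVELS):
        img = np.full((len(SUPPLY_LEVELS), len(DEMAND_LEVELS)), np.nan)
        for yi, sup in enumerate(SUPPLY_LEVELS):
            for xi, d in enumerate(DEMAND_LEVELS):
                v = float(s.loc[(iek, d, sup)])
                img[yi, xi] = v
                normalized[(iek, d, sup)] = (
                    0.5 if degenerate else (v - vmin) / span
                )
        im = ax.imshow(
            img,
            origin="lower",
            vmin=vmin - 0.5 if degenerate else vmin,
            vmax=vmax + 0.5 if degenerate else vmax,
            cmap="viridis",
            aspect="auto",
        )
        ax.set_xticks(range(len(DEMAND_LEVELS)), DEMAND_LEVELS)
        ax.set_yticks(range(len(SUPPLY_LEVELS)), SUPPLY_LEVELS)
        ax.set_xlabel("demand")
        ax.set_title(f"IEK: {iek}")
    np.atleast_1d(axes)[0].set_ylabel("supply")
    fig.colorbar(im, ax=list(np.atleast_1d(axes)), label=response_name)
    fig.suptitle(response_name)
    fig.savefig(output_path, dpi=120)
    plt.close(fig)
    return {
        "path": str(output_path),
        "response": response_name,
        "vmin": vmin,
        "vmax": vmax,
        "normalized": normalized,
    }
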
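"""Generate and inspect a synthetic pinyon-juniper woodland.

Builds the default desk-scale arena (21 x 21 cells of 8 km, one community
at the centre), stocks it at the demographic stationary density, and prints
basic stand structure. The suitability field is spatially autocorrelated
Gaussian noise rescaled to [0, 1]; stocking tracks it proportionally.
"""

import numpy as np

import woodhaul as wh

cfg = wh.default_config()
suit = wh.generate_suitability(cfg.grid, cfg.landscape.correlation_length_km, seed=7)
density = wh.stationary_density(cfg.demography)
ls = wh.populate_woodland(cfg.grid, suit, density, seed=7)

print(f"arena: {cfg.grid.nx} x {cfg.grid.ny} cells of {cfg.grid.cell_km} km")
print(f"stationary density (stems/cell at suitability 1): "
      f"{ {k: round(v, 1) for k, v in density.items()} }")
print(f"stems: {len(ls.trees):,} "
      f"({ls.trees.alive.sum():,} live, {(~ls.trees.alive).sum():,} dead)")
for sp in wh.SPECIES:
    print(f"  {sp}: live biomass {ls.live_biomass_kg(sp) / 1e6:.1f} kt, "
          f"mean live age {ls.mean_live_age(sp):.0f} yr")
dead = ls.biomass_by_cell("dead")
print(f"standing deadwood: {dead.sum() / 1e6:.1f} kt "
      f"(median {np.median(dead) / 1e3:.1f} t/cell) — the stock the "
      f"dead-wood-only harvest rule draws on")
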
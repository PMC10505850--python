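"""Render response-grid figures from an experiment table.

Loads (or, if absent, generates) an experiment table and writes one
three-panel figure per response variable: panels by IEK adherence, demand
on the x-axis, supply scenario on the y-axis, cell values colour-encoded.
"""

from pathlib import Path

import pandas as pd

import woodhaul as wh

table_path = Path("scratch/example_experiment/experiment.csv")
if table_path.exists():
    table = pd.read_csv(table_path)
else:
    table = wh.run_experiment(wh.full_grid(), replicates=3, base_seed=1)

summaries = wh.summarize_cells(table)
outdir = Path("scratch/figures")
outdir.mkdir(parents=True, exist_ok=True)
for response in wh.RESPONSES:
    meta = wh.plot_response_grid(summaries, response, outdir / f"{response}.png")
    print(f"{response}: scale {meta['vmin']:.3g} .. {meta['vmax']:.3g} "
          f"-> {meta['path']}")
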
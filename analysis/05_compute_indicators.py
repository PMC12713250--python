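"""Assemble the 12-indicator village table.

Active mobility: travel time to the local facility, facility capacity
factor score, cross-county healthcare-seeking flag.  Passive mobility:
population, village classification, age structure, ethnic composition,
road distance, bus frequency, elevation, slope and the cohesion index.
"""

from pathlib import Path

import pandas as pd

from _common import OUTDIR, get_config
from edgevillages.indicators import ACTIVE_INDICATORS, PASSIVE_INDICATORS
from edgevillages.pipeline import run_pipeline

run_pipeline(get_config("indicators"))

table = pd.read_csv(Path(OUTDIR) / "indicators.csv").set_index("village_id")
cols = list(ACTIVE_INDICATORS + PASSIVE_INDICATORS)
print(f"indicator table: {len(table)} villages x {len(cols)} indicators")
print(table[cols].describe().loc[["mean", "std"]].T.round(4).to_string())
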
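"""Simulate the synthetic county and its OD healthcare-seeking records.

Generates ~70 villages in 7 townships with facility, terrain, transport
and building-patch attributes, plus 4,314 respondent-level OD records
drawn from the known logit choice process, and writes villages.csv,
facilities.csv, od_records.csv, travel_times.csv, patches.geojson and
truth.json.
"""

import json
from pathlib import Path

import pandas as pd

from _common import OUTDIR, get_config
from edgevillages.pipeline import run_pipeline

run_pipeline(get_config("generate"))

villages = pd.read_csv(Path(OUTDIR) / "villages.csv")
facilities = pd.read_csv(Path(OUTDIR) / "facilities.csv")
od = pd.read_csv(Path(OUTDIR) / "od_records.csv")
truth = json.loads((Path(OUTDIR) / "truth.json").read_text())

print(f"county: {villages['township_id'].nunique()} townships, "
      f"{len(villages)} villages, {len(facilities)} facilities "
      f"({(~facilities['in_county']).sum()} outside the county)")
print(f"population total {villages['population'].sum():,}; "
      f"OD records simulated: {len(od):,}")
print(f"super-HSA anchor facility: {truth['anchor_facility']}")
n_edge = sum(truth["is_edge"].values())
print(f"ground truth: {n_edge} edge villages under the exact choice "
      "probabilities")
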
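"""Delineate HSAs, post-process unassigned villages, classify edge villages.

Communities become HSAs; sparse villages are re-attached by the
majority-flow rule; villages whose HSA differs from their administrative
township's and whose outflow mostly crosses the border are flagged as
edge villages with their main outflow destination.
"""

from pathlib import Path

import pandas as pd

from _common import OUTDIR, get_config
from edgevillages.pipeline import run_pipeline

run_pipeline(get_config("identify"))

hsa = pd.read_csv(Path(OUTDIR) / "hsa_summary.csv")
edge = pd.read_csv(Path(OUTDIR) / "edge_villages.csv")
flagged = edge[edge["is_edge"]]

print(f"HSAs delineated: {len(hsa)}")
super_row = hsa[hsa["is_super_hsa"]].iloc[0]
print(f"super-HSA: #{super_row['hsa_id']} with population "
      f"{super_row['population']:,}")
print(f"edge villages: {len(flagged)} of {len(edge)}")
print(flagged[["village_id", "township_id", "main_outflow_destination",
               "outflow_share"]].to_string(index=False))
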
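"""Aggregate OD records into the weighted healthcare-seeking graph.

Maps destinations to their townships, applies the fewer-than-10-records
exclusion rule, row-normalizes flows into outflow proportions and writes
the NCOL edge list.
"""

from pathlib import Path

import pandas as pd

from _common import OUTDIR, get_config
from edgevillages.flows import read_ncol
from edgevillages.pipeline import run_pipeline

manifest = run_pipeline(get_config("network"))

excluded = pd.read_csv(Path(OUTDIR) / "excluded_origins.csv")
graph = read_ncol(Path(OUTDIR) / "flow_graph.ncol")
print(f"flow graph: {graph.number_of_nodes()} nodes, "
      f"{graph.number_of_edges()} weighted edges")
print(f"origins excluded by the <10-records rule: {len(excluded)}")
for _, row in excluded.iterrows():
    print(f"  {row['origin']}: {row['reason']}")
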
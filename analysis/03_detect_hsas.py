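"""Louvain community detection on the patient-flow graph.

Each aggregation level's partition and modularity is recorded; the final
partition defines the preliminary hospital service areas.
"""

import json
from pathlib import Path

from _common import OUTDIR, get_config
from edgevillages.pipeline import run_pipeline

manifest = run_pipeline(get_config("detect"))

part = json.loads((Path(OUTDIR) / "partition.json").read_text())
for lv in part["levels"]:
    print(f"level {lv['level']}: {lv['n_communities']} communities, "
          f"modularity {lv['modularity']:.7f}")
print(f"final: {part['final_n_communities']} communities at "
      f"Q = {part['final_modularity']:.7f}")
for w in manifest.warnings:
    print("note:", w)
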
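"""Conditional logit estimation of the cross-region care choice.

Utility of the cross-region alternative carries travel time and
capacity differences (alternative-specific) plus the village's
cohesion, classification, population and ethnic share (case-specific,
with the ASC); the non-cross-region alternative is the base.  Wald and
VIF diagnostics accompany the fit.
"""

import json
from pathlib import Path

import pandas as pd

from _common import OUTDIR, get_config
from edgevillages.pipeline import run_pipeline

run_pipeline(get_config("fit"))

summary = pd.read_csv(Path(OUTDIR) / "fit_summary.csv", index_col=0)
meta = json.loads((Path(OUTDIR) / "fit_metadata.json").read_text())

print(f"cases: {meta['n_cases']}  log-likelihood: {meta['loglik']:.4f}")
print(summary.round(5).to_string())
print(f"Wald chi2({meta['wald_df']}) = {meta['wald_chi2']:.2f}, "
      f"p = {meta['wald_p']:.4f}")
print("VIF:", {k: round(v, 3) for k, v in meta["vif"].items()})
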
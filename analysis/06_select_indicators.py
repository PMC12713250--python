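"""Elastic-net feature selection of edge-village determinants.

Tenfold cross-validation over the (alpha, lambda) grid with the
edge-village flag as the logistic response; the selected pair minimizes
mean out-of-fold deviance, and the nonzero coefficients at the refit
form the key-indicator set.
"""

from pathlib import Path

import pandas as pd

from _common import OUTDIR, get_config
from edgevillages.pipeline import run_pipeline

run_pipeline(get_config("select"))

cv = pd.read_csv(Path(OUTDIR) / "cv_table.csv")
sel = pd.read_csv(Path(OUTDIR) / "selected_indicators.csv")
best = cv.loc[cv["cv_mean_deviance"].idxmin()]
print(f"CV grid: {cv['alpha'].nunique()} alphas x "
      f"{cv.groupby('alpha').size().iloc[0]} lambdas")
print(f"selected alpha = {best['alpha']:.2f}, "
      f"lambda = {best['lambda']:.6f} "
      f"(CV mean deviance {best['cv_mean_deviance']:.6f})")
print(f"indicators selected: {len(sel)}")
if len(sel):
    print(sel.round(5).to_string(index=False))
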
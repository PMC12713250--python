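"""Render the combined plain-text and JSON summary of the analysis."""

from pathlib import Path

from _common import OUTDIR, get_config
from edgevillages.pipeline import run_pipeline

run_pipeline(get_config("report"))
print((Path(OUTDIR) / "summary.txt").read_text())
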
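"""Shared configuration for the numbered analysis drivers.

All drivers write into the same output directory and use one master
seed, so each stage picks up its predecessors' artifacts.
"""

from edgevillages.pipeline import PipelineConfig

OUTDIR = "results/analysis"
SEED = 42


def get_config(*stages: str) -> PipelineConfig:
    cfg = PipelineConfig(outdir=OUTDIR, seed=SEED)
    if stages:
        cfg.stages = stages
    return cfg
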
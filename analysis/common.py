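"""Shared configuration for the numbered analysis drivers.

All drivers write into the same run directory under results/ and are
deterministic under the shared seed; each re-executes the pipeline up to
its own stage, so they can be run independently or in order.
"""

from pathlib import Path

from mubold.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run-default"
SEED = 1


def default_config() -> PipelineConfig:
    return PipelineConfig(out_dir=str(RUN_DIR), seed=SEED)
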
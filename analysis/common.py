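"""Shared paths and the demo-landscape study conditions for the drivers."""

from pathlib import Path

from econetkit.config import PipelineConfig
from econetkit.synthetic import default_demo_spec

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "demo"

SEED = 42


def demo_spec():
    """The demo landscape: 220 x 300 cells at 90 m (~20 x 27 km), 3 dates."""
    return default_demo_spec(seed=SEED)


def demo_config():
    return PipelineConfig(seed=SEED)
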
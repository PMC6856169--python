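"""Shared setup for the numbered analysis scripts.

Each script runs one pipeline stage through the command-line interface
against a single default configuration under ``results/run``, so the stages
can be re-run individually and always agree on seeds and paths.
"""

from pathlib import Path

from ecorisk.cli import main as cli_main
from ecorisk.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
RUN_DIR = RESULTS / "run"
CONFIG_PATH = RUN_DIR / "config.yaml"


def ensure_config(seed: int = 0) -> Path:
    """Write the default pipeline configuration if it is not there yet."""
    if not CONFIG_PATH.exists():
        RUN_DIR.mkdir(parents=True, exist_ok=True)
        PipelineConfig(seed=seed, outdir=str(RUN_DIR)).to_yaml(CONFIG_PATH)
    return CONFIG_PATH


def run_stage(stage: str, seed: int = 0) -> None:
    cfg = ensure_config(seed)
    cli_main([stage, "--config", str(cfg)], standalone_mode=False)
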
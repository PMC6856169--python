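#!/usr/bin/env python
"""Normalise indicators and build entropy-weighted PSR composites."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import run_stage

if __name__ == "__main__":
    run_stage("psr")
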
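#!/usr/bin/env python
"""Run LISA and the autologistic risk model on the 40-km weights."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import run_stage

if __name__ == "__main__":
    run_stage("spatial")
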
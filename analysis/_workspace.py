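"""Shared plumbing for the numbered analysis drivers.

Each driver operates on the working directory ``results/analysis`` (created
by 01_simulate.py) so the scripts can be run one after another from the
repository root, mirroring the pipeline's stage order.
"""

import argparse
from pathlib import Path

from ernascope import RunConfig

WORKDIR = Path("results/analysis")


def parse_args(description):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--workdir", type=Path, default=WORKDIR)
    return ap.parse_args()


def run_config(seed):
    # consensus repetitions reduced from the method default (1000) to 200:
    # the toy cohort's consensus matrices are already stable there
    return RunConfig(seed=seed, reps=200)
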
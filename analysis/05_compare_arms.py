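#!/usr/bin/env python
"""Pairwise ANCOVA comparison of the survival curves.

Two scenarios are run.  Under the pure linear-quadratic truth the three
arms are matched to equal survival by construction, so the pairwise
comparisons form a true null and the significance tables should stay
empty of stars (up to the 5% false-positive rate).  The second scenario
injects a normal-tissue sparing effect (a 1.5x survival multiplier on
both microbeam arms of MRC-5, emulating intercellular-communication
rescue that the LQ model does not capture): both MRT arms then separate
significantly from broad beam while remaining indistinguishable from
each other.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mrtfrac.config import RunConfig, default_config_dict
from mrtfrac.pipeline import cmd_analyze, cmd_simulate


def run(cfg, out: Path, label: str) -> None:
    records = cmd_simulate(cfg, out)
    arts = cmd_analyze(cfg, records, out)
    for path in arts["significance"]:
        print(f"\n[{label}] {path.stem}:")
        print(pd.read_csv(path, index_col=0).to_string())


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = RunConfig(default_config_dict()).with_seed(args.seed)
    run(cfg, args.out / "null_truth", "pure LQ truth, matched arms")

    raw = json.loads(json.dumps(cfg.raw))
    raw["study"]["modality_effects"] = [
        {"cell_line": "MRC-5", "modality": "MRT_fx4", "factor": 1.5},
        {"cell_line": "MRC-5", "modality": "MRT_fx4+R", "factor": 1.5},
    ]
    run(RunConfig(raw), args.out / "sparing_effect", "with MRC-5 sparing effect")


if __name__ == "__main__":
    main()
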
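#!/usr/bin/env python
"""Generate the study-shaped synthetic replica ensemble.

Four replicas of a toy two-chain complex carrying the three planted
interface motifs (an Arg->Glu hydrogen bond + salt bridge supported by all
four replicas, and an Asp bridging to either of two nearby lysines in
different replica subsets), with 0.1 A thermal jitter.  Replica PDBs and
the parameter table go to scratch/fixtures (large, regenerable); the
ground-truth manifest is copied to results/ for the downstream scripts.
"""

import json
import shutil
from pathlib import Path

from ppikit import synthetic_data as sd

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
FIXTURES = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"


def main() -> None:
    recipe = sd.default_recipe(seed=SEED)
    ens, manifest = sd.write_ensemble(recipe, FIXTURES)
    RESULTS.mkdir(exist_ok=True)
    shutil.copy(FIXTURES / "manifest.json", RESULTS / "ensemble_manifest.json")
    print(f"wrote {ens.n_replicas} replicas x {ens.n_frames[0]} frames "
          f"({len(ens.topology)} atoms) to {FIXTURES}")
    for p in manifest["plants"]:
        print(f"  planted {p['kind']:10s} {p['resA'][2]}{p['resA'][1]} -> "
              f"{p['resB'][2]}{p['resB'][1]} in replicas "
              f"{p['replicas_present']} at persistence {p['persistence']}")


if __name__ == "__main__":
    main()
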
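#!/usr/bin/env python
"""Single-trajectory MM/GBSA binding free energy of the toy complex.

Attaches the packaged per-atom parameters to the ensemble topology and
averages dG = G(complex) - G(A) - G(B) over strided frames of each
replica (HCT generalized-Born polar term, gamma*SASA nonpolar term, no
entropy).  The headline number is the mean over replica means +/- the
s.d. across replicas.
"""

import json
from pathlib import Path

from ppikit import synthetic_data as sd
from ppikit.gbsa_scoring import GBSAConfig, binding_free_energy
from ppikit.structure_io import TrajectoryEnsemble, assign_parameters

SEED = 1
STRIDE = 10
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    ens, _ = sd.generate_ensemble(sd.default_recipe(seed=SEED))
    table, formal = sd.toy_parameter_table()
    topo = assign_parameters(ens.topology, table, formal)
    gens = TrajectoryEnsemble(topo, ens.replicas, ens.frame_times)
    res = binding_free_energy(gens, GBSAConfig(), frame_stride=STRIDE)
    RESULTS.mkdir(exist_ok=True)
    payload = {
        "replica_means_kcal_mol": res.replica_means,
        "mean_kcal_mol": res.mean,
        "sd_kcal_mol": res.sd,
        "frame_stride": STRIDE,
        "n_frames_scored": len(res.per_frame),
        "protocol": "single-trajectory MM/GBSA, HCT radii, gamma*SASA, "
                    "no entropy term",
    }
    (RESULTS / "gbsa_summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print("per-replica dG_bind (kcal/mol):",
          [round(x, 2) for x in res.replica_means])
    print(f"dG_bind = {res.mean:.1f} +/- {res.sd:.1f} kcal/mol "
          f"(mean +/- s.d. over {len(res.replica_means)} replicas, "
          f"stride {STRIDE})")


if __name__ == "__main__":
    main()
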
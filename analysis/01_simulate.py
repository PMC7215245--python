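"""Simulate the study cohort and imaging data.

Generates the synthetic analogue of the study: 66 control athletes scanned
once pre-season and 33 concussed athletes scanned at ACU/RTP/1MO/1YR with
retention 27/25/25/13, dropout rank-correlated with days to return-to-play
(target rho 0.5), NAA/Cr and Ins/Cr log-ratios drawn from the reference
mixed-model effect sizes, plus an acute-session Fconn voxel stack with a
planted metabolite-correlated cluster (rho 0.7).

Writes results/cohort.csv, results/fconn_acu{.nii.gz,_mask.nii.gz,...}
and results/simulation_manifest.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

from neurometab import io as nio
from neurometab.cohort import (
    CohortConfig,
    PlantedClusterSpec,
    generate_voxel_stack,
    simulate_study,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    cfg = CohortConfig(seed=SEED)
    df = simulate_study(cfg)
    nio.write_cohort_csv(df, OUT / "cohort.csv")
    conc = df[df.group == "concussed"]
    print(f"cohort: {df.subject_id.nunique()} athletes "
          f"({(df.group == 'control').sum()} control scans, "
          f"{len(conc)} concussed session rows)")
    retained = conc[conc.observed].groupby("session").size()
    print("retention:", dict(retained))

    rng = np.random.default_rng(np.random.SeedSequence([SEED, 77]))
    acu = conc[conc.session == "ACU"]
    spec = PlantedClusterSpec(clusters=[((12, 12, 12), 4, 0.7)])
    stack = generate_voxel_stack(acu["ins_cr_complete"].to_numpy(), spec, rng)
    nio.write_voxel_stack(stack, OUT / "fconn_acu")
    print(f"voxel stack: {stack.n_subjects} subjects x {stack.data.shape[1]} voxels, "
          f"planted cluster of {int(spec.cluster_mask().sum())} voxels at rho=0.7")

    manifest = {"seed": SEED, "config": cfg.__dict__ | {"retention": list(cfg.retention)}}
    (OUT / "simulation_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )


if __name__ == "__main__":
    main()
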
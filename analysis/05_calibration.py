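"""Calibration studies: does the inference machinery keep its promises?

Runs the simulation studies behind the acceptance checks at reduced size
for a quick report: Boot-MI coefficient recovery, 95% CI coverage, type-I
error under a null generator, SOFT-IMPUTE recovery, cluster familywise
error, end-to-end planted-cluster detection and connectivity-gradient
sign recovery.  Writes results/calibration.json.

For the full-size studies (50/200/200 cohorts, 50 imaging runs) run the
acceptance script or the test suite instead.
"""

import json
import sys
from pathlib import Path

import numpy as np

from neurometab import validation

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    out = {}
    rec = validation.recovery_study(n_cohorts=15, B=40, M=2, seed=SEED)
    out["recovery"] = {
        "max_abs_bias": rec["max_abs_bias"],
        "mean_estimates": dict(zip(rec["terms"],
                                   np.round(rec["mean_estimates"], 3))),
    }
    print(f"recovery: max |bias| {rec['max_abs_bias']:.3f} over {rec['n_cohorts']} cohorts")
    cov = validation.coverage_study(n_cohorts=40, B=200, M=2, seed=SEED)
    out["coverage"] = cov
    print(f"coverage: {cov['coverage']:.3f} ({cov['n_intervals']} intervals)")
    t1 = validation.type1_study(n_cohorts=40, B=200, M=2, seed=SEED)
    out["type1"] = t1
    print(f"type-I FDR rate: {t1['type1_rate']:.3f}")
    si = validation.soft_impute_study(seed=SEED)
    out["soft_impute"] = si
    print(f"soft-impute masked error: {si['masked_rel_error']:.4f}")
    fwe = validation.cluster_fwe_study(seed=SEED, n_sims=500, n_fresh=100)
    out["cluster_fwe"] = {k: v for k, v in fwe.items() if k != "fwhm_estimate"}
    print(f"cluster FWE: {fwe['fwe_rate']:.3f} at extent {fwe['threshold_voxels']}")
    det = validation.detection_study(n_runs=10, seed=SEED)
    out["detection"] = det
    print(f"detection: {det['detection_rate']:.2f}, "
          f"false-cluster rate {det['false_cluster_rate']:.2f}")
    grad = validation.gradient_study(n_seeds=20, seed=SEED)
    out["gradient"] = grad
    print(f"gradient sign recovery: {grad['sign_correct_rate']:.2f} "
          f"(mean rho {grad['mean_rho']:.3f})")
    (OUT / "calibration.json").write_text(json.dumps(out, indent=2, default=float))


if __name__ == "__main__":
    main()
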
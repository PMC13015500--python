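#!/usr/bin/env python
"""Scaled-down validation sweep: recovery, calibration, type-I error.

A quicker version of scripts/acceptance.py for interactive use: TRF
recovery at SNR 0.5, null calibration with permuted novelty (10 sessions),
and the cluster-permutation false-positive rate (100 null stacks). Writes
validation.csv.
"""

from pathlib import Path

import pandas as pd

from fixnov import benchmarks as B

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    rows = []
    rec = B.trf_recovery(seed=SEED)
    rows.append(("fixation_trf_recovery_r", rec["fixation_trf_r"]))
    rows.append(("novelty_trf_recovery_r", rec["novelty_trf_r"]))
    print(f"TRF recovery at SNR 0.5: fixation r = {rec['fixation_trf_r']:.3f}, "
          f"novelty r = {rec['novelty_trf_r']:.3f}")

    nullc = B.null_calibration(seed=SEED, n_sessions=10)
    rows.append(("null_fdr_significant_fraction",
                 nullc["fdr_significant_fraction"]))
    rows.append(("bootstrap_ks_p", nullc["bootstrap_ks_p"]))
    print(f"null calibration: FDR-flagged fraction "
          f"{nullc['fdr_significant_fraction']:.3f} "
          f"(bound {nullc['fdr_bound']:.3f}); bootstrap KS p = "
          f"{nullc['bootstrap_ks_p']:.3f}")

    clus = B.cluster_type1(seed=SEED, n_stacks=100, n_perm=1000)
    rows.append(("cluster_familywise_fp_rate", clus["familywise_fp_rate"]))
    print(f"cluster permutation family-wise error at alpha=0.05: "
          f"{clus['familywise_fp_rate']:.3f}")

    ROOT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(
        ROOT / "validation.csv", index=False)
    print(f"wrote validation.csv -> {ROOT}")


if __name__ == "__main__":
    main()
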
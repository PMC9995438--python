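#!/usr/bin/env python
"""Skull-artifact robustness: false-positive rates per model family.

Phantoms carry a DT-elevated skull-rim patch whose voxels mimic penumbra at
the single-voxel level (DT above the 3 s threshold, healthy CBF); the
dual-threshold ground truth relabels the rim non-ischemic via single-lesion
cleanup.  Each classifier family trains on 12 artifact-bearing studies and
is applied to 6 held-out ones; reported is the fraction of rim voxels
predicted as lesion.  Tree and kernel models can represent the non-monotone
(interval) decision rule in delay time that the rim demands; a linear
multinomial model cannot, and marks much of the rim as penumbra.
"""

import sys
from pathlib import Path

import pandas as pd

from ctpseg.workflows import artifact_fp_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> int:
    rates = artifact_fp_experiment(seed=SEED)
    OUT.mkdir(exist_ok=True)
    df = pd.DataFrame(
        [{"algorithm": k, "artifact_fp_rate": round(v, 4)} for k, v in rates.items()]
    )
    df.to_csv(OUT / "artifact_fp_rates.csv", index=False)
    for k, v in rates.items():
        print(f"{k:>3}: artifact-region false-positive rate {v:.4f}")
    flexible = {k: v for k, v in rates.items() if k != "lr"}
    if all(v < rates["lr"] for v in flexible.values()):
        print("every flexible model (RF/XGB/SVM) beats logistic regression on the rim")
    print(f"rates -> {OUT / 'artifact_fp_rates.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
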
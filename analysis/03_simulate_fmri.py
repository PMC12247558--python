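#!/usr/bin/env python
"""Simulate the scanner sample's 4D time series.

Sixteen subjects on a 10^3 voxel grid (desk-scale stand-in for the
whole-brain grid), 36 stimuli in pseudo-randomised per-subject orders,
shared stimulus-locked signal delayed by 4 TRs, plus idiosyncratic signal
scaled by each subject's CMLE score (negative Anna-Karenina direction: low
scorers synchronise more). NIfTI volumes and BIDS-style events go under
scratch/fmri/ (bulky, regenerable); the ground-truth record goes to
results/imaging/.
"""

import json
from pathlib import Path

import pandas as pd

from curiosync import synthetic

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "fmri"
OUT = ROOT / "results" / "imaging"
N_SUBJECTS = 16


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    OUT.mkdir(parents=True, exist_ok=True)
    cmle_path = ROOT / "results" / "behaviour" / "cmle_scores.tsv"
    if cmle_path.exists():
        cmle = pd.read_csv(cmle_path, sep="\t").set_index("subject_id")["cmle"]
        scores = cmle.iloc[:N_SUBJECTS].tolist()
        origin = "behavioural-arm CMLE scores"
    else:
        scores = [(-1) ** i * 0.1 * (i // 2) for i in range(N_SUBJECTS)]
        origin = "fallback synthetic scores (run 02 first for the coupled version)"

    cfg = synthetic.FmriSimConfig(
        n_subjects=N_SUBJECTS, voxel_grid=(10, 10, 10), annak_scores=scores,
        annak_direction="negative", seed=400,
    )
    series = synthetic.generate_fmri(cfg)
    for s in series:
        synthetic.write_labeled_series(
            s, SCRATCH / f"{s.subject_id}_bold.nii.gz", SCRATCH / f"{s.subject_id}_events.tsv"
        )
    (OUT / "simulation_truth.json").write_text(json.dumps({
        "n_subjects": N_SUBJECTS, "voxel_grid": [10, 10, 10], "true_lag_tr": cfg.true_lag_tr,
        "annak_direction": cfg.annak_direction, "annak_scores": scores,
        "annak_scores_origin": origin, "seed": cfg.seed,
    }, indent=2) + "\n")
    print(f"wrote {N_SUBJECTS} subjects x {series[0].n_volumes} volumes to {SCRATCH}")
    print(f"ground truth ({origin}) -> {OUT / 'simulation_truth.json'}")


if __name__ == "__main__":
    main()
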
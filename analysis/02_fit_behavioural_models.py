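#!/usr/bin/env python
"""Fit the behavioural arm: per-study gLMEs, meta-integration, cutoff sweep.

Reads the trial tables written by 01_simulate_behaviour.py, fits the
logistic mixed model for recall and every confidence cutoff 0..5 in each
data collection, pools the coefficients by inverse-variance meta-analysis,
regresses the pooled effects on the cutoff, and exports mean-centred CMLE
scores from the scanner sample for the imaging arm. Outputs land in
results/behaviour/.
"""

from pathlib import Path

import pandas as pd

from curiosync import pipeline

BEHAV = Path(__file__).resolve().parents[1] / "results" / "behaviour"


def main() -> None:
    tables = {
        p.stem.replace("_trials", ""): pd.read_csv(p, sep="\t")
        for p in sorted(BEHAV.glob("*_trials.tsv"))
    }
    if not tables:
        raise SystemExit("run 01_simulate_behaviour.py first")
    cfg = pipeline.RunConfig(seed=0)
    report = pipeline.run_behavioural(tables, BEHAV, cfg=cfg, cmle_study="fmri")

    print("Integrated coefficient table (recognition / high confidence / recall):")
    print(
        report["meta_table"][["measure", "effect", "b_se", "or_ci", "z", "p_label"]]
        .to_string(index=False)
    )
    print("\nCutoff regression of pooled log-odds on confidence cutoff:")
    for eff, reg in report["cutoff_regression"].items():
        lo, hi = reg["ci95"]
        print(f"  {eff}: B = {reg['slope']:.4f}, 95%-CI [{lo:.4f}; {hi:.4f}], p = {reg['p']:.4f}")
    print(f"\nCMLE scores for {len(report['cmle_scores'])} scanner subjects "
          f"-> {BEHAV / 'cmle_scores.tsv'}")


if __name__ == "__main__":
    main()
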
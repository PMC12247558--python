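# curiosync

Statistical pipeline for studying **curiosity- and incentive-motivated
incidental learning** with naturalistic video stimuli, exercised end to
end on synthetic data with known ground truth.

The scientific setting: participants watch short videos (e.g. magic
tricks) that elicit curiosity, rate their curiosity per video (1–7), and
half of them are promised monetary bonuses for an unrelated judgement
task. A week later, recognition (with 1–6 confidence) and cued recall are
tested. Two questions follow: *does within-person curiosity, and does the
incentive context, raise the odds of encoding a given video?* and *where
in the brain do people who are behaviourally similar also process the
videos similarly?*

The package implements both analysis arms for researchers working with
this design:

* **Behavioural arm.** A logistic mixed model per data collection —
  `logit P(remember) = β₀ + β_c·c + β_g·g + β_cg·c·g + u_subj + v_stim +
  s_subj·c` with subject-mean-centred curiosity `c`, effect-coded group
  `g` (−1/+1), crossed random intercepts and per-subject random curiosity
  slopes — estimated by Laplace maximum likelihood (verified against
  lme4's `glmer` to ~1e-4). Coefficients are pooled across collections by
  inverse-variance fixed-effect meta-analysis (`b̄ = Σ(b/SE²)/Σ(1/SE²)`),
  reported as odds ratios `exp(b̄)` with 95% CIs, and the pooled effects
  are regressed on the recognition confidence cutoff (0..5) to test
  whether an effect grows with memory quality. Per-subject curiosity
  slopes (CMLE scores) are exported for the imaging arm.

* **Imaging arm.** Per-subject 4D series are reduced to stimulus-locked
  volumes, reordered to a canonical stimulus order, and shifted by a
  hemodynamic lag chosen by intersubject pattern correlation. Every
  unordered subject pair yields a voxelwise Fisher-z intersubject
  correlation (ISC) map — N(N−1)/2 maps, 1225 at N=50. Each voxel's pair
  values are modelled with a linear mixed model with **crossed random
  effects** (`z_ij = x_ij'β + u_i + u_j + e_ij`, REML), with fixed effects
  for group (pair deviation code 1/0/−1), behavioural similarity, and
  their interaction — an intersubject representational similarity
  analysis (IS-RSA). Behavioural similarity is trial-vector correlation
  (curiosity, memory; each residualised on the other for unique effects)
  or, for the scalar CMLE score, the Anna-Karenina pair mean
  `(s_i + s_j)/2`. Maps are thresholded whole-brain (voxelwise p<0.001,
  NN1 clusters ≥ 20 voxels) and within ROIs (BH-FDR q=0.05, clusters ≥ 5),
  with an optional subject-permutation cluster-extent null.

A first-class synthetic-data module generates both behavioural tables
(from exactly the logistic model above) and labelled 4D NIfTI series
(shared stimulus-locked signal + subject-idiosyncratic signal + noise,
with configurable Anna-Karenina structure), so every stage is testable
without any data download. See `docs/methods.md` for models, assumptions
and numerical choices.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (outputs under `results/`, bulky NIfTI under `scratch/`):

```bash
python analysis/01_simulate_behaviour.py   # three data collections
python analysis/02_fit_behavioural_models.py
python analysis/03_simulate_fmri.py        # 16-subject scanner sample
python analysis/04_run_imaging_arm.py
```

`02_fit_behavioural_models.py` fits 21 mixed models (recall + six
confidence cutoffs × three collections), pools them, and prints the
integrated coefficient table and cutoff regression; on the shipped seeds:

```
Integrated coefficient table (recognition / high confidence / recall):
        measure                effect           b_se             or_ci         z p_label
    recognition     curiosity_centred  0.073 (0.026) 1.08 [1.02; 1.13]  2.855478   0.004
    recognition        incentive_code  0.076 (0.079) 1.08 [0.92; 1.26]  0.962213   0.336
    recognition curiosity_x_incentive  0.023 (0.023) 1.02 [0.98; 1.07]  1.013914   0.311
high_confidence     curiosity_centred  0.074 (0.024) 1.08 [1.03; 1.13]  3.093647   0.002
high_confidence        incentive_code  0.067 (0.066) 1.07 [0.94; 1.22]  1.009036   0.313
...
Cutoff regression of pooled log-odds on confidence cutoff:
  curiosity_centred: B = -0.0083, 95%-CI [-0.0169; 0.0004], p = 0.0574
```

Read: one rating unit of within-person curiosity multiplies the odds of
encoding by ~1.08 at every memory threshold (the generator's ground truth
is 0.084 log-odds, inside every CI); the between-subject incentive
estimate (truth 0.155) is noisy at ~200 subjects, as between-group
effects are; and the cutoff regression slope is ~0 because this
generator's confidence model does not depend on curiosity — the sweep
machinery is exercised, the ground truth is flat. `04_run_imaging_arm.py`
then prints:

```
selected HRF lag: 4 TRs (truth 4)
pairwise maps: 120; concatenated volumes: 594
  whole-brain annak_cmle/similarity: 1 cluster(s): negative k=935
  ROI central annak_cmle/similarity: 64 voxels survive FDR
```

— the 4-TR lag is recovered by intersubject pattern correlation, the 16
subjects yield 120 pairwise ISC maps over 594 concatenated volumes, and
the planted negative Anna-Karenina CMLE effect (low scorers synchronise
more) appears as a large negative whole-brain cluster and survives ROI
FDR.

Library use mirrors the scripts:

```python
from curiosync import behaviour, synthetic

table = synthetic.generate_behaviour(synthetic.BehaviourSimConfig(n_subjects=50, seed=1))
fit = behaviour.fit_glme(table, behaviour.code_memory(table, cutoff=3), variant="full")
print(fit.fixed_effects)          # b, SE, z, p per effect
scores = behaviour.extract_cmle(fit)  # mean-centred per-subject curiosity slopes
```

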
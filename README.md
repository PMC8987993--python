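# padkit

Brain-age analysis for parkinsonian disorders from regional MRI feature
tables: modality-specific brain-age prediction, bias-corrected
predicted-age-difference (PAD) scores, Gaussian-process normative
deviance maps, and robust feature-contribution profiles.

## The problem

Multiple system atrophy (MSA) and Parkinson's disease (PD) are both
alpha-synucleinopathies but differ sharply in progression and prognosis,
and early differential diagnosis is hard. One concise imaging marker is
the **brain-predicted age difference**: train a regressor to predict
chronological age from regional brain features in a healthy reference
population, apply it to patients, and read the gap

    PAD = predicted age − chronological age

as an index of advanced brain aging. `padkit` implements that analysis
for two feature panels per participant:

- **GM panel (124 features)**: 56 regional gray-matter volumes (mL) plus
  68 cortical thicknesses (mm);
- **WM panel (90 features)**: generalized fractional anisotropy (GFA) and
  mean diffusivity (MD) averaged over 45 major fiber tracts.

The pipeline's stages:

1. **Brain-age model** — a 12-layer cascade-forward neural network (each
   hidden layer and the linear output see the raw inputs plus all earlier
   layers), sex included as a predictor, trained by full-batch L-BFGS on
   mean squared error with 10-fold cross-validated Pearson r / MAE
   reporting.
2. **Bias correction** — raw PAD carries an age-related bias; following
   the standard linear correction, PAD is regressed on age in a reference
   sample and the fitted trend `a·age + b` is subtracted.
3. **Normative modeling** — one Gaussian-process regression per feature
   (inputs: age, sex) on the reference population turns any observation
   into a standardized deviance `Z = (observed − μ(age,sex)) / σ(age,sex)`
   with the predictive SD including observation noise, so healthy data
   score Z ≈ N(0, 1).
4. **Contribution profiles** — within each clinical group, each feature's
   contribution to brain aging is the robust **MM-estimate** effect size
   (high-breakdown S-scale + 85%-efficiency bisquare M-step, on
   median/MAD-standardized variables) of its Z-score against the
   corrected PAD; features are ranked by |ES|, differenced between groups
   (|ΔES| > 0.3 flags a medium between-group difference), and aggregated
   into percent contributions per lobe / fiber system.
5. **Group statistics** — ANCOVA of corrected PAD across groups adjusting
   age, sex and education, Benjamini–Hochberg-adjusted pairwise post-hoc
   tests, partial correlations between GM-PAD and WM-PAD, Fisher r-to-z
   comparison of correlations, clinical-score associations, and a
   lowest-k outlier-exclusion re-analysis.

Because the clinical MRI cohorts behind such studies are not publicly
deposited, `padkit` ships a first-class **synthetic cohort generator**
with known ground truth (per-feature age/sex trajectories; group-level
brain-age offsets implemented as effective-age shifts; focal deviances;
clinical scores coupled to the true offset), so the whole pipeline is
testable end to end by parameter recovery.

## Worked example

```python
import numpy as np
from padkit import (
    BrainAgeModel, PadBiasCorrector, compute_pad,
    ClinicalCohortConfig, default_trajectory_config,
    generate_clinical_cohort, generate_normative_population,
)

traj = default_trajectory_config()
train = generate_normative_population(500, traj, seed=101)   # ages 14-92
model = BrainAgeModel(modality="GM", random_state=7).fit(
    train.tables["GM"], train.ages, train.sex_codes)

hc  = generate_clinical_cohort(ClinicalCohortConfig("HC", 200, pad_shift=0.0), traj, seed=102)
msa = generate_clinical_cohort(ClinicalCohortConfig("MSA", 200, pad_shift=9.0), traj, seed=103)

pad_hc  = compute_pad(model.predict(hc.tables["GM"],  hc.sex_codes),  hc.ages)
pad_msa = compute_pad(model.predict(msa.tables["GM"], msa.sex_codes), msa.ages)
corr = PadBiasCorrector().fit(pad_hc, hc.ages)          # reference: HC
print("HC  mean corrected PAD:", round(corr.transform(pad_hc,  hc.ages).mean(), 2))
print("MSA mean corrected PAD:", round(corr.transform(pad_msa, msa.ages).mean(), 2))
```

Output:

```
HC  mean corrected PAD: 0.0
MSA mean corrected PAD: 9.17
```

The healthy-control group centers at zero by construction of the
correction, and the MSA-like group — generated with a +9-year effective
age shift — is recovered to within a fraction of a year.

The same analysis is available from the shell: `padkit run --config
demo.yaml` executes every stage and writes models (JSON), PAD and
Z-score tables (CSV), contribution/ΔES tables (CSV) and a provenance
report (JSON); per-stage subcommands (`simulate`, `train`, `predict`,
`pad`, `normfit`, `zscore`, `contrib`, `delta`, `stats`) expose each step
individually.

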
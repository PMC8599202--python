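# svocortex

Social preferences and cortical anatomy: scoring of the Ring Measure of
social value orientation (SVO), and parcel-wise association of the scored
preferences with cortical thickness using covariate-adjusted regression and
Freedman–Lane max-statistic permutation inference.

## The problem

People differ in how they trade their own monetary payoff against another
person's. The Ring Measure elicits this preference with 24 forced choices
between adjacent points on a circle of own/other payoffs (radius €15,
centred on €15/€15). Summing the chosen payoff offsets gives a resultant
vector whose direction is the **SVO angle** (transformed so 0° = the
"sadistic" pattern, increasing angle = increasing prosociality), whose
per-choice magnitude is the **vector length** (a consistency index, maximum
1.25; responders below 0.625 are excluded as random), and whose coordinate
projections give the weights **W_self** and **W_other**,
`(total allocated − €360) / €60`, each in [−0.5, 0.5].

Whether such stable preferences are reflected in brain structure is tested
mass-univariately: for each of 74 Destrieux parcels per hemisphere,

```
thickness(parcel) = C + β₁·SVO + β₂·age + β₃·gender + β₄·avg_thickness + ε
```

(or `β₅·W_self + β₆·W_other` in place of `β₁·SVO`), with hemisphere-specific
average thickness as a covariate. Familywise error across the parcels of
each lobe (frontal 27, parietal 17, temporal 18, occipital 12) is controlled
by Freedman–Lane residual permutation: the nuisance-only model's residuals
are permuted at the subject level, added back to its fitted values, the full
model is refitted, and each observed t is referred to the permutation
distribution of the **maximum** t within its lobe.

Raw study data of this kind are rarely shareable, so the package includes a
first-class synthetic-data module: a linear-utility choice simulator with
lapse noise and a generative thickness model with a known embedded effect
(by default at the left olfactory sulcus, parcel 22), making calibration
(type-I error at 5%) and sensitivity (effect recovery) verifiable end to end.

## Worked example

```python
from svocortex import simulate, model

data = simulate.simulate_dataset(
    simulate.PopulationSpec(n_subjects=214),
    simulate.AnatomySpec(effect_map={("left", 22): 0.004}),
    seed=7,
)
m = model.ParcelThicknessModel.from_choices(
    data["choices"], data["thickness"], data["demographics"])
res = m.fit()
perm = res.permutation_test(B=1000, seed=7)
print(perm.summary())
```

prints

```
analysed 198 of 214 participants (16 excluded as inconsistent)
Freedman-Lane max-t permutation inference
  B = 1000   sidedness = upper   seed = 7

Per-lobe summary (max observed t, min corrected p):
  svo_angle  left  frontal   max t =   8.340   min p_corrected = 0.0010
  svo_angle  left  parietal  max t =   2.116   min p_corrected = 0.2328
  svo_angle  left  temporal  max t =   1.300   min p_corrected = 0.8531
  svo_angle  left  occipital max t =   1.751   min p_corrected = 0.3936
  svo_angle  right frontal   max t =   2.190   min p_corrected = 0.3167
  svo_angle  right parietal  max t =   1.144   min p_corrected = 0.9281
  svo_angle  right temporal  max t =   1.395   min p_corrected = 0.8022
  svo_angle  right occipital max t =   2.811   min p_corrected = 0.0380

Parcels significant at alpha = 0.05:
 variable hemisphere      lobe  parcel_id                         parcel_name  beta_raw     t  p_corrected
svo_angle       left   frontal         22                    Olfactory sulcus  0.004347 8.34     0.000999
svo_angle      right occipital         63 Inferior occipital gyrus and sulcus  0.001398 2.811      0.03796
```

The embedded effect (true slope 0.004 mm/degree at the left olfactory
sulcus) is recovered at 0.0043 mm/degree and survives correction at
p = 0.001; the right-occipital hit is a chance finding — correction is
familywise *per lobe*, so about one lobe in twenty produces a false
positive at α = 0.05 on null data, exactly the rate the calibration tests
verify.

16 of 214 simulated participants (the random-responder subgroup) fall below
the 0.625 consistency cut-off and are excluded before the design matrix is
built. `res.table` holds per-parcel raw and standardized coefficients with
parametric p-values; `perm.table` extends it with corrected p-values;
`res.adjusted_scatter("lh_olfactory_sulcus")` exports the partial-regression
pairs behind any finding.

The same analysis runs from the shell:

```bash
svocortex simulate --outdir data --seed 7 --n 214 --effect 0.004
svocortex analyze --choices data/choices.csv --thickness data/thickness.csv \
    --demographics data/demographics.csv --b 5000 --seed 7 --outdir run
svocortex calibrate --mode fwer --replicates 50 --b 500 --seed 0
```

`analyze` writes the profile table, exclusion report, per-parcel results
table, a reproducibility manifest and a log into `run/`.

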
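# Methods

## Ring Measure scoring

The instrument places 24 points at angles 15k° on a circle of radius €15
centred on (€15, €15) in the (self payoff, other payoff) plane; choice k
offers points k and k+1 (mod 24), so each point appears in exactly two
choices. Payoffs are *displayed* to the nearest €0.10 (half-up), and scoring
uses the displayed values throughout, since those are what participants
allocate; the rounding reproduces the instrument's published example payoffs
exactly (€28.00/€22.50 at 30°, €29.50/€18.90 at 15°).

Scoring sums the chosen points' payoff offsets from the origin into a
resultant vector:

* **Raw angle** — the four-quadrant arctangent of the resultant
  (other-offset as ordinate, self-offset as abscissa), so a pure
  self-maximiser sits at raw 0°.
* **Transformed angle** — raw angle + 135° (mod 360), placing the sadistic
  pole (the −self/−other bisector, raw 225°) at 0° so that increasing angle
  means increasing willingness to trade own money for the other's. The
  rotation offset is a module constant (`ROTATION_OFFSET_DEG`), because the
  published transformation to the 0°-sadistic scale is conventional rather
  than unique; w_self, w_other and the vector length are unaffected by it.
* **Vector length** — resultant magnitude divided by the number of choices.
  A grid-aligned perfectly consistent responder selects every point on the
  half-circle facing its preferred direction once from each of its two
  pairs; the antipodal cancellation leaves a resultant of magnitude
  2 × radius = €30, hence the maximum 30/24 = 1.25 €/choice and the
  random-responder exclusion threshold 0.625 (50% of maximum). The
  boundary itself is included: only strictly shorter vectors are excluded.
* **w_self, w_other** — (total allocated − n·origin) / (4·radius), i.e.
  (total − €360)/€60 on the default instrument, each bounded by [−0.5, 0.5].

A zero resultant (possible, e.g., when every pair's first option is chosen,
which selects each circle point exactly once) leaves the angle undefined;
the profile is flagged degenerate, assigned vector length 0 and excluded —
the consistency rule would exclude it regardless.

The eight motivational categories (sadistic, aggressive, competitive,
individualistic, prosocial/cooperative, altruistic, martyr, masochistic)
are 45°-wide sectors centred on the poles, with a boundary angle assigned
to the lower sector. Classification is diagnostic output only; all
inference uses the angle (or the weights) as continuous measures.

### Angle recovery and display rounding

For a deterministic linear-utility responder with preferred direction θ the
recovered raw angle is quantised to the 15° point grid, so the recovery
error is at most 7.5° — *for the unrounded instrument*. The €0.10 display
rounding shifts the choice tie-points slightly; a dense sweep puts the worst
case at 7.76° (θ ≈ 127.7°). Integer-degree sweeps stay within 7.5°; tests
with continuous latent directions use the measured 7.8° bound.

## Parcellation and thickness tables

The packaged atlas lists 74 parcels with IDs 1–74 and their lobe
(frontal 27, parietal 17, temporal 18, occipital 12); cingulate and insular
parcels are assigned to lobes by anatomical proximity (IDs 5, 6, 17 frontal;
28, 29, 31, 32, 39 parietal; 55 temporal). Thickness arrives as a wide
subject × parcel table with columns `lh_<parcel>` / `rh_<parcel>`; an
optional name map adapts external surface-software dialects. Values must be
finite and strictly positive (mm).

The per-hemisphere **average thickness** covariate is the unweighted mean of
that hemisphere's 74 parcel values; per-parcel surface areas are not part of
the data model, but an optional weight vector supports an area-weighted
average for users whose upstream software defines it that way. Lobe subsets
retain the whole-hemisphere average, since it remains the model covariate.

## Regression models

Per parcel, ordinary least squares of thickness on

* angle model: `C, svo_angle, age, gender, avg_thickness`;
* weights model: `C, w_self, w_other, age, gender, avg_thickness`
  (`include_age=False` drops age for the reduced variant).

Gender is coded female = 1 (configurable upstream of the design). Missing
demographics are an error by default; an imputation option replaces missing
age with the sample mean and assigns missing gender at random under the run
seed. Designs are checked for full column rank, naming the offending column.

Coefficients are reported on two scales: `beta_raw` (mm per predictor unit)
and `beta_std` = beta_raw × sd(x)/sd(y), dimensionless and invariant to
affine rescaling of either variable. Both are always emitted because raw
slopes for an angle measured in degrees (~10⁻³ mm/degree) and standardized
weights (~10⁻¹) live on very different scales and are easily confused.

## Freedman–Lane max-t permutation

Per lobe × hemisphere family, with interest column j:

1. observed t_j per parcel from the full model;
2. reduced model without column j fitted per parcel; fitted values and
   residuals stored;
3. per iteration, one subject-level permutation — **shared across all
   parcels of the lobe**, preserving their spatial dependence — applied to
   the residuals and added back to the reduced fitted values;
4. full model refitted on the permuted outcomes; the maximum t across the
   lobe's parcels recorded;
5. after B iterations, p_corrected(parcel) = (1 + #{maxT ≥ t_obs}) / (1 + B).

Numerical and procedural choices:

* **Sidedness** — default `upper` uses the signed maximum t, under which a
  negative association can only yield p near 1; `two_sided` (max |t|) is
  available and recommended for new analyses.
* **Estimator** — the add-one form keeps p in (0, 1]; ties between permuted
  and observed statistics count as exceedances (conservative; tolerance
  1e−12 for float comparison).
* **Permutation unit** — whole subject rows; no exchangeability blocks.
* **Seeding** — per-family sub-seeds are spawned from the master seed with
  `numpy.random.SeedSequence` in the fixed order (left, right) ×
  (frontal, parietal, temporal, occipital), and per interest variable in
  the weights model; every family is independently reproducible.
* **Exhaustive mode** — all n! subject permutations are enumerated instead
  of sampled, feasible for tiny n; used to verify Monte-Carlo agreement
  with an independent enumeration oracle at n = 6.
* **Degenerate fits** — when a model fits perfectly (zero residual
  variance), t is defined as 0 if the coefficient itself vanishes (outcome
  explained by the nuisance alone) and signed infinity otherwise.
* The inner refit is vectorised across permutations (pseudo-inverse
  precomputed once; permutations processed in chunks of 500), so B = 5000
  over a 27-parcel lobe at n ≈ 200 takes about a second.

With several variables of interest (weights model) the procedure runs once
per variable, the other acting as a nuisance covariate — each null
distribution then conditions on the other weight, matching the adjusted
partial associations that are reported.

## Synthetic data generator

The generator emulates the statistical structure of a behavioural +
anatomical study; it makes no attempt at biophysical realism.

**Behaviour.** Each subject draws a latent preferred direction θ from a
mixture over the motivational poles — defaults: prosocial (raw 45°) 0.40,
individualistic (0°) 0.40, competitive (315°) 0.15, altruistic (90°) 0.05,
matching the 40/40 prosocial/selfish split typical of samples measured with
this instrument, with 10° angular jitter as trait instability. Choices
follow a linear-utility rule (pick the option with the larger offset
projection on (cos θ, sin θ); ties to the first option) with a lapse
probability of a uniformly random choice: 0.02 for ordinary responders and
1.0 for a random-responder subgroup (default fraction 20/214) that the
consistency filter is meant to remove. About 9% of pure-random responders
nevertheless clear the 0.625 cut-off (Rayleigh tail of the resultant), so
the expected exclusion count is slightly below the subgroup size.

**Demographics.** Age ~ Normal(24.15, 1.90²) years; gender ~
Bernoulli(105/214) (female = 1).

**Anatomy.** thickness(subject, parcel) = parcel mean + subject global
factor + age slope · (age − mean age) + gender offset · gender +
effect(parcel) · predictor + noise, resampling any non-positive draw.
Defaults: parcel means spread deterministically over 2.0–3.0 mm, subject
global SD 0.12 mm (this shared factor is the only between-parcel
covariance), parcel noise SD 0.25 mm, age slope −0.01 mm/year (gradual
cortical thinning), gender offset 0.03 mm, and a single true association of
0.0017 mm/degree at the left olfactory sulcus (parcel 22). The generator
does **not** model spatially structured covariance between neighbouring
parcels, folding patterns or acquisition artefacts — so passing calibration
here shows the inference machinery is correct under exchangeable residuals
with a common global factor, not that real cortical dependence structures
are handled optimally (max-t correction remains valid, though possibly
conservative or liberal in power terms, under other dependence).

`simulate_dataset` drives the anatomical effect with the *latent* direction
(measurement noise then attenuates the estimate, as in a real study). The
recovery harness `parameter_recovery_experiment` instead defaults to the
*scored* angle as the generative predictor, so that the regression
predictor coincides with the generative one and OLS is exactly unbiased —
isolating the estimation/inference machinery from errors-in-variables.
With `predictor_source="truth"` the harness reproduces the realistic
setting, where the few random responders that survive the filter act as
high-leverage measurement-error points and attenuate the recovered slope by
several percent — a property of the study design worth knowing, not a bug
in the estimator.

## Calibration and problem sizes

The test suite verifies, at sizes chosen to keep the default run fast while
leaving negligible Monte-Carlo ambiguity:

* familywise error on 200 independent null datasets (12-parcel lobe,
  n = 194, B = 500) inside the 99% binomial band around 5% (0.02–0.08);
* exact agreement with exhaustive enumeration at n = 6, 2 parcels (720
  permutations), for both sidedness conventions;
* OLS agreement with an explicit normal-equations solve to 1e−8 on 50
  random instances, plus a Frisch–Waugh residualisation cross-check;
* effect recovery over the grid {0, 0.001, 0.002, 0.004} mm/degree at
  n = 214, B = 300, 12 replicates per point: bias within two empirical
  standard errors everywhere, rejection rate non-decreasing along the
  grid, ≤ 0.1 at the null and ≥ 0.9 at the largest effect.

## Known limitations

* The transformation placing the sadistic pole at 0° is one convention
  consistent with the scale's descriptive properties; any fixed rotation
  leaves the substantive quantities unchanged, but absolute angle values
  are only comparable across studies using the same convention.
* The hemisphere average is unweighted by default; analyses whose upstream
  pipeline defines an area-weighted mean should supply weights.
* Permutation p-values are Monte-Carlo estimates with resolution
  1/(B + 1); B = 5000 gives ~0.0002, ample for α = 0.05 decisions.
* The pipeline consumes thickness tables; surface reconstruction,
  segmentation and quality control happen upstream and are out of scope.
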
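# Methods

## DLW calculation engine

The engine implements the two-pool, fixed-RQ variant of the doubly-labeled-
water method. Each isotope's urine enrichment (atom-fraction excess above the
subject's pre-dose baseline) is assumed to decay mono-exponentially from dose
time; the rate and the back-extrapolated zero-time intercept are estimated by
ordinary least squares on ln(excess) vs time over all non-discarded samples.
With exactly two points this reduces to the exact two-point solution. The
five-specimen protocol (2, 3, 4 h post dose, 2 h discarded; two collections
at ~13.5 and 14 days) therefore contributes four points per isotope.

Dilution spaces are N = dose excess / intercept. A unit convention removes
the hydrogen bookkeeping: the ²H dose excess is stored in *water-equivalent*
moles (moles of dose water × atom-fraction excess per hydrogen site), so the
identity N = dose/E₀ returns moles of body water for both isotopes — the
factor of two hydrogen sites per molecule cancels between dose and pool.

Fixed constants, all exposed in `dlwtee.constants`:

| constant | value | role |
|---|---|---|
| dose rates | 2 g/kg TBW (10 atom% ¹⁸O), 0.12 g/kg (99.9 atom% ²H) | dosing |
| natural abundances | 0.2005 atom% ¹⁸O, 0.0156 atom% ²H | excess moles |
| space corrections | N_D/1.041, N_O/1.007, averaged | mean pool N |
| hydration of FFM | 0.732 | TBW → FFM |
| rCO₂ model | 0.4554·N·(1.007 k_O − 1.041 k_D) | CO₂ production |
| Weir, fixed RQ | 22.4·rCO₂·(3.941/RQ + 1.106), RQ = 0.86 | TEE (≈127.42 kcal/mol CO₂) |

The rCO₂ equation variant (fractionation-corrected mean-pool form) is a
documented default: field pipelines differ in the exact coefficient set and
space-ratio treatment, and the constants live in one module so alternatives
can be swapped. The dilution-space ratio N_D/N_O has a sanity band of
[1.00, 1.07]; values outside it set a warning flag without invalidating the
subject. Elimination rates below 10⁻⁶/day (no measurable decay over two
weeks; physiological k_D is ~0.05–0.15/day) mark the subject invalid —
flagged and reported, never silently dropped.

## Synthetic cohort generator

The generator emulates a two-week free-living DLW study of 304 adults aged
40–69: four sex × smoking-status cells (males 20 current / 138 never
smokers; females 27 / 119), each with its own covariate means and SDs for
age, height, weight, FFM and self-reported physical activity
(MET-min/week). Covariates are drawn independently within cells from
truncated normals: age hard-truncated to [40, 69], other covariates at ±4 SD,
and PA additionally at zero. Latent true TEE is

    TEE = b₀ + b_FFM·FFM + b_age·age + b_PA·PA + b_smoke·1[current] + ε,

per sex, with defaults b = (43.6, −13.3, 0.05, 111.9) for males and
(45.0, −3.5, 0.01, −81.8) for females. Intercepts are calibrated so a never
smoker at the never-cell nominal covariate means hits the target group mean
(2854 kcal/d males, 2330 females); residual SDs (288/284 kcal/d) are chosen
so the marginal never-smoker TEE SD is ≈468/415 kcal/d, which also places
the FFM–TEE Pearson correlation near the observed ~0.75.

Enrichment series are simulated by inverting the engine: TBW = 0.732·FFM
fixes the pool, the Weir equation at the subject's true TEE fixes the target
rCO₂, deuterium turnover is drawn from a water-turnover model
(≈0.085 ± 0.010 L per kg TBW per day, truncated to [0.055, 0.115] — about
3–4 L/day for a typical adult), and k_O is solved from the rCO₂ identity.
Initial enrichments use a dilution-space ratio of 1.034 with N_D and N_O
solved jointly so their fractionation-corrected mean equals the true pool
exactly; the noiseless round trip through the engine is therefore exact to
float precision. Measurement noise is multiplicative Gaussian per sample and
isotope; at the default CV of 1% the recovered-TEE CV across subjects is
≈5%, inside the 4–7% precision usually quoted for the method.

Randomness: each cell draws from its own substream (derived from the root
seed) with a fixed number of inverse-CDF draws per subject, so enlarging a
cell appends subjects without altering existing ones; enrichment simulation
uses one derived substream per subject position.

### What the generator does *not* emulate

* Covariate correlations within cells (drawn independently; real FFM, weight
  and height are strongly correlated). The only joint constraint enforced is
  FFM < body mass, maintained by raising weight to FFM/0.95 where violated so
  the FFM marginal — which drives the TEE model — stays exact.
* The zero-truncation of the wide PA distributions raises the realized PA
  mean ~20% above the nominal cell mean; intercept calibration is defined at
  the nominal means, so realized group TEE means sit within ~20 kcal/d of
  their targets rather than exactly on them.
* Former smokers, missing-data mechanisms, seasonal or within-subject TEE
  variation, and isotope analytical drift.

Passing tests on these cohorts therefore validate the *computational*
pipeline and the statistics' operating characteristics under a correctly
specified linear model — not robustness to the messier joint structure of
real field data.

## Statistics

Sexes are analyzed separately throughout, difference direction is current −
never smokers, and no multiple-testing correction is applied. The default
two-sample test is the pooled-variance t (df = n₁+n₂−2) because it
reproduces the published unadjusted confidence limits from summary
statistics; Welch is available as an option (its SE equals the power
module's two-group SE by construction). The summary-statistics path is
algebraically identical to the raw-data path given each group's n/mean/SD.
p-values from rounded summary inputs can differ from raw-data p-values in
the second decimal (the female unadjusted comparison gives 0.465 from table
inputs). OLS is delegated to statsmodels behind the module's interface, with
rank checking that names the collinear term; tests verify it against a
direct normal-equations solve. LS means are model predictions at the
unweighted covariate grand means of the analysis sample; the group
difference, SE and p coincide with the smoking coefficient's t test.

The type-I-error property uses an exact null configuration
(`CohortConfig.null_smoking()`): the smoking coefficient is zeroed *and* the
current-smoker cells inherit the never-cell covariate distributions. Under
the default (heteroscedastic) cells, the male smoker cell's larger FFM SD
gives smokers a larger marginal TEE variance, and a pooled t with n = 20 vs
138 is intrinsically anticonservative there (~9–10% size) — a property of
the t-test's equal-variance assumption, not an implementation defect; the
exact null isolates the latter.

## Power and corrections

* Two-group SE: √(s₁²/n₁ + s₂²/n₂); minimal detectable difference uses the
  normal approximation (z_{1−α/2} + z_{power})·SE, not the noncentral t.
* RMR-elevation projection: elevation × (RMR/24) × hours/cigarette ×
  cigarettes/day. The default RMR of 1200 kcal/d reproduces the conventional
  30–50 kcal/d pack-a-day band under 3–5% elevation for 1 h per cigarette,
  and is a config parameter. Total elevated time is capped at 24 h/day.
* Inhaled CO₂: cigarettes × 0.7 g combustible × carbon mass fraction 0.40 /
  12.011 × two-thirds inhaled. The carbon mass fraction of combusted tobacco
  is not a measured constant here; 0.40 yields ≈0.62 mol/day at two packs
  and is exposed as a parameter. The energy equivalent uses the Weir
  per-mole value; a companion helper expresses a percentage CO₂ overestimate
  directly as kcal/day of a given TEE (2% of 2266 to 4% of 2882 kcal/d spans
  45–115 kcal/d). The percentage reconstruction is an inference about how
  such bands are usually derived, and is labeled as such in the API.

## Numerical and design choices

* Exactly 100 lifetime cigarettes classifies as a smoker (the questionnaire
  rule leaves the boundary unstated; the gap is closed on the smoker side).
* Units are embedded in column names (`tee_kcal_d`, `time_days`) rather than
  a second header row, keeping all CSVs single-header and pandas-loadable.
* Problem sizes in the test suite: round-trip exactness uses 1000 subjects;
  coefficient-recovery coverage uses 100 replicates of n = 2000/sex;
  test size uses 1000 replicate male cohorts (20 vs 138). These sizes give
  Monte-Carlo error comfortably inside the asserted bands while keeping the
  default suite under a minute of simulation time.
* The sample-size arithmetic in `run_analysis`'s report and the desk
  calculators recompute everything at call time; nothing is cached between
  stages except via the written CSV files.

## Known limitations

Single-measurement subjects only (no repeated DLW periods); no plasma/urine
matrix corrections or analytical-error model beyond the multiplicative CV;
fixed RQ rather than diet-derived; the pooled t and OLS assume
within-group normality, which the generator satisfies by construction.
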
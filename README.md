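# dlwtee

Doubly-labeled-water (DLW) energy expenditure pipeline for smoking-group
comparisons: an isotope-kinetics calculation engine, a synthetic cohort
generator emulating a large two-week free-living field study, the
group-comparison statistics, and the accompanying power and bias-correction
desk calculations.

## Who this is for

Energy-metabolism and nutritional-epidemiology researchers who want a tested,
reproducible implementation of the DLW calculation chain and of the
statistical battery used to compare total energy expenditure (TEE) between
current smokers and never smokers — without access to subject-level field
data. Every stage runs on synthetic cohorts whose covariate structure,
smoking-group sizes (20/138 males, 27/119 females) and TEE coefficient
structure emulate a published large DLW sample.

## The model

After an oral dose of ²H- and ¹⁸O-labeled water, deuterium is eliminated as
water while ¹⁸O is eliminated as water **and** CO₂. Fitting log-linear
elimination curves to urine enrichments (five-specimen protocol: 2, 3, 4 h
post dose with the 2 h specimen discarded, plus two collections ~14 days
later) gives rates k_D, k_O and dilution spaces N_D = dose/E₀(²H),
N_O = dose/E₀(¹⁸O). Then

    N    = (N_D/1.041 + N_O/1.007) / 2          (mean body-water pool, mol)
    TBW  = N · 18.0153 / 1000                   (kg)
    FFM  = TBW / 0.732                          (kg)
    rCO₂ = 0.4554 · N · (1.007·k_O − 1.041·k_D) (mol/day)
    TEE  = 22.4 · rCO₂ · (3.941/RQ + 1.106)     (kcal/day, RQ = 0.86)

Group comparisons use the pooled-variance two-sample t (Welch available),
Pearson correlations, per-sex OLS of TEE on a current-smoking indicator,
fat-free mass, age and physical activity, and least-squares means at the
covariate grand means. The power/corrections module implements the
two-group SE, the normal-approximation minimal detectable difference
(z_{1−α/2}+z_{power})·SE, the post-cigarette RMR-elevation projection, and
the inhaled-cigarette-CO₂ overestimation model.

## Worked example

Summary-statistics mode (male smokers 3069±764 kcal/d, n=20, vs never
smokers 2854±468, n=138):

```
$ dlwtee ttest --n1 20 --mean1 3069 --sd1 764 --n2 138 --mean2 2854 --sd2 468
diff=215.0 se=122.8 t=1.751 df=156.0 p=0.082 ci=(-27.6, 457.6) [pooled]
```

The smoker–never difference is 215 kcal/d with pooled SE 122.8; the 95% CI
(−28, 458) includes zero, so the groups are not significantly different at
α = 0.05. Power arithmetic for a small reference study (496 vs 628 kcal/d
SDs, n = 11 and 10):

```
$ dlwtee power --sd1 496 --n1 11 --sd2 628 --n2 10
se_diff=248.6 kcal/d  mdd(alpha=0.05, power=0.8)=696.5 kcal/d
```

i.e. a study that size could only detect a ~700 kcal/d difference with 80%
power. Smoking-specific biases for a two-pack-a-day smoker:

```
$ dlwtee corrections --cigs-per-day 40 --tee 2882
...
inhaled_co2=0.622 mol/d energy_equiv=79.2 kcal/d
approx_pct_of_tee=2.7%
```

Inhaled cigarette CO₂ adds ~0.6 mol/day to measured CO₂ production — a 2–4%
overestimate of TEE for typical adults.

Full synthetic pipeline:

```sh
dlwtee generate --seed 1 --out study/               # 304 subjects + enrichments
dlwtee dlw --enrichments study/enrichments.csv \
           --doses study/doses.csv --out study/results.csv
dlwtee analyze --cohort study/cohort.csv \
               --dlw-results study/results.csv --out study/report/
```

`report/report.txt` contains the five analysis tables (characteristics,
unadjusted TEE, correlations, adjusted means, regression coefficients) plus
the desk calculations. With the default 1% enrichment-noise CV, the DLW
engine recovers each subject's true TEE with a ~5% CV, and with noise
disabled the round trip is exact to float precision.

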
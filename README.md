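# stagesen

Multistage–senescence modelling of age-specific cancer incidence rates.

Adult cancer incidence rises roughly as a power of age — the classical
Armitage–Doll multistage picture, in which a cell must pass through *k*
sequential, stable changes before clinical cancer — and then falls again
after about age 80. `stagesen` models both phases with the
multistage-senescence incidence curve

```
ASR(t) = u^k / Γ(k) · t^(k−1) · (1 − b·t),    0 ≤ t ≤ 1/b
```

where `ASR(t)` is the age-specific incidence rate per person-year, `u`
(1/yr) is the geometric-mean stage-transition rate, `k` the (continuous)
number of carcinogenic stages, and `b` (1/yr) the senescence tumor
suppressor: the slope of a linear old-age suppression term that drives
modelled incidence back to zero at age `1/b` (about 100 years). `t` is age
for non-reproductive cancers and age − 15 for cancers of reproductive
organs. Derived statistics include the age of peak incidence
`(k−1)/(b·k)`, the lifetime cumulative probability
`Pc = u^k/Γ(k) · b^(−k) · (1/k − 1/(k+1))`, and a two-variable (age, stage)
model in which `u` is replaced by the cross-cancer regression `c·k − d`.

The package is aimed at epidemiological modellers working with
registry-style data: tables of case counts and person-years by 5-year age
group, sex and cancer type. It provides

- `stagesen.incidence_rates` — crude rates per 100,000 person-years with
  Poisson standard errors, old-age population inference from census
  fractions, observed-peak location;
- `stagesen.model_fitting` — weighted nonlinear least-squares fits of the
  model per cancer, with parameter standard errors, Wald P-values and
  significance-based inclusion rules;
- `stagesen.core_model` — the closed-form equations and derived statistics;
- `stagesen.comparative_stats` — cross-cancer comparisons (paired/Welch
  t-tests, Holm correction, Spearman/Pearson correlations, the u-on-k
  regression, ANCOVA slope comparisons);
- `stagesen.driver_genes` — decomposition of fitted stage counts into
  driver-mutation and non-driver components;
- `stagesen.synthetic_data` — a registry simulator (Poisson counts around
  model expectations on a census-like population pyramid) and packaged
  transcriptions of the published per-cancer parameter and driver tables.

## Worked example

Simulate a registry whose true parameters equal published fits, compute
rates, and refit:

```sh
python analysis/01_simulate_registry.py
python analysis/02_compute_rates.py
python analysis/03_fit_models.py
```

which prints (seed 0, 10⁷ person-years per bin below age 60):

```
pooled fits vs simulation truth (u, k, b):
  BLCA   fitted (0.0361,  8.49, 0.00981)  truth (0.0360,  8.47, 0.00980)  peak  90.0
  BRCA   fitted (0.0231,  3.73, 0.01150)  truth (0.0230,  3.72, 0.01150)  peak  78.6
  COAD   fitted (0.0302,  7.07, 0.00952)  truth (0.0300,  7.03, 0.00950)  peak  90.2
  KIRC   fitted (0.0139,  4.67, 0.01040)  truth (0.0140,  4.69, 0.01040)  peak  75.5
  THCA   fitted (0.0059,  2.69, 0.01009)  truth (0.0059,  2.69, 0.01010)  peak  62.3
```

Each line shows the refitted (u, k, b) against the simulation truth and the
fitted age of peak incidence: a bladder-like cancer with 8.5 stages peaks
near age 90, a thyroid-like cancer with 2.7 stages near 62. The remaining
scripts run the parameter-recovery experiment
(`analysis/04_parameter_recovery.py`), recompute every published
cross-cancer statistic from the packaged fixture tables
(`analysis/05_cross_cancer_stats.py` — 46/46 reproduce), and run the
driver-gene decomposition (`analysis/06_driver_decomposition.py`, printing
the unweighted regression `y = 0.14 k + 0.87`, r = 0.42 with the
endometrial outlier removed).

The same pipeline is exposed as a CLI (`stagesen simulate|rates|fit|stats|
drivers|recover|reproduce`).

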
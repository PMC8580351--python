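# Methods

## Model

The age-specific incidence rate (ASR) of an adult cancer is modelled as the
product of an Armitage–Doll multistage power law and a linear senescence
suppression term:

```
ASR(t) = a · t^(k−1) · (1 − b·t)
       = u^k/Γ(k) · t^(k−1) · (1 − b·t),     0 ≤ t ≤ 1/b.
```

Assumptions inherited from the multistage picture: a cell passes through
`k` sequential, discrete, stable changes, each occurring at the same small
per-year rate `u`, so that the hazard grows as `t^(k−1)`; `k` is treated as
a continuous positive real because fitted stage counts are non-integer.
The `(1 − b·t)` factor is an empirical tumor-suppression term, equal to
unity at birth and zero at `t = 1/b`; it has no mechanistic cell-population
interpretation here beyond a linear decline of susceptibility with age.
Beyond the support (`t > 1/b` with `b > 0`) the model evaluates to zero
rather than a negative rate: negative hazards are meaningless.

The time axis is chronological age for non-reproductive cancers and age
minus 15 years (puberty onset) for cancers of reproductive organs (PRAD,
TGCT, BRCA, CESC, OV, UCEC, UCS).

Two peak-age expressions are exposed because both appear in use for this
model family:

- `peak_age_argmax = (k−1)/(b·k)` — the true maximizer of the incidence
  curve; this is what per-cancer "model-fitted age of peak" tables contain
  and what all table-reproduction paths use;
- `peak_age_closed_form = k/(b·(k+1))` — the maximizer of the *cumulative-density*
  shape `t^k(1−bt)`, used for the illustrative stage ladder (peak ages
  67…90 for k = 2…8 at b = 0.0099). The two differ by a few years at small
  k.

The lifetime cumulative probability is the closed form
`Pc = u^k/Γ(k) · b^(−k) / (k(k+1))`, validated in the tests against
adaptive quadrature of the rate curve to a relative 1e-6 over the whole
fitted parameter box (k ∈ [1.2, 12], b ∈ [0.005, 0.03], u ∈ [0.001, 0.05]).
For degenerate fits with `b ≤ 0` the lifetime probability is undefined and
returned as NaN with a warning. The fractional reduction in lifetime risk
attributable to the senescence term (amplitude and integration limit held
fixed) is computed from both integrals and equals `k/(k+1)` exactly.
The published ladder of reductions for k = 2,3,4,6,8 lists 67, 75, 80, 85,
88%; the analytic values are 66.7, 75.0, 80.0, 85.7 and 88.9%, so the two
largest entries appear truncated rather than rounded in the source and are
not used as checks.

### Two-variable model

Across non-reproductive cancers the fitted `u` rises linearly with `k`;
substituting the regression `u = c·k − d` yields a model in age and stage
count only. Default constants are `b = 0.0099 /yr` (pooled mean of
non-reproductive b), `c = 0.0046 /yr` per stage and `d = 0.0087 /yr`, the
values recovered by this package's own unweighted regression on the pooled
parameter table (n = 21). Two caveats discovered while reproducing the
published tables:

- the per-cancer "two-variable" lifetime probabilities tabulated alongside
  the fits combine `u = c·k − d` with each cancer's *own* fitted `b`, not
  with the pooled 0.0099; `asr_two_variable` therefore accepts an optional
  per-cancer `b` override;
- at `k = 2` the transition rate `c·k − d` is a small difference of rounded
  constants, so lifetime-risk values there are irreproducible from the
  printed precision (≈25% sensitivity); k ≥ 3 values reproduce to 2–6%.

## Incidence rates

Crude rates are `cases/person-years × 10⁵` per 5-year age bin (midpoints
2.5…112.5), with Poisson standard errors `√cases/person-years × 10⁵`.
Zero-count bins get a weighting SE computed as if one case had been
observed, so inverse-variance weights stay finite and those bins stay in
the fit with low weight. Pooled-sex series sum cases and person-years
before rate computation (a re-tabulation, not an average of estimates).
Old-age denominators are inferred by splitting an 85+ total across the bins
85–89 … 110+ with census-style fractions that are assumed constant over the
registry period; only Poisson counting error is propagated, not the
uncertainty of that inference. The 95–99 bin is included in the split even
though some published enumerations omit it — omitting it would leave a
population gap. Observed peaks are reported only for ages below 105, where
registry denominators become unstable; ties break toward the younger bin.

## Fitting

Each series is fit by weighted nonlinear least squares,
`Σ wᵢ (rateᵢ − 10⁵·ASR(tᵢ))²` with `wᵢ = 1/SEᵢ²`, over bins with midpoint
at or above the start age: 50 years by default (where case counts begin to
rise), 30 for thyroid and cervical cancer, 20 for testicular cancer. All
bins through 110+ are used; the near-zero observed rates beyond the model
support are informative about `b`. Inside the optimiser the model is
clamped at zero beyond `1/b`, exactly like the data-generating curve —
an unclamped negative tail would otherwise dominate the weighted cost in
old-age bins whose substitute SEs are small.

Parameters: `a` is fit in log space (positive by construction), `k` is
bounded to (0.5, 20), `b` is free in sign (degenerate series genuinely
produce negative b). The objective is multimodal in (a, k), so
`scipy.optimize.least_squares` (trust-region reflective; bounds rule out
plain Levenberg–Marquardt) is restarted from a ladder of k guesses — the
log-log slope of the windowed data plus one, ±2 — with `a₀` chosen to match
the observed maximum and `b₀ = 0.01`; the best converged solution wins.
Noise-free curves refit to their own parameters to better than a relative
1e-6, and point estimates are invariant under rescaling all SEs.

Standard errors come from the Jacobian-based covariance
`σ²(JᵀJ)⁻¹` with `σ² = RSS/(n−3)`; `u = (a·Γ(k))^{1/k}` gets its SE by the
delta method. Parameter P-values are two-sided Wald t-tests against zero
with n − 3 degrees of freedom — the conventional choice for NLS fits, made
explicit here because no particular test is canonical. Cancers with
P(u) > 0.1 or P(k) > 0.1 are flagged for exclusion from cross-cancer
analyses, and the combined colorectal series (COADREAD) is dropped when
COAD and READ enter individually.

## Cross-cancer statistics

Every published summary depends on an exact inclusion set, so row-selection
rules are named and versioned in `comparative_stats.subset` (e.g.
`nonrepro_n21` = non-reproductive pooled rows minus LGG, PCPG and
COADREAD). Comparisons use classical paired t, Welch t with Satterthwaite
degrees of freedom, Spearman/Pearson correlations and Holm step-down
adjustment. The u-on-k regression is unweighted ordinary least squares
(the published house style); regressions for the two sexes are compared by
interaction-term ANCOVA F-tests (common slope, then common intercept given
a shared slope). The any-cancer lifetime risk combines per-cancer
probabilities with the independence complement rule `1 − Π(1 − Pcᵢ)` over
the sex's table minus COADREAD and minus the published exclusion list —
the rule and set that reproduce the printed 41% (female) and 55% (male) —
documented as a package decision because no combination rule is canonical.

## Driver-gene decomposition

Published catalog means of driver mutations per tumor are joined onto the
fitted stage counts (pooled-sex k for non-reproductive cancers,
sex-specific k for reproductive ones); non-driver stages are the
difference, which may be negative when a catalog counts more drivers than
the model finds stages. The drivers-on-k regression is unweighted OLS;
records whose *externally studentized* residual from a preliminary fit
reaches 3.0 are removed first. The externally studentized form (R's
`rstudent`) is the package's convention: it is the variant under which the
known endometrial-cancer outlier (3.63) crosses the 3.0 threshold, while
the internal form sits at 2.98. The "95% interval" reported for the percent
stage contribution of drivers is a population interval, mean ± 1.96·SD of
the per-cancer percentages — the only reading consistent with the width of
the published interval — and is descriptive, not inferential.

## Synthetic data

The simulator emulates a cross-sectional registry: independent Poisson case
counts per bin, cancer and sex around `ASR(t)·person-years`, on a
population template that is flat to age 60 (10⁷ person-years per bin by
default), declines as a Gaussian half-bell afterwards, and re-splits the
85+ tail by census-style fractions so the old-age inference path is
exercised. It does not emulate cohort or period effects, overdiagnosis
dynamics, shared-cohort correlation between bins, or susceptible-fraction
depletion; passing recovery tests therefore demonstrate statistical
identifiability of (u, k, b) under the model's own noise assumptions, not
robustness to those real-data features.

Problem sizes: the recovery experiment uses four truth cells spanning the
fitted range at 10⁵ and 10⁷ person-years per bin with 10–20 replicates
each, and the pipeline-closure tests use single registries at 10⁷ — sizes
at which median |bias(k)| < 0.05, |bias(b)| < 1e-5 and |bias(u)| < 2e-4,
comfortably inside the half-stage/5e-4/2e-3 targets, while the whole suite
runs in well under a minute.

## Numerical choices

- All power/gamma arithmetic (amplitudes, lifetime probabilities, the
  reduction ratio) is carried out in log space with one final
  exponentiation; `u^k` underflows in naive arithmetic for u ≪ 1, k ≈ 10,
  and `(u/b)^k` overflows for large k.
- Fixture tables are packaged CSVs verified against a sha256 manifest on
  load.
- Replicate seeds in the recovery experiment are derived deterministically
  from the master seed and the cell coordinates, so cells are reproducible
  independently of execution order.
- Degenerate inputs: zero-population bins are flagged invalid and excluded;
  all-zero series and windows with fewer than six bins are rejected; t = 0
  with k < 1 is rejected as divergent.

## Known limitations

- No cohort/period adjustment and no competing-risks mortality correction;
  the model is cross-sectional by construction.
- Only Poisson counting error enters the rate SEs; census-inference
  uncertainty for 85+ denominators is ignored.
- No bootstrap or profile-likelihood uncertainty; Wald intervals can be
  optimistic near the k bound or for weakly identified b.
- The extrinsic/intrinsic risk-ratio comparison requires a user-supplied
  table of published ratios, which is not redistributed here.
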
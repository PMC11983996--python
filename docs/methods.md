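# Methods

This note documents the models, numerical choices and design decisions
behind `meddiet`, in the spirit of a statistical package's methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Score construction

The adherence index follows the classical control-median dichotomization
design. Nine food components (cereals, dairy, legumes, fruits & nuts,
vegetables, fish, poultry, red meat, alcohol) are item sums in g/day;
the tenth is the MUFA/SFA ratio, with MUFA approximated by olive-oil
consumption times its MUFA density and SFA summed over every item,
olive oil included. Items outside all food groups (olive oil, butter,
sugar, tea, sweets) contribute to energy and to the SFA denominator but
to no group. Olives and dates sit in fruits & nuts; olive *oil* is
deliberately not a food group, so it feeds only the ratio and energy.

Reference medians are computed per sex from controls only, after
excluding subjects whose ratio is undefined (zero total SFA) — the
reference population is exactly the scoreable controls. The sample
median of an even-sized group is the midpoint of the two central order
statistics.

Decisions taken where the design was open:

* **Ties.** "At or above the median" is applied literally to both rules:
  a beneficial component at the median scores 1, a detrimental one at
  the median scores 0. With continuous intakes ties are rare, but the
  rule is fixed and tested.
* **Alcohol** enters as beverage g/day exactly as recorded, not as
  ethanol grams, and uses the same below-median-scores-1 rule as the
  other detrimental components.
* **No energy adjustment** is applied before the median splits; total
  energy enters only as a regression covariate.
* **High category is 6–10.** The three categories are 0–3 / 4–5 / 6–10.
* Undefined ratios are an explicit flag, never NaN arithmetic; such
  subjects are excluded from scoring with a logged count, and a score
  request for one raises.

## Conditional logistic regression

For matched set $j$ (case first), the conditional log-likelihood is
$\ell(\beta)=\sum_j [x_{j1}^\top\beta-\log\sum_m e^{x_{jm}^\top\beta}]$,
which for 1:1 pairs reduces to $-\sum_i\log(1+e^{-\beta^\top d_i})$ on
the within-pair differences $d_i$. The fitter is Newton–Raphson with the
analytic score and observed information, plus step-halving so the
likelihood never decreases. Numerical choices:

* Convergence when the largest score component is below `1e-8` or the
  relative log-likelihood change is below `1e-10`; at most 50 iterations.
  These are double-precision comfort margins, not scientific claims.
* Covariance is the inverse observed information at the optimum; 95 %
  intervals are Wald, $e^{\hat\beta\pm1.96\,SE}$ (the standard output of
  conditional-logistic software).
* **Separation.** If in every set the case attains the column maximum
  (strictly in at least one) — or symmetrically the minimum — the
  likelihood is monotone in that coefficient and no finite MLE exists.
  The fit returns `converged=False` with a `monotone-likelihood:<column>`
  flag and NaN estimates rather than a large spurious number. This check
  is sufficient, not exhaustive; multi-column separation in small strata
  surfaces instead as a non-converged fit or near-singular information.
* A singular information matrix raises, naming the dependent columns
  found by pivoted QR on the within-set-centred design.
* Sets are sorted by id before fitting, so the result is invariant to
  input order (floating-point summation order is fixed).
* Ill-conditioned information can produce tiny negative variance
  diagonals; these are clamped to zero for SE reporting.

A deliberately independent oracle (`pair_difference_oracle`) refits the
1:1 model as intercept-free binary regression on differences by
derivative-free maximization (grid plus bounded scalar search in one
dimension, Nelder–Mead otherwise). It shares no code path with the
Newton fitter and exists only for tests, where the two must agree to
1e-6; statsmodels' `ConditionalLogit` serves as a second, external
cross-check.

**Covariates.** Categorical terms enter as full indicator sets against
fixed reference levels — residence: urban; education: illiterate;
income: low; smoking: never; BMI: normal; activity: low. Age (years) and
energy (kcal/day) are continuous; age is included even though pairs are
age-matched within ±5 years, since the caliper does not remove residual
age confounding. Family history is in the adjusted set; NSAID use is
carried in the data and is available as a covariate toggle but is not in
the default adjusted model. BMI bands are the WHO cuts (18.5/25/30);
activity bands are <600 / 600–3000 / ≥3000 MET-minutes/week. The
"crude" model adjusts for age and energy only. No multiplicity
correction is applied.

**Subsites.** A case's record carries `colon`, `rectum` or `other`;
subsite analyses keep a pair iff its case matches, `other` contributes
to overall CRC only. Sex-stratified analyses reuse the all-controls
sex-specific median table rather than re-deriving medians within the
stratum.

## Synthetic cohorts

The generator emulates the study's *structure*: 1:1 pairs sharing sex
and one of five recruitment centres, ages within a 5-year caliper,
FFQ-style item intakes, and the printed case/control covariate
contrasts. Two modes are kept deliberately distinct:

* **Marginal mode** draws case and control covariates independently
  from their respective configured marginals. It reproduces *realized*
  contrasts (cases older, more obese, less urban, less active …) and is
  the right tool for calibration and plumbing checks — but it encodes no
  conditional diet effect, so it cannot validate the estimator.
* **Mechanistic mode** draws both pair members from one common
  population model, scores each against the generator-known true
  sex-specific medians, and assigns the case within the pair with the
  exact conditional probability
  $e^{x_1^\top\beta}/(e^{x_1^\top\beta}+e^{x_2^\top\beta})$, where
  $\beta$ places the configured true log-odds-ratios on the medium/high
  category indicators (optionally per subsite). The fitted conditional
  model is therefore correctly specified by construction, which is what
  parameter-recovery and type-I-error studies need. Conflating the two
  modes would make calibration circular.

Key parameter choices (defaults in `synthetic_data.py`):

* Ages are truncated normal on [18, 95]: cases (56.4, 13.9), controls
  (55.5, 13.7) years — the study's printed summaries. In marginal mode
  the control age is drawn from its own marginal truncated to the
  case's caliper window (so the case marginal is exact and the pairing
  constraint holds; the realized control mean is pulled slightly toward
  the cases'). In mechanistic mode both members are a pair-level base
  age plus at most half a caliper each, keeping members exchangeable.
  The sampled caliper is shrunk by 0.01 years so that 2-decimal
  rounding of ages can never breach the 5-year limit.
* Categorical marginals use the printed values where available (urban
  69.2 %/75.7 %, never-smokers 77.6 %/83.8 %, current smokers
  12.1 %/6.2 %, obesity 15.8 %/8.7 %, activity high 21.7 %/26.6 % and
  low 33.9 %/22.2 % for cases/controls respectively); education, income,
  family history and NSAID distributions are synthetic defaults labelled
  as such, completing each distribution plausibly for the setting.
  The activity figures are read so that controls are the more active
  group, matching the direction of the reported contrast. BMI and
  MET-minutes are drawn uniformly within the sampled category's band so
  the continuous columns round-trip to the intended categories.
* The cohort's sex split is 50/50 (not printed in the available
  summaries); centre is uniform over the five cities.
* Intakes are log-normal per component and sex — right-skewed and
  non-negative, the standard shape for dietary data — with medians and
  geometric SDs that are plausible for a North-African diet (e.g.
  cereals ≈ 330 g/day, vegetables 300 g/day, fish ≈ 40 g/day, alcohol
  1–2 g/day reflecting low consumption) and a mild male excess for
  legumes, fruits/nuts, fish, red meat and dairy. These are synthetic
  defaults: the study's median table is not reproduced in the available
  text. Components are independent by default. The synthetic
  30-item composition table splits each component across its items with
  fixed weights and carries literature-plausible densities; it is
  non-authoritative.
* The generator-known true medians equal the configured log-normal
  medians exactly for the nine food components; the ratio's true median
  has no closed form and is estimated once per intake configuration by a
  200 000-draw fixed-seed Monte-Carlo, making it deterministic and
  reusable across replicates.

What the generator does **not** emulate: the real FFQ's 255 items,
inter-component correlation (an option left at independence), recall or
selection bias, centre-specific recruitment imbalance, and subsite
aetiology beyond a configurable per-subsite effect. Passing tests
therefore demonstrate that the *pipeline and estimator* behave correctly
under the study's design, not that the study's substantive findings are
reproduced from its data.

## Validation designs and problem sizes

* **Parameter recovery** plants a true adjusted high-vs-low conditional
  OR of 0.74 (overall) or 0.73 (rectal pairs only, with roughly half of
  case subsites rectal) in mechanistic cohorts of 1516 pairs and refits
  with the full adjustment set over 20 replicates; the mean fitted OR
  must sit within 2 Monte-Carlo SE of the truth. The fitted exposure is
  the generator's true-median score category — the exact exposure the
  assignment model used — so the simulation tests the estimator, not the
  (separately tested) median re-estimation step. The true medium-category
  OR is set to the geometric midpoint between 1 and the high-category
  truth, as only the high-category values are reported.
* **Type-I error** uses 200 null mechanistic cohorts of 250 pairs and
  checks the high-vs-low Wald rejection rate at $\alpha=0.05$ against a
  3-binomial-SE band.
* **Calibration** checks simulated case age and obesity shares at the
  full cohort size (1516 pairs) against 3-SE bands.

These sizes keep the whole validation suite to a couple of minutes on a
single CPU while leaving Monte-Carlo error well inside the decision
bands.

## Known limitations

* Wald intervals can be poor in tiny strata (few discordant pairs);
  exact conditional inference is out of scope.
* The likelihood supports 1:M sets, but set construction and the oracle
  target the study's strict 1:1 design.
* The score engine fixes the component vocabulary; alternative MD
  indices (aMED, MEDAS, tertile-based variants) are out of scope.
* Sex-stratified analyses reuse the pooled-control sex-specific medians;
  re-deriving medians within a stratum is a documented alternative the
  package does not implement.
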
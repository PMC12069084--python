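# Methods

## Model and procedure

Chronic exposure of individual *i* is `x_i = Σ_c q_i(c)·m(c)/w_i`
(μg/kg bw/day) with `q_i(c)` the individual's mean daily consumption of
category *c* (g/day, averaged over surveyed days), `w_i` body weight (kg)
and `m(c)` the category mean occurrence (μg/g). The estimators treat the
consumer sample as the variability axis and the occurrence sample as the
uncertainty axis, and propagate both by the non-parametric bootstrap:

1. draw B resamples (with replacement) of the consumers;
2. independently draw B resamples of the occurrence values — *standard*
   (OIM) or *stratified within subcategory with resample sizes fixed at the
   observed stratum sizes* (sOIM, wsOIM) — and summarize each as a mean
   occurrence: pooled arithmetic mean (OIM, sOIM) or weighted mean of
   stratum means Σ_s v_s·mean_s (wsOIM);
3. combine consumer replicate *b* with mean-occurrence replicate *b*,
   compute the requested exposure percentiles of that replicate, and form
   percentile-method confidence intervals over the B replicate percentiles.

Deterministic Estimates come from the original (un-resampled) data. The
pairing of consumer replicate *b* with occurrence replicate *b* is a
one-to-one convention; since the two streams are independently seeded it
only fixes the bookkeeping, not the distributions.

Assumptions inherited from the OIM family and *not* fixed here: no
separation of intra- from inter-individual variation (each individual is
reduced to a mean over surveyed days) and no covariate modelling. What the
refinements fix: sOIM drops the assumption that occurrence values are
identically distributed within the category (it conditions resampling on an
a-priori stratification), and wsOIM drops the assumption that every
analysed sample contributes equally to the category mean.

## Weights

* **wsOIM\*** (consumption-aware): `v_s` = (across-subject total mean daily
  consumption of subcategory s) / (category total). With the default
  synthetic survey this lands near {SO: 0.07, OO: 0.77, EVOO: 0.16}.
* **wsOIM°** (sensitivity): fixed vectors concentrating 8/10 of the weight
  on one stratum ({.8,.1,.1} and permutations). They are deliberately more
  extreme than any plausible consumption-derived vector; their role is
  tipping-point analysis, not estimation.

Weights are validated to be non-negative, to sum to 1 (tolerance 1e-9) and
to cover exactly the strata of the table they are applied to.

## Left-censored data

Two treatments, kept deliberately separate:

* **Substitution** for exposure computation: lower bound 0, middle bound
  LOD/2 (default, and the only scenario used by the simulation study),
  upper bound LOD.
* **Censored maximum likelihood** for distribution fitting: density at
  uncensored points, CDF at LOD for censored points. No substitution enters
  the likelihood. Families: normal, lognormal (meanlog/sdlog
  parameterization), gamma (shape/scale), Weibull (shape/scale); selection
  by AIC = 2k − 2·loglik (k = 2 throughout), exact ties broken by the fixed
  family order normal → lognormal → gamma → weibull with a logged warning.
  The normal is fitted without truncation at zero although concentrations
  are non-negative; for clearly positive-skewed data it loses the AIC
  contest anyway, which is the role it plays here.

Optimization is Nelder-Mead on a log-transformed scale for positive
parameters, started from moment estimates (censored points temporarily at
LOD/2 for the starting values only), with three jittered restarts before a
fit error is raised. At least 3 uncensored values are required.

## Numerical conventions

* All quantiles — exposure percentiles, eCDFs and percentile-method CI
  endpoints — use linear interpolation between order statistics
  (`numpy.quantile`, method "linear").
* Two independently seeded `numpy` Generator streams: one for consumer
  resampling, one for occurrence resampling. Identical seeds and inputs
  give bit-identical outputs.
* Degenerate inputs: a single consumer and single occurrence value yield
  zero-width CIs (valid); empty strata, non-partitioning strata, zero total
  consumption (for consumption-aware weights) and missing occurrence for a
  consumed category raise specific errors rather than producing numbers.
* CSV I/O writes floats with `%.17g` and reads with round-trip float
  parsing, so estimate files reload bit-exactly.

## Simulation study

`SimulationConfig` holds the case-study design: seed-oil occurrence
lognormal with meanlog μ̂ = −1.48 (the fitted sdlog σ̂ = 1.20 is recorded
for fitting tests), generating sdlog 1 for all strata, olive-oil meanlog
α = log(1.5 + exp(μ̂)) (recomputed, never stored) so the OO median sits
1.5 μg/g above SO, EVOO meanlog log(LOD) with LOD = 0.035 μg/g so half its
draws are censored, 1000 values per stratum, B = 1000 replicates, TDI =
2 μg/kg bw/day, and the four weight vectors above. The middle-bound rule is
applied uniformly to all strata (censored draws are possible, if rare, in
SO and OO too).

`run_study` runs the six-cell grid (OIM, sOIM, wsOIM\*, three wsOIM°). Per
replicate it simulates one fresh occurrence dataset and draws from it one
standard resample (feeding OIM) and one stratified resample whose stratum
means feed sOIM and every wsOIM cell; a single consumer-resample stream is
shared by all cells. Sharing datasets and resamples across cells does not
change any cell's marginal distribution — it only removes between-cell
Monte-Carlo noise, which is what makes the grid comparable at moderate B.
DEs are computed on one dedicated reference dataset simulated from its own
child seed (with simulated occurrence there is no canonical "original"
dataset; one shared reference keeps DEs comparable across cells).
`scale` shrinks the replicate count proportionally (minimum 10); the test
suite runs the grid at scale 0.1–0.5 and the examples at 0.1, with the
full-scale defaults left to explicit runs.

## Risk characterization and robustness

The UTP (95th-percentile exposure) is compared with the TDI through its 95%
percentile CI: `below_tdi` if the upper bound is under the TDI, `above_tdi`
if the lower bound exceeds it, `not_different` otherwise. This CI-inclusion
rule is our operationalization of "not statistically different at 0.05";
likewise, two estimates are flagged "different" only if each DE falls
outside the other's CI. Both are heuristics (percentile CIs are not exact
tests) and are labelled as such in outputs.

Robustness follows a tipping-point rule: a primary conclusion is robust
unless some wsOIM° scenario yields a verdict of strictly higher risk under
the ordering below_tdi < not_different < above_tdi; the scenarios that flip
it are reported. The rule is monotone — adding scenarios can only remove
robustness.

## Synthetic consumption survey

`simulate_consumers` is a synthetic stand-in for an adult dietary survey,
not an emulation of any real survey's design (no households, multi-day
diaries or sampling weights). Defaults, chosen once as realistic for an
adult Mediterranean population: consumer probabilities {SO: 0.30, OO: 0.90,
EVOO: 0.50}; among-consumer amounts lognormal with sdlog 0.5 and meanlogs
set so expected subcategory totals are in ratio 0.07 : 0.77 : 0.16 with an
expected total of ≈ 30 g/day of vegetable oil; body weight normal(70, 12) kg
truncated at 35 kg by redraw; ages uniform on 18–79. Non-consumers of the
category are retained and contribute zero exposure. Because amounts are
independent lognormals, the generator does not reproduce real-data features
such as day-to-day correlation, age/body-weight/consumption dependence, or
reporting error — passing tests therefore validate the estimators'
mechanics and orderings, not survey realism.

## Problem sizes

The test suite and examples use scaled-down sizes chosen to keep runs
comfortable on a laptop: 100–1000 occurrence values per stratum, 120–500
consumers (2830 in the headline example, matching the case-study survey
size), B = 40–1000, 10–100 repeated experiments for stochastic properties.
The statistical checks state their own tolerances (e.g. median separation
±0.05 at 100,000 draws; censoring fraction ±0.01; CI-narrowing win rates
≥ 90–95%; MLE recovery within 3 standard errors).

## Known limitations

* Single-contaminant, flat category/subcategory labels; no food
  classification hierarchy.
* Percentile-method CIs only (no BCa or studentized intervals); the
  stratified bootstrap must not be used to compensate for tiny strata.
* The censored normal's support mismatch noted above.
* The "statistical difference" verdicts are CI heuristics, not tests with
  controlled size.
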
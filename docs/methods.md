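# Methods

`garddr` analyses dose–response data from the GARDskin assay, an in-vitro
test for skin sensitization in which a dendritic-like cell line is exposed
to a chemical and a frozen support-vector classifier converts the induced
biomarker expression into a signed **decision value** (DV); DV ≥ 0
classifies the sample as a sensitizer. The package estimates a chemical's
sensitizing potency as **cDV0** — the lowest exposure concentration at
which the DV turns positive — and benchmarks it against animal (LLNA EC3)
and human (NOEL) reference potency data. DVs are inputs throughout: the
package never computes them from gene expression.

## Dose–response model

The response curve is the four-parameter log-logistic (4PL)

    f(x; b, c, d, e) = c + (d − c) / (1 + exp(b (log x − log e))),

with `x` the concentration in µM, `c`/`d` the lower/upper response limits,
`b` the slope and `e` the midpoint (ED50, µM). Two constraints reflect the
assay's logic:

* `c` is **fixed** at the decision value of unstimulated controls (what
  the classifier returns when nothing happens), supplied per dataset as
  `control_dv` and required to be negative;
* `b < 0`, so fitted curves are monotonically non-decreasing in
  concentration.

Errors are modelled as i.i.d. Gaussian on the DV scale, so the
least-squares fit is the maximum-likelihood fit. The free parameters are
(b, d, e); the Gaussian error variance is profiled out as RSS/n.

### Fitting

The residual surface of the 4PL can be multimodal under noise, so the fit
is a deterministic multi-start: the midpoint starts at the geometric mean
of the assayed range, at the concentration whose DV is closest to the
curve midpoint and at both range extremes; the slope starts from a logit
linearisation of centred responses plus fixed fallbacks (−0.7, −2.5); the
upper limit starts at max(DV). Each start is polished by
Levenberg–Marquardt on an unconstrained reparameterisation — b = −(10⁻⁶ +
exp β) enforces the slope bound smoothly (the box bound b ≤ −10⁻⁶ of the
constrained formulation), u = log e keeps the midpoint positive — with
analytic Jacobian, ftol 1e−10, xtol 1e−8, and at most 600 function
evaluations per start. The best-RSS solution wins. Optimizer failure never
raises: the `converged` flag is cleared and the best-found parameters
retained. A fit whose upper limit collapses to or below the fixed lower
limit (d ≤ c) is degenerate and also flagged not converged. β and u are
clipped to generous fixed windows (±40, ±60) purely to keep exp() finite
on degenerate flat data.

The reported parameter covariance is the Gauss–Newton approximation
σ̂² (JᵀJ)⁻¹ on (b, d, log e), with σ̂² = RSS/(n − 3); it is undefined when
n = 3, when the fit is degenerate or when the normal matrix is singular.

### No-effect test

Concentration dependence is tested by a likelihood-ratio comparison of the
4PL against the best horizontal line (the shape expected when
concentration has no effect). Under the Gaussian error model

    LR = n · ln(RSS_flat / RSS_4PL),

referred to a χ² upper tail. The degrees of freedom are set to 2 — the
4PL has three free mean parameters, the flat line one. The χ² reference is
approximate because the constraints (b < 0; effectively d ≥ c) put part of
the null on the parameter-space boundary, which makes the test
conservative: the observed type-I error at nominal 0.05 on simulated
flat-line data is ≈ 0.02–0.03 (recomputed by `scripts/acceptance.py` and
`tests/test_acceptance.py`). A degenerate fit reports LR = 0, p = 1.

## cDV0 estimation

**Model-based.** Solving f(x) = t (t = 0 by default) gives the closed form

    cDV0 = e · ((d − c)/(t − c) − 1)^(1/b),

returned as censored "NS" when the fitted upper limit never reaches the
threshold (d ≤ t), when the lower limit already exceeds it (c ≥ t) or when
the fit did not converge. The 95% confidence interval is an
inverse-regression approximation: the variance of log cDV0 is obtained by
the delta method from the (b, d, log e) covariance and the interval
exponentiated, so the bounds are positive and asymmetric in concentration.
A bound is NA when the covariance is unavailable or an endpoint diverges.
A Fieller-type interval would be a natural alternative; it is not
implemented. The data type can represent a censored estimate that still
carries a finite lower confidence bound (such entries occur in the
bundled reference table), but the estimator itself does not produce them —
the delta method needs a point estimate.

**Linear interpolation.** The lowest-concentration pair of adjacent
assayed points with DV₋ < t ≤ DV₊ is interpolated linearly:

    cDV0 = c₋ − DV₋ (c₊ − c₋) / (DV₊ − DV₋).

Its locality makes it robust to departures from the sigmoid shape (e.g. an
early plateau followed by a second rise), which is why it is the default
estimator for benchmarking. Censoring: "NS" when no DV reaches the
threshold; "<cmin" when already the lowest assayed concentration is
positive, because the true crossing then lies below the assayed range — a
left-censored outcome, not a number.

To reduce the impact of noise on which point counts as positive, a centred
**running median** (window 3, symmetric window shrinking at the edges) can
be applied first. In the automatic mode it is applied only when the sign
pattern of (DV − t) flips more than once — a single crossing needs no
smoothing, repeated flips indicate chatter. Window and trigger are both
configurable.

`compare_estimators` runs both methods and flags chemicals where one is
censored and the other defined, or where the estimates differ more than
2-fold (configurable); flagged curves are left to the analyst, never
auto-excluded — U-shaped responses in particular are a data-quality
question, not a statistical one.

## Concentration-series design

Exposure concentrations form a descending geometric ladder with ratio 3/5:
c_i = c_input · (3/5)^(i−3) for i = 1..12, so the top of the ladder sits
two steps above the assay input concentration. The ladder is capped at
500 µM (the standard upper concentration limit); when the two-steps-above
anchor would exceed the cap, the whole 12-step ladder is re-anchored to
descend from the cap — chemicals assayed at a 500 µM input are then tested
at and below 500 µM — with plain truncation available as an alternative.
After cytotoxicity screening, non-viable concentrations and (by default)
the lowest step are deselected, typically leaving eight to nine
concentrations; every exclusion is logged.

## Benchmarking

cDV0 (µM) is converted to mg/L through the molecular weight so chemicals
are comparable on a weight basis, then correlated — Pearson, on log-scale,
p-value from the two-sided t distribution with n − 2 df — against LLNA EC3
(%) and human NOEL (µg/cm²). Censored entries (NS/ND/NA) drop out of the
pairing, which fixes n per metric. GHS sub-categories come from EC3 with
the inclusive 2% cutoff (1A ≤ 2% < 1B); the class-separation report sorts
chemicals by cDV0 and lists the 1B chemicals ranking below any 1A
chemical.

The packaged reference table (`resources/table1_reference.csv`) carries
the 29 study chemicals (22 sensitizers, 7 non-sensitizers) with their
printed potency values and censoring tokens, plus a molecular-weight
column compiled from chemical identity; for the mixture benzalkonium
chloride the molecular weight is back-computed from the table's paired
µM/mg-L values. Loading validates the µM↔mg/L consistency of every row at
2% relative tolerance; the dimethyl fumarate row fails that check (the
printed µM and mg/L values imply different molecular weights), which is a
rounding/consistency defect of the source table itself — the loader warns
and keeps both printed values.

## Synthetic data

The simulator generates what the analysis assumes: DVs from a 4PL with the
lower asymptote at the control DV, plus homoscedastic Gaussian noise on
the DV scale. Defaults: DV span roughly −1 to +1 (the classifier's typical
output range), noise sd 0.1 — a convention, since the true DV noise
magnitude is not quantified anywhere — on the nine-step 3/5 ladder
re-anchored at 500 µM. Two deterministic contamination modes reproduce the
pathological shapes seen in practice: `u_shape` adds a positive bump (in
log-concentration) at the lowest doses, and `two_phase` adds an early
steep rise to a barely-positive plateau ahead of the main transition.
Panels draw sensitizer crossing concentrations log-uniformly over 1–500 µM
and back-solve the midpoint so the true cDV0 is exact by construction;
non-sensitizers are flat at the control DV plus noise. All randomness runs
through one `numpy` generator per entry point, so a seed fixes the panel
bit-for-bit.

What passing simulation tests shows — and does not. The generator matches
the model's own assumptions, so recovery results (true-vs-estimated log
cDV0 correlation ≈ 0.99 at noise sd 0.1, CI coverage ≈ 0.90, type-I error
≈ 0.02–0.03) demonstrate internal correctness of the estimation machinery,
not robustness to real-data pathologies: heteroscedastic or non-Gaussian
DV noise, model misspecification beyond the two scripted contamination
modes, cytotoxicity correlated with response, and between-replicate
variability are not emulated. Real per-chemical raw titration data are not
deposited anywhere, so per-chemical reproduction of the reference table's
cDV0 values is out of reach by design; the bundled table instead anchors
the benchmark statistics end-to-end.

## Numerical and I/O conventions

* Problem sizes in the test and acceptance harnesses: 1000 flat-curve
  simulations for the type-I error, 500 draws for CI coverage, 200+
  synthetic sensitizers for recovery, 1000 random parameter sets for the
  closed-form-vs-bisection check.
* Censoring is encoded as a status column (NS/"<cmin"), never as a
  sentinel numeric.
* Pipeline CSVs serialize numerics at 6 significant digits so reruns are
  byte-comparable; the raw-data writer uses full `repr` precision and the
  reader parses with round-trip float precision, so datasets survive a
  write/read cycle exactly.
* The input schema has no control-DV column in its mandatory part; an
  optional `control_dv` column (constant per chemical) or the reader's
  `default_control_dv` argument (−1.0) supplies the fixed lower asymptote.

## Known limitations

* The χ²(2) reference for the no-effect test ignores the boundary
  constraints; the test is conservative rather than anti-conservative.
* Delta-method intervals undercover slightly at small n relative to the
  nominal 95% (observed ≈ 0.90 at n = 9); Fieller-type intervals are not
  implemented.
* Left-censored ("<cmin") and non-crossing ("NS") outcomes carry no
  numeric value and silently drop out of correlations; with many censored
  chemicals the pairing n shrinks accordingly.
* Only the 4PL family is fitted; hormesis-type (e.g. Brain–Cousens) or
  Weibull shapes are out of scope.
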
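# Methods

## Problem and model

Large monotherapy viability screens measure, for thousands of cancer cell
lines, the fraction of cells surviving a drug at a given concentration
relative to an untreated control (percent relative viability: 0 = complete
kill, 1 = untreated level; the metric cannot distinguish cytotoxic from
cytostatic action).  This package predicts the efficacy of drug
*combinations* from those monotherapy measurements alone, under two
null-interaction hypotheses:

**Independent drug action (IDA).**  A combination's effect on a cell line
equals the effect of its single best constituent drug.  For drugs A…Z with
viabilities `EA_k … EZ_k` in cell line k and n complete-case lines,

    mu_combo,IDA = (1/n) * sum_k min(EA_k, …, EZ_k)

on a viability-oriented panel; for effect-oriented metrics (higher = more
effective, e.g. viability reduction) the per-line `min` becomes `max`.
The surrounding prose conventions for the two orientations are easy to
invert; the implementation keys the `min`/`max` choice off an *explicit*
panel orientation attribute and never infers it from data.  IDA uses raw
viabilities unclamped — screen noise legitimately produces values below 0
and above 1, and clamping them would bias per-line minima.

**Bliss independence** (comparator).  Drugs kill independently, so
per-line combined survival is the product of per-drug survival
probabilities:

    mu_combo,Bliss = (1/n) * sum_k PA_k × … × PZ_k

Bliss is only defined for probabilities, so each component viability is
clamped to [0, 1] before the product (and an effect-oriented panel is
rejected outright).

Both means are taken over the *complete-case* cell-line set: lines with a
usable estimate for every component.  No imputation.  Default minima are
50 lines for pan-cancer analyses and 3 for cancer-subtype analyses, both
overridable.

## Dose–response fitting

Clinically relevant concentrations are rarely tested directly, so
viability at an arbitrary dose is predicted from a four-parameter
log-logistic (LL4) fit per (cell line, drug):

    f(x) = c + (d − c) / (1 + exp(b (ln x − ln e)))

with slope `b` (b > 0: viability decreases with dose), lower asymptote
`c`, upper asymptote `d` (= f(0), the untreated level) and inflection
`e` in µM (f(e) = (c+d)/2).  Choices:

- **Initialization:** d₀ = max observed viability, c₀ = min, e₀ = tested
  dose whose mean response is nearest the half-range, b₀ = 1.  Up to
  3 jittered restarts on non-convergence; best residual sum wins.
- **Bounds:** c, d ∈ [−0.5, 1.5] (raw screens overshoot both ends),
  e ∈ [min dose/100, max dose×100], |b| ≤ 20.  These stabilize fits
  without truncating realistic screen noise.
- **Covariance:** heteroskedasticity-consistent sandwich estimator
  (HC0 analogue for nonlinear least squares) by default,
  `(JᵀJ)⁻¹ Jᵀ diag(r²) J (JᵀJ)⁻¹`; HC1 (small-sample scale) and classical
  homoskedastic covariance are config options (`cov_type`).  The exact
  sandwich variant is a genuinely open choice; HC0 is the simplest
  consistent one.  A singular information matrix falls back to a
  pseudo-inverse and is flagged.  The matrix is projected to symmetric
  PSD by flooring eigenvalues at zero.
- **Prediction SE:** delta method, `se = sqrt(gᵀ Σ g)` with g the LL4
  gradient in (b, c, d, e).  At dose 0 the gradient is (0, 0, 1, 0), so
  the SE reduces to the SE of d.  A floor of 1e-6 keeps bootstrap draws
  well-defined for zero-residual fits.
- **Extrapolation:** doses above the maximum tested concentration are
  flagged; doses above 2× the tested maximum are refused (mirroring the
  clinical admission rule that relevant concentrations be ≤ 2× the tested
  range).  Between 1× and 2× the prediction is allowed but flagged, since
  the ≤2× admission rule implies extrapolation in that band is used.
- **Few-dose designs** (e.g. 3-dose combination screens): curve fitting is
  impractical, so `panel_from_observations` takes viability directly from
  the measured value at the exact requested dose, with SE from the
  replicate spread (sd/√n) or a user default.  `fit_ll4` itself requires
  ≥ 2 distinct positive doses and marks fits from < 4 distinct doses as
  `underdetermined`.
- Constant-response data yields a flat fit (c = d) flagged `degenerate`.

At the package's default synthetic study conditions (8 log-spaced doses
over 0.01–10 µM × 3 replicates, Gaussian noise sd 0.05, slopes
b ~ U(0.5, 3)), ln e is recovered with a median absolute error of about
0.1; oracle-initialized fits do no better, so this is the information
limit of that design (shallow-slope curves barely complete their
transition inside three decades), not an optimizer artifact.

## Clinical translation

Mean predicted viability is mapped to hazard by the identity on the
fraction scale — viability 1 ↔ hazard 1 (all cancer cells alive relative
to untreated), viability 0 ↔ hazard 0 — an acknowledged simplification;
no alternative mapping is defined, so none is implemented.  Negative
predicted means floor at hazard 0 (hazards are non-negative); means above
1 pass through with a log message (HR > 1 is meaningful: test worse than
control).  The hazard ratio of a test vs control therapy is the ratio of
their mean viabilities, computed on an enforced shared cell-line set.

**Trial power.**  Power of a log-rank test with m observed events,
experimental:control allocation ratio k and two-sided level α is the
Freedman-type approximation

    power = Φ( √(k·m) · |HR − 1| / (k·HR + 1) − z_{1−α/2} )

This is the documented closed form of the `powerCT.default0` function of
the R package powerSurvEpi (Freedman 1982, *Stat Med* 1:121–129): that
function computes `pnorm(sqrt(k*m)*abs(RR-1)/(k*RR+1) - qnorm(1-alpha/2))`.
The formula was checked against that documented form and against its
limits before freezing: at HR = 1 it reduces to α/2 exactly; it is
strictly decreasing in HR on (0,1), strictly increasing in m for HR ≠ 1,
and tends to 1 as m → ∞.  Trials are classified "likely to succeed" at
power ≥ 0.80 by default (boundary counts as success).  Multi-arm trials
are handled as pairwise control-vs-experimental comparisons; a missing
allocation ratio defaults to k = 1.

**Prospective ranking.**  Combinations are ranked against their best
constituent (or an explicit multi-drug backbone treated as a single
reference) with

    IDAcomboscore = Δvia − Δvia × HR_C/Mbest = Δvia · (1 − HR_C/Mbest)

where Δvia = (best-reference mean viability) − (combination mean) and
HR_C/Mbest their ratio.  The score is 0 exactly when the combination
equals its best reference and positive iff it beats it.  Pairwise score
matrices evaluate each drug at its clinically sustained plasma
concentration (Csustained: the maximum plasma level sustained ≥ 6 h after
administration; when several published values exist, the highest is
used), capped at 2× the tested range.  A display cutoff (0.004 in
pan-cancer use, derived from heatmap cluster boundaries) optionally drops
drugs with no promising partner.  Dose-grid scans evaluate the mean IDA
viability surface over per-drug grids from 0 (upper asymptote) to
Csustained, with the best-monotherapy plane for reference.

## Uncertainty: semi-parametric bootstrap

Per simulation: (1) every panel cell is redrawn as v* = v̂ + z·se with
z ~ N(0,1); (2) per-line therapy efficacies are recomputed under the
relevant model; (3) cell lines are resampled with replacement; (4) mean
efficacies are taken; (5) the statistic (HR, power, IDAcomboscore) is
evaluated.  The SE is the SD of the simulated statistics.  Defaults:
10,000 simulations for trial comparisons, 1,000 per combination in
prospective scans.

**Coupling.**  When two compared therapies share a compound, the same
standard-normal deviate drives that compound's draw in both, so shared
components move together; identical therapies then give HR ≡ 1 with SE
exactly 0.  Coupling keys on the (cell line, drug, concentration) triple —
one panel column — so a drug shared at *different* concentrations is not
coupled (that would require simulating curve parameters instead of
deviates; deviate coupling is used because it is simpler, faster and
works even when only measured viabilities and SDs exist, with no fitted
curves).  Deviate coupling rather than curve-parameter simulation is the
deliberate design; parameter simulation is an acknowledged, unimplemented
alternative.

**Details.**  Confidence intervals are normal-approximation
(point ± z·se) by default with percentile intervals as a config option
(the underlying convention is stated only as "SD-based", so both are
provided and the default documented).  Randomness uses one root seed with
counter-derived substreams (one generator per simulation index), so
results cannot depend on evaluation order.  Statistics that are exactly
invariant across simulations report SE 0 exactly (no summation dust).  A
statistic failing in > 50% of simulations aborts with diagnostics;
isolated failures are dropped and counted.  The empirical null
probability of a score is the fraction of simulated scores ≤ 0; a raw 0
is additionally reported as "< 1/n_sims" (the raw 0 is kept for FDR
input, the bound for human reading).  Benjamini–Hochberg adjustment (via
statsmodels) controls FDR across combinations, with FDR ≤ 0.05 the
conventional significance line.  Note BH is a step-up envelope, not a
projection: re-adjusting adjusted values can only push them up.

Only random measurement error and cell-line sampling are modeled.
Systematic errors (drug dilution, counting, protocol differences between
screens), the representativeness of the cell-line panel for any patient
population, and uncertainty in the clinically relevant dose are not — so
these SEs are lower bounds, not hypothesis-test-grade uncertainties.

`subsample_stability` quantifies how prediction dispersion grows as the
cell-line panel shrinks (subsets without replacement, SD of the mean
prediction across repetitions): dispersion rises steeply below ~50 lines,
which motivates the pan-cancer minimum.

## Synthetic data: what it emulates and what it does not

`generate_screen` emulates the shape of large pharmacogenomic screens:
per (line, drug) LL4 truth with d = 1 (anchored at the untreated level),
c ~ U(0, 0.6) (partial-kill floors), ln e ~ N(0, 1) (potencies spread
over ~1.5 decades around 1 µM), b ~ U(0.5, 3); 8 log-spaced doses over
0.01–10 µM × 3 replicates; homoskedastic Gaussian noise sd 0.05 by
default, with a heteroskedastic mode (sd ∝ viability) to exercise the
sandwich-covariance path; single-site replicate structure by default.
`generate_combo_measurements` produces per-line combination measurements
as the null-model value (min under IDA truth, clamped product under
Bliss) plus an interaction offset (negative = synergy, positive =
antagonism) plus noise.

Not simulated: plate and edge effects, batch structure, systematic
dilution errors, and any biological interaction structure beyond the
additive offset.  Passing tests therefore demonstrate correctness of the
estimator pipeline under its own assumptions — not predictive validity on
real screens, which depends on data the package does not ship.

## Replicate and identifier handling

Multi-site screens are restricted, per (cell line, drug) unit, to the
site with the most experiments (protocol differences between sites make
pooling inappropriate); ties break lexicographically by site id and are
logged.  Remaining replicates at the same (line, drug, dose) are
averaged.  The operation is idempotent.  Identifier harmonization applies
a user-supplied explicit mapping (cross-screen naming differs); unmapped
names pass through unchanged so single-dataset runs need no mapping, and
conflicting mappings are a configuration error.  Fuzzy name matching is
deliberately out of scope.

Viability is stored as a fraction (1 = untreated); percent-scale input
requires an explicit flag and is never guessed.  Raw values outside
[0, 1] are preserved at ingestion — clamping is model-specific (Bliss
only).

## Problem sizes used in tests and the acceptance script

Engine-vs-enumeration agreement uses 500 random panels (≤ 10 lines,
≤ 4 drugs).  Dose–response recovery uses 500 (line, drug) pairs — large
enough to keep the Monte-Carlo error of the median small.  The
sandwich-vs-classical covariance comparison uses 4,000 points for the
same reason.  Bootstrap contracts run at the full 10,000 simulations;
CI coverage uses 200 replicate experiments of 40 lines with 400
simulations each.  End-to-end self-consistency uses 15 drugs (105
combinations) on 15-line screens.  These sizes are the package's own
choices balancing Monte-Carlo precision against quick iteration.

## Known limitations

- The viability→hazard identity is a strong simplification; it ignores
  endpoint differences (PFS vs OS), pharmacokinetic interactions and
  dose-schedule effects.
- IDA ignores within-patient drug interactions by construction; it is a
  null model, and injected synergy makes its predictions conservative
  (it underestimates combination kill).
- ln e recovery precision at the default synthetic conditions is ~0.1
  (information-limited for shallow slopes over three decades).
- Coupling across differing concentrations of a shared compound is not
  modeled (would need curve-parameter simulation).
- No synergy estimation of any kind: Bliss is a comparator null model
  here, not an interaction measure.
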
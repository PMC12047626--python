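# Methods

## The model

`grtmeta` analyzes two-stage metamemory experiments in which, on every
recall failure, a participant reports a binary metacognitive state
(tip-of-the-tongue yes/no, or feeling-of-knowing high/low), makes a
two-choice recognition decision, and rates confidence in that decision.
Each trial belongs to one of three stimulus conditions: *correct name*
(the probe matches the target), *incorrect name* (it does not), and
*catch* (no correct answer exists).

The core model is a two-dimensional general recognition theory (GRT)
model: each stimulus condition generates bivariate Gaussian evidence
(x, y), where x drives the recognition/confidence response and y the
metacognitive report. At the group level the three distributions have
free means and correlations but unit marginal variances, and the catch
distribution is centred at the origin. Individual differences follow the
GRT-wIND construction: participant *i* perceives the shared distributions
with axis variances

    Var_x = 1 / (kappa_i * lambda_i),   Var_y = 1 / (kappa_i * (1 - lambda_i)),

where `kappa_i > 0` is global scaling (attention/precision) and
`lambda_i` in (0, 1) splits it between the axes; correlations are
unaffected. Each participant owns three decision criteria, all
axis-parallel (decisional separability on both axes): a metacognitive
criterion `c_y` (report the state present iff y > c_y) and two confidence
criteria `c_x1 < c_x2` partitioning x into *confident-incorrect*,
*not-confident* and *confident-correct*. The criteria therefore cut the
plane into 2 x 3 rectangles, and the response distribution per stimulus
is an exact 6-cell multinomial.

Confidence enters the model at two levels, not four: ratings 3–4
("somewhat"/"very" confident) are collapsed to *confident* and 1–2 to
*not confident* before aggregation, which keeps every multinomial cell
populated and the model parsimonious. The descriptive analyses (below)
use the raw 4-level scale.

### Rectangle probabilities

Cell probabilities are bivariate-normal rectangle probabilities. They
are computed through Owen's T function (exact to double precision,
vectorized), not by generic numerical integration. Only the two interior
grid corners (c_x1, c_y) and (c_x2, c_y) need the bivariate CDF; every
other corner involves an infinite edge and reduces to a univariate
normal CDF.

## Maximum-likelihood fitting

The free parameters are the four famous-condition means, three
correlations, and five numbers per participant, optimized jointly on an
unconstrained scale (atanh for correlations, log for kappa, logit for
lambda, and `c_x2 = c_x1 + exp(gap)` for the ordered criteria). The
objective is the multinomial log-likelihood (multinomial coefficient
omitted — constant in the parameters). L-BFGS-B maximizes it from
`n_restarts` (default 100) random starting configurations; the best
restart wins. Gradients are central finite differences evaluated in one
batched vectorized pass, so a full gradient costs about two likelihood
evaluations of wall time.

Numerical choices:

* **Probability regularization.** Cell probabilities are differences of
  CDF values, so their absolute accuracy bottoms out near 1e-15; below
  that the computed value flickers between 0 and roundoff junk as
  parameters move, which turns `log p` into a discontinuous surface and
  breaks the line search. The fitting objective therefore uses
  `log(p + 1e-12)`. The regularizer is far below any probability a cell
  with observed counts attains at an optimum (at least 1/trials), so the
  MLE is unaffected in practice. The reference `log_likelihood` function
  documents a 1e-300 floor instead, matching the textbook definition.
* **Bounds.** Generous box bounds on the unconstrained vector
  (|mean| <= 20, |atanh rho| <= 6, |log kappa| <= 12) keep the line
  search out of numerically degenerate territory; they sit far outside
  any plausible optimum.
* **Convergence.** `ftol = 1e-8` on the objective, at most 2,000
  iterations per restart. Restarts draw starting points from child seeds
  of the master seed, so results are independent of execution order.

### Identifiability

Fixing the catch mean at the origin and the group variances at 1 does
not fully pin the scale: the likelihood sees criteria and means only in
units of each participant's per-axis noise SD, and the per-participant
precisions `kappa*lambda` and `kappa*(1-lambda)` are free, so the x and
y axes can each absorb an arbitrary common stretch (a two-parameter
orbit). The fitted model is renormalized so the *geometric mean* across
participants of `kappa*lambda` and of `kappa*(1-lambda)` is 1 on each
axis — the "neutral" participant (kappa = 2, lambda = 0.5) has unit
noise. Any anchor choice is observationally equivalent; recovery scores
compare fitted and true models after applying the same anchor to both.

An axis-reflection convention (correct-name mean on the positive x side)
is enforced through the starting distribution. With labelled response
categories the reflection is *not* a likelihood invariance — the data
identify the sign — so no post-hoc reflection is applied; the convention
only protects pathological starts.

### Goodness of fit

`variance_accounted` reports 100 * r^2, the squared Pearson correlation
between observed cell proportions and model probabilities pooled over
all participants, stimuli and cells. (1 - SSE/SST is a defensible
alternative; r^2 is the shipped default.)

## The type-2 SvM curve

For each metacognitive evidence level y the curve reports two
quantities, both at the group level (unit variances):

* **Relative likelihood** `L(y)`: the equal-weight mixture of the two
  famous conditions' y-marginal densities divided by the catch marginal.
  Equal weights reflect equal presentation rates. L(y) converts the
  binary report into a graded state-strength axis.
* **Conditional meta-d'**: slice the model at height y. Each stimulus's
  conditional x-distribution is Gaussian with mean
  `mu_x + rho*(y - mu_y)` and SD `sqrt(1 - rho^2)`. Together with the
  group-level reference confidence criteria this implies 3-category
  confidence probabilities for the correct- and incorrect-name
  conditions; conditional meta-d' is the sensitivity of the
  equal-variance SDT observer (means +/- meta_d/2, unit SDs, free
  criteria t1 < t2) whose category probabilities best match them.
  The discrepancy is unweighted least squares over the six probabilities
  (a KL-divergence option is provided); optimization uses
  Levenberg-Marquardt from 10 starts (one moment-based closed-form
  start, the rest randomized from a fixed seed), and each grid point
  warm-starts from its neighbour. meta-d' is positive when
  confident-correct responses are more probable under the correct-name
  condition. When the two correlations are equal the conditional model
  *is* an equal-variance SDT observer and the fit is exact with
  meta_d = |Delta conditional mean| / sqrt(1 - rho^2).

The **objective criterion** y\* solves L(y\*) = 1 — with equal priors and
variances, the boundary an optimal observer uses to categorize their own
metacognitive states. It is found by bracketed root finding (tolerance
1e-10) on a dense scan of [-10, max mu_y + 10]; if several roots exist
(possible when the famous y-means differ) the largest is returned with a
warning, matching the operative low/high boundary in the right tail.

**Reference criteria and participant positions.** The curve is a
group-level object, but criteria are per-participant and live in
participant-scaled coordinates. Each participant's confidence criteria
are mapped into group coordinates by multiplying by
`sqrt(kappa*lambda)` (their x-axis precision), then averaged
arithmetically; metacognitive criteria map by
`sqrt(kappa*(1-lambda))` and are displayed as positions
`L(c_y_i * sqrt(kappa_i*(1-lambda_i)))` on the likelihood axis. This is
one defensible aggregation rule; it is isolated behind
`aggregate_reference_criteria`.

The default grid is 201 evenly spaced y values on
[-3, max famous mu_y + 3], covering > 99.8% of the marginal evidence
mass.

## Parametric bootstrap

Confidence bands come from simulating `n_boot` (default 1,000) datasets
from the fitted model with the observed per-row trial totals, refitting
each (default 10 restarts — a full 100 x 1000 refit schedule is not a
desk-scale default; configurable), rebuilding the curve, and
interpolating each replicate's meta-d' against its own L(y) onto a
shared logarithmically spaced L grid (0.1–20, 101 points; L is the
plotted x-axis, and refits' y-spaces differ). The band is the pointwise
simple percentile pair at (1-level)/2 on each side, computed with the
'lower'/'higher' percentile methods so both endpoints are actual
replicate values. Replicates whose refit fails (or whose likelihood axis
is non-monotone, indicating a degenerate refit) are dropped and counted;
more than 20% failures aborts. One child seed pair per replicate derives
from the master seed by a fixed counter scheme, so partial or reordered
runs reproduce exactly. Replicate curves default to a 61-point grid with
4 meta-d' starts — the curve is smooth and the band percentile noise
dominates any interpolation error at that resolution.

## Descriptive analyses

* **Exclusions**: participants are dropped if they recalled *more than*
  80% of famous names or scored *below* 51% recognition accuracy
  (strict inequalities; both thresholds configurable). Accuracy is
  computed over famous recall-failed trials only — catch trials have no
  correct answer, so accuracy is undefined there (documented choice).
* **State means**: per-participant mean 4-level confidence in
  state-present versus state-absent recall-failed trials; catch trials
  carry metacognitive responses and are included by default
  (configurable). Participants lacking trials in either state are
  dropped from the paired comparison and logged.
* **Friedman test**: within-row average ranks with the standard tie
  correction, chi-squared reference distribution with k-1 degrees of
  freedom; the all-tied table returns statistic 0, p = 1. k = 2 is
  retained (not replaced by a sign test) to mirror the two-state
  comparisons.

## Synthetic data generator

The generator emulates the design, not the psychology: 70 participants x
600 trials (200 per condition) by default, blocks of 10 trials per
condition, two sessions. Famous trials are recalled with probability
0.35 *independently of evidence* (recall is a censoring coin flip, not a
modelled process); recalled trials carry no metacognitive data; catch
trials are never recalled. On recall failure, (x, y) is drawn from the
participant's scaled distribution; TOT is reported iff y > c_y and high
FOK iff y > c_y - 0.4 — one shared evidence axis with offset criteria is
an emulation convenience (it guarantees the FOK-high rate weakly
dominates the TOT rate), whereas the analysis fits TOT and FOK in
separate models, as it would on real data. The recognition response is
"correct" iff x exceeds the criteria midpoint, and the 4-level rating is
read off x by splitting the confident region 0.6 evidence units beyond
the criterion (4 vs 3) and the not-confident band 0.35 units inside
(1 vs 2).

Population hyperparameters: kappa log-normal(log 2, 0.3) — consistent
with the fitting anchor — lambda uniform(0.35, 0.65), criteria =
anchors (0.5, -1, +1) + N(0, 0.3) noise. The main text of record for
this design does not pin these values; they were chosen once as
plausible for a healthy adult sample and are fully configurable.

The default generating group model places the famous conditions at
x = +/-1 with metacognitive mean 1 and correlations +0.5 / -0.5 (catch
at the origin, correlation 0), the configuration in which confidence
sensitivity rises with metacognitive evidence. Note its SvM curve is
*negative* deep in the left tail: the conditional mean separation is
2 + (y - 1) * (rho_c - rho_i) = 1 + y, which crosses zero at y = -1
(L = e^{-1.5} ~ 0.22). Tests assert positivity in the low-likelihood
region adjacent to the objective criterion (L in [0.5, 1]), where the
pattern of interest lives.

What passing tests on synthetic data do **not** show: robustness to
evidence-dependent recall, session/order effects, non-Gaussian evidence,
criterion drift, or violations of decisional separability — none of
which the generator produces.

## Problem sizes used in the checks

The recovery study fits 20 participants x 200 trials/condition with 20
restarts; bootstrap sanity checks use a 5-participant study with 200
replicates of 10 restarts each; Monte-Carlo validation of cell
probabilities uses 10^6 draws per randomized configuration. These sizes
give comfortably stable results for the properties being checked
(recovery RMSE, band coverage) while keeping a full run on one CPU in
the minutes range.

## Known limitations

* Standard errors from the Hessian, model comparison across GRT
  variants, and perceptual-separability test batteries are out of scope.
* Response-specific meta-d' and type-2 ROC construction are not
  implemented.
* The "% variance accounted" definition (r^2) and the criterion
  aggregation rule are documented conventions, isolated behind single
  functions so alternatives can be swapped in.
* The nonparametric (resample-participants) bootstrap and BCa intervals
  are not provided; bands are simple percentiles by design.
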
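# Methods

## The model

The gamma-Pareto type I convolution (GPC) is the density of the sum of two
independent positive variates: a gamma variate with shape `a` (dimensionless)
and rate `b` (1/h), and a Pareto type I variate with shape `alpha`
(dimensionless, non-integer) and location/scale `beta` (hours; accepted in
seconds at API boundaries and divided by 3600).  In the pharmacokinetic
reading of an intravenous bolus, `beta` is the circulation delay between
injection and the peripheral sampling site, and the Pareto component gives
the disposition a power-function tail, `f(t) ~ t^-(alpha+1)`: the signature
of drug taken up into tissue by active transport and released over very long
times.  Concentration is the AUC-scaled density `C(t) = AUC * f(t)`, and
clearance is `CL = dose/AUC`.

Four related functions are evaluated, all analytic on `t > beta`:

* `pdf` — the density `f` (1/h),
* `cdf` — `F`, the fraction of one dose eliminated by time t,
* `supercdf` — the "super-cumulative" integral of F (hours), whose
  differences give time-averaged retained amounts exactly,
* `deriv` — `f'` (1/h^2), used for peak finding and the local half-life
  `t_half(t) = -ln2 * f/f'`.

All four are zero at `t <= beta` (step convention `theta(x)=0` for `x<=0`,
the continuous choice since the incomplete beta vanishes at argument 0).

## Two series, one dispatcher

The defining convolution integral expands to an alternating series in
powers of `(-b t)^n / n!` with incomplete-beta coefficients
`B_{1-beta/t}(a+n, -alpha)` (the **short-t** form).  Near `t = beta` it
converges in a handful of terms; for `t >> beta` the terms first grow to
astronomical magnitude before cancelling — at half a year the largest
summand is ~1e1392 while the value is ~1e-6.  The engine therefore runs in
two passes: a machine-precision log-magnitude scan that records the number
of terms required by the stopping rule and the largest term's base-10
exponent, followed by a full recomputation of exactly those terms at
`max_term_log10 + target + guard` decimal digits.  Stored summands include
the constant prefactor, so the scanned magnitudes are the magnitudes of the
actual contributions.  The stopping rule is absolute — stop at the first
term below `10^stop_exponent` (default 1e-65) after the magnitude sequence
has peaked — and the stopping term itself is counted and summed.  An
optional relative mode rescales the threshold by the running dominant
magnitude for values far below 1e-65.

Reflecting the incomplete beta, exchanging the two absolutely convergent
summations, and closing the inner sum yields the **long-t** form: a
closed-form part (the gamma density plus a `-pi csc(pi alpha)`
regularised-confluent-hypergeometric asymptote; for the integrals also
regularised upper incomplete gamma `Q(a, bt)` terms) plus a k-indexed sum
whose terms shrink monotonically by roughly `beta/(k t)` per term.  A
single last-term test therefore suffices to stop; no precision
precalculation is needed.  Each `1F1(a, a-k; -bt)` in the sum is evaluated
through the Kummer transformation as `e^-bt` times a terminating
(k+1)-term polynomial — exact, cancellation-free, O(k) at any `t`.

The dispatcher uses the short-t branch for `beta < t < 4 beta` and the
long-t branch for `t >= 4 beta`.  The cut is not critical; it only needs to
keep the long-t first-term ratio away from 1 (at `t = 4 beta` the next term
is at worst about 1/4 of the current one).  Forced-branch evaluation is kept
for cross-validation: at the 65-digit policy the two branches agree to
66-67 decimal places at t = 1, 12 and 72 h for the reference parameters.
Because the stopping threshold is absolute, branch agreement (and the
accuracy of small function values) is naturally measured in decimal places,
not significant figures; for values of order 1e-4 the same evaluation
carries ~62 significant figures.

### The `beta/(k t)` ratio is a small-`bt` statement

The next/current term ratio of the long-t sum is `~beta/(k t)` only while
`b t` is small; at `b t ~ 9` the terminating hypergeometric factors grow
with k and the observed ratios are a small multiple of `beta/t`, roughly
k-independent, and still ~3 decades per term.  Tests assert the true
invariants (ratios << 1; strictly decreasing term magnitudes) and check the
`beta/(k t)` scale only near the dispatch floor.

## Special functions

The negative-second-parameter incomplete beta — the one piece standard
double-precision libraries refuse — is computed from the power series
`B_z(A,B) = z^A sum_k (1-B)_k z^k / (k! (A+k))`, valid for any real `B` and
convergent for `|z| < 1`; for `z > 1/2` the reflection
`B_z(A,B) = B(A,B) - B_{1-z}(B,A)` keeps the series ratio at or below 1/2.
The complete beta goes through the entire reciprocal gamma, so
nonpositive-integer `A+B` is a zero, not a pole.  `alpha` within 1e-8 of an
integer is rejected at parameter construction (`csc(pi alpha)` pole).
The derivative kind needs `(a+n-1) * B_z(a+n-1, -alpha)` at `n=0`, which is
a 0 * inf limit when `a` is exactly 1; the scaled product form
`A*B_z(A,B) = z^A [1 + A sum_{k>=1} ...]` is pole-free and used throughout.
Non-terminating confluent hypergeometrics (only the asymptote terms need
them) are delegated to mpmath with precision elevated by `|x| log10(e)`
guard digits against cancellation at large negative argument, and the
regularised form routes negative arguments through the Kummer transform to
a positive-argument series.  mpmath also supplies `Q(a,x)`, gamma/csc, and
the tanh-sinh quadrature under the test oracles; the convolution oracle
substitutes `y = x^a` to remove the `x^(a-1)` endpoint singularity exactly,
which is what lets it reach ~45+ digits.

## Numerical policy

`PrecisionPolicy(target_digits=65, guard_digits=10, stop_exponent=-65,
max_terms=1e6)` is the default.  Results carry roughly
`target - 2` correct significant digits (the absolute stopping rule costs a
little more for values far below 1).  Multidose work runs at a 30-digit
policy — the published accumulation figures need 3; the margin is cheap.
A term cap (1e6) and a working-precision guard (1e6 digits) fail loudly on
runaway inputs.  Peak finding is bisection on the sign of `f'` in
`(beta*(1+1e-6), a/b + 10/b)` — precision-safe at arbitrary digits, unlike
derivative-based root polishing.  Interval troughs are left limits at dose
times; interval peaks are interior maxima of the superposed curve found by
bisection on its derivative.  "One year" is 8792 h (2 x 4396 h) for
consistency with the printed half-year.

## Fitting and inference

The loss is the relative root-mean-square error (1/C^2-weighted least
squares), matching the proportional error of the assay; it is scale
invariant, so concentration units cancel.  The search is multi-start
Nelder-Mead inside bounds (default: the span of the published seven-dog
fits widened ~50%, `beta` constrained to 25-30 s, since 20-min-to-72-h data
cannot resolve a seconds-scale delay).  Gradient post-refinement is
deliberately absent: the loss surface is nonconvex and interior-point
polishing fails on it.  R^2 is reported in the 1/C^2-weighted form (the
reference mean is the weighted mean), consistent with the loss; the
unweighted convention would mostly reflect the two earliest samples.

The search runs on a vectorised IEEE-double evaluation of the long-t
density (valid for all samples at `t >= 4 beta`; ~1e-13 relative accuracy,
verified against the mpmath engines over a random parameter sweep).  The
double path reorganises the k-sum into a triangular coefficient-matrix
contraction, making a 21-point loss evaluation ~0.1 ms — which is what
makes bootstrap and coverage studies desk-scale.  A fitted model's reported
loss can be re-evaluated once on the arbitrary-precision engines by passing
a policy; the search itself never needs more than doubles because the data
carry 5-9% noise.

Model-based bootstrap resamples multiplicative residuals `C_i/Chat_i` with
replacement and re-applies them to the fitted curve (`C* = Chat * r*`, the
proportional-error convention), refitting each replicate warm-started at
the original solution with a 600-evaluation budget (capped refits land
within ~0.1% of the full optimum, two orders below replicate scatter).
Shapiro-Wilk normality (of log residuals) and a Spearman
heteroscedasticity screen are computed and reported before resampling,
never enforced.  Two intervals are reported: the Weibull-quantile interval
(plotting positions `i/(n+1)`, linear interpolation) — this is the
parameter confidence interval, with ~95% simulated coverage at nominal
95% — and the Student-t interval of the replicate mean with `df = n`
(the `n` convention corrects the small-n downward bias of the sample SD),
which locates the bootstrap mean only and is roughly `sqrt(n_reps)` times
narrower than the parameter uncertainty.  CV summaries flag columns whose
mean is within 3 SE of zero and offer the median-of-group-CVs aggregate
for grouped inputs.

## Synthetic data

The generator emulates the source study design: 19-22 samples (default 21)
on a jittered log-spaced grid from 20 min to 72 h, multiplicative lognormal
noise with `sigma = sqrt(log(1+rrms^2))` so the rms relative error equals
the requested level exactly in expectation (default 8.6%, the fitted
residual level; the assay alone was ~5%).  It does **not** emulate:
assay quantification limits or censoring, between-dose occasion effects,
real sampling-time jitter structure, or model misspecification — so
passing recovery/coverage tests demonstrate correctness of the estimator
under the model, not robustness of the GPC model on real data.

## Study sizes used by the checks

Branch agreement runs at the 65-digit policy at t = 1, 12, 72 h; the
half-year scan is log-domain only.  The multidose block is the full
14-dose regimen at a 30-digit policy.  The oracle sweep uses seeded random
draws of `a in [0.2,1.2], b in [0.3,25], alpha in [0.1,1.9] (non-integer),
beta in [1e-3,1e-2] h`.  The coverage study simulates 100 subjects, each
fit warm-started at the generating values (the original analysis likewise
started near the solution) with a 40-replicate bootstrap; noise-free
recovery uses 4 cold multi-starts.  These sizes were chosen as the smallest
that make the binomial/Monte-Carlo margins of the assertions comfortable.

## Known limitations

* `alpha` must stay 1e-8 away from integers; the integer-alpha limit
  (where the csc pole cancels against the sum) is not implemented.
* The short-t branch's working precision grows like `b t log10(e)`; forcing
  it far beyond `4 beta` is supported but quadratically slow — that is the
  phenomenon the long-t branch exists to remove.
* Requesting N digits returns *about* N digits (a few more or fewer
  depending on the value's magnitude), not exactly N.
* The double-precision fast path covers the density only, and only for
  `t >= 4 beta`; fitting designs that sample inside `(beta, 4 beta)` would
  need the mpmath path in the loss.
* Variable-dose regimens are structurally supported but only equal-dose
  regimens are exercised against published values.
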
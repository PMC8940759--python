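# gpcpk — gamma-Pareto convolution pharmacokinetics

Tools for modelling intravenous-bolus drug disposition with a
**gamma-Pareto type I convolution (GPC)**: a four-parameter density with a
power-function tail that describes drugs whose extensive active transport
into tissue makes the classic sums-of-exponentials fail — metformin being
the motivating case.  Written for pharmacokineticists and biostatisticians
who need the GPC family as a practical research tool: evaluable at any
time point, fittable to concentration data, and usable for multidose
predictions.

## The model

The density is the convolution of a gamma density (shape `a`, rate `b`)
with a Pareto type I density (shape `α`, delay `β`):

    GPC(t; a,b,α,β) = θ(t−β) · (α b^a β^α / Γ(a)) · t^(a−α−1)
                      · Σ_{n≥0} (−bt)^n/n! · B_{1−β/t}(a+n, −α)

where `B_z(·,·)` is the incomplete beta function (here with a negative
parameter) and `θ` the unit step: nothing arrives at the sampling site
before the circulation delay `β`.  The same series differentiates and
integrates term by term, giving the CDF `F` (fraction of a dose
eliminated), the super-cumulative `𝓕 = ∫F` (which turns time-averaged
body burdens into closed-form differences), and `f′` (for peaks and the
local half-life `t½ = −ln2·f/f′`).  Concentration is AUC-scaled density,
`C(t) = AUC·f(t)`, and `CL = dose/AUC`.

Evaluated naively, the series is unusable at long times: the alternating
terms grow to ~10^1392 at half a year before cancelling down to ~10^-6.
The package implements the two-branch accelerated algorithm: a **short-t**
engine (two-pass: a log-magnitude scan sizes the required precision, then
the summation re-runs at that precision) and a **long-t** engine (a
rearranged series whose terms shrink monotonically, each a terminating
Kummer polynomial, plus a closed-form asymptote), dispatched at `t = 4β`.
Cross-checked against each other the branches agree to ~66 decimal places
at the default 65-digit policy.

On top of the distribution sit the pharmacokinetic applications: multidose
superposition with dose-equivalent body-burden accounting, proportional
error (1/C²) Nelder-Mead fitting, model-based residual bootstrap CIs
(Weibull-quantile and Student-t with df = n), and a synthetic-data
generator reproducing the source study design (19–22 samples, 20 min–72 h,
~8.6% proportional noise).

## Worked example

```python
import gpcpk as g

model  = g.dog1_model()      # metformin reference: a=0.3493, b=0.7318/h,
params = model.params        # alpha=0.2644, beta=25 s, AUC=31.16, dose=18.248

# high-precision evaluation with diagnostics
r = g.evaluate("pdf", 12.0, params, g.PrecisionPolicy(target_digits=65))
print(r.value_str(20), r.branch, r.n_terms)
# -> 0.0032742826562838816583 long 19

# why the rearrangement matters: the primary series at half a year
print(g.scan_short_terms("pdf", 4396.0, params, g.PrecisionPolicy()))
# -> (8882, 1392)         8882 terms, largest ~1e1392, for a 1.76e-6 value

# fourteen daily doses: flat peaks, rising troughs, tissue accumulation
reg = g.DoseRegimen(interval_h=24, n_doses=14, dose_mg_per_kg=18.248)
pol = g.PrecisionPolicy(target_digits=30)
s1, s14 = (g.interval_stats(model, reg, i, pol) for i in (1, 14))
print(f"{100*(s14.peak_conc/s1.peak_conc - 1):.3f} %   "
      f"{s14.trough_conc/s1.trough_conc:.2f} x   {s14.mean_retained:.3f} doses")
# -> 0.089 %   2.48 x   1.117 doses
```

Read: after two weeks of daily dosing the serum *peaks* rose only 0.089%
while the *troughs* rose 2.48-fold and an average of 1.12 dose-equivalents
sit in the body during the last interval — the power tail accumulates in
tissue where peak-time serum sampling cannot see it.

The `examples/` directory holds narrative scripts, one per capability
(`evaluate_density.py`, `single_dose_profile.py`,
`multidose_accumulation.py`, `fit_and_bootstrap.py`); each prints the
numbers above with a line on what they mean.  A thin CLI mirrors the
library:

```bash
gpcpk eval --a 0.3493 --b 0.7318 --alpha 0.2644 --beta-seconds 25 \
      --t-hours 12 --function pdf --digits 30 --diagnostics
gpcpk simulate ... | gpcpk fit ... | gpcpk bootstrap ...
```

## Documentation

`docs/methods.md` describes the model and both series in detail, the
precision policy, the fitting/bootstrap conventions, what the synthetic
data generator does and does not emulate, and known limitations.
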
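"""Simulate a subject, fit the model, and bootstrap confidence intervals.

Generates one synthetic subject from the reference model (21 samples, 20
min to 72 h, 8.6% proportional noise), fits (a, b, alpha, beta, AUC) by
1/C^2-weighted (relative-error) Nelder-Mead least squares, then runs a
40-replicate residual bootstrap.  The quantile interval is the parameter
CI; the much narrower t-interval locates the replicate mean only.
"""

import numpy as np

import gpcpk as g

model = g.dog1_model()
data = g.generate_synthetic(model, g.SynthDesign(seed=2024))
print(f"simulated {len(data)} samples, t = {data.times.min():.2f}..{data.times.max():.1f} h")

res = g.fit(data, dose=model.dose, seed=0, n_starts=4,
            policy=g.PrecisionPolicy(target_digits=30))
print("\nfitted parameters (true values in brackets):")
print(f"  a     = {res.params.a:.4f}   [{model.params.a}]")
print(f"  b     = {res.params.b:.4f}   [{model.params.b}] 1/h")
print(f"  alpha = {res.params.alpha:.4f}   [{model.params.alpha}]")
print(f"  beta  = {res.params.beta_s:.1f}     [{model.params.beta_s:.0f}] s")
print(f"  AUC   = {res.auc:.2f}    [{model.auc}] mg*h/L")
print(f"  CL    = {res.cl * 1000 / 60:.2f}     [{model.cl_ml_min_kg:.2f}] mL/(min kg)")
print(f"  rrms  = {100*res.rrms:.2f} %   (noise was 8.6 %)   R^2 = {res.r2:.5f}")

boot = g.bootstrap(data, res, n_reps=40, seed=1)
print(f"\nresidual bootstrap, {boot.n_replicates} replicates "
      f"({boot.n_failures} failures); screens: "
      f"Shapiro p = {boot.screens['shapiro_p']:.2f}, "
      f"heteroscedasticity p = {boot.screens['heteroscedasticity_spearman_p']:.2f}")
print("parameter   mean      95% CI (quantile)        CV%   (cl in L/(h kg))")
for k in ("a", "b", "alpha", "auc", "cl"):
    lo, hi = boot.ci_q[k]
    print(f"  {k:6s} {boot.mean[k]:8.4f}   [{lo:8.4f}, {hi:8.4f}]   "
          f"{100*abs(boot.cv[k]):5.1f}")
print("\nReading: the quantile CIs are the parameter uncertainty; the gamma")
print("shape a is the softest (~12% CV here), alpha/AUC/CL sit at a few")
print("percent for a single 21-sample subject.")
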
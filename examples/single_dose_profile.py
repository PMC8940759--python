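"""Single-dose concentration profile: peak, clearance, tail, half-life.

The AUC-scaled density C(t) = AUC * f(t) is the concentration model; its
mode is the (very early) concentration peak, clearance follows from
CL = dose/AUC, and the local half-life -ln2 f/f' shows the hallmark of the
power tail: it keeps growing with time instead of settling at a terminal
constant, so a late 'terminal half-life' read off any finite window
understates how long the drug really lingers.
"""

import gpcpk as g

model = g.dog1_model()
params = model.params
policy = g.PrecisionPolicy(target_digits=30)

t_peak, f_peak = g.find_peak(params, policy)
print(f"density peak at t = {float(t_peak)*3600:.1f} s post arrival "
      f"({float(t_peak):.6f} h)")
print(f"peak concentration = {float(model.auc * f_peak):.2f} mg/L")
print(f"clearance = {model.cl_ml_min_kg:.2f} mL/(min kg) "
      f"(dose {model.dose} mg/kg / AUC {model.auc} mg*h/L)")

one_year = 8792.0
ratio = g.evaluate("pdf", one_year, params, policy).value / f_peak
print(f"concentration at one year = {float(ratio):.2e} of peak "
      "(an exponential tail would be ~0 here)")

print("\nlocal half-life  -ln2 f/f'  [h]")
for t in (1.0, 12.0, 72.0, 1000.0):
    print(f"  t={t:7g} h: {float(g.half_life(t, params, policy)):10.2f}")
print("(grows ~ t*ln2/(1+alpha): no terminal exponential phase exists)")
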
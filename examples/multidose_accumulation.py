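"""Drug accumulation under repeated daily dosing.

Superposes 14 daily bolus doses of the reference subject's model and
reports the body burden in dose equivalents.  The power-tail signature:
serum peak concentrations barely move (<0.1%) while troughs rise ~2.5x and
the retained body burden accumulates to about one full extra dose held in
tissue — invisible to serum sampling at the peaks.
"""

import gpcpk as g

model = g.dog1_model()
regimen = g.DoseRegimen(interval_h=24.0, n_doses=14, dose_mg_per_kg=model.dose)
policy = g.PrecisionPolicy(target_digits=30)

s1 = g.interval_stats(model, regimen, 1, policy)
s14 = g.interval_stats(model, regimen, 14, policy)

print("interval  peak[mg/L]  trough[mg/L]  retained(peak)  retained(trough)  mean retained")
for s in (s1, s14):
    print(f"{s.index:8d}  {s.peak_conc:10.3f}  {s.trough_conc:12.4f}  "
          f"{s.peak_retained:14.3f}  {s.trough_retained:16.3f}  {s.mean_retained:13.3f}")

print(f"\npeak concentration rise over 14 doses: "
      f"{100*(s14.peak_conc/s1.peak_conc - 1):.3f} %")
print(f"trough concentration ratio:            "
      f"{s14.trough_conc/s1.trough_conc:.2f} x")
print(f"trough retained fold:                  "
      f"{s14.trough_retained/s1.trough_retained:.2f} x")
print(f"mean eliminated by interval 14:        {s14.mean_eliminated:.2f} doses")
print("\nReading: by day 14 about one full dose-equivalent is retained in the")
print("body at trough even though serum peaks look unchanged — trough (not")
print("peak) sampling is where multidose kinetics are observable.")
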
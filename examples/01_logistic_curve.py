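"""The four-parameter logistic baroreflex curve and its derived metrics.

Builds a representative curve (response range 100 a.u., slope coefficient
0.1 /mmHg, centered at 120 mmHg, lower plateau 10 a.u.) and prints the
descriptors a physiologist reads off a baroreflex function curve.
"""

import baroreset as br

params = br.LogisticParams(a1=100.0, a2=0.1, a3=120.0, a4=10.0)
m = br.curve_metrics(params)

print(f"SNA at the midpoint pressure ({params.a3:.0f} mmHg): "
      f"{br.evaluate(params, params.a3):.1f} a.u.  (= a1/2 + a4)")
print(f"threshold pressure : {m.threshold:.2f} mmHg")
print(f"saturation pressure: {m.saturation:.2f} mmHg")
print(f"operating range    : {m.operating_range:.2f} mmHg")
print(f"maximum gain       : {m.max_gain:.2f} a.u./mmHg at {m.midpoint_pressure:.0f} mmHg")
print(f"plateaus           : {m.upper_plateau:.0f} (upper) / {m.lower_plateau:.0f} (lower) a.u.")
print()
print("The threshold is where SNA has fallen 5% of the range below the")
print("upper plateau; the saturation is where it sits 5% above the lower")
print("plateau; between them lies the pressure range over which the")
print("reflex meaningfully regulates sympathetic outflow.")
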
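"""Fit the logistic to a simulated modified-Oxford recording.

The modified Oxford protocol drives pressure down to a nadir and back up
to a peak with vasoactive drugs, tracing the full reflex curve. Here the
pressure ramp is fed through the resting circuit, Gaussian measurement
noise (sd 2 a.u.) is added to the SNA channel, and the four-parameter
logistic is recovered from the noisy record.
"""

import baroreset as br

protocol = br.RampProtocol(start_pressure=100, nadir=50, peak=190,
                           rate=1.0, sample_interval=1.0)
pressures = br.generate_oxford_pressures(protocol)
series = br.sample_observations(
    br.DEFAULT_CIRCUIT, br.preset_state("rest"), pressures,
    br.NoiseSpec(sd=2.0, seed=42), label="rest",
)
print(f"simulated recording: {len(series)} samples, "
      f"{series.pressure.min():.0f}-{series.pressure.max():.0f} mmHg")

fit = br.fit_logistic(series)
a1, a2, a3, a4 = fit.params.as_tuple()
print(f"fitted parameters: a1={a1:.1f} a.u., a2={a2:.3f} /mmHg, "
      f"a3={a3:.1f} mmHg, a4={a4:.2f} a.u.")
print(f"goodness of fit: r2={fit.r_squared:.4f}, residual sd={fit.residual_sd:.2f} a.u.")
print()
print("The residual sd should be close to the generating noise sd (2 a.u.)")
print("and r2 close to 1: the logistic describes the circuit's curve well.")
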
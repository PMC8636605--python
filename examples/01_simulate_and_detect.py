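"""Simulate one unwinding trace and detect its steps.

The generator implements the delayed-release looping mechanism: the
helicase unwinds 1 bp per catalytic cycle but sequesters the nascent
single strands, releasing 1-4 nt per strand after a variable number of
cycles.  The observable position therefore moves in variable steps
averaging ~3 bp on a half-integer-bp lattice.
"""

import numpy as np

import helistep as h

cfg = h.GeneratorConfig()  # 100 Hz, 0.3 bp rms noise, Vmax 220 bp/s, KM 39 uM
rng = np.random.default_rng(0)
trace, log = h.simulate_trace(cfg, atp=0.5, duration=30.0, rng=rng,
                              trace_id="demo")

fit = h.detect_steps(trace)
steps = h.extract_steps(fit, trace=trace)
true_steps = log.observed_steps()

print(f"simulated {trace.n_samples} samples at {trace.sample_rate:g} Hz, "
      f"{len(log.events)} true release events")
print(f"detected {fit.n_steps} transitions "
      f"(step-quality ratio {fit.quality:.1f})")
print(f"mean detected unwinding step: "
      f"{steps.loc[steps.s > 0, 's'].mean():.2f} bp")
print(f"mean true release jump:       {true_steps[true_steps > 0].mean():.2f} bp")
print("Both sit near 3 bp: the release of ~6 sequestered nucleotides "
      "(2 nt per bp) per detected step.")
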
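"""Error-weighted step-size KDE with bootstrap band and periodicity.

Each detected step contributes a Gaussian kernel centered at its size with
width equal to its standard error, so precisely measured steps sharpen the
distribution.  With low measurement error the half-integer-bp lattice of
the release mechanism shows up as 0.5-bp peak spacing.
"""

import numpy as np
import pandas as pd

import helistep as h
from helistep.stepstats import bootstrap_kde, periodicity_estimate

cfg = h.GeneratorConfig()
frames = []
for i in range(12):
    rng = np.random.default_rng(np.random.SeedSequence([1, i]))
    tr, _ = h.simulate_trace(cfg, atp=0.5, duration=30.0, rng=rng,
                             trace_id=f"t{i}")
    frames.append(h.extract_steps(h.detect_steps(tr), trace=tr))
steps = pd.concat(frames, ignore_index=True)
up = steps[steps.s > 0]

kde = bootstrap_kde(steps, side="unwinding", n_boot=2000, seed=0)
per = periodicity_estimate(kde)

print(f"{len(up)} unwinding steps; "
      f"{(up.sigma_s < 0.25).mean():.0%} with standard error < 0.25 bp")
print(f"mean step {up.s.mean():.2f} bp, sd {up.s.std():.2f} bp")
print(f"KDE peak spacing: {per:.2f} bp")
print("A ~0.5-bp spacing means an odd total number of nucleotides is often "
      "released: the two strands release independently.")
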
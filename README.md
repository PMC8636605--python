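# helistep

Single-molecule stepping analysis for non-hexameric helicases processing a
DNA hairpin under constant force — the assay in which an SF1 helicase such
as *E. coli* UvrD unwinds an ~89-bp hairpin stem held between optically
trapped beads, and every base pair unwound releases two nucleotides of
ssDNA that lengthen the tether.

The package is aimed at single-molecule biophysicists who need the full
chain from raw position-vs-time traces to mechanistic statistics:

- **`helistep.synthetic`** — a kinetic Monte-Carlo generator implementing
  the *delayed-release looping* mechanism: the motor unwinds 1 bp per ATP
  (waiting time `Exp(k_on·[ATP]) + Exp(k_cat)`), sequesters the nascent 3′
  and 5′ strands as loops, and releases 1–4 nt per strand after a variable
  number of cycles (default pmf on {1,2,3,4} cycles, mean 3). Observed
  jumps are `(r₃+r₅)/2` bp, so steps are variable, average ~3 bp, and live
  on a half-integer-bp lattice. Ground-truth event logs accompany every
  trace.
- **`helistep.detection`** — iterative chi-square (Kerssemakers-style) step
  detection with a counter-fit quality criterion; per-dwell most-probable
  positions from a 0.1-bp-bandwidth KDE and standard errors
  `σᵢ = √(⟨(x−x*)²⟩/Nᵢ)` with `Nᵢ` the number of uncorrelated samples;
  sub-0.5-bp steps excluded with dwell merging.
- **`helistep.stepstats`** — error-weighted step-size KDE (one Gaussian
  kernel per step, width `σ_s = √(σᵢ²+σᵢ₊₁²)`), 10,000-iteration bootstrap
  bands, double-Gaussian mixture fits, signed pairwise-distance
  periodicity, covariate-independence tests.
- **`helistep.kinetics`** — dwell classification (+/+, −/−, +/−, −/+) with
  dead-time cutoffs, boxcar dwell-vs-step trendlines `κ(d+d₀)`, the inverse
  randomness parameter `n_min = (⟨t²⟩/⟨t⟩² − 1)⁻¹` with bootstrap outlier
  screening, speed estimation, and Michaelis–Menten fits
  `v = V_max[ATP]/(K_M+[ATP])`.
- **`helistep.polymer`** — extensible worm-like chain mechanics
  `x(F) = h(1 − ½√(kT/FP) + F/S)`, nm↔bp conversion, nearest-neighbor
  hairpin thermodynamics, and the thermal opening probability `P_open(n,F)`.
- **`helistep.loopmodel`** — the theoretical step-size distribution as the
  convolution of independent per-strand release pmfs, mapped to bp via ÷2.

## Worked example

```sh
python examples/01_simulate_and_detect.py
```

```
simulated 3000 samples at 100 Hz, 32 true release events
detected 32 transitions (step-quality ratio 20.4)
mean detected unwinding step: 2.79 bp
mean true release jump:       2.79 bp
```

Thirty seconds of 0.5 µM ATP trace at 100 Hz contains 32 release events;
the chi-square detector recovers all of them and the detected mean step
matches the generator's ground truth exactly — near the ~3 bp that the
release of ~6 sequestered nucleotides (2 nt per bp) produces. The other
examples cover the step-size KDE and its 0.5-bp periodicity
(`02_step_size_distribution.py`), dwell kinetics, n_min and
Michaelis–Menten recovery (`03_dwell_kinetics.py`), hairpin mechanics and
`P_open` (`04_hairpin_mechanics.py`), and the loop-release convolution
model (`05_loop_release_model.py`).

A thin CLI wraps the same functions:

```sh
helistep simulate --atp 0.5 --n-traces 3 --duration 30 --out fixtures
helistep detect fixtures/sim_0.5uM_000.tsv
helistep run config.yaml
```

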
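# Methods

## The generative model

`helistep.synthetic` simulates a helicase processing a DNA hairpin at
constant force as a two-state renewal process. Each catalytic cycle waits
an ATP-binding time `Exp(k_on·[ATP])` followed by a catalysis time
`Exp(k_cat)` and moves the fork by one base pair (unwinding) or minus one
(re-zipping). Because speeds are one base pair per cycle, the mean speed is
exactly Michaelis–Menten, `v = V_max[ATP]/(K_M+[ATP])` with
`V_max = k_cat·(1 bp)` and `K_M = k_cat/k_on`. Defaults are
`k_cat = 220 s⁻¹` and `k_on = 220/39 µM⁻¹s⁻¹` (unwinding); re-zipping uses
210 s⁻¹ and 210/35 when modeled separately.

The two nascent single strands are not released immediately: each cycle
adds 1 nt to a 3′ loop and 1 nt to a 5′ loop sequestered in the motor core.
After `N_c` cycles — drawn from a pmf on {1,2,3,4} with default
(0.05, 0.20, 0.45, 0.30), mean exactly 3.0 and mode 3 — a release event
draws `r₃` and `r₅` independently from per-strand release pmfs (same
default support and weights), truncated to the available loop contents,
**with the un-released remainder carried over to the next event**. The
observable position jumps by `(r₃+r₅)/2` bp. This carry-over is what
decouples `r₃+r₅` from `2·N_c`: odd totals produce half-integer steps, and
the long-run mean observed step equals the mean cycles-per-release (3.0 bp)
by conservation — every unwound nucleotide is eventually released. Plain
truncation without carry-over would lose outflow at small loops, drift the
loops against their cap, and bias the mean step several percent low.

Numerical/structural choices:

- **Loop cap 8 nt per strand**, with a forced release when a loop exceeds
  it, bounds the carry-over random walk. Forced releases are rare (~0.1%
  of events at defaults). A consequence worth knowing: per-strand release
  *rates* must equal the common 1 nt/cycle inflow in steady state, so
  deliberately unbalanced strand pmfs (say δ(2) vs δ(3)) hold their
  nominal means only transiently, until the slower strand's loop meets the
  cap.
- **Re-zipping** mirrors unwinding: loops shorten by 1 nt/strand per cycle
  and lengthen at incorporation events drawn from the same pmfs (truncated
  to the cap, remainders carried), with a forced incorporation when a loop
  empties. The observable jumps are negative. Symmetric defaults are the
  least-assumption choice; the mechanism on the opposing strand is less
  constrained by structure than unwinding.
- **Backsteps** occur with probability 0.08 per event and are modeled as
  the sign-flipped process (spontaneous re-looping of released strand
  during unwinding, spontaneous release during re-zipping), bounded by the
  released/sequestered inventory so strand bookkeeping stays exact. The
  realized backstep fraction is ~5% of steps, under the <10% the stepping
  data show.
- **Noise** is i.i.d. Gaussian, 0.3 bp rms per sample at 100 Hz (267 Hz
  for the 10 µM condition). Instrument noise is not published for this
  assay; the value is set so that the dwell-position standard errors are
  comfortably below 0.25 bp at 0.5 µM ATP, the regime in which 0.5-bp
  features resolve. Real traces have correlated bead noise, drift, and
  force-feedback artifacts that this generator does not emulate — passing
  tests show the analysis chain is correct, not that it is robust to every
  instrumental pathology.
- **Reproducibility**: each trace uses a `numpy` RNG derived from
  `(seed, trace_index)` via `SeedSequence`, so fixture sets are
  byte-identical across runs.

The event log records every cycle (time, Δh, loop contents) and every
event (time, r₃, r₅, observed jump, kind, cycle count). The invariant
`released nt = 2·(bp unwound) − (L₃+L₅)` holds exactly at every event in
unwinding mode and is enforced by a property test.

## Step detection

`detect_steps` is an iterative chi-square fitter. Starting from one dwell,
the split that most reduces the residual sum of squares is inserted
greedily (minimum segment 3 samples). For each candidate step count `k`, a
counter-fit places steps at the centers of the best-fit dwells; the
quality ratio `S(k) = χ²_counter/χ²_fit` peaks at the true step count. The
segmentation at the peak is accepted if `S ≥ 3.0` (the default
sensitivity), otherwise the trace is declared step-free. The threshold was
calibrated on simulated fixtures: pure 0.3-bp-noise traces reach `S ≈ 1.6`
at most (0/100 false-positive traces), while resolvable steps (≥2 bp,
dwells ≥30 samples) give `S ≥ 14` and ≥95% of transitions recovered within
±2 samples.

Dwell positions are the mode of a Gaussian KDE (bandwidth 0.1 bp) on a
0.01-bp grid — robust to brief contamination from neighboring levels,
unlike the mean. Dwell standard errors divide the mean squared deviation
by an effective sample count `Nᵢ = max(1, n/(1+2τ))`, with `τ` the
integrated autocorrelation time (initial-positive-sequence estimator), so
correlated noise widens `σᵢ` honestly. Steps smaller than 0.5 bp are
excluded; their flanking dwells are merged (position and uncertainty
recomputed from pooled samples, durations summed — conserving total time)
and the filter re-applied until stable.

## Step statistics

The step-size KDE sums one Gaussian kernel per step, centered at `s` with
width `σ_s = √(σᵢ²+σᵢ₊₁²)` (floored at 10⁻³ bp so noise-free fixtures stay
finite), normalized on a 0.01-bp grid spanning 0 to `max(s+3σ)`
(unwinding) or `min(s−3σ)` to 0 (re-zipping). Bootstrap bands resample
steps with replacement (10,000 iterations by default, multinomial-weighted
kernel sums for speed) and report the per-grid-point standard deviation.

Peak significance is operationalized as **prominence**: a local maximum
counts if it rises at least 2 bootstrap SEs above its surrounding saddle.
(A raw-height rule misfires when kernels are very narrow: sampling ripple
on top of a tall cluster creates spurious micro-maxima that are far above
zero but not above their neighborhood.) The periodicity estimate is the
median spacing of adjacent significant maxima; it returns ~0.5 bp for the
mixed-parity release lattice and 1.0 bp when release pmfs force even
nucleotide totals.

The double-Gaussian fit is a 2-component maximum-likelihood mixture
(EM via scikit-learn) initialized at the sample mean and twice the sample
mean — the double-step interpretation of the upper mode — with components
reported in ascending |mean| and a flagged single-Gaussian fallback on
collapse. Covariate checks use Pearson correlation of |s| against force,
stem position, or ATP with a 10⁴-shuffle permutation p-value: no
parametric assumption on the step distribution.

## Dwell kinetics

Dwells are classified by flanking step signs; dead-time cutoffs are 20 ms
(≤5 µM ATP) and 7 ms (10 µM). Dwell-vs-step curves use a boxcar window of
35 points (midpoint of the 25–45 range; configurable) over records sorted
by succeeding step size, with SE = sd/√window. Trendlines `κ(d+d₀)` are
weighted least squares, linear in `(κ, κd₀)`; `d₀`'s standard error comes
from the delta method, and flat curves are flagged with `d₀ = NaN` rather
than reported.

`n_min = (⟨t²⟩/⟨t⟩² − 1)⁻¹` uses sample moments; its standard error is the
delta method with the full 2×2 moment covariance (including the
⟨t⟩–⟨t²⟩ covariance, which the univariate propagation would miss).
`n_min` is scale-invariant and equals the stage count only for i.i.d.
exponential stages; heterogeneous rates pull it below the count — the
inference logic that lets dwell fluctuations bound the number of
*rate-limiting* events.

The outlier screen bootstraps `n_min` (2,000 resamples), fits a
2-component mixture to the bootstrap distribution, and declares
bimodality when the low mode has weight ≥0.1 and the means separate by ≥4
pooled sds. Dwells whose inclusion rate in low-mode resamples exceeds the
global rate by ≥3 binomial standard deviations are removed and `n_min`
recomputed. The thresholds are this package's operationalization of a
qualitative procedure; on clean Erlang samples the screen removes nothing
in ≥95% of runs and a single 20× dwell is flagged reliably.

Speeds come from mean step over mean same-direction dwell (≤10 µM, where
steps are resolvable; backstep-flanked dwells excluded) or from
straight-line fits to monotone intervals ≥0.5 s (saturating ATP; intervals
may be supplied explicitly, mirroring manual selection, or auto-selected
from the smoothed trace). Michaelis–Menten fits are SE-weighted nonlinear
least squares; weighting by SEs is a choice — equal weighting changes the
fitted constants by less than their standard errors on the synthetic data.

## Hairpin mechanics

The XWLC closed form `x(F) = h(1 − ½√(kT/FP) + F/S)` (Odijk high-force
interpolation) is used for both ssDNA (P = 1 nm, h = 0.59 nm/nt,
S = 1000 pN) and dsDNA (P = 53 nm, h = 0.34 nm/bp, S = 1100 pN) at
T = 295.15 K, `kT = k_B·T ≈ 4.075 pN·nm`. Extension changes convert to
base pairs by dividing by twice the ssDNA extension per nucleotide at the
measured force. The ssDNA stretching free energy is the trapezoid
quadrature of `x(F)` with the integrand clamped at zero below
`F₀ = kT/4P` where the interpolation turns unphysically negative — this
keeps the free energy non-negative and monotone.

Base-pairing free energies use unified nearest-neighbor ΔH/ΔS parameters
(packaged TSV) evaluated at temperature with the logarithmic monovalent
salt entropy correction (+0.368·ln[Mono⁺] cal mol⁻¹K⁻¹ per step) at 55 mM.
Base pair `i` carries the cost of NN step `(i, i+1)`; the terminal pair
duplicates the last step, and the tetraloop is a fixed cap excluded from
opening sums. `P_open(n,F)` sums Boltzmann weights of opening the next `m`
base pairs, `ΔG(m) = Σ costs − 2m·g_ss(F)`, over the full remaining stem
(`m` up to `L−n`; opening past the loop is full unfolding and excluded).
The packaged stems are synthetic: an 89-nt blocky ~49% G-C sequence
reproducing the high-variance `P_open` profile of a natural stem, and a
uniform-G-C variant with low variance (the published stem sequences live
in supplementary material not reproduced here; position-dependence
conclusions transfer because only the variance structure matters).

## Problem sizes and limitations

The reference analyses in `helistep.benchmarks` use 25 traces × 30 s at
0.5 µM (≥400 detected steps, ~2 s of compute), 3,000 cycles per ATP level
for kinetic fits, and 60 traces at 10 µM for the double-step analysis —
sizes chosen to put Monte-Carlo error well inside the effect sizes while
keeping any analysis under a minute on one core.

Known limitations: no bead/trap Brownian dynamics, trap stiffness, or
force-feedback modeling; no sequence-dependent unwinding rates; dimer
kinetics are generated by the same model (the measured dimer step
distribution is indistinguishable); re-zipping loop kinetics are a
symmetric assumption; strand-switch bursts are geometric with mean 20 bp,
an assumption beyond the burst-length scale. In the double-step analysis,
the merged fraction at 10 µM (~3% of steps) is smaller than real data
show (~25%), because the generator's dwell distribution is
Erlang-like with little mass below the dead time; the *location* of the
second mixture component (≈2× the elementary step) is the robust
observable, its weight is not.
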
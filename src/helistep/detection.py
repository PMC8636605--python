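"""Statistical step detection and per-dwell position / uncertainty estimation.

The detector is an iterative chi-square step fitter in the style of
Kerssemakers: starting from a single dwell, the step location giving the
largest residual sum-of-squares reduction is inserted repeatedly.  For each
candidate step count ``k`` a counter-fit is built with its steps at the
centers of the best-fit dwells; the ratio of counter-fit to best-fit
chi-square (the step-quality ratio ``S``) peaks at the true step count.
The segmentation at the peak is accepted when ``S`` exceeds a sensitivity
threshold, otherwise the trace is declared step-free.

Dwell positions are the modes of a Gaussian kernel density estimate
(bandwidth 0.1 bp) of the samples in each dwell, and dwell standard errors
account for correlated noise through the integrated autocorrelation time:
``sigma_i = sqrt(<(x - x*)^2> / N_i)`` with ``N_i = max(1, n / (1 + 2 tau))``
uncorrelated points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import Trace

__all__ = [
    "StepFitResult",
    "detect_steps",
    "dwell_position",
    "dwell_uncertainty",
    "extract_steps",
    "DEFAULT_SENSITIVITY",
]

#: Step-quality ratio the best segmentation must exceed.  Calibrated on
#: simulated fixtures so that pure-noise traces yield zero detected steps
#: in >= 95% of runs while well-resolved steps are kept (the quality ratio
#: at a true step is typically far above this).
DEFAULT_SENSITIVITY = 3.0

_MIN_SEG = 3  # smallest dwell, in samples


@dataclass
class StepFitResult:
    """Dwell segmentation of one trace.

    ``boundaries`` are sample indices ``[0, b_1, ..., b_k, n]``; dwell ``i``
    is the half-open segment ``[boundaries[i], boundaries[i+1])``.
    """

    boundaries: np.ndarray
    x_star: np.ndarray  # most probable dwell positions (bp)
    sd: np.ndarray  # per-dwell sample standard deviation
    sigma: np.ndarray  # per-dwell standard error (bp)
    n_eff: np.ndarray  # uncorrelated sample counts
    durations: np.ndarray  # dwell durations (s)
    sample_rate: float
    chi2: float  # residual sum of squares of the accepted fit
    quality: float  # counter-fit / best-fit chi-square ratio
    degenerate: np.ndarray = field(default=None)  # zero-variance dwell flags

    @property
    def n_dwells(self) -> int:
        return self.x_star.size

    @property
    def n_steps(self) -> int:
        return self.n_dwells - 1

    def transition_times(self) -> np.ndarray:
        return self.boundaries[1:-1] / self.sample_rate


# ---------------------------------------------------------------------------
# chi-square segmentation


def _segment_ss(c1, c2, a, b):
    """Residual sum of squares of samples [a, b) about their mean."""
    n = b - a
    s1 = c1[b] - c1[a]
    s2 = c2[b] - c2[a]
    return s2 - s1 * s1 / n


def _best_split(c1, c2, a, b):
    """Best split of segment [a, b): returns (index, ss_reduction)."""
    if b - a < 2 * _MIN_SEG:
        return -1, 0.0
    js = np.arange(a + _MIN_SEG, b - _MIN_SEG + 1)
    nl = js - a
    nr = b - js
    s1l = c1[js] - c1[a]
    s2l = c2[js] - c2[a]
    s1r = c1[b] - c1[js]
    s2r = c2[b] - c2[js]
    ss = (s2l - s1l * s1l / nl) + (s2r - s1r * s1r / nr)
    k = int(np.argmin(ss))
    total = _segment_ss(c1, c2, a, b)
    return int(js[k]), float(total - ss[k])


def _counter_chi2(c1, c2, boundaries, n):
    """Chi-square of the counter-fit: steps at the centers of each dwell."""
    centers = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        c = (a + b) // 2
        if 0 < c < n:
            centers.append(c)
    cb = np.unique(np.concatenate([[0], centers, [n]]))
    return sum(_segment_ss(c1, c2, a, b) for a, b in zip(cb[:-1], cb[1:]))


def detect_steps(trace: Trace | np.ndarray,
                 sensitivity: float = DEFAULT_SENSITIVITY,
                 max_steps: int | None = None,
                 sample_rate: float | None = None) -> StepFitResult:
    """Segment a trace into dwells by iterative chi-square step placement.

    Parameters
    ----------
    trace : Trace or 1-D array of positions
    sensitivity : float
        Threshold on the step-quality ratio (counter-fit chi-square over
        best-fit chi-square) below which the trace is declared step-free.
    max_steps : int, optional
        Cap on the number of candidate steps explored.

    Returns
    -------
    StepFitResult
    """
    if isinstance(trace, Trace):
        y = trace.position
        rate = trace.sample_rate
    else:
        y = np.asarray(trace, dtype=float)
        rate = sample_rate if sample_rate is not None else 1.0
    n = y.size
    if n < 10:
        raise ValueError("trace too short for step detection (need >= 10 samples)")

    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    if max_steps is None:
        max_steps = max(10, min(n // (2 * _MIN_SEG), 300))

    # grow the segmentation greedily, recording quality at each step count
    boundaries = [0, n]
    split_cache = {(0, n): _best_split(c1, c2, 0, n)}
    chi2_fit = _segment_ss(c1, c2, 0, n)
    history = []  # (split_index, chi2_fit_after)
    eps = 1e-12 * max(chi2_fit, 1.0)

    while len(history) < max_steps:
        segs = list(zip(boundaries[:-1], boundaries[1:]))
        best = (-1, 0.0, None)
        for seg in segs:
            if seg not in split_cache:
                split_cache[seg] = _best_split(c1, c2, *seg)
            j, red = split_cache[seg]
            if j >= 0 and red > best[1]:
                best = (j, red, seg)
        j, red, _ = best
        if j < 0 or red <= eps:
            break
        boundaries = sorted(boundaries + [j])
        chi2_fit -= red
        history.append((j, chi2_fit))
        if chi2_fit <= eps:
            break

    # evaluate the quality ratio along the greedy path
    best_k, best_quality = 0, 0.0
    for k in range(1, len(history) + 1):
        bnd = np.unique([0, n] + [h[0] for h in history[:k]])
        cf = history[k - 1][1]
        cc = _counter_chi2(c1, c2, bnd, n)
        quality = np.inf if cf <= eps else cc / cf
        if quality > best_quality:
            best_k, best_quality = k, quality

    if best_k == 0 or best_quality < sensitivity:
        bnd = np.array([0, n])
        quality = best_quality
        chi2 = _segment_ss(c1, c2, 0, n)
    else:
        bnd = np.unique([0, n] + [h[0] for h in history[:best_k]])
        quality = best_quality
        chi2 = history[best_k - 1][1]

    return _build_fit(y, bnd, rate, chi2, quality)


def _build_fit(y, boundaries, rate, chi2, quality) -> StepFitResult:
    x_star, sd, sigma, n_eff, durations, degen = [], [], [], [], [], []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        seg = y[a:b]
        xs = dwell_position(seg)
        if seg.size >= 2:
            s, ne, flag = _dwell_uncertainty_impl(seg, xs)
        else:
            s, ne, flag = 1e-6, 1.0, True
        x_star.append(xs)
        sd.append(float(np.std(seg)))
        sigma.append(s)
        n_eff.append(ne)
        durations.append(seg.size / rate)
        degen.append(flag)
    return StepFitResult(
        boundaries=np.asarray(boundaries),
        x_star=np.asarray(x_star),
        sd=np.asarray(sd),
        sigma=np.asarray(sigma),
        n_eff=np.asarray(n_eff),
        durations=np.asarray(durations),
        sample_rate=rate,
        chi2=float(chi2),
        quality=float(quality),
        degenerate=np.asarray(degen),
    )


# ---------------------------------------------------------------------------
# dwell position and uncertainty


def dwell_position(samples, bandwidth: float = 0.1,
                   grid_step: float = 0.01) -> float:
    """Most probable dwell position: mode of a Gaussian KDE of the samples.

    Bandwidth 0.1 bp, mode located on a 0.01-bp grid spanning the sample
    range (plus 3 bandwidths on either side).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty dwell segment")
    if x.size == 1 or np.ptp(x) == 0:
        return float(x[0])
    lo = x.min() - 3 * bandwidth
    hi = x.max() + 3 * bandwidth
    grid = np.arange(lo, hi + grid_step, grid_step)
    # KDE evaluated as the mean of per-sample Gaussian kernels
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def _autocorr_time(resid: np.ndarray) -> float:
    """Integrated autocorrelation time (initial-positive-sequence cutoff)."""
    n = resid.size
    r = resid - resid.mean()
    var = float(r @ r) / n
    if var == 0:
        return 0.0
    max_lag = n // 3
    tau = 0.0
    for lag in range(1, max_lag + 1):
        rho = float(r[:-lag] @ r[lag:]) / (n * var)
        if rho <= 0:
            break
        tau += rho
    return tau


def _dwell_uncertainty_impl(seg, x_star):
    m2 = float(np.mean((seg - x_star) ** 2))
    if m2 == 0:
        return 1e-6, float(seg.size), True
    tau = _autocorr_time(seg)
    n_eff = max(1.0, seg.size / (1.0 + 2.0 * tau))
    return float(np.sqrt(m2 / n_eff)), float(n_eff), False


def dwell_uncertainty(samples, sample_rate: float | None = None):
    """Standard error and effective uncorrelated count of a dwell.

    Returns ``(sigma_i, N_i)`` with ``sigma_i = sqrt(<(x - x*)^2> / N_i)``
    and ``N_i = max(1, n / (1 + 2 tau))`` from the integrated
    autocorrelation time ``tau`` of the dwell samples.  Degenerate
    (zero-variance) dwells return a machine-floor sigma.
    """
    seg = np.asarray(samples, dtype=float)
    if seg.size < 2:
        raise ValueError("dwell_uncertainty needs >= 2 samples")
    sigma, n_eff, _ = _dwell_uncertainty_impl(seg, dwell_position(seg))
    return sigma, n_eff


# ---------------------------------------------------------------------------
# step extraction with sub-threshold filtering


def extract_steps(fit: StepFitResult, trace: Trace | None = None,
                  min_size: float = 0.5,
                  samples: np.ndarray | None = None) -> pd.DataFrame:
    """Signed steps between consecutive dwells, with sub-0.5-bp filtering.

    Steps smaller than ``min_size`` (absolute) are excluded and their
    flanking dwells merged — position and uncertainty recomputed from the
    pooled samples, duration summed — then steps are re-derived; the rule
    is applied repeatedly (smallest offender first) until stable.

    Returns a DataFrame with one row per surviving step: signed size ``s``
    (bp), standard error ``sigma_s = sqrt(sigma_i^2 + sigma_{i+1}^2)``,
    transition time, flanking dwell durations, the preceding dwell position,
    and trace metadata when a :class:`~helistep.synthetic.Trace` is given.
    """
    if trace is not None and samples is None:
        samples = trace.position
    rate = fit.sample_rate

    bounds = list(fit.boundaries)
    xs = list(fit.x_star)
    sig = list(fit.sigma)
    neff = list(fit.n_eff)
    dur = list(fit.durations)

    def recompute(i):
        """Merge dwells i and i+1."""
        del bounds[i + 1]
        if samples is not None:
            seg = samples[bounds[i]:bounds[i + 1]]
            xs[i] = dwell_position(seg)
            s, ne, _ = _dwell_uncertainty_impl(seg, xs[i])
            sig[i], neff[i] = s, ne
        else:
            # no raw samples: inverse-variance pool the two dwell estimates
            w1, w2 = 1.0 / sig[i] ** 2, 1.0 / sig[i + 1] ** 2
            xs[i] = (xs[i] * w1 + xs[i + 1] * w2) / (w1 + w2)
            sig[i] = 1.0 / np.sqrt(w1 + w2)
            neff[i] = neff[i] + neff[i + 1]
        dur[i] = dur[i] + dur[i + 1]
        del xs[i + 1], sig[i + 1], neff[i + 1], dur[i + 1]

    while len(xs) >= 2:
        steps = np.diff(xs)
        small = np.abs(steps) < min_size
        if not small.any():
            break
        i = int(np.argmin(np.where(small, np.abs(steps), np.inf)))
        recompute(i)

    rows = []
    for i in range(len(xs) - 1):
        rows.append(
            {
                "s": xs[i + 1] - xs[i],
                "sigma_s": float(np.sqrt(sig[i] ** 2 + sig[i + 1] ** 2)),
                "t_transition": bounds[i + 1] / rate,
                "dwell_before": dur[i],
                "dwell_after": dur[i + 1],
                "position": xs[i],
                "trace_id": trace.id if trace is not None else "",
                "force": trace.force if trace is not None else np.nan,
                "atp": trace.atp if trace is not None else np.nan,
            }
        )
    cols = ["s", "sigma_s", "t_transition", "dwell_before", "dwell_after",
            "position", "trace_id", "force", "atp"]
    return pd.DataFrame(rows, columns=cols)
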
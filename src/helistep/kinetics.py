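"""Dwell-time statistics and kinetic fits.

Classifies dwells by the signs of their flanking steps (+/+, -/-, +/-, -/+),
applies the instrument dead-time cutoffs, builds dwell-time-vs-step-size
trendlines by boxcar averaging, computes the inverse randomness parameter

    n_min = (<t^2> / <t>^2 - 1)^(-1)

(a lower bound on the number of rate-limiting kinetic events per dwell),
screens for outlier dwells by bootstrap, estimates unwinding / re-zipping
speeds, and fits Michaelis-Menten kinetics across ATP concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.mixture import GaussianMixture

__all__ = [
    "DwellRecord",
    "TrendlineFit",
    "NminResult",
    "MichaelisMentenFit",
    "classify_and_filter_dwells",
    "dwell_cutoff",
    "dwell_vs_step",
    "fit_trendline",
    "n_min",
    "nmin_outlier_scan",
    "speed_step_over_dwell",
    "speed_line_fit",
    "fit_michaelis_menten",
]

#: Dead-time cutoffs (s): the stepping instrument resolves dwells above
#: 20 ms at 0.5-5 uM ATP; the faster acquisition used at 10 uM resolves
#: dwells above 7 ms.
CUTOFF_LOW_ATP = 0.020
CUTOFF_HIGH_ATP = 0.007
HIGH_ATP_THRESHOLD = 10.0  # uM


@dataclass
class TrendlineFit:
    """Linear trendline kappa * (d + d0) with parameter standard errors."""

    kappa: float
    d0: float
    kappa_se: float
    d0_se: float
    flagged: bool = False  # flat curve: d0 unidentifiable


@dataclass
class NminResult:
    mean_t: float
    mean_t2: float
    n_min: float
    se: float
    n: int
    removed: tuple = ()
    flagged: bool = False  # zero variance


@dataclass
class MichaelisMentenFit:
    v_max: float
    k_m: float
    v_max_se: float
    k_m_se: float
    flags: tuple = ()


def dwell_cutoff(atp: float) -> float:
    """Dead-time cutoff in seconds for the given ATP concentration (uM)."""
    return CUTOFF_HIGH_ATP if atp >= HIGH_ATP_THRESHOLD else CUTOFF_LOW_ATP


#: Columns of the dwell table produced by :func:`classify_and_filter_dwells`.
DwellRecord = ("t", "cls", "d", "atp", "force", "trace_id")


def classify_and_filter_dwells(steps: pd.DataFrame,
                               atp: float | None = None) -> pd.DataFrame:
    """Dwells between consecutive steps, classified and dead-time filtered.

    A dwell is the interval between two consecutive detected transitions
    within one trace; its class is the pair of flanking step signs
    (``+/+``, ``-/-``, ``+/-``, ``-/+``) and ``d`` is the size of the
    succeeding step.  Dwells shorter than the ATP-dependent dead-time
    cutoff are excluded.
    """
    rows = []
    for _, grp in steps.groupby("trace_id", sort=False):
        grp = grp.sort_values("t_transition")
        s = grp["s"].to_numpy(float)
        t_dwell = grp["dwell_after"].to_numpy(float)
        atps = grp["atp"].to_numpy(float)
        forces = grp["force"].to_numpy(float)
        ids = grp["trace_id"].to_numpy()
        for i in range(len(grp) - 1):
            a = atp if atp is not None else atps[i]
            t = t_dwell[i]
            if t < dwell_cutoff(a):
                continue
            cls = f"{'+' if s[i] > 0 else '-'}/{'+' if s[i+1] > 0 else '-'}"
            rows.append({"t": t, "cls": cls, "d": s[i + 1], "atp": a,
                         "force": forces[i], "trace_id": ids[i]})
    return pd.DataFrame(rows, columns=list(DwellRecord))


def dwell_vs_step(dwells: pd.DataFrame, cls: str = "+/+",
                  window: int = 35) -> pd.DataFrame:
    """Boxcar averages of dwell time and its square against step size.

    Records of the requested class are sorted by succeeding step size ``d``
    and averaged in a sliding window (25-45 points; default 35), yielding
    ``<t>``, ``<t^2>`` and ``<d>`` curves with standard errors
    ``sd / sqrt(window)``.
    """
    if not 25 <= window <= 45:
        raise ValueError("window must lie in [25, 45]")
    sub = dwells[dwells["cls"] == cls].sort_values("d")
    if len(sub) < window:
        raise ValueError(f"need >= {window} dwells of class {cls}")
    t = sub["t"].to_numpy(float)
    d = sub["d"].to_numpy(float)
    t2 = t * t

    def roll(x):
        s = pd.Series(x).rolling(window)
        return s.mean().to_numpy()[window - 1:], s.std(ddof=1).to_numpy()[
            window - 1:] / np.sqrt(window)

    t_m, t_se = roll(t)
    t2_m, t2_se = roll(t2)
    d_m, d_se = roll(d)
    d_sd = pd.Series(d).rolling(window).std(ddof=1).to_numpy()[window - 1:]
    return pd.DataFrame(
        {"d": d_m, "d_sd": d_sd, "t_mean": t_m, "t_se": t_se,
         "t2_mean": t2_m, "t2_se": t2_se, "window": window}
    )


def fit_trendline(curve: pd.DataFrame, y: str = "t_mean",
                  yerr: str | None = "t_se") -> TrendlineFit:
    """Weighted least squares of a boxcar curve to ``kappa * (d + d0)``.

    Linear in ``(kappa, kappa * d0)``; weights are inverse squared standard
    errors when available and nonzero, ordinary least squares otherwise.
    A flat curve (kappa indistinguishable from zero) is flagged, with
    ``d0`` reported as NaN.
    """
    d = curve["d"].to_numpy(float)
    v = curve[y].to_numpy(float)
    if d.size < 3:
        raise ValueError("need >= 3 window points")
    w = None
    if yerr is not None and yerr in curve:
        se = curve[yerr].to_numpy(float)
        if np.all(np.isfinite(se)) and np.all(se > 0):
            w = 1.0 / se**2
    X = np.column_stack([d, np.ones_like(d)])
    if w is None:
        w = np.ones_like(v)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], v * sw, rcond=None)
    kappa, intercept = beta
    resid = v - X @ beta
    dof = max(d.size - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    try:
        cov = s2 * np.linalg.inv((X * w[:, None]).T @ X)
    except np.linalg.LinAlgError:
        raise ValueError("singular design in trendline fit")
    kappa_se = float(np.sqrt(cov[0, 0]))
    if abs(kappa) < 1e-10 * max(1.0, abs(intercept)):
        return TrendlineFit(float(kappa), float("nan"), kappa_se,
                            float("nan"), flagged=True)
    d0 = intercept / kappa
    # delta-method SE of d0 = b / a
    g = np.array([-intercept / kappa**2, 1.0 / kappa])
    d0_se = float(np.sqrt(g @ cov @ g))
    return TrendlineFit(float(kappa), float(d0), kappa_se, d0_se)


def n_min(t_values, removed: tuple = ()) -> NminResult:
    """Inverse randomness parameter of a dwell-time sample.

    ``n_min = (<t^2>/<t>^2 - 1)^(-1)``, with a delta-method standard error
    propagated from the (co)variances of the sample moments <t> and <t^2>.
    Zero-variance samples are flagged (n_min infinite).
    """
    t = np.asarray(t_values, dtype=float)
    if t.size < 10:
        raise ValueError("n_min needs >= 10 dwells")
    m1 = float(t.mean())
    m2 = float((t * t).mean())
    var = m2 - m1 * m1
    if var <= 1e-12 * m1 * m1:
        return NminResult(m1, m2, float("inf"), float("nan"), t.size,
                          removed, flagged=True)
    nm = m1 * m1 / var
    n = t.size
    # covariance of the sample moments (m1, m2)
    c11 = var / n
    c22 = float(np.var(t * t)) / n
    c12 = float(np.mean((t - m1) * (t * t - m2))) / n
    grad = np.array([2 * m1 * m2 / var**2, -(m1 * m1) / var**2])
    se = float(np.sqrt(grad @ np.array([[c11, c12], [c12, c22]]) @ grad))
    return NminResult(m1, m2, float(nm), se, n, removed)


def nmin_outlier_scan(t_values, n_boot: int = 2000, seed: int = 0,
                      weight_min: float = 0.1, sep_sds: float = 4.0,
                      excess_sds: float = 3.0) -> NminResult:
    """Bootstrap screen for outlier dwells that depress n_min.

    Because the dwell-time variance grows much faster than the squared mean,
    a single extreme dwell can drag n_min down.  The bootstrap n_min
    distribution is then multi-modal: resamples rich in the outlier form a
    low mode.  The screen fits a two-component mixture to the bootstrap
    n_min values; when a distinct low mode exists (weight >= ``weight_min``,
    mean separation >= ``sep_sds`` pooled sds), dwells over-represented in
    low-mode resamples (inclusion rate exceeding the global rate by
    >= ``excess_sds`` binomial sds) are removed and n_min recomputed.
    """
    t = np.asarray(t_values, dtype=float)
    if t.size < 30:
        raise ValueError("nmin_outlier_scan needs >= 30 dwells")
    n = t.size
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    m1 = counts @ t / n
    m2 = counts @ (t * t) / n
    var = m2 - m1 * m1
    with np.errstate(divide="ignore", invalid="ignore"):
        nm = np.where(var > 0, m1 * m1 / var, np.inf)
    finite = np.isfinite(nm)
    nmf = nm[finite]
    cf = counts[finite]

    gm = GaussianMixture(n_components=2, random_state=0, n_init=1)
    gm.fit(nmf.reshape(-1, 1))
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    wt = gm.weights_.ravel()
    low, high = (0, 1) if mu[0] < mu[1] else (1, 0)
    pooled = np.sqrt(0.5 * (sd[0] ** 2 + sd[1] ** 2))
    bimodal = wt[low] >= weight_min and (mu[high] - mu[low]) >= sep_sds * pooled

    removed: tuple = ()
    if bimodal:
        assign = gm.predict(nmf.reshape(-1, 1))
        low_mask = assign == low
        k_low = int(low_mask.sum())
        if 0 < k_low < nmf.size:
            mean_low = cf[low_mask].mean(axis=0)  # mean count per dwell
            c_var = cf.var(axis=0)
            se = np.sqrt(np.maximum(c_var, 1e-12) / k_low)
            excess = (mean_low - 1.0) / se
            removed = tuple(np.nonzero(excess >= excess_sds)[0].tolist())
    if removed:
        keep = np.ones(n, dtype=bool)
        keep[list(removed)] = False
        return n_min(t[keep], removed=removed)
    return n_min(t)


# ---------------------------------------------------------------------------
# speeds and Michaelis-Menten


def speed_step_over_dwell(steps: pd.DataFrame, dwells: pd.DataFrame,
                          direction: str = "unwinding"):
    """Speed as mean step size over mean same-direction dwell time (bp/s).

    Unwinding uses positive steps and +/+ dwells; re-zipping uses negative
    steps and -/- dwells (the speed is reported as a positive number).
    Backstep-flanked dwells (+/- and -/+) are excluded.  Returns
    ``(speed, se)`` with the error propagated from the two sample means.
    """
    if direction == "unwinding":
        s = steps.loc[steps["s"] > 0, "s"].to_numpy(float)
        t = dwells.loc[dwells["cls"] == "+/+", "t"].to_numpy(float)
    elif direction == "rezipping":
        s = -steps.loc[steps["s"] < 0, "s"].to_numpy(float)
        t = dwells.loc[dwells["cls"] == "-/-", "t"].to_numpy(float)
    else:
        raise ValueError("direction must be 'unwinding' or 'rezipping'")
    if s.size == 0 or t.size == 0:
        raise ValueError(f"empty step or dwell class for {direction}")
    sbar, tbar = s.mean(), t.mean()
    v = sbar / tbar
    rel = np.sqrt(
        (s.std(ddof=1) / np.sqrt(s.size) / sbar) ** 2
        + (t.std(ddof=1) / np.sqrt(t.size) / tbar) ** 2
    ) if s.size > 1 and t.size > 1 else np.nan
    return float(v), float(v * rel)


def speed_line_fit(trace, intervals=None, min_duration: float = 0.5,
                   smooth_window: int = 25):
    """Speed from straight-line fits to monotone trace intervals (bp/s).

    ``intervals`` is a list of ``(t_start, t_stop)`` pairs (mirroring
    manual selection); when omitted, maximal monotone runs of the
    boxcar-smoothed trace lasting at least ``min_duration`` seconds are
    used.  Returns ``(mean_speed, se, slopes)`` over intervals, with
    unwinding and re-zipping intervals contributing |slope|.
    """
    t = trace.time
    y = trace.position
    if intervals is None:
        kernel = np.ones(smooth_window) / smooth_window
        ys = np.convolve(y, kernel, mode="same")
        sign = np.sign(np.diff(ys))
        sign[sign == 0] = 1
        # maximal constant-sign runs
        change = np.nonzero(np.diff(sign))[0] + 1
        starts = np.concatenate([[0], change])
        stops = np.concatenate([change, [sign.size]])
        intervals = [
            (t[a], t[b]) for a, b in zip(starts, stops)
            if t[b] - t[a] >= min_duration
        ]
    slopes = []
    for a, b in intervals:
        m = (t >= a) & (t <= b)
        if m.sum() < 5:
            continue
        slope = np.polyfit(t[m], y[m], 1)[0]
        slopes.append(abs(slope))
    if not slopes:
        raise ValueError("no usable intervals for line-fit speed")
    slopes = np.asarray(slopes)
    se = slopes.std(ddof=1) / np.sqrt(slopes.size) if slopes.size > 1 else np.nan
    return float(slopes.mean()), float(se), slopes


def fit_michaelis_menten(atp, v, v_se=None) -> MichaelisMentenFit:
    """Nonlinear least squares of speeds to v = Vmax [ATP] / (KM + [ATP]).

    Weighted by the speed standard errors when provided.  Flags: ``low_km``
    when the fitted KM collapses below 1% of the smallest ATP (saturation
    degeneracy), ``km_above_range`` when KM exceeds the largest ATP tested
    (weak identification).
    """
    atp = np.asarray(atp, dtype=float)
    v = np.asarray(v, dtype=float)
    if atp.size < 3:
        raise ValueError("need >= 3 ATP levels")
    if np.ptp(atp) == 0:
        raise ValueError("ATP levels must vary")

    def mm(a, vmax, km):
        return vmax * a / (km + a)

    sigma = None
    if v_se is not None:
        v_se = np.asarray(v_se, dtype=float)
        if np.all(np.isfinite(v_se)) and np.all(v_se > 0):
            sigma = v_se
    p0 = (float(v.max()), float(np.median(atp)))
    popt, pcov = optimize.curve_fit(
        mm, atp, v, p0=p0, sigma=sigma, absolute_sigma=False, maxfev=10_000
    )
    se = np.sqrt(np.diag(pcov))
    flags = []
    if popt[1] < atp.min() / 100.0:
        flags.append("low_km")
    if popt[1] > atp.max():
        flags.append("km_above_range")
    return MichaelisMentenFit(float(popt[0]), float(popt[1]),
                              float(se[0]), float(se[1]), tuple(flags))
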
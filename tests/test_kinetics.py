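"""Dwell kinetics: classification, trendlines, n_min, speeds, MM fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import helistep as h
from helistep.kinetics import (
    classify_and_filter_dwells,
    dwell_cutoff,
    dwell_vs_step,
    fit_michaelis_menten,
    fit_trendline,
    n_min,
    nmin_outlier_scan,
    speed_line_fit,
    speed_step_over_dwell,
)
from helistep.synthetic import Trace, sample_cycle_times

from conftest import steps_frame


def test_dwell_classification_signs():
    df = steps_frame([3.0, 2.5, -3.0], dwell=0.5, atp=1.0)
    dwells = classify_and_filter_dwells(df, atp=1.0)
    assert list(dwells["cls"]) == ["+/+", "+/-"]
    assert list(dwells["d"]) == [2.5, -3.0]


def test_dead_time_cutoffs():
    assert dwell_cutoff(1.0) == 0.020
    assert dwell_cutoff(10.0) == 0.007
    df = steps_frame([3.0, 3.0], dwell=0.015)
    assert len(classify_and_filter_dwells(df, atp=1.0)) == 0
    assert len(classify_and_filter_dwells(df, atp=10.0)) == 1


def test_generator_dwell_classes_dominated_by_same_direction():
    cfg = h.GeneratorConfig(noise_sd=0.0)
    frames = []
    for i in range(6):
        rng = np.random.default_rng(np.random.SeedSequence([40, i]))
        tr, _ = h.simulate_trace(cfg, atp=0.5, duration=40, rng=rng,
                                 trace_id=f"t{i}")
        fit = h.detect_steps(tr)
        frames.append(h.extract_steps(fit, trace=tr))
    steps = pd.concat(frames, ignore_index=True)
    dwells = classify_and_filter_dwells(steps)
    counts = dwells["cls"].value_counts()
    mixed = counts.get("+/-", 0) + counts.get("-/+", 0)
    assert counts.get("+/+", 0) > 5 * max(mixed, 1)


def test_dwell_vs_step_constant_and_identity():
    t = np.full(60, 0.25)
    df = pd.DataFrame({"t": t, "cls": "+/+", "d": np.linspace(1, 4, 60),
                       "atp": 1.0, "force": 12.0, "trace_id": "x"})
    curve = dwell_vs_step(df, window=25)
    assert np.allclose(curve["t_mean"], 0.25)
    assert np.allclose(curve["t_se"], 0.0)
    df2 = df.assign(t=df["d"])
    curve2 = dwell_vs_step(df2, window=25)
    assert np.allclose(curve2["t_mean"], curve2["d"])


def test_dwell_vs_step_window_bounds():
    df = pd.DataFrame({"t": np.ones(50), "cls": "+/+", "d": np.ones(50),
                       "atp": 1.0, "force": 12.0, "trace_id": "x"})
    with pytest.raises(ValueError):
        dwell_vs_step(df, window=20)
    with pytest.raises(ValueError):
        dwell_vs_step(df, window=50)


@pytest.mark.parametrize("kappa,d0", [
    (0.16, 2.6), (-0.11, 5.1), (0.22, 2.4), (-0.29, 1.2),
])
def test_trendline_exact_recovery(kappa, d0):
    d = np.linspace(1, 6, 12)
    curve = pd.DataFrame({"d": d, "t_mean": kappa * (d + d0),
                          "t_se": np.full(d.size, np.nan)})
    fit = fit_trendline(curve)
    assert fit.kappa == pytest.approx(kappa, rel=1e-6)
    assert fit.d0 == pytest.approx(d0, rel=1e-6)


def test_trendline_flat_curve_flagged():
    d = np.linspace(1, 6, 10)
    curve = pd.DataFrame({"d": d, "t_mean": np.full(10, 0.4)})
    fit = fit_trendline(curve, yerr=None)
    assert fit.flagged
    assert np.isnan(fit.d0)


def test_trendline_coverage_under_noise():
    rng = np.random.default_rng(0)
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        d = np.linspace(1, 6, 30)
        se = np.full(30, 0.02)
        y = 0.16 * (d + 2.6) + rng.normal(0, 0.02, 30)
        curve = pd.DataFrame({"d": d, "t_mean": y, "t_se": se})
        fit = fit_trendline(curve)
        if (abs(fit.kappa - 0.16) < 2 * fit.kappa_se
                and abs(fit.d0 - 2.6) < 2 * fit.d0_se):
            hits += 1
    assert hits >= 90


def test_n_min_arithmetic():
    # <t> = 1, <t^2> = 1.5 -> n_min = (1.5/1 - 1)^-1 = 2
    a = np.sqrt(0.5)
    t = np.array([1 - a, 1 + a] * 10)
    res = n_min(t)
    assert res.mean_t == pytest.approx(1.0)
    assert res.mean_t2 == pytest.approx(1.5)
    assert res.n_min == pytest.approx(2.0)


def test_n_min_analytic_distributions():
    rng = np.random.default_rng(123)
    assert n_min(rng.exponential(1.0, 10_000)).n_min == pytest.approx(
        1.0, abs=0.05)
    assert n_min(rng.gamma(2.0, 1.0, 10_000)).n_min == pytest.approx(
        2.0, abs=0.10)
    assert n_min(rng.gamma(3.0, 1.0, 10_000)).n_min == pytest.approx(
        3.0, abs=0.15)


def test_n_min_zero_variance_flagged():
    res = n_min(np.full(20, 0.3))
    assert res.flagged
    assert np.isinf(res.n_min)


@settings(max_examples=20, deadline=None)
@given(st.floats(min_value=1e-3, max_value=1e3),
       st.integers(min_value=0, max_value=100))
def test_n_min_scale_invariant(c, seed):
    t = np.random.default_rng(seed).gamma(2.0, 1.0, 200)
    assert n_min(c * t).n_min == pytest.approx(n_min(t).n_min, rel=1e-9)


def test_n_min_below_cycle_count_for_heterogeneous_rates():
    # dwell = sum of k exponentials: n_min = k only for equal rates
    rng = np.random.default_rng(7)
    k = 3
    same = rng.exponential(1.0, (10_000, k)).sum(axis=1)
    hetero = (rng.exponential(1.0, 10_000)
              + rng.exponential(0.1, 10_000)
              + rng.exponential(0.1, 10_000))
    assert n_min(same).n_min == pytest.approx(3.0, abs=0.15)
    assert n_min(hetero).n_min < 2.0


def test_nmin_outlier_scan_specificity_and_sensitivity():
    rng = np.random.default_rng(11)
    clean_removals = 0
    for i in range(20):
        t = np.random.default_rng(500 + i).gamma(2.0, 1.0, 150)
        if nmin_outlier_scan(t, seed=i).removed:
            clean_removals += 1
    assert clean_removals <= 1
    t = rng.gamma(2.0, 1.0, 150)
    spiked = np.concatenate([t, [20 * t.mean()]])
    res = nmin_outlier_scan(spiked, seed=0)
    assert res.removed == (150,)
    assert res.n_min > n_min(spiked).n_min


def test_speed_step_over_dwell():
    steps = steps_frame([3.0] * 10)
    dwells = pd.DataFrame({"t": np.full(10, 0.5), "cls": "+/+", "d": 3.0,
                           "atp": 1.0, "force": 12.0, "trace_id": "x"})
    v, _ = speed_step_over_dwell(steps, dwells)
    assert v == pytest.approx(6.0)
    with pytest.raises(ValueError):
        speed_step_over_dwell(steps, dwells, direction="rezipping")


def test_speed_line_fit_on_ramp():
    t = np.arange(0, 3, 0.01)
    tr = Trace(time=t, position=45.0 * t, sample_rate=100.0)
    v, _, slopes = speed_line_fit(tr)
    assert v == pytest.approx(45.0, rel=1e-6)


def test_generator_speed_matches_michaelis_menten(default_config):
    cfg = default_config
    rng = np.random.default_rng(3)
    _, log = h.simulate_trace(cfg.replace(noise_sd=0.0, backstep_prob=0.0),
                              atp=10.0, duration=120, rng=rng)
    cyc_t = np.array([c["time"] for c in log.cycles])
    v_mc = cyc_t.size / cyc_t[-1]  # bp/s: 1 bp per cycle
    v_theo = h.synthetic.mean_speed_theoretical(cfg, 10.0)
    assert v_mc == pytest.approx(v_theo, rel=0.05)


def test_michaelis_menten_exact_recovery():
    atp = np.array([0.5, 1, 2.5, 5, 10, 100, 250, 500, 1000], float)
    v = 220.0 * atp / (39.0 + atp)
    fit = fit_michaelis_menten(atp, v)
    assert fit.v_max == pytest.approx(220.0, rel=1e-6)
    assert fit.k_m == pytest.approx(39.0, rel=1e-6)


def test_michaelis_menten_saturation_degeneracy_flagged():
    atp = np.array([10.0, 100.0, 1000.0])
    fit = fit_michaelis_menten(atp, np.full(3, 220.0))
    assert "low_km" in fit.flags


def test_michaelis_menten_coverage_under_noise():
    rng = np.random.default_rng(2)
    atp = np.array([0.5, 1, 2.5, 5, 10, 100, 250, 500, 1000], float)
    truth = 220.0 * atp / (39.0 + atp)
    hits_v = hits_k = 0
    n_rep = 100
    for _ in range(n_rep):
        v = truth * (1 + rng.normal(0, 0.05, atp.size))
        fit = fit_michaelis_menten(atp, v, v_se=0.05 * truth)
        if abs(fit.v_max - 220.0) < 2 * fit.v_max_se:
            hits_v += 1
        if abs(fit.k_m - 39.0) < 2 * fit.k_m_se:
            hits_k += 1
    assert hits_v >= 90
    assert hits_k >= 90


def test_dwell_time_increases_with_step_size(default_config):
    # generator dwells are sums of N_c cycles and the following step size
    # tracks N_c, so <t>(d) must rise ~linearly with d
    cfg = default_config.replace(noise_sd=0.0, backstep_prob=0.0)
    rng = np.random.default_rng(17)
    _, log = h.simulate_trace(cfg, atp=0.5, duration=2000, rng=rng)
    tt = log.event_times()
    dx = log.observed_steps()
    rows = []
    for i in range(1, len(dx)):
        rows.append({"t": tt[i] - tt[i - 1], "cls": "+/+", "d": dx[i],
                     "atp": 0.5, "force": 12.0, "trace_id": "g"})
    dwells = pd.DataFrame(rows)
    curve = dwell_vs_step(dwells, window=35)
    fit = fit_trendline(curve)
    assert fit.kappa > 0
    # normalized collapse: mean dwell rises by roughly one cycle per bp
    mean_cycle = 1.0 / h.synthetic.mean_speed_theoretical(cfg, 0.5)
    assert fit.kappa * (3.0 + fit.d0) == pytest.approx(
        curve["t_mean"].mean(), rel=0.25)
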
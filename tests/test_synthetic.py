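"""Generator: degenerate exactness, conservation, renewal balance, kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import helistep as h
from helistep.synthetic import (
    GeneratorConfig,
    make_fixture_set,
    mean_speed_theoretical,
    sample_cycle_times,
    simulate_trace,
)

DELTA3 = (0.0, 0.0, 1.0, 0.0)


def test_degenerate_pmfs_give_constant_3bp_staircase():
    cfg = GeneratorConfig(noise_sd=0.0, backstep_prob=0.0,
                          cycles_per_release=DELTA3,
                          release_3p=DELTA3, release_5p=DELTA3)
    _, log = simulate_trace(cfg, atp=2.0, duration=60, mode="unwinding")
    steps = log.observed_steps()
    assert steps.size > 10
    assert np.all(steps == 3.0)


def test_odd_total_release_gives_half_integer_steps():
    # unbalanced strand pmfs are sustainable only while the slower strand's
    # loop can keep growing, so lift the cap out of the way
    cfg = GeneratorConfig(noise_sd=0.0, backstep_prob=0.0,
                          cycles_per_release=DELTA3,
                          release_3p=(0.0, 1.0, 0.0, 0.0),  # delta(2)
                          release_5p=DELTA3,  # delta(3)
                          loop_cap=10**6)
    _, log = simulate_trace(cfg, atp=2.0, duration=60)
    steps = log.observed_steps()
    assert steps.size > 10
    assert np.all(steps == 2.5)


def test_noise_free_steps_on_half_integer_lattice():
    cfg = GeneratorConfig(noise_sd=0.0)
    _, log = simulate_trace(cfg, atp=5.0, duration=120)
    steps = log.observed_steps()
    assert np.allclose(2 * steps, np.round(2 * steps))


def test_renewal_balance_mean_step_equals_mean_cycles(quiet_config):
    # long-run mean observed step (bp) = mean of cycles_per_release (3.0)
    rng = np.random.default_rng(7)
    _, log = simulate_trace(quiet_config, atp=100.0, duration=400,
                            mode="unwinding", rng=rng)
    steps = log.observed_steps()
    assert steps.size > 10_000
    assert abs(steps.mean() - 3.0) / 3.0 < 0.02


def test_rezipping_mean_step_balanced(quiet_config):
    rng = np.random.default_rng(8)
    _, log = simulate_trace(quiet_config, atp=100.0, duration=300,
                            mode="rezipping", rng=rng)
    steps = log.observed_steps()
    assert steps.size > 5_000
    assert abs(steps.mean() + 3.0) / 3.0 < 0.02


def _conservation_violation(log):
    """Max violation of released = 2*unwound - loops across events."""
    cyc_t = np.array([c["time"] for c in log.cycles])
    cyc_dh = np.array([c["dh"] for c in log.cycles])
    released = 0
    worst = 0
    for e in log.events:
        if e["kind"] == "release":
            released += e["r3"] + e["r5"]
        elif e["kind"] == "backstep":
            released -= e["r3"] + e["r5"]
        h_now = int(cyc_dh[cyc_t <= e["time"]].sum())
        worst = max(worst, abs(released - (2 * h_now - (e["L3"] + e["L5"]))))
    return worst


def test_conservation_at_every_event_unwinding():
    cfg = GeneratorConfig(noise_sd=0.0)  # backsteps on
    _, log = simulate_trace(cfg, atp=10.0, duration=60)
    assert len(log.events) > 100
    assert _conservation_violation(log) == 0


@settings(max_examples=10, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_conservation_property_random_seeds(seed):
    cfg = GeneratorConfig(noise_sd=0.0, seed=seed)
    _, log = simulate_trace(cfg, atp=20.0, duration=20)
    assert _conservation_violation(log) == 0


def test_loops_never_negative_and_capped():
    cfg = GeneratorConfig(noise_sd=0.0)
    for mode in ("unwinding", "rezipping", "alternating"):
        _, log = simulate_trace(cfg, atp=10.0, duration=40, mode=mode,
                                rng=np.random.default_rng(3))
        L3 = np.array([c["L3"] for c in log.cycles])
        L5 = np.array([c["L5"] for c in log.cycles])
        assert (L3 >= 0).all() and (L5 >= 0).all()
        # transient overshoot: a backstep can re-loop up to 4 nt on top of
        # the cap, plus one cycle before the forced release fires
        assert L3.max() <= cfg.loop_cap + 5
        assert L5.max() <= cfg.loop_cap + 5


def test_cycle_count_between_releases_matches_log(quiet_config):
    _, log = simulate_trace(quiet_config, atp=5.0, duration=60)
    cyc_t = np.array([c["time"] for c in log.cycles])
    prev = 0.0
    for e in log.events:
        n = int(((cyc_t > prev) & (cyc_t <= e["time"])).sum())
        assert n == e["n_cycles"]
        prev = e["time"]


def test_backstep_fraction_below_ten_percent():
    cfg = GeneratorConfig(noise_sd=0.0)
    _, log = simulate_trace(cfg, atp=10.0, duration=300,
                            rng=np.random.default_rng(9))
    steps = log.observed_steps()
    frac = (steps < 0).mean()
    assert 0.0 < frac < 0.10


def test_mean_speed_theoretical_identities(default_config):
    cfg = default_config
    vmax = cfg.k_cat
    km = cfg.k_cat / cfg.k_on
    assert mean_speed_theoretical(cfg, 1e9) == pytest.approx(vmax, rel=1e-6)
    assert mean_speed_theoretical(cfg, km) == pytest.approx(vmax / 2)
    with pytest.raises(ValueError):
        mean_speed_theoretical(cfg, 0.0)


def test_mean_speed_matches_monte_carlo(default_config):
    rng = np.random.default_rng(12)
    ct = sample_cycle_times(default_config, 10.0, 100_000, rng)
    mc = 1.0 / ct.mean()
    theo = mean_speed_theoretical(default_config, 10.0)
    se = theo * ct.std() / ct.mean() / np.sqrt(ct.size)
    assert abs(mc - theo) < 4 * se


def test_trace_grid_and_noise(default_config):
    tr, _ = simulate_trace(default_config, atp=1.0, duration=5.0)
    assert tr.n_samples == 500
    assert np.allclose(np.diff(tr.time), 1.0 / default_config.sample_rate)
    assert np.isfinite(tr.position).all()


@pytest.mark.parametrize("bad", [
    dict(k_on=-1.0),
    dict(cycles_per_release=(0.5, 0.5, 0.5, 0.5)),
    dict(release_3p=(1.0, 0.0, 0.0, -0.0 - 1e-3)),
    dict(noise_sd=-0.1),
    dict(backstep_prob=1.5),
])
def test_config_validation_rejects(bad):
    with pytest.raises(ValueError):
        GeneratorConfig(**bad).validate()


def test_simulate_rejects_bad_duration(default_config):
    with pytest.raises(ValueError):
        simulate_trace(default_config, atp=1.0, duration=0.0)
    with pytest.raises(ValueError):
        simulate_trace(default_config, atp=-1.0, duration=1.0)


def test_fixture_set_deterministic(tmp_path, default_config):
    a = tmp_path / "a"
    b = tmp_path / "b"
    for out in (a, b):
        make_fixture_set(default_config, [0.5, 1.0], 2, out, seed=42,
                         duration=3.0)
    for f in sorted(a.iterdir()):
        assert f.read_bytes() == (b / f.name).read_bytes()


def test_fixture_set_empty_atp_list(tmp_path, default_config):
    manifest = make_fixture_set(default_config, [], 5, tmp_path / "e", seed=1)
    assert manifest["traces"] == []
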
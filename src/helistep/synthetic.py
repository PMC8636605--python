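"""Kinetic Monte-Carlo generator of helicase unwinding / re-zipping traces.

Implements a delayed-release looping mechanism for a non-hexameric helicase
processing a DNA hairpin under constant force: the motor unwinds (or re-zips)
one base pair per catalytic cycle, but the two nascent single strands are
sequestered as loops within the motor core and only released (unwinding) or
incorporated (re-zipping) after a variable number of cycles.  Because the
hairpin assay detects released ssDNA, the observable position is piecewise
constant, jumping by ``(r3 + r5) / 2`` base pairs per release event — which
puts observed step sizes on a half-integer-bp lattice whenever the total
number of nucleotides released is odd.

Each catalytic cycle waits an ``Exp(k_on * [ATP]) + Exp(k_cat)`` time
(ATP binding followed by catalysis), so simulated speeds follow
Michaelis-Menten kinetics with ``V_max = k_cat * 1 bp`` and
``K_M = k_cat / k_on`` exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GeneratorConfig",
    "EventLog",
    "Trace",
    "simulate_trace",
    "mean_speed_theoretical",
    "sample_cycle_times",
    "make_fixture_set",
    "DEFAULT_RELEASE_PMF",
]

#: Default per-strand release-size pmf on {1, 2, 3, 4} nt and default
#: cycles-per-release pmf (mean exactly 3.0, mode 3).
DEFAULT_RELEASE_PMF = (0.05, 0.20, 0.45, 0.30)

_PMF_TOL = 1e-12


def _check_pmf(name: str, pmf: np.ndarray) -> np.ndarray:
    pmf = np.asarray(pmf, dtype=float)
    if pmf.ndim != 1 or pmf.size == 0:
        raise ValueError(f"{name}: pmf must be a non-empty 1-D array")
    if np.any(pmf < 0):
        raise ValueError(f"{name}: pmf entries must be non-negative")
    if abs(pmf.sum() - 1.0) > _PMF_TOL:
        raise ValueError(f"{name}: pmf must sum to 1 (got {pmf.sum()!r})")
    return pmf


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the delayed-release looping generator.

    Parameters
    ----------
    k_on : float
        ATP binding rate, per uM per second.  Default ``220 / 39`` so that
        ``K_M = k_cat / k_on = 39 uM``.
    k_cat : float
        Catalytic rate, per second.  ``V_max = k_cat * 1 bp = 220 bp/s``.
    cycles_per_release : tuple of float
        Pmf over {1, 2, 3, 4} catalytic cycles between release events.
    release_3p, release_5p : tuple of float
        Per-strand release (incorporation) size pmfs over {1, 2, 3, 4} nt.
        Draws are truncated to the current loop content; the remainder
        carries over, which decouples the released total from twice the
        cycle count and produces half-integer observed steps.
    loop_cap : int
        Maximum sequestered nt per strand; a release is forced when a loop
        exceeds it, keeping the carry-over random walk bounded.
    noise_sd : float
        Additive i.i.d. Gaussian measurement noise, bp rms per sample.
    sample_rate : float
        Sampling rate in Hz (100 Hz; 267 Hz for the high-ATP condition).
    backstep_prob : float
        Probability that a release event has inverted sign (observed as a
        backstep; modelled as a spontaneous re-looping / unlooping event so
        strand bookkeeping stays exact).
    burst_mean_bp : float
        Mean unwinding burst length (bp) before a strand switch in
        ``alternating`` mode.
    seed : int
        Default RNG seed for :func:`simulate_trace`.
    """

    k_on: float = 220.0 / 39.0
    k_cat: float = 220.0
    cycles_per_release: tuple = DEFAULT_RELEASE_PMF
    release_3p: tuple = DEFAULT_RELEASE_PMF
    release_5p: tuple = DEFAULT_RELEASE_PMF
    loop_cap: int = 8
    noise_sd: float = 0.3
    sample_rate: float = 100.0
    backstep_prob: float = 0.08
    burst_mean_bp: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.k_on <= 0 or self.k_cat <= 0:
            raise ValueError("rates k_on and k_cat must be positive")
        for name in ("cycles_per_release", "release_3p", "release_5p"):
            _check_pmf(name, getattr(self, name))
        if self.loop_cap < 4:
            raise ValueError("loop_cap must be at least the maximum release size")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0 <= self.backstep_prob < 1:
            raise ValueError("backstep_prob must be in [0, 1)")
        if self.burst_mean_bp <= 0:
            raise ValueError("burst_mean_bp must be positive")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class EventLog:
    """Ground-truth record of catalytic cycles and strand release events.

    ``cycles`` has one row per catalytic cycle: (time, dh, L3, L5) where
    ``dh`` is the signed change in hairpin base pairs (+1 unwinding, -1
    re-zipping) and L3/L5 the loop contents (nt) after the cycle.
    ``events`` has one row per release / incorporation event:
    (time, r3, r5, dx_bp, kind, n_cycles) where ``dx_bp`` is the observed
    jump in bp — ``(r3 + r5) / 2`` signed by direction — and ``kind`` is
    ``release``, ``incorporation`` or ``backstep``.
    """

    cycles: list = field(default_factory=list)
    events: list = field(default_factory=list)

    def observed_steps(self) -> np.ndarray:
        return np.array([e["dx_bp"] for e in self.events], dtype=float)

    def event_times(self) -> np.ndarray:
        return np.array([e["time"] for e in self.events], dtype=float)

    def release_tallies(self, max_size: int = 4) -> np.ndarray:
        """Counts of per-strand release sizes 1..max_size over release events."""
        counts = np.zeros(max_size, dtype=int)
        for e in self.events:
            if e["kind"] == "release":
                for r in (e["r3"], e["r5"]):
                    if 1 <= r <= max_size:
                        counts[r - 1] += 1
        return counts

    def to_json(self, path) -> None:
        payload = {"cycles": self.cycles, "events": self.events}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "EventLog":
        payload = json.loads(Path(path).read_text())
        return cls(cycles=payload["cycles"], events=payload["events"])


@dataclass
class Trace:
    """Uniformly sampled hairpin position (bp unwound) vs time."""

    time: np.ndarray
    position: np.ndarray
    force: float = 12.0
    atp: float = 1.0
    sample_rate: float = 100.0
    id: str = "trace"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.time.shape != self.position.shape:
            raise ValueError("time and position must have the same shape")

    @property
    def n_samples(self) -> int:
        return self.time.size


class _LoopState:
    """Mutable strand-bookkeeping state shared by the simulation loop."""

    __slots__ = ("h", "L3", "L5", "released3", "released5", "x",
                 "debt3", "debt5")

    def __init__(self, L3: int = 0, L5: int = 0):
        self.h = 0  # bp unwound relative to trace start
        self.L3 = L3
        self.L5 = L5
        self.released3 = 0  # cumulative net nt released, per strand
        self.released5 = 0
        self.x = 0.0  # latent observable position (bp)
        # carry-over remainders: nt a release (unwinding) or incorporation
        # (re-zipping) wanted to move but could not; applied to the next
        # event, which keeps the long-run event size balanced
        self.debt3 = 0
        self.debt5 = 0


def _draw(pmf: np.ndarray, rng: np.random.Generator) -> int:
    return int(rng.choice(pmf.size, p=pmf)) + 1


def simulate_trace(
    config: GeneratorConfig,
    atp: float,
    duration: float,
    mode: str = "unwinding",
    rng: np.random.Generator | None = None,
    trace_id: str = "trace",
    force: float = 12.0,
):
    """Simulate one constant-force trace and its ground-truth event log.

    Parameters
    ----------
    config : GeneratorConfig
    atp : float
        ATP concentration in uM.
    duration : float
        Trace duration in seconds.
    mode : {"unwinding", "rezipping", "alternating"}
        Direction of motor activity.  ``alternating`` switches direction
        after geometric bursts with mean ``config.burst_mean_bp``.
    rng : numpy Generator, optional
        Supplied RNG; defaults to one seeded from ``config.seed``.

    Returns
    -------
    (Trace, EventLog)
    """
    config.validate()
    if duration <= 0:
        raise ValueError("duration must be positive")
    if atp <= 0:
        raise ValueError("atp must be positive")
    if mode not in ("unwinding", "rezipping", "alternating"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    cyc_pmf = np.asarray(config.cycles_per_release, float)
    p3 = np.asarray(config.release_3p, float)
    p5 = np.asarray(config.release_5p, float)
    # Re-zipping incorporation uses the same pmfs mirrored (symmetric default).
    cap = config.loop_cap

    # Loops start mid-range in re-zipping/alternating mode so shrinking has room.
    init_loop = 0 if mode == "unwinding" else cap // 2
    state = _LoopState(init_loop, init_loop)
    log = EventLog()

    direction = -1 if mode == "rezipping" else +1
    burst_left = _draw_burst(config, rng) if mode == "alternating" else np.inf

    event_times = [0.0]
    event_positions = [0.0]
    t = 0.0
    n_cycles_target = _draw(cyc_pmf, rng)
    cycles_since = 0

    while t < duration:
        # ---- forced events before the next cycle -------------------------
        if direction < 0 and (state.L3 == 0 or state.L5 == 0):
            # re-zipping cannot shorten an empty loop: force incorporation
            t_evt = t
            _incorporation_event(state, p3, p5, rng, log, t_evt, cycles_since,
                                 event_times, event_positions, cap=cap,
                                 forced=True)
            cycles_since = 0
            n_cycles_target = _draw(cyc_pmf, rng)

        # ---- one catalytic cycle ----------------------------------------
        dt = rng.exponential(1.0 / (config.k_on * atp)) + rng.exponential(
            1.0 / config.k_cat
        )
        t += dt
        if t >= duration:
            break
        state.h += direction
        state.L3 += direction
        state.L5 += direction
        cycles_since += 1
        burst_left -= 1
        log.cycles.append(
            {"time": t, "dh": direction, "L3": state.L3, "L5": state.L5}
        )

        forced = state.L3 > cap or state.L5 > cap
        if cycles_since >= n_cycles_target or forced:
            if direction > 0:
                if rng.random() < config.backstep_prob and min(
                    state.released3, state.released5
                ) >= 1 and not forced:
                    _incorporation_event(
                        state, p3, p5, rng, log, t, cycles_since,
                        event_times, event_positions, backstep=True,
                    )
                else:
                    _release_event(
                        state, p3, p5, rng, log, t, cycles_since,
                        event_times, event_positions, forced=forced,
                    )
            else:
                if rng.random() < config.backstep_prob and min(
                    state.L3, state.L5
                ) >= 1:
                    _release_event(
                        state, p3, p5, rng, log, t, cycles_since,
                        event_times, event_positions, backstep=True,
                    )
                else:
                    _incorporation_event(
                        state, p3, p5, rng, log, t, cycles_since,
                        event_times, event_positions, cap=cap,
                    )
            cycles_since = 0
            n_cycles_target = _draw(cyc_pmf, rng)

        if mode == "alternating" and burst_left <= 0:
            direction = -direction
            burst_left = _draw_burst(config, rng)

    # ---- sample the latent staircase on the uniform grid ----------------
    n = int(round(duration * config.sample_rate))
    time = np.arange(n) / config.sample_rate
    idx = np.searchsorted(np.asarray(event_times), time, side="right") - 1
    latent = np.asarray(event_positions)[idx]
    position = latent.copy()
    if config.noise_sd > 0:
        position = position + rng.normal(0.0, config.noise_sd, size=n)

    trace = Trace(
        time=time,
        position=position,
        force=force,
        atp=atp,
        sample_rate=config.sample_rate,
        id=trace_id,
    )
    return trace, log


def _draw_burst(config: GeneratorConfig, rng: np.random.Generator) -> int:
    return int(rng.geometric(1.0 / config.burst_mean_bp))


def _release_event(state, p3, p5, rng, log, t, n_cycles, ev_t, ev_x,
                   forced=False, backstep=False):
    """Release nt from the loops; observed jump +(r3+r5)/2 bp.

    The drawn amounts are truncated to the loop contents; in the dominant
    direction the remainders carry over to the next event (decoupling
    r3+r5 from twice the cycle count).  Backstep releases (re-zipping
    mode) use plain truncation.
    """
    if backstep:
        r3 = min(_draw(p3, rng), state.L3)
        r5 = min(_draw(p5, rng), state.L5)
    else:
        w3 = _draw(p3, rng) + state.debt3
        w5 = _draw(p5, rng) + state.debt5
        r3 = min(w3, state.L3)
        r5 = min(w5, state.L5)
        state.debt3 = w3 - r3
        state.debt5 = w5 - r5
    if r3 + r5 == 0:
        return
    state.L3 -= r3
    state.L5 -= r5
    state.released3 += r3
    state.released5 += r5
    dx = (r3 + r5) / 2.0
    state.x += dx
    kind = "backstep" if backstep else "release"
    log.events.append(
        {"time": t, "r3": r3, "r5": r5, "dx_bp": dx, "kind": kind,
         "n_cycles": n_cycles, "forced": bool(forced),
         "L3": state.L3, "L5": state.L5}
    )
    ev_t.append(t)
    ev_x.append(state.x)


def _incorporation_event(state, p3, p5, rng, log, t, n_cycles, ev_t, ev_x,
                         cap=None, forced=False, backstep=False):
    """Incorporate nt into the loops; observed jump -(r3+r5)/2 bp.

    In re-zipping mode the drawn amounts are truncated so a loop never
    exceeds the cap, with remainders carried over.  Backstep
    incorporations (unwinding mode: spontaneous re-looping of previously
    released strand) are bounded by what has been released.
    """
    if backstep:
        r3 = min(_draw(p3, rng), state.released3)
        r5 = min(_draw(p5, rng), state.released5)
        if r3 + r5 == 0:
            return
        state.released3 -= r3
        state.released5 -= r5
    else:
        w3 = _draw(p3, rng) + state.debt3
        w5 = _draw(p5, rng) + state.debt5
        room3 = (cap - state.L3) if cap is not None else w3
        room5 = (cap - state.L5) if cap is not None else w5
        r3 = min(w3, max(room3, 0))
        r5 = min(w5, max(room5, 0))
        state.debt3 = w3 - r3
        state.debt5 = w5 - r5
        if r3 + r5 == 0:
            return
    state.L3 += r3
    state.L5 += r5
    dx = -(r3 + r5) / 2.0
    state.x += dx
    kind = "backstep" if backstep else "incorporation"
    log.events.append(
        {"time": t, "r3": r3, "r5": r5, "dx_bp": dx, "kind": kind,
         "n_cycles": n_cycles, "forced": bool(forced),
         "L3": state.L3, "L5": state.L5}
    )
    ev_t.append(t)
    ev_x.append(state.x)


def mean_speed_theoretical(config: GeneratorConfig, atp: float) -> float:
    """Closed-form mean speed (bp/s) of the two-step kinetic scheme.

    ``1 bp / (1/(k_on*atp) + 1/k_cat) = V_max * atp / (K_M + atp)``.
    """
    if atp <= 0:
        raise ValueError("atp must be positive")
    if config.k_on <= 0 or config.k_cat <= 0:
        raise ValueError("rates must be positive")
    return 1.0 / (1.0 / (config.k_on * atp) + 1.0 / config.k_cat)


def sample_cycle_times(
    config: GeneratorConfig, atp: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` per-cycle waiting times Exp(k_on*atp) + Exp(k_cat)."""
    if atp <= 0:
        raise ValueError("atp must be positive")
    return rng.exponential(1.0 / (config.k_on * atp), n) + rng.exponential(
        1.0 / config.k_cat, n
    )


def make_fixture_set(
    config: GeneratorConfig,
    atp_list,
    n_traces_per_atp,
    out_dir,
    seed: int,
    duration: float = 30.0,
    mode: str = "unwinding",
):
    """Write a reproducible set of trace TSVs + event-log JSONs + manifest.

    ``n_traces_per_atp`` may be a single int or a sequence parallel to
    ``atp_list`` (the source study used 25/16/12/12/12 traces at
    0.5/1/2.5/5/10 uM).  Each trace gets its own RNG stream derived from
    ``(seed, trace_index)``, so the same seed reproduces byte-identical
    files.
    """
    from . import io as hio  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atp_list = list(atp_list)
    if np.isscalar(n_traces_per_atp):
        n_traces_per_atp = [int(n_traces_per_atp)] * len(atp_list)
    if len(n_traces_per_atp) != len(atp_list):
        raise ValueError("n_traces_per_atp must match atp_list length")

    manifest = {"seed": int(seed), "mode": mode, "duration_s": duration,
                "traces": []}
    index = 0
    for atp, n_traces in zip(atp_list, n_traces_per_atp):
        for _ in range(n_traces):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), index]))
            trace_id = f"sim_{atp:g}uM_{index:03d}"
            trace, log = simulate_trace(
                config, atp=atp, duration=duration, mode=mode, rng=rng,
                trace_id=trace_id,
            )
            tsv = out / f"{trace_id}.tsv"
            ev = out / f"{trace_id}.events.json"
            hio.write_trace(tsv, trace, seed=index)
            log.to_json(ev)
            manifest["traces"].append(
                {"id": trace_id, "atp_uM": atp, "trace": tsv.name,
                 "events": ev.name, "stream": index}
            )
            index += 1
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
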
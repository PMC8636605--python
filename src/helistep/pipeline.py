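"""End-to-end analysis pipeline.

Runs (optionally) trace simulation, then step detection, step-size
statistics, dwell-time kinetics, and the loop-release model comparison,
writing TSV tables and a JSON summary.  Every stage failure is re-raised
with a stage tag so a pipeline abort names the stage that failed.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, io, kinetics, loopmodel, stepstats, synthetic

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("helistep")


class PipelineError(RuntimeError):
    pass


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - tag and re-raise
        raise PipelineError(f"[{name}] {exc}") from exc
    log.info("stage %s: done", name)


def run_pipeline(config: io.AnalysisConfig) -> dict:
    """Execute the full analysis described by ``config``; returns the summary.

    Stages: simulate (if a ``simulate`` block is present) -> detect ->
    step statistics -> dwell kinetics -> loop-model comparison.  Outputs
    (steps TSV, dwells TSV, summary JSON) go to ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    traces = []
    with _stage("simulate"):
        if config.simulate:
            sim = dict(config.simulate)
            gen = synthetic.GeneratorConfig(
                **{k: v for k, v in sim.get("generator", {}).items()}
            )
            atp_list = sim.get("atp_list", [0.5])
            n_traces = sim.get("n_traces_per_atp", 5)
            duration = sim.get("duration_s", 30.0)
            mode = sim.get("mode", "unwinding")
            if np.isscalar(n_traces):
                n_traces = [int(n_traces)] * len(atp_list)
            idx = 0
            for atp, n in zip(atp_list, n_traces):
                for _ in range(n):
                    rng = np.random.default_rng(
                        np.random.SeedSequence([int(config.seed), idx])
                    )
                    tr, _ = synthetic.simulate_trace(
                        gen, atp=atp, duration=duration, mode=mode, rng=rng,
                        trace_id=f"sim_{atp:g}uM_{idx:03d}",
                    )
                    traces.append(tr)
                    idx += 1
            summary["n_simulated"] = len(traces)
        for p in config.traces:
            traces.append(io.read_trace(p))
    if not traces:
        raise PipelineError("[simulate] no input traces")

    with _stage("detect"):
        step_frames = []
        for tr in traces:
            fit = detection.detect_steps(tr, sensitivity=config.sensitivity)
            step_frames.append(
                detection.extract_steps(fit, trace=tr,
                                        min_size=config.min_step)
            )
        steps = pd.concat(step_frames, ignore_index=True)
        io.write_steps(out / "steps.tsv", steps)
        summary["n_steps"] = int(len(steps))

    with _stage("stepstats"):
        up = steps[steps["s"] > 0]
        summary["mean_unwinding_step_bp"] = (
            float(up["s"].mean()) if len(up) else float("nan")
        )
        down = steps[steps["s"] < 0]
        summary["mean_rezipping_step_bp"] = (
            float(down["s"].mean()) if len(down) else float("nan")
        )
        if len(up) >= 2:
            kde = stepstats.bootstrap_kde(
                steps, side="unwinding", n_boot=config.n_boot,
                seed=config.seed,
            )
            summary["kde_periodicity_bp"] = stepstats.periodicity_estimate(kde)
            pd.DataFrame(
                {"grid_bp": kde.grid, "density": kde.density, "se": kde.se}
            ).to_csv(out / "step_kde.tsv", sep="\t", index=False)

    with _stage("dwellstats"):
        dwells = kinetics.classify_and_filter_dwells(steps)
        io.write_steps(out / "dwells.tsv", dwells)
        summary["n_dwells"] = int(len(dwells))
        for cls in ("+/+", "-/-"):
            sub = dwells[dwells["cls"] == cls]
            if len(sub) >= 10:
                nm = kinetics.n_min(sub["t"].to_numpy())
                key = "unwinding" if cls == "+/+" else "rezipping"
                summary[f"n_min_{key}"] = nm.n_min
                summary[f"n_min_{key}_se"] = nm.se
            if len(sub) >= config.boxcar_window + 3:
                curve = kinetics.dwell_vs_step(
                    dwells, cls=cls, window=config.boxcar_window
                )
                fitk = kinetics.fit_trendline(curve)
                key = "unwinding" if cls == "+/+" else "rezipping"
                summary[f"trendline_{key}"] = {
                    "kappa_per_bp": fitk.kappa, "d0_bp": fitk.d0,
                }
        # speeds and Michaelis-Menten across ATP, if several levels present
        by_atp = []
        for atp, grp in steps.groupby("atp"):
            dsub = dwells[dwells["atp"] == atp]
            try:
                v, se = kinetics.speed_step_over_dwell(grp, dsub)
                by_atp.append({"atp": atp, "v": v, "se": se})
            except ValueError:
                continue
        if len(by_atp) >= 3:
            tab = pd.DataFrame(by_atp)
            mm = kinetics.fit_michaelis_menten(tab["atp"], tab["v"], tab["se"])
            summary["michaelis_menten"] = {
                "v_max_bp_s": mm.v_max, "k_m_uM": mm.k_m,
            }

    with _stage("loopmodel"):
        d3 = loopmodel.DEFAULT_RELEASE("3p")
        d5 = loopmodel.DEFAULT_RELEASE("5p")
        theo = loopmodel.step_pmf_from_release(d3, d5)
        summary["loop_model"] = {
            "mean_bp": theo.mean, "sd_bp": theo.sd,
            "support_bp": theo.support.tolist(),
            "pmf": theo.pmf.tolist(),
        }

    with _stage("report"):
        io.write_summary(out / "summary.json", summary,
                         config=config.as_dict())
    return summary
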
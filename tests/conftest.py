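import numpy as np
import pandas as pd
import pytest

import helistep as h


@pytest.fixture(scope="session")
def default_config():
    return h.GeneratorConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free, backstep-free generator for exactness checks."""
    return h.GeneratorConfig(noise_sd=0.0, backstep_prob=0.0)


def make_staircase(dwell_lens, positions, noise_sd=0.0, seed=0):
    """Piecewise-constant trace from dwell lengths (samples) and levels."""
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.full(n, p, dtype=float)
                        for n, p in zip(dwell_lens, positions)])
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, y.size)
    return y


def steps_frame(s, sigma_s=0.1, atp=0.5, force=12.0, trace_id="t0",
                dwell=0.5):
    """Minimal step table with the columns downstream modules expect."""
    s = np.asarray(s, float)
    n = s.size
    sigma = np.full(n, sigma_s, float) if np.isscalar(sigma_s) else \
        np.asarray(sigma_s, float)
    t_tr = np.cumsum(np.full(n, dwell))
    dw = np.full(n, dwell) if np.isscalar(dwell) else np.asarray(dwell, float)
    return pd.DataFrame({
        "s": s, "sigma_s": sigma, "t_transition": t_tr,
        "dwell_before": dw, "dwell_after": dw,
        "position": np.concatenate([[0.0], np.cumsum(s)[:-1]]),
        "trace_id": trace_id, "force": force, "atp": atp,
    })
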
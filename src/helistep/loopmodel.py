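"""Theoretical step-size distribution from independent strand-release pmfs.

The delayed-release mechanism sequesters both nascent single strands and
releases them in bursts of 1-4 nt per strand.  Assuming the 3' and 5'
releases are independent, the observed step size in base pairs is
``(r3 + r5) / 2`` — the exact discrete convolution of the two per-strand
release distributions mapped onto a half-integer-bp lattice.  The
per-strand pmfs are consumed as parameters (e.g. count tables exported
from molecular-dynamics post-processing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReleaseDistribution",
    "TheoreticalStepDistribution",
    "DEFAULT_RELEASE",
    "step_pmf_from_release",
    "sample_theoretical_steps",
    "release_dist_from_counts",
]


@dataclass(frozen=True)
class ReleaseDistribution:
    """Pmf over nucleotides released per event for one strand (3' or 5')."""

    strand: str  # "3p" | "5p"
    support: tuple = (1, 2, 3, 4)
    pmf: tuple = (0.05, 0.20, 0.45, 0.30)

    def __post_init__(self):
        pmf = np.asarray(self.pmf, float)
        supp = np.asarray(self.support, int)
        if supp.size == 0 or pmf.size != supp.size:
            raise ValueError("support and pmf must be non-empty, same length")
        if np.any(supp <= 0):
            raise ValueError("support must be positive integers")
        if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-12:
            raise ValueError("pmf must be non-negative and sum to 1")

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))


def DEFAULT_RELEASE(strand: str) -> ReleaseDistribution:
    """Packaged default per-strand release pmf (mean 3.0 nt, mode 3 nt)."""
    return ReleaseDistribution(strand=strand)


@dataclass
class TheoreticalStepDistribution:
    """Exact step-size pmf on the half-integer-bp lattice."""

    support: np.ndarray  # bp
    pmf: np.ndarray
    mean: float
    sd: float
    samples: np.ndarray | None = field(default=None, repr=False)


def step_pmf_from_release(d3: ReleaseDistribution,
                          d5: ReleaseDistribution
                          ) -> TheoreticalStepDistribution:
    """Exact convolution of the two release pmfs, mapped to bp via /2."""
    s3 = np.asarray(d3.support, int)
    s5 = np.asarray(d5.support, int)
    totals = {}
    for a, pa in zip(s3, d3.pmf):
        for b, pb in zip(s5, d5.pmf):
            totals[a + b] = totals.get(a + b, 0.0) + pa * pb
    nt = np.array(sorted(totals), dtype=int)
    pmf = np.array([totals[k] for k in nt])
    bp = nt / 2.0
    mean = float(np.dot(bp, pmf))
    sd = float(np.sqrt(np.dot((bp - mean) ** 2, pmf)))
    return TheoreticalStepDistribution(bp, pmf, mean, sd)


def sample_theoretical_steps(d3: ReleaseDistribution,
                             d5: ReleaseDistribution,
                             n: int = 500, seed: int = 0
                             ) -> TheoreticalStepDistribution:
    """``n`` i.i.d. draws of ``(r3 + r5) / 2`` bp, with empirical moments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    r3 = rng.choice(np.asarray(d3.support), size=n, p=np.asarray(d3.pmf))
    r5 = rng.choice(np.asarray(d5.support), size=n, p=np.asarray(d5.pmf))
    samples = (r3 + r5) / 2.0
    exact = step_pmf_from_release(d3, d5)
    exact.samples = samples
    exact.mean = float(samples.mean())
    exact.sd = float(samples.std(ddof=1)) if n > 1 else 0.0
    return exact


def release_dist_from_counts(counts, support=None,
                             strand: str = "3p") -> ReleaseDistribution:
    """Normalize a release-size count table into a pmf.

    ``counts`` are non-negative event counts per size; ``support`` defaults
    to 1..len(counts) nt.  Supports ingestion of count tables exported from
    external trajectory post-processing.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("counts must be non-negative and non-empty")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero counts")
    if support is None:
        support = tuple(range(1, counts.size + 1))
    return ReleaseDistribution(strand=strand, support=tuple(support),
                               pmf=tuple(counts / total))
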
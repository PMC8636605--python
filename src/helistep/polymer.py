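"""DNA polymer mechanics and hairpin thermodynamics.

Extensible worm-like chain (XWLC) force-extension models for ssDNA and
dsDNA, conversion between tether extension changes (nm) and base pairs
unwound, the free-energy credit for stretching released ssDNA, and the
force-dependent probability ``P_open(n, F)`` that one or more base pairs
downstream of position ``n`` in a hairpin stem open thermally.

The XWLC closed form is the high-force Odijk / Marko-Siggia interpolation

    x(F) = h * (1 - 1/2 * sqrt(kT / (F * P)) + F / S)

per monomer (nt or bp), with persistence length ``P``, stretch modulus
``S`` and inter-phosphate distance ``h``.  Hairpin base-pairing free
energies use unified nearest-neighbor dH/dS parameters evaluated at the
working temperature with a logarithmic monovalent-salt entropy correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PolymerParams",
    "HairpinModel",
    "xwlc_extension",
    "delta_x_to_bp",
    "bp_to_delta_x",
    "ss_stretch_free_energy",
    "p_open",
    "p_open_from_costs",
    "fec_predict",
    "load_nn_table",
    "load_packaged_hairpin",
]

#: Boltzmann constant in pN nm / K.
K_B = 1.380649e-2
#: Gas constant in kcal / (mol K), for converting kcal/mol to kT units.
R_KCAL = 1.98720425864083e-3


@dataclass(frozen=True)
class PolymerParams:
    """Elasticity constants for dsDNA handles and released ssDNA."""

    P_ds: float = 53.0  # nm
    P_ss: float = 1.0  # nm
    h_ds: float = 0.34  # nm per bp
    h_ss: float = 0.59  # nm per nt
    S_ds: float = 1100.0  # pN
    S_ss: float = 1000.0  # pN
    temperature: float = 295.15  # K (22 C)

    def __post_init__(self):
        for name in ("P_ds", "P_ss", "h_ds", "h_ss", "S_ds", "S_ss",
                     "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy in pN nm."""
        return K_B * self.temperature


def xwlc_extension(force, params: PolymerParams = PolymerParams(),
                   kind: str = "ss"):
    """XWLC extension per nt (ss) or per bp (ds) at the given force (pN)."""
    force = np.asarray(force, dtype=float)
    if np.any(force <= 0):
        raise ValueError("force must be positive")
    if kind == "ss":
        P, h, S = params.P_ss, params.h_ss, params.S_ss
    elif kind == "ds":
        P, h, S = params.P_ds, params.h_ds, params.S_ds
    else:
        raise ValueError("kind must be 'ss' or 'ds'")
    ext = h * (1.0 - 0.5 * np.sqrt(params.kT / (force * P)) + force / S)
    return ext if ext.ndim else float(ext)


def delta_x_to_bp(delta_x, force: float,
                  params: PolymerParams = PolymerParams()):
    """Convert a tether extension change (nm) to base pairs unwound.

    Each base pair unwound releases two nucleotides of ssDNA, so the
    change in extension is divided by twice the ssDNA extension per nt
    at the measured force.  Sign-preserving.
    """
    return np.asarray(delta_x, float) / (2.0 * xwlc_extension(force, params, "ss"))


def bp_to_delta_x(bp, force: float, params: PolymerParams = PolymerParams()):
    """Inverse of :func:`delta_x_to_bp` (bp unwound -> nm of extension)."""
    return np.asarray(bp, float) * 2.0 * xwlc_extension(force, params, "ss")


def ss_stretch_free_energy(force: float,
                           params: PolymerParams = PolymerParams(),
                           n_grid: int = 2000) -> float:
    """Free energy (kT per nt) gained by stretching released ssDNA to ``force``.

    Trapezoid quadrature of the XWLC extension over [0, F].  The Odijk
    interpolation predicts negative extension below ``F0 = kT / (4 P_ss)``
    (outside its validity range); the integrand is clamped at zero there,
    which keeps the free energy non-negative and increasing in force.
    """
    if force <= 0:
        raise ValueError("force must be positive")
    f = np.linspace(1e-9, force, n_grid)
    x = np.maximum(xwlc_extension(f, params, "ss"), 0.0)
    return float(np.trapezoid(x, f) / params.kT)


# ---------------------------------------------------------------------------
# Hairpin nearest-neighbor thermodynamics


def load_nn_table(path=None) -> pd.DataFrame:
    """Load the nearest-neighbor dH/dS table (packaged by default)."""
    if path is None:
        path = resources.files("helistep") / "data" / "nn_santalucia.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("dinucleotide")
    return df


@dataclass
class HairpinModel:
    """A DNA hairpin: stem sequence (5'->3', one strand) plus tetraloop.

    Position index ``n`` is 1-based in bp from the fork toward the loop;
    the tetraloop is treated as a fixed cap excluded from opening sums.
    """

    stem: str
    loop: str = "TTTT"
    monovalent_mM: float = 55.0
    nn_table: pd.DataFrame = field(default_factory=load_nn_table, repr=False)

    def __post_init__(self):
        self.stem = self.stem.upper()
        if len(self.stem) < 1:
            raise ValueError("stem must be at least 1 bp")
        if set(self.stem) - set("ACGT"):
            raise ValueError("stem must contain only A/C/G/T")
        for i in range(len(self.stem) - 1):
            if self.stem[i:i + 2] not in self.nn_table.index:
                raise ValueError(f"no NN entry for {self.stem[i:i+2]}")

    def __len__(self) -> int:
        return len(self.stem)

    def bp_opening_costs(self, params: PolymerParams = PolymerParams()
                         ) -> np.ndarray:
        """Per-bp duplex opening cost in kT at temperature and salt.

        Base pair ``i`` (1-based from the fork) is assigned the
        nearest-neighbor step (i, i+1); the terminal bp duplicates the
        last step.  Salt: entropic correction ``+0.368 ln[Mono+]``
        cal/(mol K) per NN step.
        """
        T = params.temperature
        salt = self.monovalent_mM / 1000.0
        costs = np.empty(len(self.stem))
        for i in range(len(self.stem)):
            dinuc = self.stem[i:i + 2] if i < len(self.stem) - 1 else \
                self.stem[-2:]
            if len(dinuc) < 2:  # single-bp stem
                dinuc = self.stem[0] * 2
            row = self.nn_table.loc[dinuc]
            dS = row["dS_cal"] + 0.368 * np.log(salt)
            dG_kcal = row["dH_kcal"] - T * dS / 1000.0  # duplex formation
            costs[i] = -dG_kcal / (R_KCAL * T)  # opening cost, kT
        return costs

    @classmethod
    def from_fasta(cls, path, name: str | None = None, **kw) -> "HairpinModel":
        """Read a stem from FASTA; ``loop=XXXX`` may be annotated in the
        description line."""
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            if name is None or rec.id == name:
                loop = "TTTT"
                for tok in rec.description.split():
                    if tok.startswith("loop="):
                        loop = tok.split("=", 1)[1]
                return cls(stem=str(rec.seq), loop=loop, **kw)
        raise ValueError(f"record {name!r} not found in {path}")


def load_packaged_hairpin(kind: str = "mixed", **kw) -> HairpinModel:
    """Load one of the packaged synthetic 89-bp stems (mixed | uniform)."""
    path = resources.files("helistep") / "data" / "hairpins_synthetic.fasta"
    return HairpinModel.from_fasta(str(path), name=f"hp_{kind}_89", **kw)


def p_open_from_costs(costs_kT: np.ndarray, g_ss_kT: float) -> float:
    """Opening probability from per-bp costs (kT) and per-nt stretch credit.

    ``P_open = sum_{m>=1} exp(-dG(m)) / sum_{m>=0} exp(-dG(m))`` with
    ``dG(m) = sum of the next m opening costs - 2 m g_ss`` — each bp opened
    releases two nucleotides that stretch at the applied force.
    """
    costs = np.asarray(costs_kT, dtype=float)
    dg = np.concatenate([[0.0], np.cumsum(costs - 2.0 * g_ss_kT)])
    w = np.exp(-(dg - dg.min()))  # shift for numerical stability
    return float(np.clip(w[1:].sum() / w.sum(), 0.0, 1.0))


def p_open(hairpin: HairpinModel, n: int, force: float,
           params: PolymerParams = PolymerParams()) -> float:
    """Probability that >=1 bp opens thermally downstream of stem position n.

    ``n`` is 1-based; base pairs ``n+1 .. L`` are available to open (the
    tetraloop is excluded; opening past it would be full unfolding).
    ``n = L`` returns 0.  Non-decreasing in force.
    """
    L = len(hairpin)
    if not 1 <= n <= L:
        raise ValueError(f"n must be in [1, {L}]")
    if force <= 0:
        raise ValueError("force must be positive")
    costs = hairpin.bp_opening_costs(params)[n:]
    if costs.size == 0:
        return 0.0
    g_ss = ss_stretch_free_energy(force, params)
    return p_open_from_costs(costs, g_ss)


def fec_predict(hairpin: HairpinModel, params: PolymerParams,
                force_grid, handles_bp: int = 3000,
                folded_offset_nm: float = 0.0) -> pd.DataFrame:
    """Predicted force-extension branches for the folded and unfolded hairpin.

    Folded branch: dsDNA handles plus an optional fixed offset for the
    folded hairpin width.  Unfolded branch adds ssDNA for both stem strands
    and the loop (extension clamped at zero below the XWLC validity range).
    Intended for fixture validation, not for fitting instrument data.
    """
    f = np.asarray(force_grid, dtype=float)
    if np.any(f <= 0) or np.any(np.diff(f) <= 0):
        raise ValueError("force_grid must be positive and ascending")
    handles = handles_bp * xwlc_extension(f, params, "ds")
    ss_nt = 2 * len(hairpin) + len(hairpin.loop)
    folded = handles + folded_offset_nm
    unfolded = handles + ss_nt * np.maximum(xwlc_extension(f, params, "ss"), 0.0)
    return pd.DataFrame(
        {"force_pN": f, "ext_folded_nm": folded, "ext_unfolded_nm": unfolded}
    )
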
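"""Frequency sweeps and surfaces of the variance components.

Two scan shapes reproduce the package's applied analyses as data tables:
sweeps of the variance components along the standardized disequilibrium
index D' at fixed allele frequencies, and surfaces over a lattice of
allele-frequency pairs at fixed D' and fixation index F.  Each grid point
runs one full decomposition; rows carry the mean and all variance
components in long-friendly wide format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .frequencies import LDSpec, d_bounds, frequencies_from_ldspec
from .solver import VarianceDecomposition, decompose

__all__ = [
    "default_dprime_grid",
    "default_frequency_lattice",
    "allele_freq_pair",
    "dprime_sweep",
    "freq_surface",
]

#: variance columns reported per scan row
_VAR_COLS = ["V_A", "V_D", "V_I", "V_AA", "V_DA", "V_AD", "V_DD", "V_G"]


def default_dprime_grid(step: float = 0.01, limit: float = 0.99) -> np.ndarray:
    """Symmetric D' grid avoiding +-1 so every genotype class stays supported."""
    n = int(round(limit / step))
    return np.round(np.arange(-n, n + 1) * step, 10)


def default_frequency_lattice(step: float = 0.01) -> np.ndarray:
    """Allele-frequency lattice over (0, 1), endpoints excluded."""
    n = int(round(1.0 / step))
    return np.round(np.arange(1, n) * step, 10)


def allele_freq_pair(f: float, convention: str = "B2") -> tuple[float, float]:
    """Translate a shared allele frequency into (pA1, pB1).

    The applied two-locus settings are quoted in two conventions that do
    not agree with each other in the source material: ``"B2"`` sets
    f(A1) = f(B2) = f (so pB1 = 1 - f; the secondary-contact configuration
    where the derived alleles segregate on complementary backgrounds) and
    ``"B1"`` sets f(A1) = f(B1) = f.  Both are exposed so either reading
    can be reproduced explicitly.
    """
    if convention == "B2":
        return f, 1.0 - f
    if convention == "B1":
        return f, f
    raise ValueError(f"convention must be 'B1' or 'B2', got {convention!r}")


def _row(gpmap, pA1, pB1, dprime, F, feasible=True, **solver_kw) -> dict:
    # tabulate the mixed class through its sequential detachment so that
    # V_AA + V_DA + V_AD + V_DD == V_I holds exactly row by row
    solver_kw.setdefault("da_ad_mode", "sequential")
    p = frequencies_from_ldspec(LDSpec(pA1, pB1, Dprime=dprime, F=F))
    res = decompose(gpmap, p, **solver_kw)
    v = res.variances
    sv = res.split_variances
    return {
        "pA1": pA1,
        "pB1": pB1,
        "Dprime": dprime,
        "F": F,
        "feasible": feasible,
        "mu": res.mu,
        "V_A": v["A"],
        "V_D": v["D"],
        "V_I": v["I"],
        "V_AA": v["AA"],
        "V_DA": sv.get("DA", v.get("DA", np.nan)),
        "V_AD": sv.get("AD", v.get("AD", np.nan)),
        "V_DD": v["DD"],
        "V_G": v["G"],
    }


def dprime_sweep(
    gpmap,
    pA1: float,
    pB1: float,
    F: float = 0.0,
    grid=None,
    **solver_kw,
) -> pd.DataFrame:
    """Variance components along a D' grid at fixed allele frequencies."""
    if grid is None:
        grid = default_dprime_grid()
    rows = [_row(gpmap, pA1, pB1, float(dp), F, **solver_kw) for dp in grid]
    return pd.DataFrame(rows)


def freq_surface(
    gpmap,
    dprime: float = 0.0,
    F: float = 0.0,
    grid=None,
    **solver_kw,
) -> pd.DataFrame:
    """Variance components over an allele-frequency lattice at fixed D', F.

    D' is feasible for every interior frequency pair by construction of
    the standardized index; rows keep a ``feasible`` flag for forward
    compatibility with recipes parameterized by raw D.
    """
    if grid is None:
        grid = default_frequency_lattice()
    grid = np.asarray(grid, dtype=float)
    rows = []
    for pB1 in grid:
        for pA1 in grid:
            rows.append(_row(gpmap, float(pA1), float(pB1), dprime, F, **solver_kw))
    return pd.DataFrame(rows)
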
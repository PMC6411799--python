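"""Genotype-frequency vectors and the two-locus D'/F frequency generator.

The decomposition engine consumes an arbitrary vector of multilocus genotype
frequencies (the diagonal of the weights matrix of the regression chain).
For the two-locus applied cases, frequencies are generated from a compact
recipe: marginal allele frequencies, the standardized linkage-disequilibrium
index D' (Lewontin normalization of the gametic covariance D), and a
per-locus fixation index F controlling the heterozygote deficit.

Construction used for F: the population is a mixture in which, with
probability 1 - F, an individual is the random union of two gametes drawn
from the haplotype pool, and with probability F the two gametes are
identical copies of a single draw.  This yields a marginal fixation index of
exactly F at each locus while keeping the gametic D' of the pool intact
(at F = 0 it reduces to random union of gametes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._ordering import genotype_labels, infer_loci, n_genotypes

__all__ = [
    "HaplotypeFreqs",
    "LDSpec",
    "PopulationFrequencies",
    "d_bounds",
    "haplotypes_from_ldspec",
    "genotype_freqs",
    "ld_measures",
    "read_frequencies",
    "write_frequencies",
]

_CLAMP_TOL = 1e-12
_SUM_TOL = 1e-8


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Frequencies of the four gametes A1B1, A1B2, A2B1, A2B2."""

    f11: float
    f12: float
    f21: float
    f22: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -_CLAMP_TOL):
            raise ValueError(f"haplotype frequencies must be >= 0, got {arr}")
        if abs(arr.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"haplotype frequencies must sum to 1, got {arr.sum()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.f11, self.f12, self.f21, self.f22], dtype=float)

    @property
    def pA1(self) -> float:
        return self.f11 + self.f12

    @property
    def pB1(self) -> float:
        return self.f11 + self.f21

    @property
    def D(self) -> float:
        """Gametic disequilibrium D = f11 - pA1*pB1."""
        return self.f11 - self.pA1 * self.pB1


@dataclass(frozen=True)
class LDSpec:
    """Two-locus frequency recipe: allele frequencies, D', fixation index."""

    pA1: float
    pB1: float
    Dprime: float = 0.0
    F: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pA1", "pB1"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(
                    f"{name} must lie strictly inside (0, 1) for the D' "
                    f"parameterization; got {v}"
                )
        if not -1.0 <= self.Dprime <= 1.0:
            raise ValueError(f"Dprime must lie in [-1, 1], got {self.Dprime}")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"F must lie in [0, 1], got {self.F}")


class PopulationFrequencies:
    """Vector of 3**l multilocus genotype frequencies in canonical order."""

    def __init__(self, p, loci: int | None = None):
        p = np.asarray(p, dtype=float)
        if p.ndim != 1:
            raise ValueError("frequency vector must be one-dimensional")
        if loci is None:
            loci = infer_loci(p.size)
        elif p.size != n_genotypes(loci):
            raise ValueError(
                f"expected {n_genotypes(loci)} frequencies for {loci} loci, "
                f"got {p.size}"
            )
        if not np.all(np.isfinite(p)):
            raise ValueError("frequencies must be finite")
        if np.any(p < -_CLAMP_TOL):
            raise ValueError(f"frequencies must be >= 0, min was {p.min()}")
        total = p.sum()
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"frequencies must sum to 1, got {total}")
        p = np.clip(p, 0.0, None)
        self.p = p / p.sum()
        self.loci = loci

    def __len__(self) -> int:
        return self.p.size

    def __repr__(self) -> str:
        return f"PopulationFrequencies(loci={self.loci}, p={self.p!r})"

    @property
    def labels(self) -> list[str]:
        return genotype_labels(self.loci)

    def support(self) -> np.ndarray:
        """Boolean mask of genotype classes with non-zero frequency."""
        return self.p > 0.0


def _as_freq(p) -> PopulationFrequencies:
    return p if isinstance(p, PopulationFrequencies) else PopulationFrequencies(p)


def d_bounds(pA1: float, pB1: float) -> tuple[float, float]:
    """Feasible range (Dmin, Dmax) of the gametic disequilibrium D.

    Lewontin bounds: ``Dmax = min(pA1*(1-pB1), (1-pA1)*pB1)`` and
    ``Dmin = -min(pA1*pB1, (1-pA1)*(1-pB1))``; D' = D/Dmax for D >= 0 and
    D/|Dmin| for D < 0.
    """
    for name, v in (("pA1", pA1), ("pB1", pB1)):
        if not 0.0 < v < 1.0:
            raise ValueError(
                f"{name}={v}: D bounds are only defined for allele frequencies "
                "strictly inside (0, 1)"
            )
    dmax = min(pA1 * (1.0 - pB1), (1.0 - pA1) * pB1)
    dmin = -min(pA1 * pB1, (1.0 - pA1) * (1.0 - pB1))
    return dmin, dmax


def haplotypes_from_ldspec(spec: LDSpec) -> HaplotypeFreqs:
    """Haplotype frequencies realizing the allele frequencies and D' of a spec."""
    dmin, dmax = d_bounds(spec.pA1, spec.pB1)
    d = spec.Dprime * dmax if spec.Dprime >= 0 else spec.Dprime * abs(dmin)
    pA2 = 1.0 - spec.pA1
    pB2 = 1.0 - spec.pB1
    f = np.array(
        [
            spec.pA1 * spec.pB1 + d,
            spec.pA1 * pB2 - d,
            pA2 * spec.pB1 - d,
            pA2 * pB2 + d,
        ]
    )
    f = np.clip(f, 0.0, None)  # |D'| = 1 can leave -1e-17 residues
    return HaplotypeFreqs(*f)


def genotype_freqs(h: HaplotypeFreqs, F: float = 0.0) -> PopulationFrequencies:
    """Nine two-locus genotype frequencies from a haplotype pool and fixation F.

    An ordered gamete pair (g1, g2) has probability
    ``(1-F) f(g1) f(g2) + F f(g1) [g1 == g2]``; phase is then pooled, so the
    coupling (A1B1/A2B2) and repulsion (A1B2/A2B1) double heterozygotes fall
    into the same genotype class.
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"F must lie in [0, 1], got {F}")
    f = h.as_array()
    # haplotype index -> (allele at A, allele at B), 0-based
    hap_alleles = [(0, 0), (0, 1), (1, 0), (1, 1)]
    p = np.zeros(9)
    for i, (a1, b1) in enumerate(hap_alleles):
        for j, (a2, b2) in enumerate(hap_alleles):
            prob = (1.0 - F) * f[i] * f[j] + (F * f[i] if i == j else 0.0)
            code_a = a1 + a2  # number of A2 alleles
            code_b = b1 + b2
            p[code_a + 3 * code_b] += prob
    return PopulationFrequencies(p, loci=2)


def _corner_hap_freq(p_corner: float, F: float) -> float:
    """Invert p_corner = (1-F) f**2 + F f for the haplotype frequency f."""
    if F >= 1.0:
        return p_corner
    disc = F * F + 4.0 * (1.0 - F) * p_corner
    return (-F + np.sqrt(max(disc, 0.0))) / (2.0 * (1.0 - F))


def ld_measures(p) -> dict[str, float]:
    """Marginal allele frequencies, fixation indices, and gametic D/D'.

    D and D' are recovered by inverting the mixture construction of
    :func:`genotype_freqs` on the four double-homozygote classes; for
    frequency vectors not produced by that construction (e.g. arbitrary
    phase-pooled data) they are approximations.  A monomorphic locus makes
    D' undefined; it is reported as NaN.
    """
    pf = _as_freq(p)
    if pf.loci != 2:
        raise ValueError("ld_measures is defined for two-locus frequency vectors")
    v = pf.p
    m = v.reshape(3, 3)  # m[code_b, code_a] given locus-1-fastest layout
    pa = m.sum(axis=0)  # genotype freqs at locus A
    pb = m.sum(axis=1)
    pA1 = pa[0] + 0.5 * pa[1]
    pB1 = pb[0] + 0.5 * pb[1]

    def fix_index(geno: np.ndarray, p1: float) -> float:
        h_exp = 2.0 * p1 * (1.0 - p1)
        if h_exp <= 0.0:
            return np.nan
        return 1.0 - geno[1] / h_exp

    F_A = fix_index(pa, pA1)
    F_B = fix_index(pb, pB1)
    if np.isnan(F_A) and np.isnan(F_B):
        F_hat = 0.0
    else:
        F_hat = np.nanmean([F_A, F_B])

    if min(pA1, 1.0 - pA1, pB1, 1.0 - pB1) <= 0.0:
        return {
            "pA1": pA1,
            "pB1": pB1,
            "D": np.nan,
            "Dprime": np.nan,
            "F_A": F_A,
            "F_B": F_B,
        }

    # corner classes: A1A1B1B1=m[0,0], A1A1B2B2=m[2,0], A2A2B1B1=m[0,2], A2A2B2B2=m[2,2]
    f11 = _corner_hap_freq(m[0, 0], F_hat)
    f12 = _corner_hap_freq(m[2, 0], F_hat)
    f21 = _corner_hap_freq(m[0, 2], F_hat)
    f22 = _corner_hap_freq(m[2, 2], F_hat)
    total = f11 + f12 + f21 + f22
    if total > 0:
        f11, f12, f21, f22 = (x / total for x in (f11, f12, f21, f22))
    d = f11 - (f11 + f12) * (f11 + f21)
    dmin, dmax = d_bounds(pA1, pB1)
    if d >= 0:
        dprime = d / dmax if dmax > 0 else np.nan
    else:
        dprime = d / abs(dmin) if dmin < 0 else np.nan
    return {
        "pA1": pA1,
        "pB1": pB1,
        "D": d,
        "Dprime": dprime,
        "F_A": F_A,
        "F_B": F_B,
    }


def frequencies_from_ldspec(spec: LDSpec) -> PopulationFrequencies:
    """Convenience: LDSpec -> haplotypes -> nine genotype frequencies."""
    return genotype_freqs(haplotypes_from_ldspec(spec), spec.F)


def read_frequencies(path) -> PopulationFrequencies:
    """Read a genotype-frequency vector from CSV or JSON.

    CSV needs columns ``genotype_label,frequency``; JSON maps labels to
    frequencies.  Labels must cover the canonical genotype space exactly;
    file row order is ignored in favour of the canonical order.
    """
    mapping = _read_labelled(path, value_field="frequency")
    return PopulationFrequencies(_to_canonical_vector(mapping, path))


def write_frequencies(p, path) -> None:
    pf = _as_freq(p)
    _write_labelled(pf.labels, pf.p, path, value_field="frequency")


def _read_labelled(path, value_field: str) -> dict[str, float]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: JSON must be an object of label -> value")
        return {str(k): float(v) for k, v in data.items()}
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}
    if "genotype_label" not in cols or value_field not in cols:
        raise ValueError(
            f"{path}: expected columns genotype_label,{value_field}; "
            f"found {list(df.columns)}"
        )
    return dict(
        zip(df[cols["genotype_label"]].astype(str), df[cols[value_field]].astype(float))
    )


def _to_canonical_vector(mapping: dict[str, float], path) -> np.ndarray:
    loci = infer_loci(len(mapping))
    labels = genotype_labels(loci)
    missing = [lab for lab in labels if lab not in mapping]
    if missing:
        raise ValueError(
            f"{path}: missing genotype(s) {missing[:3]}{'...' if len(missing) > 3 else ''} "
            f"for a {loci}-locus system"
        )
    return np.array([mapping[lab] for lab in labels])


def _write_labelled(labels, values, path, value_field: str) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(
                {lab: float(v) for lab, v in zip(labels, values)}, fh, indent=1
            )
            fh.write("\n")
    else:
        pd.DataFrame({"genotype_label": labels, value_field: values}).to_csv(
            path, index=False
        )
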
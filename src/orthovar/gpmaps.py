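"""Genotype-phenotype maps: applied-case fixtures, effect builder, file I/O.

Two two-locus maps of evolutionary interest ship with the package:

* a Bateson-Dobzhansky-Muller (BDM) incompatibility map, in which two
  initially neutral derived alleles (A2, B2) arising in isolated
  populations depress fitness as soon as they co-occur in one individual
  after secondary contact; and
* a sign-epistasis map built from a single additive-by-additive effect
  referenced at the double heterozygote, whose marginal effects change
  sign across backgrounds and which collapses to an over- or underdominant
  single locus under complete positive or negative allelic association.

Maps can also be built from individual-referenced genetic effects (corner
or center coding) or read from CSV/JSON files keyed by genotype label.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from ._ordering import genotype_codes
from .frequencies import _read_labelled, _to_canonical_vector, _write_labelled
from .solver import GPMap

__all__ = [
    "EffectSpec",
    "from_effects",
    "corner_effects",
    "sign_epistasis_map",
    "bdm_map",
    "read_gpmap",
    "write_gpmap",
]

#: frozen expected sign-epistasis values in canonical order (see
#: :func:`sign_epistasis_map`)
SIGN_EPISTASIS_VALUES = (0.0, 1.0, 2.0, 1.0, 1.0, 1.0, 2.0, 1.0, 0.0)

_BDM_RESOURCE = "bdm_synthetic.csv"


@dataclass(frozen=True)
class EffectSpec:
    """Individual-referenced genetic effects of a two-locus biallelic system.

    ``coding="corner"`` references the genotype homozygous for allele 1 at
    both loci (G_1111): the additive covariate x_j counts substituted
    alleles (0, 1, 2) and h_j indicates the heterozygote.  ``"center"``
    references the double heterozygote (G_1212): x_j runs over (-1, 0, 1).
    The map is

        G = R + a1*x1 + a2*x2 + d1*h1 + d2*h2
              + aa*x1*x2 + ad*x1*h2 + da*h1*x2 + dd*h1*h2.
    """

    reference: float
    coding: str = "corner"
    a1: float = 0.0
    d1: float = 0.0
    a2: float = 0.0
    d2: float = 0.0
    aa: float = 0.0
    ad: float = 0.0
    da: float = 0.0
    dd: float = 0.0

    def __post_init__(self) -> None:
        if self.coding not in ("corner", "center"):
            raise ValueError(
                f"coding must be 'corner' (reference G_1111) or 'center' "
                f"(reference G_1212), got {self.coding!r}"
            )


def _covariates(coding: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    codes = genotype_codes(2)
    x1 = codes[:, 0].astype(float)
    x2 = codes[:, 1].astype(float)
    if coding == "center":
        x1 = x1 - 1.0
        x2 = x2 - 1.0
    h1 = (codes[:, 0] == 1).astype(float)
    h2 = (codes[:, 1] == 1).astype(float)
    return x1, h1, x2, h2


def _effect_design(coding: str) -> np.ndarray:
    x1, h1, x2, h2 = _covariates(coding)
    one = np.ones(9)
    return np.column_stack(
        [one, x1, h1, x2, h2, x1 * x2, x1 * h2, h1 * x2, h1 * h2]
    )


def from_effects(spec: EffectSpec) -> GPMap:
    """Build the 9-genotype GP map encoded by an :class:`EffectSpec`."""
    beta = np.array(
        [
            spec.reference,
            spec.a1,
            spec.d1,
            spec.a2,
            spec.d2,
            spec.aa,
            spec.ad,
            spec.da,
            spec.dd,
        ]
    )
    return GPMap(_effect_design(spec.coding) @ beta, loci=2)


def corner_effects(gpmap) -> EffectSpec:
    """Recover corner-referenced effects from a two-locus GP map.

    Inverts the (full-rank) 9x9 effect design, so composing with
    :func:`from_effects` is the identity.
    """
    gp = gpmap if isinstance(gpmap, GPMap) else GPMap(gpmap)
    if gp.loci != 2:
        raise ValueError("effect extraction is defined for two-locus maps")
    beta = np.linalg.solve(_effect_design("corner"), gp.values)
    return EffectSpec(
        reference=float(beta[0]),
        coding="corner",
        a1=float(beta[1]),
        d1=float(beta[2]),
        a2=float(beta[3]),
        d2=float(beta[4]),
        aa=float(beta[5]),
        ad=float(beta[6]),
        da=float(beta[7]),
        dd=float(beta[8]),
    )


def sign_epistasis_map() -> GPMap:
    """The sign-epistasis GP map: one AA effect referenced at G_1212.

    ``from_effects(center, R=1, aa=-1)`` gives, in canonical order,
    (0, 1, 2, 1, 1, 1, 2, 1, 0): the coupling genotypes (A1B1|A1B1,
    A1B1|A2B2, A2B2|A2B2) read 0, 1, 0 -- an overdominant single locus
    under complete positive association -- and the repulsion genotypes
    (A1A1B2B2, A1B2|A2B1, A2A2B1B1) read 2, 1, 2, an underdominant one.
    """
    gp = from_effects(EffectSpec(reference=1.0, coding="center", aa=-1.0))
    expected = np.array(SIGN_EPISTASIS_VALUES)
    if not np.array_equal(gp.values, expected):
        raise AssertionError(
            "sign-epistasis construction no longer matches its frozen values"
        )
    return gp


def _bdm_path() -> Path:
    return Path(resources.files("orthovar").joinpath("data", _BDM_RESOURCE))


def bdm_map(validate: bool = True) -> GPMap:
    """The packaged BDM incompatibility GP map.

    The shipped values are a synthetic reconstruction (see the packaged
    file ``data/bdm_synthetic.csv``): fitness 1 for every genotype in which
    the derived alleles A2 and B2 do not meet, and 0 for every genotype
    carrying at least one copy of each.  The loader validates the
    structure this case must have: every corner-referenced marginal effect
    (from G_1111) is nil, and all four pairwise epistasis classes (AA, AD,
    DA, DD) are non-zero.
    """
    gp = read_gpmap(_bdm_path())
    if gp.loci != 2:
        raise AssertionError("BDM fixture must describe two loci")
    if validate:
        eff = corner_effects(gp)
        marginals = np.array([eff.a1, eff.d1, eff.a2, eff.d2])
        if np.any(np.abs(marginals) > 1e-12):
            raise AssertionError(
                f"BDM fixture has non-nil marginal effects {marginals} from "
                "the G_1111 reference"
            )
        pairwise = np.array([eff.aa, eff.ad, eff.da, eff.dd])
        if np.any(np.abs(pairwise) < 1e-12):
            raise AssertionError(
                "BDM fixture must carry all four pairwise epistasis classes; "
                f"got (aa, ad, da, dd) = {pairwise}"
            )
    return gp


def read_gpmap(path) -> GPMap:
    """Read a GP map from CSV (columns genotype_label,value) or JSON."""
    mapping = _read_labelled(path, value_field="value")
    return GPMap(_to_canonical_vector(mapping, path))


def write_gpmap(gpmap, path) -> None:
    gp = gpmap if isinstance(gpmap, GPMap) else GPMap(gpmap)
    _write_labelled(gp.labels, gp.values, path, value_field="value")
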
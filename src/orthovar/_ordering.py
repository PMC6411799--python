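"""Canonical genotype ordering and labels for multilocus biallelic systems.

Every vector in this package (genotypic values, genotype frequencies,
per-genotype component values) is laid out over the 3**l multilocus
genotype space with the per-locus code

    0 = homozygote for allele 1, 1 = heterozygote, 2 = homozygote for allele 2,

and with the code of locus 1 varying fastest down the vector.  For two loci
this is the order

    A1A1B1B1, A1A2B1B1, A2A2B1B1,
    A1A1B1B2, A1A2B1B2, A2A2B1B2,
    A1A1B2B2, A1A2B2B2, A2A2B2B2.
"""

from __future__ import annotations

import itertools
import string

import numpy as np

__all__ = [
    "n_genotypes",
    "genotype_codes",
    "genotype_labels",
    "locus_letters",
    "infer_loci",
]

_GENOTYPE_SUFFIX = {0: "11", 1: "12", 2: "22"}


def n_genotypes(loci: int) -> int:
    """Number of multilocus genotypes for ``loci`` biallelic loci."""
    if loci < 1:
        raise ValueError(f"number of loci must be >= 1, got {loci}")
    return 3**loci


def genotype_codes(loci: int) -> np.ndarray:
    """(3**l, l) integer array of per-locus codes, locus 1 varying fastest."""
    n = n_genotypes(loci)
    codes = np.empty((n, loci), dtype=np.int64)
    for j in range(loci):
        codes[:, j] = (np.arange(n) // 3**j) % 3
    return codes


def locus_letters(loci: int) -> list[str]:
    """Single-letter locus names A, B, C, ... (only used for l <= 26)."""
    if loci > 26:
        raise ValueError("letter naming supports at most 26 loci")
    return list(string.ascii_uppercase[:loci])


def genotype_labels(loci: int) -> list[str]:
    """Canonical genotype labels in canonical order.

    Two-locus labels read ``A1A1B1B1`` ... ``A2A2B2B2``; beyond two loci the
    compact integer-code form ``L1:0,L2:1,...`` is used.
    """
    codes = genotype_codes(loci)
    if loci <= 2:
        letters = locus_letters(loci)
        out = []
        for row in codes:
            parts = []
            for letter, c in zip(letters, row):
                s = _GENOTYPE_SUFFIX[int(c)]
                parts.append(f"{letter}{s[0]}{letter}{s[1]}")
            out.append("".join(parts))
        return out
    return [
        ",".join(f"L{j + 1}:{int(c)}" for j, c in enumerate(row)) for row in codes
    ]


def infer_loci(length: int) -> int:
    """Number of loci from a vector length, which must be a power of 3."""
    loci = 0
    n = 1
    while n < length:
        n *= 3
        loci += 1
    if n != length or loci == 0:
        raise ValueError(
            f"vector length {length} is not 3**l for a positive number of loci"
        )
    return loci


def marginal_genotype_labels(letter: str) -> list[str]:
    """Labels of the three genotypes at a single locus, e.g. A1A1, A1A2, A2A2."""
    return [f"{letter}1{letter}1", f"{letter}1{letter}2", f"{letter}2{letter}2"]


def subset_iter(loci: int, order: int):
    """Ordered locus subsets (0-based indices) of a given interaction order."""
    return itertools.combinations(range(loci), order)
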
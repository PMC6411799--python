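"""Regression design matrices for the sequential decomposition chain.

The chain detaches, in order: the population mean, the additive component
(allele-count columns for every locus), the dominance component (per-locus
genotype indicator columns), and then the epistasis classes order by order
(AA, DA|AD, DD for pairs; AAA, DAA|ADA|AAD, DDA|DAD|ADD, DDD for triples;
and so on).  Interaction columns are built as row-wise (face-splitting)
Kronecker products of the per-locus marginal rows: the allele-count row
where a locus enters additively, the genotype-indicator row where it enters
through dominance.  Rows follow the canonical genotype order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._ordering import (
    genotype_codes,
    locus_letters,
    marginal_genotype_labels,
    n_genotypes,
)

__all__ = [
    "DesignBlock",
    "single_locus_additive",
    "multilocus_additive",
    "multilocus_dominance",
    "interaction_block",
    "detachment_schedule",
]

#: one-locus additive design: allele counts of each type in genotypes 11, 12, 22
N_ADDITIVE = np.array([[2, 0], [1, 1], [0, 2]], dtype=float)
#: one-locus dominance design: genotype indicators (identity rows)
N_DOMINANCE = np.eye(3)


@dataclass(frozen=True)
class DesignBlock:
    """A design matrix together with its component label and column names."""

    label: str
    matrix: np.ndarray
    column_labels: tuple[str, ...]
    #: sub-blocks a concatenated step is made of (pattern label, column slice)
    parts: tuple[tuple[str, slice], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be two-dimensional")
        if self.matrix.shape[1] != len(self.column_labels):
            raise ValueError("one label per design column is required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def part_blocks(self) -> list["DesignBlock"]:
        """Split a concatenated step back into its constituent blocks."""
        if not self.parts:
            return [self]
        return [
            DesignBlock(lab, self.matrix[:, sl], self.column_labels[sl])
            for lab, sl in self.parts
        ]


def single_locus_additive() -> DesignBlock:
    """The 3x2 allele-count matrix of the one-locus regression."""
    return DesignBlock("A", N_ADDITIVE.copy(), ("A1", "A2"))


def _marginal_rows(loci: int, locus: int, kind: str) -> tuple[np.ndarray, list[str]]:
    """Per-genotype marginal design rows for one locus: 'A' or 'D' columns."""
    codes = genotype_codes(loci)[:, locus]
    letter = locus_letters(loci)[locus]
    if kind == "A":
        return N_ADDITIVE[codes], [f"{letter}1", f"{letter}2"]
    if kind == "D":
        return N_DOMINANCE[codes], marginal_genotype_labels(letter)
    raise ValueError(f"pattern letters must be 'A' or 'D', got {kind!r}")


def multilocus_additive(loci: int) -> DesignBlock:
    """3**l x 2l additive design: concatenated per-locus allele-count rows."""
    n_genotypes(loci)
    mats, labels = [], []
    for j in range(loci):
        m, lab = _marginal_rows(loci, j, "A")
        mats.append(m)
        labels.extend(lab)
    return DesignBlock("A", np.hstack(mats), tuple(labels))


def multilocus_dominance(loci: int) -> DesignBlock:
    """3**l x 3l dominance design: concatenated per-locus indicator rows."""
    n_genotypes(loci)
    mats, labels = [], []
    for j in range(loci):
        m, lab = _marginal_rows(loci, j, "D")
        mats.append(m)
        labels.extend(lab)
    return DesignBlock("D", np.hstack(mats), tuple(labels))


def _rowwise_kron(mats: list[np.ndarray]) -> np.ndarray:
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(out.shape[0], -1)
    return out


def interaction_block(loci: int, subset: tuple[int, ...], pattern: str) -> DesignBlock:
    """Interaction design for one locus subset and one A/D pattern.

    Each row is the row-wise Kronecker product, over the loci in ``subset``,
    of the locus's additive row (pattern letter A) or indicator row (letter
    D).  E.g. the two-locus AA block has columns for the four products of
    allele counts; the DA block crosses the indicator rows of the first
    locus with the allele-count rows of the second.
    """
    subset = tuple(subset)
    if len(subset) != len(pattern):
        raise ValueError("pattern must name one letter per locus in the subset")
    if len(subset) < 2:
        raise ValueError("interaction blocks involve at least two loci")
    if len(set(subset)) != len(subset):
        raise ValueError(f"repeated locus in subset {subset}")
    mats, label_sets = [], []
    for locus, letter in zip(subset, pattern):
        m, lab = _marginal_rows(loci, locus, letter)
        mats.append(m)
        label_sets.append(lab)
    cols = tuple("*".join(combo) for combo in itertools.product(*label_sets))
    label = pattern if loci == len(subset) else f"{pattern}{subset}"
    return DesignBlock(label, _rowwise_kron(mats), cols)


def _class_patterns(order: int, n_dominance: int) -> list[str]:
    """All A/D patterns of a given order with a given number of D letters.

    D positions advance left to right, matching the conventional class
    listing DAA, ADA, AAD (then DDA, DAD, ADD) for third-order terms.
    """
    patterns = []
    for positions in itertools.combinations(range(order), n_dominance):
        letters = ["A"] * order
        for pos in positions:
            letters[pos] = "D"
        patterns.append("".join(letters))
    return patterns


def _concat_blocks(label: str, blocks: list[DesignBlock]) -> DesignBlock:
    mats = [b.matrix for b in blocks]
    cols: list[str] = []
    parts: list[tuple[str, slice]] = []
    start = 0
    for b in blocks:
        cols.extend(b.column_labels)
        parts.append((b.label, slice(start, start + b.shape[1])))
        start += b.shape[1]
    return DesignBlock(label, np.hstack(mats), tuple(cols), tuple(parts))


def detachment_schedule(loci: int) -> list[DesignBlock]:
    """The ordered regression steps of the full decomposition.

    Always ``[A, D]`` first (all loci jointly), then for each interaction
    order k = 2..l the classes in order of increasing dominance content,
    with every locus subset of size k and every pattern of a class
    concatenated into a single step (the two-locus sequence is
    ``A, D, AA, DA|AD, DD``).  The final all-dominance step of order l spans
    the residual space, so its component is the last error term of the
    chain.
    """
    n_genotypes(loci)
    schedule = [multilocus_additive(loci), multilocus_dominance(loci)]
    for order in range(2, loci + 1):
        subsets = list(itertools.combinations(range(loci), order))
        for n_dom in range(order + 1):
            patterns = _class_patterns(order, n_dom)
            blocks = [
                interaction_block(loci, subset, pattern)
                for pattern in patterns
                for subset in subsets
            ]
            label = "|".join(patterns)
            schedule.append(_concat_blocks(label, blocks))
    return schedule
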
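"""Sequential weighted-least-squares decomposition of genotypic values.

Given a genotype-phenotype map G (one expected phenotype per multilocus
genotype) and a vector of population genotype frequencies p, the genotypic
values are reparameterized as

    G = mu + alpha_G + delta_G + eps_AA + eps_DA + eps_AD + eps_DD (+ ...)

by a chain of weighted least-squares regressions: the mean is removed
first, then the additive component is the weighted projection of the
mean-corrected values onto the allele-count design, the dominance component
is the projection of the resulting residual onto the genotype-indicator
design, and each epistasis class is detached from the running residual in
turn, the last all-dominance class being the final error term.  Because
every step projects the previous step's residual, each component is
orthogonal (in the frequency-weighted inner product) to the sum of all
later ones, so the weighted variances of the components add up exactly to
the genetic variance under completely arbitrary genotype frequencies --
including arbitrary Hardy-Weinberg disequilibrium and linkage
disequilibrium.

The normal-equation matrices X'PX of these regressions are singular (the
designs are deliberately over-parameterized so that their column spans
nest).  The chain therefore solves each step "outside the kernel": the
eigendecomposition of X'PX is truncated to its non-nil eigenvalues and the
resulting pseudoinverse yields the minimum-norm coefficient vector.  The
fitted component values are invariant to this choice; only the coefficient
representation is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._ordering import genotype_labels, infer_loci, n_genotypes
from .designs import (
    DesignBlock,
    detachment_schedule,
    multilocus_additive,
    single_locus_additive,
)
from .frequencies import PopulationFrequencies

__all__ = [
    "GPMap",
    "ProjectionStep",
    "DecompositionResult",
    "VarianceDecomposition",
    "weighted_mean",
    "wls_project",
    "decompose",
    "variance_table",
    "orthogonality_audit",
    "joint_vs_sequential_check",
    "one_step_vs_sequential_check",
]

DEFAULT_EIG_RTOL = 1e-10


class GPMap:
    """Vector of genotypic values over the 3**l genotype space."""

    def __init__(self, values, loci: int | None = None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1:
            raise ValueError("genotypic values must form a one-dimensional vector")
        if loci is None:
            loci = infer_loci(values.size)
        elif values.size != n_genotypes(loci):
            raise ValueError(
                f"expected {n_genotypes(loci)} genotypic values for {loci} loci, "
                f"got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("genotypic values must be finite")
        self.values = values
        self.loci = loci

    def __len__(self) -> int:
        return self.values.size

    def __repr__(self) -> str:
        return f"GPMap(loci={self.loci}, values={self.values!r})"

    @property
    def labels(self) -> list[str]:
        return genotype_labels(self.loci)


@dataclass
class ProjectionStep:
    """One weighted regression step of the chain."""

    block: DesignBlock
    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rank: int
    eigenvalues: np.ndarray = field(repr=False, default=None)

    @property
    def label(self) -> str:
        return self.block.label


@dataclass
class DecompositionResult:
    """Mean, per-genotype component values and variance components."""

    loci: int
    mu: float
    steps: list[ProjectionStep]
    components: dict[str, np.ndarray]
    variances: dict[str, float]
    epistasis_labels: list[str]
    frequencies: PopulationFrequencies
    gpmap: GPMap
    split_components: dict[str, np.ndarray] = field(default_factory=dict)
    split_variances: dict[str, float] = field(default_factory=dict)
    unsupported: np.ndarray = None

    @property
    def V_A(self) -> float:
        return self.variances["A"]

    @property
    def V_D(self) -> float:
        return self.variances["D"]

    @property
    def V_G(self) -> float:
        return self.variances["G"]

    @property
    def V_I(self) -> float:
        return self.variances["I"]


def _as_gpmap(G) -> GPMap:
    return G if isinstance(G, GPMap) else GPMap(G)


def _as_freq(p) -> PopulationFrequencies:
    return p if isinstance(p, PopulationFrequencies) else PopulationFrequencies(p)


def weighted_mean(G, p) -> tuple[float, np.ndarray]:
    """Population mean mu = sum p_g G_g and the mean-corrected values G - mu."""
    gp, pf = _as_gpmap(G), _as_freq(p)
    if len(gp) != len(pf):
        raise ValueError(
            f"genotypic values ({len(gp)}) and frequencies ({len(pf)}) differ in length"
        )
    mu = float(pf.p @ gp.values)
    return mu, gp.values - mu


def weighted_variance(x: np.ndarray, p: np.ndarray) -> float:
    """Frequency-weighted variance sum(p x^2) - (sum p x)^2."""
    m = p @ x
    return float(p @ (x * x) - m * m)


def _ones_in_span(X: np.ndarray) -> bool:
    ones = np.ones(X.shape[0])
    fit = X @ np.linalg.lstsq(X, ones, rcond=None)[0]
    return float(np.max(np.abs(fit - ones))) < 1e-8


def wls_project(
    y,
    block: DesignBlock,
    p,
    eig_rtol: float = DEFAULT_EIG_RTOL,
    require_centered: bool = True,
) -> ProjectionStep:
    """Minimum-norm weighted projection of y onto a design block.

    Solves the P-weighted normal equations X'PX b = X'Py through the
    eigendecomposition of X'PX restricted to eigenvalues above
    ``eig_rtol`` times the largest one (the regression "outside the
    kernel").  The fitted values are the weighted projection of y onto the
    column span of X restricted to the support of p; the coefficients are
    the minimum-norm representative and are not unique when the design is
    rank-deficient.
    """
    y = np.asarray(y, dtype=float)
    pf = _as_freq(p)
    X = block.matrix
    if y.shape[0] != X.shape[0] or len(pf) != X.shape[0]:
        raise ValueError("y, design rows and frequencies must share their length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in the regression input")
    w = pf.p
    if require_centered and _ones_in_span(X):
        wmean = abs(w @ y)
        if wmean > 1e-8 * (1.0 + np.max(np.abs(y))):
            raise ValueError(
                "input to a mean-absorbing regression step must have weighted "
                f"mean zero; got {w @ y}"
            )
    M = X.T @ (w[:, None] * X)
    M = 0.5 * (M + M.T)
    lam, U = np.linalg.eigh(M)
    lam_max = lam[-1] if lam.size else 0.0
    if lam_max <= 0.0:
        coef = np.zeros(X.shape[1])
        kept = np.zeros(0)
    else:
        keep = lam > eig_rtol * lam_max
        kept = lam[keep]
        Uk = U[:, keep]
        rhs = X.T @ (w * y)
        coef = Uk @ ((Uk.T @ rhs) / kept)
    fitted = X @ coef
    return ProjectionStep(
        block=block,
        coefficients=coef,
        fitted=fitted,
        residuals=y - fitted,
        rank=int(kept.size),
        eigenvalues=lam,
    )


def _final_step(y: np.ndarray, block: DesignBlock) -> ProjectionStep:
    """The last all-dominance class is the error term of the previous step.

    Its design spans the whole genotype space, so taking the carried
    residual as the component (with an exact minimum-norm coefficient
    representation) keeps the reconstruction identity exact even at
    zero-frequency genotype classes.
    """
    coef, *_ = np.linalg.lstsq(block.matrix, y, rcond=None)
    return ProjectionStep(
        block=block,
        coefficients=coef,
        fitted=y.copy(),
        residuals=np.zeros_like(y),
        rank=block.shape[0],
        eigenvalues=None,
    )


def decompose(
    G,
    p,
    schedule: list[DesignBlock] | None = None,
    da_ad_mode: str = "concatenated",
    eig_rtol: float = DEFAULT_EIG_RTOL,
    check_invariants: bool = True,
) -> DecompositionResult:
    """Full orthogonal decomposition of a GP map at given genotype frequencies.

    Parameters
    ----------
    G, p
        Genotypic values and genotype frequencies over the same canonical
        genotype space (any objects accepted by :class:`GPMap` and
        :class:`PopulationFrequencies`).
    schedule
        Ordered design blocks; defaults to :func:`detachment_schedule` for
        the map's number of loci.
    da_ad_mode
        ``"concatenated"`` fits each mixed epistasis class (e.g. DA|AD) as
        one regression on the concatenated design; ``"sequential"`` detaches
        its pattern blocks one after another.  Both give the same fitted
        values; the concatenated form is the default and the per-pattern
        split is computed from the sequential sub-chain either way.
    eig_rtol
        Relative eigenvalue threshold separating the kernel from the
        non-nil eigenspace of each X'PX.
    check_invariants
        Assert exact reconstruction and variance additivity (1e-10
        relative) before returning.
    """
    gp, pf = _as_gpmap(G), _as_freq(p)
    if gp.loci != pf.loci:
        raise ValueError(
            f"GP map has {gp.loci} loci but frequencies describe {pf.loci}"
        )
    if da_ad_mode not in ("concatenated", "sequential"):
        raise ValueError(f"unknown da_ad_mode {da_ad_mode!r}")
    if schedule is None:
        schedule = detachment_schedule(gp.loci)

    mu, y = weighted_mean(gp, pf)
    steps: list[ProjectionStep] = []
    components: dict[str, np.ndarray] = {}
    split_components: dict[str, np.ndarray] = {}

    expanded: list[tuple[DesignBlock, bool]] = []
    for i, block in enumerate(schedule):
        last = i == len(schedule) - 1
        if da_ad_mode == "sequential" and len(block.parts) > 1 and not last:
            expanded.extend((b, False) for b in block.part_blocks())
        else:
            expanded.append((block, last))

    for block, last in expanded:
        if last:
            step = _final_step(y, block)
        else:
            step = wls_project(y, block, pf, eig_rtol=eig_rtol)
        steps.append(step)
        components[block.label] = step.fitted
        if len(block.parts) > 1:
            # per-pattern split of a concatenated class, via its sequential
            # sub-chain (the sub-fits add up to the concatenated fit); the
            # final all-D class is a single pattern and never reaches here
            y_sub = y
            for part in block.part_blocks():
                sub = wls_project(y_sub, part, pf, eig_rtol=eig_rtol)
                split_components[part.label] = (
                    split_components.get(part.label, 0.0) + sub.fitted
                )
                y_sub = sub.residuals
        y = step.residuals

    labels = list(components)
    epistasis_labels = [lab for lab in labels if lab not in ("A", "D")]

    variances = {lab: weighted_variance(components[lab], pf.p) for lab in labels}
    variances["G"] = weighted_variance(gp.values - mu, pf.p)
    v_epi = sum(variances[lab] for lab in epistasis_labels)
    variances["I"] = v_epi
    split_variances = {
        lab: weighted_variance(vec, pf.p) for lab, vec in split_components.items()
    }

    result = DecompositionResult(
        loci=gp.loci,
        mu=mu,
        steps=steps,
        components=components,
        variances=variances,
        epistasis_labels=epistasis_labels,
        frequencies=pf,
        gpmap=gp,
        split_components=split_components,
        split_variances=split_variances,
        unsupported=~pf.support(),
    )
    if check_invariants:
        _assert_invariants(result)
    return result


def _assert_invariants(result: DecompositionResult) -> None:
    gp, pf = result.gpmap, result.frequencies
    scale = max(1.0, float(np.max(np.abs(gp.values))))
    recon = result.mu + sum(result.components.values())
    err = np.max(np.abs(recon - gp.values))
    if err > 1e-10 * scale:
        raise AssertionError(
            f"reconstruction mu + sum(components) != G (max error {err:.3e})"
        )
    v = result.variances
    vscale = max(1.0, v["G"])
    gap = abs(v["G"] - (v["A"] + v["D"] + v["I"]))
    if gap > 1e-10 * vscale:
        raise AssertionError(
            f"V_G != V_A + V_D + V_I (gap {gap:.3e}); decomposition is not "
            "orthogonal at these inputs"
        )
    for lab, vec in result.components.items():
        m = abs(pf.p @ vec)
        if m > 1e-10 * scale:
            raise AssertionError(f"component {lab} has weighted mean {m:.3e} != 0")


def variance_table(result: DecompositionResult) -> pd.DataFrame:
    """Tidy table of variance components and their shares of V_G.

    Shares are missing (pandas NA) when the genetic variance is zero.
    """
    labels = ["A", "D", *result.epistasis_labels]
    v_g = result.variances["G"]
    rows = []
    for lab in labels:
        v = result.variances[lab]
        share = v / v_g if v_g > 0.0 else pd.NA
        rows.append({"component": lab, "variance": v, "share": share})
    rows.append({"component": "I", "variance": result.variances["I"],
                 "share": result.variances["I"] / v_g if v_g > 0.0 else pd.NA})
    rows.append({"component": "G", "variance": v_g,
                 "share": 1.0 if v_g > 0.0 else pd.NA})
    return pd.DataFrame(rows)


def _span_contains(outer: np.ndarray, inner: np.ndarray) -> bool:
    """Whether every column of ``inner`` lies in the column span of ``outer``."""
    coef, *_ = np.linalg.lstsq(outer, inner, rcond=None)
    resid = inner - outer @ coef
    scale = 1.0 + float(np.max(np.abs(inner)))
    return float(np.max(np.abs(resid))) < 1e-10 * scale


def orthogonality_audit(result: DecompositionResult) -> pd.DataFrame:
    """Normalized weighted cross-products between all component pairs.

    The column ``provable`` marks pairs whose orthogonality follows from
    the column-span nesting of the chain (the earlier component lies in the
    span of every later design up to and including the partner's); the
    remaining pairs quantify the cross-orthogonality that holds empirically
    but is not implied by construction.
    """
    p = result.frequencies.p
    labels = list(result.components)
    blocks = [s.block for s in result.steps]
    spans = [b.matrix for b in blocks]
    n = len(labels)
    contains = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            contains[i, j] = _span_contains(spans[j], spans[i]) if i != j else True
    rows = []
    for i in range(n):
        xi = result.components[labels[i]]
        ni = np.sqrt(max(p @ (xi * xi), 0.0))
        for j in range(i + 1, n):
            xj = result.components[labels[j]]
            nj = np.sqrt(max(p @ (xj * xj), 0.0))
            dot = float(p @ (xi * xj))
            norm = dot / (ni * nj) if ni > 0 and nj > 0 else 0.0
            provable = all(contains[i, k] for k in range(i + 1, j + 1))
            rows.append(
                {
                    "component_1": labels[i],
                    "component_2": labels[j],
                    "weighted_dot": dot,
                    "normalized_dot": norm,
                    "provable": provable,
                }
            )
    return pd.DataFrame(rows)


def joint_vs_sequential_check(G, p, tol: float = 1e-8) -> dict:
    """Concatenated vs sequential detachment of the mixed DA|AD class.

    Fits the two-locus chain once with the DA and AD designs concatenated
    into a single regression and once detaching DA then AD sequentially,
    and reports whether the dominance-by-dominance error terms and all
    variance components agree.
    """
    gp = _as_gpmap(G)
    if gp.loci != 2:
        raise ValueError("the DA|AD check is defined for two-locus systems")
    joint = decompose(gp, p, da_ad_mode="concatenated")
    seq = decompose(gp, p, da_ad_mode="sequential")
    dd_diff = float(np.max(np.abs(joint.components["DD"] - seq.components["DD"])))
    combined = seq.components["DA"] + seq.components["AD"]
    fit_diff = float(np.max(np.abs(joint.components["DA|AD"] - combined)))
    var_diffs = {
        lab: abs(joint.variances[lab] - seq.variances.get(lab, np.nan))
        for lab in ("A", "D", "AA", "DD", "G", "I")
    }
    var_diffs["DA|AD"] = abs(
        joint.variances["DA|AD"] - (seq.variances["DA"] + seq.variances["AD"])
    )
    agree = dd_diff <= tol and fit_diff <= tol and all(
        d <= tol for d in var_diffs.values()
    )
    return {
        "agreement": bool(agree),
        "max_dd_difference": dd_diff,
        "max_fitted_difference": fit_diff,
        "variance_differences": var_diffs,
        "tolerance": tol,
    }


def one_step_vs_sequential_check(G, p, tol: float = 1e-8) -> dict:
    """One-step joint (mean|additive) regression vs the two-step procedure.

    The single-locus model can be posed as one regression on the design
    (1 | N) or solved in two steps (mean removal, then the additive
    regression on the mean-corrected values).  The two procedures give
    different mean and additive-effect estimates for generic frequencies;
    this check quantifies the difference on a concrete instance.
    """
    gp, pf = _as_gpmap(G), _as_freq(p)
    if gp.loci != 1:
        raise ValueError("the one-step check is defined for single-locus systems")
    N = single_locus_additive()
    joint_block = DesignBlock(
        "mu|A", np.hstack([np.ones((3, 1)), N.matrix]), ("mu", *N.column_labels)
    )
    joint = wls_project(gp.values, joint_block, pf, require_centered=False)
    mu_joint = float(joint.coefficients[0])
    alpha_joint = joint.coefficients[1:]
    mu_two, ybar = weighted_mean(gp, pf)
    two = wls_project(ybar, N, pf)
    alpha_two = two.coefficients
    mu_diff = abs(mu_joint - mu_two)
    alpha_diff = float(np.max(np.abs(alpha_joint - alpha_two)))
    return {
        "differs": bool(mu_diff > tol or alpha_diff > tol),
        "mu_one_step": mu_joint,
        "mu_two_step": mu_two,
        "alpha_one_step": alpha_joint,
        "alpha_two_step": alpha_two,
        "mu_difference": mu_diff,
        "alpha_difference": alpha_diff,
        "tolerance": tol,
    }


class VarianceDecomposition(BaseEstimator):
    """Orthogonal genetic variance decomposition, estimator-style.

    A scikit-learn flavoured front end to :func:`decompose`: construct with
    the numerical options, then ``fit`` a GP map against genotype
    frequencies.  Fitted attributes carry the mean, the per-genotype
    component values and the variance components.

    Parameters
    ----------
    da_ad_mode : str, default "concatenated"
        How mixed epistasis classes are detached; see :func:`decompose`.
    eig_rtol : float, default 1e-10
        Relative eigenvalue threshold of the kernel cut in each weighted
        regression.
    check_invariants : bool, default True
        Verify reconstruction and variance additivity after fitting.

    Attributes
    ----------
    mu_ : float
        Population mean phenotype.
    components_ : dict[str, numpy.ndarray]
        Per-genotype component values keyed by component label.
    variances_ : dict[str, float]
        Variance components, including "G" and the epistasis total "I".
    result_ : DecompositionResult
        The full decomposition record.

    Examples
    --------
    >>> from orthovar import VarianceDecomposition, sign_epistasis_map
    >>> from orthovar.frequencies import LDSpec, frequencies_from_ldspec
    >>> p = frequencies_from_ldspec(LDSpec(0.5, 0.5, Dprime=0.0, F=0.0))
    >>> vd = VarianceDecomposition().fit(sign_epistasis_map(), p)
    >>> round(vd.variances_["AA"], 10)
    0.25
    """

    def __init__(
        self,
        da_ad_mode: str = "concatenated",
        eig_rtol: float = DEFAULT_EIG_RTOL,
        check_invariants: bool = True,
    ):
        self.da_ad_mode = da_ad_mode
        self.eig_rtol = eig_rtol
        self.check_invariants = check_invariants

    def fit(self, G, p, schedule: list[DesignBlock] | None = None):
        """Decompose genotypic values ``G`` at genotype frequencies ``p``."""
        result = decompose(
            G,
            p,
            schedule=schedule,
            da_ad_mode=self.da_ad_mode,
            eig_rtol=self.eig_rtol,
            check_invariants=self.check_invariants,
        )
        self.result_ = result
        self.n_loci_ = result.loci
        self.mu_ = result.mu
        self.components_ = result.components
        self.variances_ = result.variances
        self.split_variances_ = result.split_variances
        self.epistasis_labels_ = result.epistasis_labels
        return self

    def variance_table(self) -> pd.DataFrame:
        """Tidy (component, variance, share) table of the fitted result."""
        self._check_fitted()
        return variance_table(self.result_)

    def orthogonality_audit(self) -> pd.DataFrame:
        """Cross-product audit of the fitted components."""
        self._check_fitted()
        return orthogonality_audit(self.result_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise AttributeError(
                "this VarianceDecomposition instance is not fitted yet; call "
                "fit(G, p) first"
            )
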
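# Methods

## Model and scope

`orthovar` operates on exact population summaries, not on samples: a
genotype–phenotype (GP) map `G` assigning one genotypic value (expected
phenotype, trait units) to each of the `3^l` genotypes of `l` biallelic
loci, and a probability vector `p` over the same genotype space. Both
share a canonical ordering — per-locus codes 0/1/2 for the allele-1
homozygote, heterozygote and allele-2 homozygote, with locus 1 varying
fastest. The package answers one question: how do `G` and the genetic
variance `V_G` split into additive, dominance and epistasis components at
*these* frequencies, with no equilibrium assumption of any kind. Because
the inputs are exact, there are no standard errors; estimating `G` or `p`
from data is out of scope, as are multiallelic marginal designs (the
per-locus design rows are pluggable, but only biallelic ones ship) and
genomic imprinting.

## The sequential weighted regression chain

The decomposition is defined operationally by a chain of weighted
least-squares (WLS) projections, each consuming the previous residual:

| step | design columns | component |
|------|----------------|-----------|
| 0 | the ones vector | mean `μ = Σ p_g G_g` |
| 1 | per-locus allele counts (2 per locus) | additive values `α_G` |
| 2 | per-locus genotype indicators (3 per locus) | dominance deviations `δ_G` |
| 3… | row-wise Kronecker products of marginal rows, class by class (`AA`; `DA|AD`; `DD`; then order 3, …) | epistasis components |

All projections use the inner product `<x, y> = Σ_g p_g x_g y_g`. The
interaction columns for a locus subset and a letter pattern (e.g. `DA`)
are the products, genotype by genotype, of that locus's additive row
(letter `A`) or indicator row (letter `D`) — the standard construction of
interaction regressors. Mixed classes concatenate all patterns of the
class (and all subsets of the order) into a single regression step; the
final all-dominance class of order `l` spans the whole residual space, so
its component *is* the last error term, taken directly rather than
re-projected (this keeps the reconstruction identity exact at
zero-frequency genotypes too).

Two properties follow from the chain structure alone, for any `p`:

* **Exact reconstruction.** `μ + Σ components = G` identically.
* **Exact variance additivity.** Each fitted component is P-orthogonal to
  its own step's residual, which equals the sum of all later components;
  hence all cross-covariances telescope away and
  `V_G = V_A + V_D + V_I`, `V_I = Σ class variances`, without any
  orthogonality between *individual* later pairs being needed.

Variances are computed as `V(x) = Σ p_g x_g² − (Σ p_g x_g)²`; the
subtracted term is identically zero for the mean-zero components and only
guards against accumulated drift.

### Singular normal equations and the kernel threshold

The designs deliberately over-parameterize (the ones vector lies in every
span; allele counts sum to 2; indicators sum to 1), so every normal matrix
`X'PX` is singular. Each step is solved through the eigendecomposition of
`X'PX`, keeping eigenvalues above `eig_rtol · λ_max` (default
`eig_rtol = 1e-10`, configurable) — equivalently, applying the
Moore–Penrose pseudoinverse. Fitted values, and therefore all components
and variance components, are invariant to this choice; the *coefficient*
vectors (per-allele effects `α_i`, per-genotype deviations `δ_ij`, …) are
the minimum-norm representatives and are reported as such — they are not
unique and should not be interpreted individually without that caveat.

### Zero-frequency genotype classes

Extreme LD (`|D'| = 1`) or complete fixation empties genotype classes.
Projections are then defined on the support of `p`; fitted values at
unsupported genotypes are the minimum-norm extrapolation of the design and
are flagged in the output (`unsupported_genotypes` in the JSON report).
Variances are support-only sums, so the genotypic value assigned to an
unsupported class is irrelevant to every variance component (this is
tested directly).

### Degenerate inputs and validation

Frequency vectors must be non-negative within `1e-12` (tiny negative
values from floating-point cancellation are clamped to zero) and sum to 1
within `1e-8` (then renormalized exactly). A constant GP map yields zero
variance everywhere and missing (NA) variance shares rather than NaNs.
Inputs to mean-absorbing steps are asserted to have weighted mean zero at
`1e-8` relative; a violated invariant raises instead of returning silent
output, and the CLI converts this into a non-zero exit with a diagnostic.

## The two-locus frequency generator

The applied analyses parameterize `p` by allele frequencies `pA1`, `pB1`,
the standardized disequilibrium index `D'`, and a per-locus fixation index
`F`:

* `D'` uses the Lewontin normalization: `D = D'·Dmax` for `D' ≥ 0` with
  `Dmax = min(pA1(1−pB1), (1−pA1)pB1)`, and `D = D'·|Dmin|` for `D' < 0`
  with `Dmin = −min(pA1·pB1, (1−pA1)(1−pB1))`. Haplotype frequencies are
  `f11 = pA1·pB1 + D`, etc.
* `F` enters through a haplotype-level mixture: with probability `1−F` an
  individual is the random union of two independent gamete draws, with
  probability `F` it carries two copies of a single draw. This is one of
  several constructions that combine LD with HWD; it was chosen because it
  provably yields a marginal fixation index of exactly `F` at *each*
  locus (verified by round-trip tests) while preserving the gametic `D'`
  of the pool, and because `F = 0` reduces to random union of gametes.
  The engine accepts arbitrary explicit frequency vectors, so any other
  construction can be supplied directly.

Phase is pooled: the coupling and repulsion double heterozygotes fall in
one genotype class. `ld_measures` inverts the construction (corner
double-homozygote classes give the haplotype frequencies given `F`
estimated from the marginal heterozygote deficits); for frequency vectors
*not* produced by this generator its `D`/`D'` output is an approximation,
and a monomorphic locus reports `D'` as NaN rather than raising.

What the generator does **not** emulate: sampling noise, more than two
loci (explicit vectors only for `l > 2`), mutation/selection dynamics, or
sex-linked and imprinted transmission. Passing tests therefore certify
the algebra of the decomposition at given frequencies, not inference from
real data.

## Applied GP maps

* **Sign epistasis** — built from a single individual-referenced effect:
  center coding (covariates `x_j ∈ {−1,0,1}`, heterozygote indicators
  `h_j`), reference `R = 1` at the double heterozygote, `aa = −1`. In
  canonical order the values are `(0, 1, 2, 1, 1, 1, 2, 1, 0)`. The
  coupling genotypes read `(0, 1, 0)` (overdominant single locus under
  complete positive association) and the repulsion genotypes `(2, 1, 2)`
  (underdominant under complete negative association).
* **BDM incompatibility** — shipped as `data/bdm_synthetic.csv`, a
  *synthetic* reconstruction (the file name marks it as such): fitness 1
  for every genotype in which the derived alleles `A2` and `B2` do not
  meet, 0 for every genotype carrying at least one copy of each
  (dominant expression of the incompatibility, matching the scenario in
  which the fitness decline appears as soon as the two derived alleles
  co-occur in an individual). The loader validates the structure this
  case must have instead of trusting the file: corner-referenced marginal
  effects from the ancestral reference `G_1111` all nil, and all four
  pairwise epistasis classes non-zero (here `aa = ad = da = dd = −1/4`).
  The fitness scale is immaterial: every headline BDM quantity is a
  variance ratio, invariant under rescaling the map.

Both coding conventions (corner, referenced at a double homozygote;
center, referenced at the double heterozygote) are provided because the
two maps are naturally expressed from different references; a 9×9 linear
solve recovers corner-referenced effects from any two-locus map exactly.

## Measured findings the package reports honestly

Two properties that are sometimes *assumed* of decompositions like this
one hold only under restricted conditions, and `orthovar` measures rather
than asserts them:

* **Pairwise orthogonality of all six components.** The chain proves
  orthogonality for the pairs whose earlier component lies in the span of
  every intervening design (the additive component against everything;
  `AA` against `DA|AD` and `DD`; `DA|AD` against `DD`; dominance against
  the epistasis *total*). The remaining pairs — e.g. dominance against
  `AA` — are not implied, and under combined HWD and LD their normalized
  weighted cross-products are measurably non-zero (order 0.1–0.4 in the
  shipped examples) even though all variance-additivity identities remain
  exact. `orthogonality_audit` tabulates every pair with a `provable`
  flag.
* **Concatenated vs sequential detachment of the mixed class.** Fitting
  `DA|AD` as one concatenated regression projects onto
  `span(N_DA) + span(N_AD)`; detaching `DA` then `AD` sequentially equals
  that projection if and only if the class-specific subspaces (the
  complements of the shared bilinear span) are P-orthogonal — true for
  product-form weights (linkage equilibrium, or per-locus-independent
  HWD), false in general under LD, where the two procedures can differ in
  the third decimal of the `DD` component. The concatenated form is the
  default (`da_ad_mode="concatenated"`); the per-pattern split reported
  alongside it comes from the sequential sub-chain, so under LD the split
  variances `V_DA + V_AD` need not equal the concatenated class variance.
  The sweep/surface tables therefore tabulate the mixed class through the
  sequential detachment, making their four epistasis columns add exactly
  to `V_I` row by row. `joint_vs_sequential_check` quantifies the
  discrepancy on any instance.

A related boundary of the model class itself: at the secondary-contact
setting `f(A1) = f(B2)` with complete repulsion LD, the only surviving
genotypes are the two parental double homozygotes (both incompatibility-
free, hence equal-valued) and the hybrid heterozygote, a value-symmetric
configuration whose additive variance vanishes at `f = 1/2`. Additive
variance along that sweep therefore decays toward `D' = −1` for *any* map
with nil marginal effects, while dominance variance rises and epistasis
variance decays; the package's sweeps show exactly this pattern.

## Default sizes and tolerances

* D' grids default to `−0.99 … 0.99` in steps of 0.01 (199 points),
  avoiding `|D'| = 1` so all nine classes stay supported; the endpoints
  are available explicitly and are handled through the support logic.
* Frequency lattices default to `0.01 … 0.99` in steps of 0.01; tests and
  examples use coarser grids (steps of 0.05–0.2), which is ample for the
  monotonicity and ridge diagnostics they check.
* Kernel threshold `1e-10` (relative); reconstruction and additivity
  invariants asserted at `1e-10` relative; equilibrium-reduction
  comparisons at `1e-8`.
* Property tests run the chain on random Dirichlet frequency vectors and
  Gaussian maps for 1–3 loci; a thousand such instances complete in a few
  seconds.

## Known limitations

* Biallelic loci only; `l > 2` requires explicit frequency vectors (no
  multilocus LD recipe) and the effect-builder covers pairwise terms only
  (arbitrary maps can always be supplied as files).
* Minimum-norm coefficients are representation-dependent; only fitted
  components and variances are canonical.
* `ld_measures` assumes the generator's phase pooling when inverting
  arbitrary frequency vectors.
* The decomposition is descriptive for the supplied population; it does
  not by itself predict selection response under HWD/LD, where additive
  components no longer coincide with breeding values in the classical
  sense.
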
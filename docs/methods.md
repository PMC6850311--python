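# Methods

## Model and estimands

Phenotypes follow the whole-genome regression model

    y = X1 β1 + X2 β2 + e,

where `X` = [X1 X2] is an n × p matrix of real-valued marker genotype
codes, `X1` (n × p1, full column rank, p1 typically 1–5) is the tested
set, `X2` the background (p2 may exceed n), and nuisance location effects
are assumed already eliminated — no intercept is fitted. Background
effects are random, `β2 ~ N(0, Iσβ²)`; residuals are `e ~ N(0, Iσe²)`.
Variance components are treated as *known and constant across tests*;
estimating them (REML/ML, or re-estimating per tested set) is out of
scope by design, because the invariance results only hold under fixed
components.

Two phenotypic covariance structures arise from treating the tested
effects as fixed:

    V2  = X2X2'σβ² + Iσe²            (tested set excluded from the random part)
    V12 = X1X1'σβ² + X2X2'σβ² + Iσe² (all markers random; β1 estimated as fixed)

The package computes the BLUE of the tested effects under either
structure, exploiting three exact identities:

1. invariance: the GLS estimators under V2 and V12 coincide;
2. the Woodbury down-date `V2⁻¹ = V12⁻¹ + σβ²V12⁻¹X1(I −
   σβ²X1'V12⁻¹X1)⁻¹X1'V12⁻¹`;
3. the variance adjustment `(X1'V2⁻¹X1)⁻¹ = (X1'V12⁻¹X1)⁻¹ − Iσβ²`.

A scan therefore factors V12 once; each tested set costs one p1 × p1
capacitance solve. Inference always uses the adjusted covariance (the
correct sampling covariance, taken under V2); the naive V12-path
covariance is reported alongside to expose the overstatement of
uncertainty, which is exactly σβ² per diagonal element.

The similarity matrices are also exposed in genomic-relationship form,
`S12 = G12σg²` with `G12 = (X1X1' + X2X2')/p`, `σg² = pσβ²`, and
`S2 = G2σg'²` with `G2 = X2X2'/p2`, `σg'² = p2σβ²`. Whether codes should
be allele-frequency-centered before building a GRM is a modelling choice
the algebra does not constrain: a `center` flag (default off, since every
identity holds for arbitrary real codes) subtracts column means; no
VanRaden-style frequency rescaling is applied.

## Mixed-model equations and conventions

The double-counting model `y = X1(α + β1) + X2β2 + e` is solved through
Henderson's equations. For scalar i.i.d. effects the system is assembled
exactly in its printed form (identity metric, `Iλ` prior blocks with
`λ = σe²/σβ²`); `σβ² = 0` is rejected (λ undefined — use the GLS path).

For block effect covariances `B = [[B11, B12], [B21, B22]]` with residual
covariance R (general positive definite; the estimators default it to
`Iσe²`), the prior blocks added to the random-effect equations are the
blocks of the joint *precision* `P = B⁻¹`, with the data part in the
`R⁻¹` metric. This is a deliberate convention choice: writing the
covariance blocks themselves into the coefficient matrix is the other
conceivable reading, but only the precision convention is consistent with
the scalar system (where the prior block is `Iλ = σe²·(Iσβ²)⁻¹`) and with
standard mixed-model theory, under which the fixed-effect solution equals
GLS under `V = [X1 X2]·B·[X1 X2]' + R` — a property the test suite checks
against a dense oracle.

Consequences verified (with the *direct* dense solve of the full printed
system, so they are emergent results rather than by-products of the
solver's reduction):

- independent blocks (B12 = 0): `β→1 = 0` identically, and (α̂, β→2)
  equal the solutions of the reduced system that omits the double-counted
  block;
- correlated blocks: `β→1 + C·β→2 = 0` with `C = P11⁻¹P12` (equivalently
  `C = −B12B22⁻¹` in covariance terms), which is non-null, and the
  fixed-effect solutions shift relative to the independent treatment —
  the invariance property fails. Under the covariance-as-printed reading
  with `B11 = I` the same identity takes the familiar form
  `β→1 = −B12β→2`; the two readings coincide in what they assert
  qualitatively, and this package's convention is stated here precisely
  because the choice is easy to get silently wrong.

The default solve route is the exact algebraic reduction mirroring the
zero-BLUP proof (subtract the α block-row from the β1 block-row,
eliminate β1, solve the nonsingular reduced system, back-substitute);
`method="direct"` retains the dense solve of the full system for
verification. Solutions are accepted only if the relative
normal-equation residual is below 1e−6; measured residuals in the battery
are ≤ 1e−10.

## Conditional model

When `Cov(β1, β2') = B12 ≠ 0`, fixing β1 alters the distribution of β2:
`β2 = B21B11⁻¹β1 + δ`, `δ ~ N(0, B2.1)` with the Schur complement
`B2.1 = B22 − B21B11⁻¹B12`. The model becomes `y = X1*β1 + X2δ + e` with
effective design `X1* = X1 + X2B21B11⁻¹` and covariance
`V2* = X2B2.1X2' + R`. The package computes GLS(β1) under V2*, BLUP(δ) =
`B2.1X2'V2*⁻¹(y − X1*β̂1)` (the fixed-effect estimate in the residual is
the same β̂1 — the only coherent reading), and the direct/indirect signal
split `X1β1` + `X2B21B11⁻¹β1`. The common presentation `β2 = B21β1 + δ`
presumes unit tested-set prior variance; the general regression
coefficient `B21B11⁻¹` is used and reduces to it when `B11 = I`.
A semidefinite B2.1 (perfectly correlated blocks) is accepted with a
warning since V2* stays positive definite through R.

## Synthetic data generator

The generator reproduces exactly the sampling assumptions above and
nothing more: genotype columns are Binomial(2, f) counts with
f ~ Uniform(maf_range) per column (default maf_range (0.05, 0.5), the
usual post-QC frequency band), effects i.i.d. N(0, σβ²) or jointly
Gaussian with a user-supplied block covariance, residuals i.i.d.
N(0, σe²). Defaults n = 100, p = 200, σβ² = σe² = 1 give the n < p,
heritable-trait regime the model is meant for. One root seed is split
into independent child streams (genotypes / effects / residuals) so any
component can be regenerated alone. Monomorphic columns are redrawn up to
100 times and then accepted with a warning, keeping full-rank checks on
X1 meaningful without silent failure.

Deliberately not emulated: linkage disequilibrium (columns are
independent), frequency ascertainment, missingness, population structure
beyond what random sharing of marker counts induces. Passing tests
therefore certify the *algebra and calibration under the model's own
assumptions*; they say nothing about robustness to LD or confounding,
which the model itself does not claim.

## Numerical choices

- Symmetric positive-definite solves use Cholesky throughout; explicit
  inverses are formed only for V12⁻¹ (reused across all tested sets of a
  scan) and V2⁻¹ where a formula reuses it. On factorization failure a
  diagonal jitter of 1e−10·σe² is added once, with a warning.
- Every assembled symmetric matrix is symmetrized as (A + A')/2.
- Rank of X1 is checked by column-pivoted QR with tolerance
  1e−10·‖X1‖ before any solve; failures name the dependent columns.
- The Woodbury capacitance matrix is declared singular when
  max(σmax, 1)/σmin exceeds 1e12 (it is I minus a contraction, so O(1)
  scale is the correct reference); the error carries the condition
  number.
- An adjusted covariance that is not positive definite within
  1e−10·scale raises a degeneracy error — the signature of
  near-collinear tested sets, for which the estimates would be unstable
  anyway.
- Wald p-values come from the upper tail of χ²(p1); variance components
  are known, so no t/F small-sample correction is used. Scan output
  optionally appends a Bonferroni column (a reporting convenience only).
- Scan results are written with %.10e float formatting so reruns are
  byte-identical and the dual-strategy equivalence is visible in diffs.

## Verification battery and problem sizes

`gblue verify` / `scripts/acceptance.py` measure every identity on
freshly simulated instances: 50 instances for the BLUE invariance and 20
for the Woodbury/variance identities spanning n ∈ [20, 100],
p ∈ [2n, min(500, 5n)], p1 ∈ [1, 5], σβ², σe² ∈ {0.1, 1, 10}; 15
instances for the MME identities; 10 correlated-block instances with
effect correlation 0.8 (each tested marker paired with one background
marker, which keeps the joint covariance positive definite); a
2000-replicate null-calibration study at n = 100, p = 200 (tested marker
carries no effect and is excluded from the generative random part; the
adjusted-variance rejection rate must land in the 99% binomial interval
around 0.05 and the naive rate must not exceed it); and a full
300-singleton dual-strategy scan at n = 80, p = 300. These sizes exercise
the p > n regime the method targets while keeping the whole battery
under ten seconds on one core.

## Known limitations

- Dense n × n algebra throughout: intended for method verification and
  desk-scale analyses, not biobank-scale n.
- Variance components must be supplied; there is no REML, and no per-test
  re-estimation (the strategy the invariance results explicitly do not
  cover).
- Covariate adjustment is assumed done upstream; the scan fits no
  intercept or nuisance effects.
- The correlated-scan configuration expresses B12 sparsely
  (tested-marker / background-marker / value triplets) with scalar
  B11/B22; arbitrary dense B matrices are available through the library
  API only.
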
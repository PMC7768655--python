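# Methods

## Model

For M regions with standardized BOLD series (columns centered and scaled to
unit L2 norm), region i's coefficient vector β_i minimizes

    ½‖x_i − Σ_{j≠i} x_j β_ji‖² + λ₁ Σ_{j≠i} D_ji |β_ji|
                               + (λ₂/2) Σ_{(u,v)} |β_ui − β_vi|.

Unit-norm standardization is what makes the fixed λ₁ grid [0, 0.9]
meaningful: cross products x_jᵀx_i are then correlations, so λ₁ sweeps the
support from dense (λ₁ = 0) to empty (λ₁ above the largest absolute
correlation divided by the smallest active weight). On raw z-scored columns
the same grid would leave every network dense.

The fused term couples all coefficient pairs within one column (an option
restricts pairs to structurally connected region pairs). Note the
row-versus-column reading of the pairwise term is immaterial: an entrywise
L1 norm of row differences decomposes into exactly these within-column pair
terms, so a single implementation covers both.

### Penalty weights

D_ji = exp(−ρ_ji²/σ) maps structural weight ρ to an L1 weight in (0, 1]:
absent connections get full penalty 1. The automatic bandwidth σ is the
variance of each subject's off-diagonal structural weights, averaged over
subjects (`penalty_sigma(mode="within_subject")`). The alternative —
averaging the per-edge across-subject variance — is available as
`mode="across_subject"`, but with realistic subject-level variability it is
orders of magnitude smaller than typical ρ², which collapses the kernel to
a binary structural mask and removes the functional modality from the model
entirely. Weights are floored at 1e-3: below that a coefficient is
effectively unpenalized anywhere on the λ grid, and exact zeros would break
the weighted-lasso column rescaling used by the fast path.

### Solver

Each column is a generalized lasso solved by ADMM on the splitting z = Fβ
(F stacks the weighted identity and the scaled pairwise-difference
operator). Defaults: ρ_ADMM = 1, absolute/relative tolerances 1e-6/1e-4,
max 5000 iterations; convergence is declared on primal/dual residuals (the
objective at ADMM iterates is not monotone, so residuals — not objective
decrease — are the stopping criterion). With λ₂ = 0 the sweep dispatches to
scikit-learn's coordinate-descent lasso path with the weights folded into
column scales (α = λ₁/T); supports are read back on the original scale.
Cross-checks in the test suite: OLS (λ₁ = λ₂ = 0), coordinate-descent lasso
(λ₂ = 0), and a generic constrained-QP solver (λ₂ > 0, objective within
1e-5).

## Multiscale integration and filtration

The λ₁ grid is uniform on [0, 0.9] (endpoints included; N_λ1 is the free
resolution parameter). Appearance probabilities p_ij over the grid map to
distances d_ij = √(1 − p_ij²); the diagonal is forced to 0. The filtration
thresholds d_ij < ε strictly, ε ∈ [0, 1]. Edges with d_ij ≥ 1 never enter
the complex; features alive at ε = 1 are capped at death 1.

Barcodes are computed exactly from edge-weight events (the 1000-point
uniform grid is only used to sample curves):

* β₀ by union–find over edges sorted ascending (ties broken by vertex
  pair); finite deaths are single-linkage merge heights.
* β₁ on the clique (Vietoris–Rips) complex up to dimension 2 — the graph
  alone can never kill a cycle, so triangles (filtration value = longest
  side) are required for finite cycle deaths. Standard GF(2)
  boundary-matrix reduction pairs creator edges with filling triangles;
  zero-persistence pairs are dropped.
* The representative of a cycle born at edge (u, v) is that edge plus the
  hop-shortest path between u and v among strictly earlier edges
  (lexicographic tie-breaks). Representatives are not unique in homology;
  this deterministic rule is fixed so frequency networks are reproducible.

## Features

The β₀ step function (bars alive per threshold; death-capped bars count
throughout) is fitted with an order-4 B-spline basis (40 uniform interior
knots) minimizing SSE + λ ∫(f″)². The roughness penalty is the standard
second-derivative form — a literal squared-function penalty would not
produce the documented straight-line limit as λ → ∞, so the printed variant
is treated as typographical. Default smoothing λ = 1e-4. Curve distances
(cityblock, euclidean, standardized euclidean with a cohort variance
vector) are computed on derivative curves by default, on values behind a
flag.

Persistence landscapes use the standard tent function min(x − b, d − x)
(again treating the printed branch conditions as typographical) and are
stored as exact piecewise-linear breakpoint lists: the k-th largest of
tents is linear between the critical abscissae {b_i, d_i, (b_i + d_j)/2},
so sampling there is exact. Means and L_p distances are computed by exact
segment integration (with a numerically stable near-constant branch);
p = ∞ is the sup over layers and breakpoints.

Frequency networks integrate a subject's retained cycles (persistence at or
above the subject's median positive persistence by default; configurable).
Two modes: `probability` (fraction of retained cycles containing the edge,
the default) and `persistence_weighted` (cycles weighted by persistence).

## Statistics

Graph metrics are computed on the binary network at a single λ₁ (grid
midpoint 0.45 by default, realized as the appearance-probability threshold
p ≥ 1 − λ₁/0.9, which equals the single-λ network under support
nestedness) and compared by two-sided two-sample t-tests. PH measures use a
label-permutation test: statistic = distance between group-mean feature
objects (cityblock on mean β₀ derivative curves for PH-0; L_p on mean
landscape vectors for PH-1), add-one p-value (1 + #{perm ≥ obs})/(1 +
n_perm), default n_perm = 10 000 (tests use 199 for budget). DWG/DBG panels
use Euclidean distances between per-subject feature vectors (β₀ derivative
on the 1000-grid, or the first five landscape layers on a 200-point grid).
The grid search evaluates the full pipeline per {N_λ1, λ₂} cell and ranks
cells by p-value.

## Patterns

Per-group frequency networks are summed edge-wise (optional group-size
normalization, off by default because the source rule is a raw sum — note
this biases toward the larger group). The difference network keeps edges
with summed difference ≥ ε_t; the printed "<" is read as "≥" since the
stated semantics is "edges appearing more often in the first group".
ε_t = 2 by default — an absolute count threshold implicitly calibrated to
~27-subject groups; scaled-down cohorts should scale it by group size (the
acceptance experiments use 2·8/27). Loops are a minimum cycle basis per
difference network (networkx), canonically oriented, ranked by edge count.

## Synthetic world

The generator emulates a two-group resting-state cohort. Defaults: 27 + 36
subjects, M = 90 regions, T = 280 time points, 6 modules.

* **Structural template.** Within-module edges with density 0.85 and
  heavy-tailed weights 0.2·exp(1.2|Z|) (streamline-count-like: a few
  dominant bundles, many moderate ones); between-module density 0.08 with
  weights U(0.02, 0.18), strictly below. Heavy tails matter: they are what
  places the variance-based σ rule on the scale of typical ρ², so the
  penalty kernel genuinely blends modalities. Subject-level variability is
  multiplicative lognormal edge jitter (sd 0.1).
* **BOLD coupling.** Spatial covariance Σ = (1 − c)·I + c·corr((I − A)⁻¹)
  with A = 0.8·D^{-1/2}·SC·D^{-1/2} the degree-normalized adjacency:
  functional correlation accumulates over all white-matter walks, directly
  connected pairs correlate most, and no single dominant bundle can
  suppress everyone else's coupling (a plain spectral normalization does
  exactly that, and a covariance directly proportional to SC makes the
  functional support identical to the structural support, leaving a
  functional effect invisible to the SC-guided model). Default coupling
  c = 0.6. Rows are i.i.d. Gaussian (optional AR(1) flag; the method uses
  only spatial covariance).
* **Planted effect.** For carriers, within-module entries of A are
  attenuated by `effect_size` after normalization (so renormalization
  cannot undo it); observed SC matrices are identical in distribution
  across groups. `effect_size` 0 = null cohort, 0.8 = the "strong" setting
  used in power experiments.

What a green test does *not* establish: the generator has Gaussian noise,
no hemodynamics, no temporal autocorrelation by default, module-aligned
effects only, and stylized weight distributions — power and recovery
results are statements about this stated world, not about ADNI-scale data.

## Reduced-size acceptance experiments

Null calibration (200 replicate 8+8 cohorts, M = 16, n_perm = 199) uses
T = 120 and N_λ1 = 20: permutation validity — hence uniformity of null
p-values — holds at any size, so the fast setting is unbiased. The power
arm keeps the full stated T = 280 and the smallest stated grid candidate
N_λ1 = 100, because power does depend on those. Pattern recovery uses 2
modules of 8 (modules must be large enough to host 1-cycles),
persistence-weighted frequency networks (suppresses short rerouted noise
cycles; the probability mode concentrates less sharply), and the
group-size-scaled ε_t above. All acceptance experiments run at λ₂ = 0
(lasso-path route) to fit a single-CPU budget; λ₂ > 0 is exercised by the
solver unit tests.

## Known limitations

* β₁ representative cycles are one deterministic choice among homologous
  cycles; frequency networks depend on that choice.
* The dimension-2 reduction is pure Python; fine for M ≤ ~30 (the tested
  regime), slow for M = 90 cohorts.
* Graph-metric selection of the single-λ network via the probability
  threshold assumes support nestedness along λ₁, which coordinate-descent
  paths can violate marginally.
* No multiple-testing correction across measures or grid cells, matching
  the source analysis.
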
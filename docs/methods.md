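# Methods

This note documents the models, algorithms, numerical choices and
limitations of `canred`, at the level of detail a maintainer or a careful
user needs.  It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Formalisms and conversions

All models live on the open positive orthant; `x^E` denotes the monomial
vector `(x^E)_i = ∏_j x_j^{E_ij}`, which is smooth there for arbitrary real
exponents and undefined at zero — every evaluator therefore rejects
non-positive states outright rather than clipping.

* **GMA**: `ẋ = N diag(γ) x^F`, `N` (n×m) stoichiometry, `γ > 0` rate
  constants, `F` (m×n) kinetic orders.  Constant environmental inputs are
  assumed pre-folded into `γ`.
* **s-system**: one aggregate production and one degradation term per
  variable; `(G − H) log x* = log(β/α)` gives the closed-form steady state
  whenever `G − H` is invertible (checked by SVD at relative tolerance
  1e−12; rank-deficient systems raise an error naming the numerical rank).
* **Normalized s-system**: variables scaled by `x*`, equilibrium at
  `z = 1`, dynamics `ż = diag(f)(z^G − z^H)`.  The turnover
  `f_i = α_i x*^{G_i}/x*_i = β_i x*^{H_i}/x*_i` is computed from both the
  production and the degradation side; disagreement beyond 1e−8 relative is
  an internal-consistency error.
* **GLV**: `ẋ = diag(x)(λ + A x^B)`; **LV canonical form**:
  `q̇ = diag(q)(Bλ + BA q)` with `q = x^B`.

Conversions are exact rewrites, not approximations:

* s-system → GMA is structural: `N = [I | −I]`, `γ = (α, β)`, `F = [G; H]`.
* GMA → GLV factors each variable out of its own equation: term `j` of
  variable `i` becomes a quasimonomial with coefficient `N_ij γ_j` and
  exponent row `F_j − e_i`.  Exponent rows that vanish (terms proportional
  to the variable itself) accumulate into `λ`.  Duplicate exponent rows —
  which arise freely from floating-point conversions — are merged by
  summing coefficient columns; rows are compared after rounding to 12
  decimal places so the merge is deterministic.  Monomials are ordered by
  first appearance (equation-major), which reproduces conventional
  presentations of worked examples.
* GLV → s-system multiplies `diag(x)` back in and requires exactly one
  positive and one negative power-law term per equation; anything else
  raises an explicit "not s-system representable" error.  Aggregating
  multi-term GMA equations into s-system form is deliberately out of scope.

Variables are reported 1-based in user-facing output (names `x1…xn`);
internal indexing is 0-based.

## Quasimonomial transformations and spectral diagnostics

`x = y^C` (equivalently `log x = C log y`) maps a GLV to another GLV with
`Â = C⁻¹A`, `λ̂ = C⁻¹λ`, `B̂ = BC`.  `C` must be invertible; the condition
number is computed on construction and values above 1e12 are rejected with
the number reported.  Jacobian spectra at corresponding steady states and
the LV embedding (`Bλ`, `BA`) are invariants of the equivalence class; both
facts are enforced as tests.

**Kernel decoupling.** When `rank(B) = r < n`, transforming with
`C = [completion | φ_1…φ_k]` (orthonormal kernel basis of `B` in the
trailing columns) produces `B̂` whose last `k = n − r` columns vanish: those
variables enter no equation but their own and reduce to quadratures.  The
completion columns are the `r` standard basis vectors with the largest
residual after projection onto the kernel (scores rounded to 12 decimals,
ties to the lowest index), which keeps `C` well conditioned regardless of
variable ordering.  The trailing columns of `B̂` are exactly zeroed after
verifying they are below 1e−8 relative; a full-rank `B` returns the model
unchanged with an empty decoupled list rather than raising.

**SVD conventions.** Singular values are non-increasing, so the slow
direction is always the last right singular vector.  SVD signs are
arbitrary; each right singular vector is oriented so its largest-magnitude
component is positive (ties to the first maximal entry), with the matching
left vector flipped consistently.  One consequence worth knowing: external
references for a worked example may use the opposite sign for individual
columns, flipping the signs of the corresponding rows/columns of the
transformed `λ̂`, `Â`, `B̂` without changing anything physical.  Effective
rank counts `σ_i > rank_tol · σ_max` with `rank_tol = 1e−10` by default and
user-settable, since "singular" and "merely ill-conditioned" are a matter
of degree here.

**Kinetic vs stoichiometric stiffness.** `BA = U_B Σ_B W Σ_A V_Aᵀ` with
`W = V_Bᵀ U_A`; only the diagonal factors can amplify or dampen
perturbations.  The dominance label compares the spreads (max/min over
nonzero singular values): *kinetic* when `spread(Σ_B) ≥ 10·spread(Σ_A)`,
*stoichiometric* for the reverse, *mixed* otherwise.  The factor 10 is a
documented, configurable default — the underlying notion ("one set of
singular values has extreme values") is qualitative.

**Log-modes.** The eigendecomposition of the Jacobian at a steady state
(identical in original and logarithmic coordinates for s-systems at
equilibrium) defines monomial modes `ℓ = x^M` with `M` the inverse of the
(realified) eigenvector matrix.  Complex conjugate pairs are kept together
as real 2×2 rotation-scaling blocks, since such modes remain coupled.
Numerically non-diagonalizable Jacobians (eigenbasis condition above 1e12,
or off-block residual of `M J M⁻¹` above 1e−8 relative) raise an error;
near-zero real parts (within 1e−9 relative of zero) attach a
non-hyperbolicity warning to the result without failing.  `slow_direction`
is the unit *right* eigenvector of the smallest-magnitude eigenvalue,
sign-fixed like a singular vector.  The mode *coefficients* are rows of `M`
(left eigenvectors); both are exposed, and the slow-direction/-coefficient
distinction is deliberately not papered over — for near-normal Jacobians
the two nearly coincide, which is exactly what the three-gene example
exhibits.

## Time-scale partition and QSS reduction

Turnovers are sorted non-increasingly (stable sort) and the cut maximizes
the gap between consecutive values — raw differences by default, log10
differences optionally; ties pick the smallest `k` (the most aggressive
reduction).  A constant turnover vector is an error ("no separation");
`ε = f_{k+1}/f_k > 0.1` warns ("separation weak") but proceeds, because the
quality of a reduction is ultimately judged by simulation, not a priori.

For the normalized system the QSS constraint of the fast block is linear in
log coordinates with zero offset (the equilibrium is all ones):
`Φ = −D_FF⁻¹ D_FS`, `c = 0`, `D = G − H`.  A singular `D_FF` (SVD test at
1e−12 relative) raises an error naming the fast variables that support the
null space.  Back-substitution gives the slow model
`ĝ = G_SS + G_SF Φ`, `ĥ = H_SS + H_SF Φ` with unchanged turnovers — the
telescopic property in action; the algebra is verified against exact
symbolic elimination (sympy, rational exponents) on small instances in the
test suite.  The slow model is kept on the original time axis (rates
`f_slow`) rather than the stretched slow time, so full and reduced
trajectories are directly comparable.  The fast subsystem keeps blocks
`G_FF`, `H_FF` and absorbs frozen slow monomials into its rate constants;
frozen values default to the steady state and any positive vector is
accepted.  Multi-scale splits order variables by non-decreasing turnover
and apply the same elimination per scale, with slower blocks frozen at
`z = 1` (so they drop out) and faster blocks eliminated; a single cut
reproduces the two-scale reduction exactly.

## Simulation and the error protocol

The integration horizon is `t_end = −5/max(Re eig J)` at the steady state —
five times the slowest linear relaxation time; non-negative eigenvalue real
parts raise "not asymptotically stable".  Integration uses scipy's LSODA
with `rtol = 1e−8`, `atol = 1e−10`, in logarithmic coordinates: for all
formalisms here `d(log x)/dt` is an exponential-affine expression, so the
trajectory is positive by construction and the power laws are never
evaluated near zero.  (The log-state absolute tolerance acts as a relative
tolerance on concentrations, which is the natural accuracy notion for
positive pools.)  Trajectories are sampled at 100 uniform points on
`[0, t_end]` by default.

Fast initial values are perturbed multiplicatively, `x_{f,qss}·10^u` with
`u ~ Uniform[−1, 1]` per variable, bounding each ratio within a factor of
10; an `edges` mode (`u ∈ {−1, +1}`) saturates the bound.  `δy` is the
Euclidean norm of the log-ratios to the QSS values.  Trajectory errors
resample both trajectories by linear interpolation onto a common uniform
grid and use trapezoidal quadrature:
`E_i = ∫|x_red − x_full| dt / ∫|x_full| dt`, aggregated as `‖E‖₂`.  The
error is scale-invariant per variable and zero exactly when the
trajectories coincide.

The ensemble protocol perturbs *only* the fast initial values per
simulation.  Because a slow block started at equilibrium would make the
comparison trivial, the slow initial state is displaced once per ensemble —
drawn from the seed with the same factor-10 law — and shared by the full
and reduced runs; the reduced trajectory is computed once, each full run
records `(δy, E, ‖E‖)` against it, and failed integrations are excluded
and counted.  Results are bit-reproducible for a fixed seed.  The per-time
mean and standard deviation of the full runs' slow trajectories provide the
±3σ envelopes used in plots.  A caveat documented deliberately: past the
fast boundary layer the ensemble spread can collapse faster than the O(ε)
reduction bias, so the reduced trajectory may sit a sub-percent margin
outside a literal 3σ band at isolated times even when, at plot resolution,
it lies inside; the acceptance test therefore bounds excursions by 1% of
each variable's dynamic range.

## Random network generation

`ẋ_i = F_i(∏_j x_j^{g_ij} − x_i)` in normalized coordinates: interactions
in `G`, first-order degradation (`H = I`), equilibrium at `z = 1` by
construction (so rejection sampling needs no steady-state solve).
Defaults emulate a sparse transcriptional network with grouped time scales:

* **Turnovers**: per group, normal with the prescribed mean and
  `sd = (distance to the nearest neighbouring group mean)/6`, truncated
  below at `mean/10` (keeps draws positive and groups ordered); a single
  group uses `sd = mean/6`.
* **Kinetic orders**: exactly `floor(density · n²)` positions drawn
  uniformly without replacement over the full n×n grid (self-edges
  allowed; degradation is separate, in `H`), magnitudes uniform on
  [0.1, 1] with random sign — inside the usual band of power-law kinetic
  orders while avoiding near-zero entries that would defeat the sparsity
  bookkeeping.  Both the magnitude range and density are configurable.
* **Filters**: accepted instances must be asymptotically stable at `z = 1`
  (spectral abscissa of `diag(f)(G − I)` negative) and connected as an
  undirected interaction graph; rejection sampling redraws everything fresh
  up to `max_attempts` and reports the failure split on exhaustion.

What the generator does *not* emulate: scale-free or modular topology,
correlated kinetic orders, saturation kinetics, measurement noise, or any
particular organism's parameters.  Passing tests on generated networks
therefore demonstrate the correctness and scaling behavior of the
algorithms under controlled multi-scale conditions, not predictive accuracy
for a specific real network.

## Problem sizes and study conditions

The bundled analyses use: the three-gene example (n = 3); the
75-variable three-scale design (groups 10/25/40, mean turnovers 1, 10²,
10⁴, density 0.05 — 281 nonzero kinetic orders and 75 turnovers, 356
parameters); a 20-variable two-scale network (turnovers 1 and 10³,
density 0.15) with 100-simulation ensembles for the error-vs-perturbation
protocol; and batches of 100 random stable s-systems (n = 3–5) for
reduction-consistency checks, with symbolic verification on n ≤ 4.  The
ensemble and batch sizes are chosen so the full suite runs in seconds on a
single CPU while keeping the statistical assertions well resolved.

## Model files

JSON schema `canred-model-v1`: a `formalism` tag, variable names, and the
defining matrices as nested row-major arrays.  JSON was preferred over SBML
because these objects *are* raw matrices and SBML has no native
s-system/GLV semantics.  Numbers are serialized as plain JSON numbers;
Python's shortest round-trip float representation makes write → read
bit-identical without resorting to decimal strings.  Unknown top-level
fields are carried through untouched.  Validation errors name the offending
field and entry (`/gamma`, entry index) and distinguish schema-version,
dimension and positivity failures.

## Known limitations

* Reduction requires the s-system form; general GMA systems lack the
  telescopic property and are out of scope (convert first, when exact).
* GLV → s-system refuses rather than approximates when an equation has
  multiple positive or negative terms.
* The QSS manifold is computed from the normalized equilibrium; systems
  with multiple positive steady states are outside the theory used here.
* `check_stability` is local (linearization at the equilibrium); it says
  nothing about global dynamics or limit cycles.
* Matched inner/outer asymptotic expansions are not implemented — the fast
  and slow submodels are intended to be used within their own time scales.
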
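# Methods

## Model

The state is a pair of integer counts (Y, X): lethal and sublethal DNA
lesions in one cell nucleus. Three reaction channels, all consuming
sublethal lesions, define a continuous-time Markov jump process:

| channel | stoichiometry | count-scale propensity |
|---|---|---|
| repair | (y, x) → (y, x−1) | r·x |
| direct conversion | (y, x) → (y+1, x−1) | a·x (logistic variant: x·(a + ā·x)) |
| pairwise conversion | (y, x) → (y+1, x−2) | b̃·x·(x−1) |

The pairwise propensity is written with x(x−1) and **no 1/2 symmetry
factor**; b̃ is defined by that convention, and every layer of the package
(master equation, Gillespie simulator, expansion coefficients) uses it
identically, so the layers are mutually consistent by construction.

Because x never increases, the chain starting from (y0, x0) lives on the
finite lattice 0 ≤ x ≤ x0, y0 ≤ y ≤ y0 + x0 and is eventually absorbed at
x = 0. Two structural invariants follow and are asserted throughout the
tests: x is non-increasing and y non-decreasing along every path, and
(x0 − x(t)) ≥ (y(t) − y0) (each lethal lesion consumes at least one
sublethal lesion — the "lesion budget").

## System-size scaling

Counts relate to a dimensionless system size K by X = K·x̄ + √K·ξ,
Y = K·ȳ + √K·υ, with the pairwise rate scaling as b̃ = b/K so that the
macroscopic rate b stays order one. The package treats K as an explicit
user parameter with the convention **K = x0 by default**, which makes
x̄(0) = 1 — the order-one macroscopic initial condition the expansion
assumes. The benchmark configuration (r = 4, a = 0.1, b̃ = 0.01,
x0 = 100, y0 = 0, times in arbitrary units) therefore has b = 1 on the
concentration scale; running with K = 1 reproduces the count scale
exactly (b = b̃), and all solvers are scale-covariant, so the choice is a
bookkeeping convention, not a modelling assumption.

Counts mapped back from fluctuation coordinates are real-valued and may be
negative; clamping is deliberately left to the sampling/reporting layers
(documented contract), because the Gaussian layer itself has no boundary.

## Macroscopic (MKM) limit

The order-√K balance yields dȳ/dt = a x̄ + b x̄², dx̄/dt = −(a+r) x̄ − 2b x̄².
The sublethal equation is a Bernoulli ODE with the overflow-safe closed
form x̄(t) = λ e^{−λt}/(c − 2b e^{−λt}), λ = a+r, c = λ/x̄0 + 2b. The
lethal mean follows by exact quadrature along the trajectory:

    ȳ(t) = ȳ0 + (x̄0 − x̄(t))/2 + (a−r)/(4b) · log[(λ + 2b x̄0)/(λ + 2b x̄(t))],

whose t → ∞ limit gives ȳ∞ = ȳ0 + x̄0/2 + (a−r)/(4b)·log(1 + 2b x̄0/λ)
(≈ 11.26 lesions at the benchmark, count scale). **Numerical ODE
integration (LSODA, rtol 1e-10, atol 1e-12) is the authority**; the
closed forms are validated against it in the tests rather than trusted,
because printed closed forms in this literature carry typographical risk.
The simplified low-LET variant drops the quadratic loss from the
sublethal balance only; its lethal closed form is obtained by direct
integration (b-term b x̄0²(1−e^{−2λt})/(2λ)) and cross-checked against
quadrature.

## Linear-noise approximation

The order-one balance is a linear Fokker–Planck equation. Rather than
transcribing printed moment equations, the covariance ODEs are derived
from its drift/diffusion pair on the (υ, ξ) ordering,

    M = [[0, 2bx̄+a], [0, −(4bx̄+a+r)]],
    D = [[ax̄+bx̄², −(ax̄+2bx̄²)], [−(ax̄+2bx̄²), (a+r)x̄+4bx̄²]],

as the Lyapunov flow dC/dt = M C + C Mᵀ + D; a dedicated test confirms
the componentwise ODEs and the matrix form agree to 1e-9. D is PSD
wherever x̄ ≥ 0 (det D = x̄²(ar + b x̄ (a+r))). First moments with zero
initial data are returned as exact zeros (the system is linear and
homogeneous), avoiding spurious solver noise in a quantity that is
identically zero.

Initial conditions: a deterministic start means C(0) = 0; a Gaussian
initial law with count-scale variances (σx, σy) — default Poisson-like,
equal to the means — enters as C(0) = diag(σy, σx)/K. The default
assigns variance x0 to the sublethal and y0 to the lethal coordinate (the
natural Poisson-like reading; the source material prints the two diagonal
entries in an ambiguous order, so the covariance is user-configurable).

The under-dispersion statement is quantified by
δ(t) = −∫ 2(2bx̄+a) c_ξυ ds, computed by cumulative Simpson quadrature on
the covariance grid (error O(h⁴); the identity c_υυ = c_υυ(0) + ȳ − ȳ0 − δ
holds to ~3e-7 on a 2001-point grid over [0, 10] and is asserted at 1e-6).
δ∞ is computed from the stationary lethal mean and a long-horizon
covariance solve (horizon 40/λ), which is exact to solver tolerance —
more robust than extrapolating the quadrature. Note δ > 0 **even for
b = 0**: from a deterministic start the linear network's lethal count is
Binomial, with variance x0·p(1−p) < mean x0·p; the gap x0·p² is the
oracle used in the tests.

## Exact master-equation solver

On a lattice with x_max ≥ x0 and y_max ≥ y0 + x0 (the default,
reachability-tight bounds) the truncated generator is exact — no
probability leaks, since x never increases. States are enumerated
row-major over (y, x) with x fastest. The generator G is assembled
sparsely with columns summing to zero, and p(t) = e^{Gt} p(0) is computed
with `scipy.sparse.linalg.expm_multiply`. A stiff implicit ODE integrator
would also work, but for a constant linear generator the exponential
action is both more accurate and conservative to machine precision, which
is what the 1e-9 mass-conservation contract asks for; mass and
non-negativity are checked after every step and violations raise rather
than being clipped. Practical up to x0 ≈ 200 (~40k states); larger
problems use SSA or the Gaussian layer.

## Stochastic simulation

Gillespie's direct method, exact by construction. Each path draws its
entire random budget up front (at most x0 exponentials and uniforms — the
jump-count bound above), which makes a 10⁴-path ensemble at x0 = 100 run
in a few seconds of pure NumPy/Python. Path i of an ensemble uses the
stream seeded by (master_seed, i) via `numpy.random.default_rng`, so
ensembles are bitwise reproducible and order-independent. A Gaussian
initial law is realised by sampling the bivariate normal, rounding to the
nearest integer and clamping at zero — an approximation (documented) that
matches how the lattice solver discretises the same law (per-unit-cell
integration with tail mass absorbed at the boundary cells).

## Ornstein–Uhlenbeck sampling

The fluctuation law is also the law of a time-dependent OU process with
drift −A(t) and any diffusion factor Q(t) with QQᵀ = D(t); only D is
distributionally meaningful, so Q is taken as the Cholesky factor (with a
symmetric-eigendecomposition fallback near singularity). Integration is
Euler–Maruyama, default dt = 1e-3 (x̄ varies on the scale 1/λ ≈ 0.24 at
the benchmark), with the macroscopic state evaluated from the exact
closed form at every substep and steps clipped to land exactly on
observation times. Weak order 1 suffices here: the dt bias at the default
step (~0.4% of the variance) is below the Monte-Carlo error of a
10⁴-path ensemble, and a halving test asserts this.

Absorption: in the exact model x = 0 stops everything, so with
`boundary="absorb"` a path whose count-scale X reaches ≤ 0 has ξ pinned
to the moving boundary value −√K·x̄(t) (X ≡ 0) and υ frozen — lethal
counts cannot change without sublethal lesions. The initial OU state is
**centred** (mean zero, covariance diag(σ)/K), as fluctuations are
deviations from the macroscopic mean by definition.

## Comparison metrics

Count marginals are compared with unit-width integer bins (counts are
integers, so binning is unambiguous). Total variation is computed on the
integer support; Kolmogorov–Smirnov compares the discrete CDF at k with
the Gaussian CDF at k + 0.5 (continuity correction), a fair
discrete-vs-continuous comparison. Reports are numeric tables (CSV);
plotting is intentionally out of the numeric contract.

## What the tests do and do not establish

The verification suite is anchored on layer-vs-layer agreement at the
benchmark configuration: SSA vs exact lattice marginals (TV ≤ 0.05 at 10⁴
paths), Gaussian vs exact lethal variance (within 5% at x0 = 100),
Gaussian vs SSA lethal marginal (KS ≤ 0.05), OU vs covariance ODEs
(4 Monte-Carlo SE), and closed forms vs quadrature/ODE oracles at 1e-6 to
1e-12. For b = 0 the network is linear and the Gaussian second moments are
*exact* (Binomial oracle), which pins the covariance equations
independently of any tolerance budget. None of this establishes accuracy
of the Gaussian layer at small lesion numbers: near x = 0 the continuum
description degrades (visible as the larger sublethal KS distance at late
times), which is the known regime limit of the expansion — the absorbing
OU boundary mitigates, but does not remove, it.

## Known limitations

- No dose-deposition / track-structure modelling: initial lesion counts
  or laws are user inputs.
- No protracted-irradiation source terms in the kinetics.
- The nonlinear (Kramers–Moyal-truncated) Fokker–Planck alternative and
  cell-survival endpoint formulas are out of scope.
- The exact lattice solver is limited to ~40k states; the SSA and
  Gaussian layers are the intended tools beyond that.
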
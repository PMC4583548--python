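# Methods

## Model

`growdom` solves the coupled linear reaction–diffusion system for the
densities C_i(x, t) of successive cell generations on a uniformly
growing interval 0 < x < L(t):

    ∂C_1/∂t = D ∂²C_1/∂x² − ∂(v C_1)/∂x − k_1 C_1
    ∂C_i/∂t = D ∂²C_i/∂x² − ∂(v C_i)/∂x + m k_{i−1} C_{i−1} − k_i C_i

with zero diffusive flux at both ends.  Generation i converts into
generation i+1 at rate k_i; the amplification factor m is 2 for a
proliferation process (each division produces two daughters) and 1 for a
differentiation process (one-for-one conversion).  Uniform growth means
the local stretch rate ∂v/∂x = σ(t) = L′(t)/L(t) is independent of
position, so v(x, t) = x σ(t) with the origin fixed, and growth enters
the fixed-frame equations purely as the dilution sink −σ(t) C_i.

The system is linear, so it is best read as the low-density (leading
edge) approximation of the corresponding nonlinear invasion models: it
is quantitatively meaningful where densities are small — exactly the
regime that decides whether the spreading front reaches the moving
boundary — and it overestimates growth of the bulk where a logistic
model would saturate.

## Exact solution

Three exact ingredients are composed:

1. **Uncoupling (Sun–Clement) transformation.**  The reaction matrix K
   of the chain is lower bidiagonal; when all k_i are pairwise distinct
   the unit-lower-triangular matrix W with
   W[i,j] = Π_{l=j}^{i−1} m k_l/(k_l − k_i) satisfies
   W K W⁻¹ = diag(−k), so a = W C solves G independent scalar
   equations.  The transform degrades numerically as rates approach
   each other; rates closer than 1e-8 (relative) are declared repeated
   and the transform refuses to build (`DistinctRatesRequiredError`).

2. **Boundary fixing and time rescaling.**  In ξ = x/L(t) the advection
   cancels; in T(t) = ∫₀ᵗ D/L²(s) ds the diffusion coefficient becomes
   unity.  With Neumann walls each uncoupled field is a cosine series

       a_i = Σ_{n=0}^{N} Ψ_{i,n} cos(nπξ) e^{−(nπ)²T(t)} e^{−k_i t} L(0)/L(t).

   The factor e^{−k_i t}·L(0)/L(t) is the closed form of the combined
   reaction-plus-dilution decay e^{−∫(k_i+σ)dt}, valid for *any*
   uniform growth law because ∫σ dt = ln(L(t)/L(0)); for exponential
   growth it reduces to e^{−t(α+k_i)}.  This general form is validated
   against the finite-difference solver on a linearly growing domain.

3. **Coefficients.**  For the Heaviside block initial condition
   (generation 1 at density 𝒞 on 0 < x < γ, all else empty):
   Ψ_{1,0} = 𝒞γ/L(0), Ψ_{1,n} = (2𝒞/nπ) sin(nπγ/L(0)), and
   Ψ_{i,n} = W[i,1] Ψ_{1,n}.  Arbitrary initial profiles are projected
   onto the cosine basis by adaptive quadrature and mixed through W.

Repeated rates are handled by L'Hôpital limits where a printed closed
form exists — all rates equal gives C_i = (m k_1 t)^{i−1}/(i−1)! · C_1,
and the four-generation pattern k_1=k_2=k_3≠k_4 has an explicit mixed
form — and by delegation to the per-mode solver otherwise (see below).
The choice not to derive symbolic limits for every multiplicity pattern
is deliberate: the per-mode route is exact up to truncation for any
pattern, so additional symbolic forms would add surface without adding
capability.

## Per-mode matrix-exponential solver (`mode_oracle`)

Because the diffusion/dilution decay g_n(t) = e^{−(nπ)²T} L(0)/L(t) is
shared by all generations, each cosine mode's amplitude vector evolves
by the constant ODE db_n/dt = K b_n, i.e. b_n(t) = expm(K t) b_n(0).
This route needs no distinct-rates assumption and is an *independent*
derivation of the same solution: the test suite requires it to agree
with the uncoupling-transform series to < 1e-10 and uses it as the
oracle for every repeated-rate closed form.  The G×G exponential is
computed densely (scipy's scaling and squaring); G is at most tens, so
structure exploitation would buy nothing.

## Finite-difference reference (`fd_solver`)

The coupled system is marched on the fixed ξ-grid: central second
differences with ghost-point Neumann closure, backward Euler in time
with the coefficient D/L²(t) and σ(t) evaluated at the new level.  The
lower-bidiagonal coupling lets the step stay fully implicit while
solving generations in order, one tridiagonal solve each — backward
Euler is unconditionally stable, so the reference steps δξ = δt = 1e-3
are accuracy-, not stability-limited (O(δt) + O(δξ²)).  The block
initial condition is discretised by cell averages so the node straddling
the jump carries the fractional value and the captured initial mass is
independent of where the jump falls relative to the grid.

## Parameters and defaults

| parameter | meaning | default / worked-example value |
|---|---|---|
| L0 | initial domain length | 1 |
| α | exponential growth rate (1/time) | 0.1 |
| D | cell diffusivity (length²/time) | 1e-5 (failure) / 1e-2 (success) |
| k | per-generation conversion rates (1/time) | (0.1, 0.2, 0.3, 0) |
| m | amplification per conversion | 2 (proliferation) |
| 𝒞, γ | block density and width | 1, 0.2 |
| N | series truncation (modes 0..N) | 1000 |
| δξ, δt | FD steps | 1e-3, 1e-3 |

k_4 = 0 keeps the fourth (last tracked) generation from draining into an
untracked fifth.  N = 1000 is deliberately conservative: the iterative
doubling procedure (`converged_truncation`, default tolerance 1e-12)
shows ~10 terms already reach machine precision for the worked examples
because e^{−(nπ)²T(20)} collapses fast in n.  Negative rates are
accepted with a warning (solutions can grow without bound); shrinking
domains are rejected.

## Numerical choices

* Rate equality threshold 1e-8 (relative): below it the uncoupling
  products overflow into pure roundoff; callers are redirected to the
  limit forms or the per-mode solver.
* Custom growth laws supply L(t) only; σ(t) is a central difference of
  ln L with step 1e-6·max(1, t) and T(t) adaptive quadrature with
  absolute tolerance 1e-12.  Closed forms are used for exponential and
  linear growth; the exponential form is written as
  (D t/L0²)·(1 − e^{−z})/z, z = 2αt, with a series branch for small z
  so it stays accurate down to α = 0.
* Evaluation is internally in ξ; output grids may be fixed-ξ (default,
  matching scaled profile plots) or fixed-x inside the domain at all
  requested times.
* Headline boundary densities are rounded half-to-even to four decimal
  places.
* The series at t = 0 inherits the Gibbs phenomenon of the block
  profile: away from the jump the partial-sum error decays like
  1/(π²N·d) at distance d, about 1e-2 at d = 0.01·L0 for N = 1000.
  Comparisons against the discontinuous profile therefore exclude a
  window of width 0.02·L0 around the jump and use a larger N; for t > 0
  the e^{−(nπ)²T} damping removes the issue entirely.

## What the tests do and do not show

The acceptance-style checks rerun the worked four-generation examples
(colonization failure at D = 1e-5, success at D = 1e-2, the truncation
study, equal-rate ratios, series-vs-FD agreement at δξ = δt = 1e-3) and
property checks on randomly drawn problems: mass balance of the series
totals against the compartment ODE dM/dt = K M (20 draws, 1e-6
relative), agreement of the three solution routes, and convergence of
the distinct-rate evaluation to the repeated-rate limit as the rate gap
closes.  Problem sizes in the tests (grids of 41–2001 points, N of
100–1000, FD to t = 20 at the reference steps) are the sizes at which
the solution features are resolved; nothing in the results depends on
scaling beyond them.  All of this validates the *linear* model's
implementation.  It does not validate the linear model as biology:
density saturation, nonlinear motility, branching lineages,
position-dependent growth and 2-D/3-D geometry are all outside scope,
and conclusions about real colonization phenomena (e.g. enteric nervous
system development) transfer only through the leading-edge
interpretation above.

## Known limitations

* Homogeneous Neumann boundaries only; Dirichlet or non-zero-flux
  conditions raise `NotImplementedError` (non-zero flux interacts with
  dilution in a way that needs dedicated care).
* Chain (non-branching) lineages with constant rates; no k_i(t).
* The similarity property of W is a roundoff-amplifying computation:
  with near-equal rates ‖W‖ grows like (gap)^{1−G} and the numerical
  diagonalisation residual grows proportionally.  This is inherent to
  the transform, and precisely why the repeated-rate fallbacks exist.
* `general_ic_coefficients` performs one adaptive quadrature per mode
  and generation; for N ~ 1000 and smooth profiles a fast cosine
  transform would be cheaper, but the block closed form covers the
  common case.
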
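# Methods

## Model

The state is the myofibroblast density `m(x, y, t)` (g/cm³) on the
homogenized damaged region `D = [0.3, 0.6]² cm`, over horizons of 350 days
(control) / 400 days (forward simulation). The dynamics are

    ∂m/∂t − r ∇²m = −d_m m + [λ_mfT σ_T (1 − η_T) + λ_mfG σ_G (1 − η_G)] f

— apoptosis at rate `d_m` plus fibroblast→myofibroblast activation — where
`σ_T = T/(K_T + T)` and `σ_G = G/(K_G + G)` are Michaelis–Menten
saturations of the two cytokine pathways and `η_T, η_G` are dimensionless
drug efficacies. Boundary conditions are zero flux; the initial density is
spatially uniform.

Assumptions worth making explicit:

* **Static cytokines.** No dynamics are modelled for `T` and `G`; both stay
  at their initial values. With the defaults `σ_T ≈ 0.0245` (TGF-β far
  below its saturation constant) and `σ_G ≈ 0.99997` (PDGF fully
  saturating). Consequently the activation source
  `c = (λ_mfT σ_T + λ_mfG σ_G) f ≈ 5.839×10⁻⁴ g/cm³/day` is constant, and
  the control-effectiveness coefficients `b_T = −λ_mfT σ_T f`,
  `b_G = −λ_mfG σ_G f` satisfy `c = |b_T| + |b_G|` exactly — full blockade
  (η_T = η_G = 1) cancels activation identically.
* **Homogenization enters only through coefficients.** The alveolar
  micro-geometry is represented by `a = 0.11` and `γ = 127/343`, giving the
  effective diffusivity `r = a D_m/γ ≈ 4.367×10⁻⁶ cm²/day`.
* **Uniform initial condition.** The initial density 8.5×10⁻³ g/cm³ is
  applied uniformly over D. Since the PDE coefficients and controls are
  spatially constant and the boundary is zero-flux, a uniform state remains
  uniform; the entire reported dynamics live on this one-dimensional
  manifold, on which the exact solution is
  `m(t) = m_∞ + (m0 − m_∞) e^{−d_m t}`,
  `m_∞ = (c + b_T η_T + b_G η_G)/d_m`. This closed form is the package's
  primary verification oracle.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| D_m | myofibroblast diffusivity | 1.47e-5 | cm²/day |
| d_m | apoptosis rate | 1.66e-2 | 1/day |
| λ_mfT, λ_mfG | activation rates | 0.12 | 1/day |
| K_TGF, K_G | saturation constants | 1e-10, 1.5e-8 | g/cm³ |
| f | fibroblast density in D | 4.75e-3 | g/cm³ |
| m0 | initial myofibroblast density | 8.5e-3 | g/cm³ |
| T_GF0, G0 | cytokine concentrations | 2.51e-12, 0.58e-3 | g/cm³ |
| a, γ | homogenization coefficients | 0.11, 127/343 | — |
| t_f, t_end_sim | control / simulation horizon | 350, 400 | days |
| q_m, r_T, r_G | cost weights | 1, 1, 1 | — |

All computations stay in this unit system (cm, day, g/cm³); no internal
rescaling is applied. Parameter files are flat YAML with these key names;
unknown keys are rejected by name.

## Discretization

Nodal Legendre–Gauss–Lobatto (GLL) spectral Galerkin on a single
tensor-product element per dimension. Nodes are ±1 plus the roots of
`L_N'`, found by Newton iteration (Chebyshev–Gauss–Lobatto initial guesses,
tolerance 1e-14, ≤100 iterations — reproducible to machine precision
without external root finders). Weights are `w_k = 2/(N(N+1) L_N(ξ_k)²)`,
exact for degree ≤ 2N−1. The differentiation matrix uses the standard
cardinal formula off the diagonal with diagonal entries set to negated
off-diagonal row sums, so constants are annihilated to machine precision —
this exactness is what keeps uniform states uniform under time stepping at
high order. The 1-D stiffness is the quadrature form `S = (2/h) DᵀWD`
(exact: integrand degree 2N−2); the mass is the lumped (diagonal)
quadrature mass `K = (h/2) diag(w)`; the load is `C = K·1`.

Two 2-D stiffness conventions are provided. The default,
`laplacian_consistent`, is the Galerkin matrix of the 2-D Laplacian,
`S = S_x⊗K_y + K_x⊗S_y`. The alternative `tensor_literal` is the pure
tensor product `S_x⊗S_y`; it is **not** a Laplacian discretization (its
spectrum scales like the square of the Laplacian's) and is retained only
for strict replication of the formulation it comes from. Both annihilate
constants, so they coincide on the uniform manifold where all reported
results live. The diffusion sign is likewise selectable: the dissipative
`stable_minus_rS` (obtained by integration by parts of the weak form;
default) or the anti-dissipative `literal_plus_rS` kept for replication.

**Explicit Euler stability.** All time integration is forward Euler (the
production scheme for every study; a Runge–Kutta oracle exists only in the
tests). The stiffest resolved diffusion mode has rate `r·λ_max ≈ 44/day`
at N = 32 in 2-D (consistent convention), so Euler is stable at the default
10000 steps over 350–400 days but **unstable at 4000 and 7000 steps**:
rounding seeds the unstable modes even from exactly uniform data and the
run diverges. The integrator detects non-finite states and reports the
offending step index; the convergence study records such cells with an
`unstable` flag instead of an error value. The tensor-literal stiffness and
the anti-dissipative sign are unstable at N = 32 even at 10000 steps.

## Optimal control

The regulator problem minimizes
`J = ½∫ (q_m ⟨m²⟩ + r_T η_T² + r_G η_G²) dt` subject to the semi-discrete
dynamics, free endpoint, no terminal cost. `⟨m²⟩` is the **mean-square
nodal density**, so the state penalty measures the physical density level
independently of the spectral order. Pontryagin stationarity gives
`η* = −Bᵀλ/r`; the affine term `C_b` makes the costate ansatz
`λ = P m̂ + s` (scalar mode: `λ = p m̂ + c g`) produce extended Riccati
equations, integrated backward by explicit Euler from `P(t_f) = 0,
s(t_f) = 0` — the standard free-endpoint terminal condition.

Numerical/design choices:

* **Scalar mode (default).** On the uniform manifold the full matrix
  Riccati flow reduces exactly to two scalar ODEs; the closed-loop forward
  solve still integrates the full nodal system, with the feedback driven by
  the spatial mean. Matrix mode (full n×n sweep) is the verification
  oracle: with the mean-square weighting `Q = (q_m/n) I` the aggregates
  `1ᵀP1` and `1ᵀs` obey the scalar flows identically, so the two modes
  agree to rounding — tested at N = 2 and 4. A per-node Euclidean state
  cost (`Q = q_m I`, equivalent to scalar `q_m·n`) is selectable
  (`state_weighting="per_node"`).
* **Hamiltonian normalization.** `H = ½(q_m⟨m²⟩ + r_T η_T² + r_G η_G²) +
  λᵀ(Am̂ + B_Tη_T + B_Gη_G + C_b)`, the unique normalization consistent
  with both `η* = −Bᵀλ/r` and a unit state weight in the Riccati equation.
* **Objective reporting** uses trapezoidal quadrature of the running cost
  along the realized trajectory (presentation-only choice).
* **Control admissibility.** No bounds are imposed inside the solve; an
  optional [0, 1] clamp is available for pharmacological reading and is
  applied in the forward pass only, never inside the Riccati sweep.
* **Duration summaries.** A schedule "settles" when it falls below a
  threshold and stays below through the horizon: thresholds default to
  1e-3 (absolute) for controls and 1% of m0 for the state, both
  configurable and recorded in the output metadata; "never" is the
  +inf sentinel.
* **Report-time extraction** (t = 50/100/150/250 days) uses linear
  interpolation on the raw step grids (the printed step counts do not land
  on those days exactly); step counts rounded to multiples of 70 are a
  config choice away, and both choices are recorded in the manifest.

## Scale sensitivity of the unit-weight cost — and what the solver finds

With unit weights the optimal schedules are small. The reason is structural:
the control-effectiveness coefficients are |b_T| ≈ 1.4×10⁻⁵ and
|b_G| ≈ 5.7×10⁻⁴ (g/cm³/day per unit efficacy), while the state never
exceeds ~3.5×10⁻² g/cm³, so the integrated squared-density cost
(~4×10⁻⁴·t_f) is far below the ~2·t_f cost of sustained full blockade. The
closed loop therefore stays near the uncontrolled trajectory, rising toward
c/d_m, and any affine-LQR closed loop here decays no slower than
`d_m + |B|²p(t) ≥ d_m` toward its own affine equilibrium — a slow decay to
zero is not expressible in this cost regime under any of the convention
flags. Schedules that actually clear the density require state weights
q_m ≳ 3×10⁵ (equivalently, working in units where the density is O(1)); the
test suite demonstrates the q_m = 10⁷ regime. The acceptance tests run the
unit-weight study conditions across every convention path and record, per
path, how the computed center densities and crossing days relate to
previously reported values for this model; those comparisons are computed
at run time, not asserted as facts here.

## What the studies emulate — and what they do not

The study runner regenerates, as machine-readable artifacts: the drug-free
forward solve per order (16/24/32), the constant-dose comparison at
(0,0)/(0.1,0.1)/(0.3,0.3)/(0.5,0.5), the optimal regulator solve with its
center-density table and duration summaries, and order-vs-order convergence
tables at 4000/7000/10000 steps. There is no external data anywhere; the
default configuration *is* the study condition set, and all inputs are the
built-in constants. Because the dynamics are exactly uniform under the
default initial condition, order-vs-order differences measure only rounding
(or instability), not spectral convergence — a genuinely non-uniform
initial state would be needed for the latter, and none is part of the
reported conditions. Passing tests therefore validate the discretization
operators, the uniform-manifold dynamics, and the optimality system; they
say nothing about spatially heterogeneous lesions, cytokine feedback, or
pharmacokinetics, none of which are modelled.

## Known limitations

* Single spectral element per dimension; no multi-element meshes or curved
  geometry. Dense matrix storage (orders ≤ 33 per dimension).
* Explicit Euler only; the stability limits above bind at high order and
  coarse steps. No adaptive or implicit stepping.
* Static cytokine concentrations; no immune-network coupling.
* The quadratic cost is scale-sensitive (see above); unit weights represent
  a specific — and weak — dosing preference.
* Matrix-mode Riccati sweeps store the full P(t) path and are intended for
  verification at small orders, not for N = 32.
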
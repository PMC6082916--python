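# Methods

## Model

The package computes electrostatic energies and forces of periodic
point-charge systems under an isotropic-periodic-sum pseudo pair potential
`u_pseudo(r, R_c) = u(r) + phi(r, R_c)`, with `u = 1/r` per unit charge
product and `phi` a bounded reaction field encoding isotropically
distributed periodic images inside the cutoff sphere. Pair energies are
`q_i q_j · u_pseudo(r_ij) · k_C`, with the Coulomb prefactor `k_C = 1` in
reduced units (configurable for physical unit systems; no conversion
constant is baked in).

The exact three-way split into `u_S` (vanishing beyond an auxiliary cutoff
`r_c`), `u_L` (bounded, vanishing beyond `R_c`) and the constant boundary
term `u_B` is an algebraic identity: their sum reproduces
`u_pseudo(r, R_c)` for every `r < R_c`, which the tests verify to 1e-12
relative for every shipped reaction field. At `r` exactly equal to a cutoff
the zero branch is taken; this is a measure-zero convention and `u_S` is
continuous there anyway. The limit
`u_L(0) = phi(0,R_c) − phi(0,r_c) + u_pseudo(r_c,r_c) − u_pseudo(R_c,R_c)`
is finite because the Coulomb singularities cancel; it is evaluated through
`phi_at_zero` when the plug-in provides it and by Richardson extrapolation
at `r = 1e-3 r_c, 1e-4 r_c` otherwise.

### Reaction-field plug-ins

The closed forms of published LIPS-type reaction fields are not reproduced;
`phi` is a registered plug-in. Shipped:

| name  | phi(r, R_c)                        | notes |
|-------|------------------------------------|-------|
| null  | 0                                  | shifted truncated Coulomb baseline |
| poly5 | Σ_{k≤5} c_k (r/R_c)^k              | generic polynomial family; coefficients carry energy units, supplied by the user |
| rf    | r²/(2R_c³) − 3/(2R_c)              | classic Coulomb reaction field; potential *and* force continuous at R_c |

`rf` is the default choice in examples and the toy MD because its
continuous force makes NVE conservation measurements clean. The whole mesh
machinery is potential-agnostic; any object satisfying the pair-potential
contract (finite, differentiable `u` for `r > 0`; finite `phi` on
`[0, R_c]`) can be registered.

## Real-space path

`U_S` uses a cell list with cell edge ≥ `r_c` (falling back to all pairs
when the box holds fewer than three cells per axis or N < 64, where the
list cannot prune anything); the cell-list result is identical, not
approximate, to the all-pairs sum. `U_B` uses a direct double loop: at
`R_c ≈ L/2` nearly every pair is inside the cutoff, so a cell list gains
nothing, and the term is a force-free scalar. Both sums exclude `j = i`;
self-interaction enters only through the mesh and is corrected there.
Cutoffs are validated against the minimum-image bound `cutoff ≤ min(L)/2`.
Boxes are orthorhombic only; cutoffs are atom-based.

## Mesh path

- **Spreading.** Scaled fractional coordinates `w = K x / L`; each charge is
  deposited on the `n` nearest grid points per axis with cardinal B-spline
  weights `M_n`, evaluated by the standard two-term recursion (exact compact
  support, O(n²) work). The spline order must be even — odd orders can zero
  the structure-factor denominator at `m = K/2` — and `K ≥ 2n` per axis so a
  spline's support never wraps onto itself.
- **Energy array.** `Φ*` samples `u_L` pointwise at grid-node displacements,
  summed over the 27 nearest periodic images with `r < R_c` strict. With
  `R_c ≤ L/2` at most one image contributes per entry, but the full sum is
  robust when `R_c` sits exactly at `L/2` on grid boundaries. The
  zero-displacement entry is `u_L(0)`.
- **Deconvolution and energy.** `B(m) = |b₁|²|b₂|²|b₃|²` deconvolves the two
  spline spreadings of the charge pair; `Φ*` is tabulated, not spread, so it
  is not deconvolved. Modes whose `b`-denominator falls below 1e-10 in
  modulus are dropped (B = 0). With the numpy/scipy FFT convention (inverse
  transform carries `1/(K₁K₂K₃)`) the energy is
  `U_L = 1/(2K₁K₂K₃) Σ_m B |F(Q)|² F(Φ*)`; this normalization is fixed in
  one helper and pinned by the oracle-convergence tests rather than by any
  transcription.
- **Self term.** The convolution includes `i = j`, whose continuum value is
  the constant `½ (Σ qᵢ²) u_L(0)`. The assembly subtracts it by default so
  the total matches the pairwise direct sum; a flag retains the raw grid
  value.
- **Forces.** `f_{α,i} = −Σ_grid (∂Q/∂r_{α,i}) · IFFT[B F(Q) F(Φ*)]`, with
  `∂Q/∂r` from `dM_n/dw = M_{n−1}(w) − M_{n−1}(w−1)` and the chain-rule
  factor `K_α/L_α`. These are the *exact* gradient of the discrete mesh
  energy (verified to ~1e-9 against central differences); their deviation
  from the true pairwise forces is the grid discretization error, which the
  refinement tests show decreasing monotonically over spacings
  0.2 → 0.1 → 0.05 at order 8.

Defaults mirror common practice for B-spline particle-mesh electrostatics:
spline order 8, target grid spacing 0.1 (length units), `r_c = 1.0`,
`R_c = L/2`.

## Oracle

The reference path sums `q_i q_j u_pseudo(r_ij, R_c)` over all minimum-image
pairs inside `R_c` — an O(N²) double loop with analytic pair derivatives
(5-point central differences with step `1e-6 r_c` for plug-ins without
`dphi`). The decomposition closure test confirms, end to end in real space,
that the direct total equals `U_S + U_L(no self) + U_B` to 1e-10 relative.

## Observables and force metrics

`δ_f` uses the `3N − 1` denominator; `e_f,max` is the max per-component
deviation. `g(r)` is implemented with the `N(N−1)` normalization and no
factor-2 pair convention — users comparing against codes that normalize per
distinct pair should expect that convention difference. The Einstein
diffusion fit takes `D = slope/6` over the central `[t_max/4, t_max/2]`
window (avoids the ballistic start and the noisy tail; configurable), with
origin-averaged MSD by default for statistics and a log-log slope
diagnostic that flags ballistic (slope ≈ 2) trajectories. `ψ(z)` double
integrates the binned charge density with two cumulative-trapezoid passes
on bin centers, referenced to the first bin (the vacuum region in slab
geometries); `ε₀` is configurable and 1 in reduced units.

## Synthetic data

The generators are pure functions of their arguments including the seed
(`numpy.random.default_rng`, no global state):

- `random_neutral_system`: ±1 charges, uniform positions, rejection radius
  `0.05 min(L)` — a generic disordered ionic configuration, the workhorse
  of the oracle-equivalence tests.
- `slab_system`: dipolar pairs confined to a central slab — heterogeneity
  for profile observables.
- `dipole_pair`: the two-body closed-form input.
- `brownian_trajectory`: Gaussian steps of variance `2 D₀ dt` per axis with
  the unwrapped truth retained — ground truth for diffusion recovery.

These fixtures probe the *numerics* of the method: they contain no
molecular structure, no polarization, no thermal correlations. Passing
tests demonstrate that the split is exact, that the mesh converges to the
pairwise sum, and that the observable estimators recover planted values —
not that any particular reaction field is accurate for real water or
ionic liquids, which depends on coefficients this package deliberately
does not fix.

## Toy MD

Verlet leapfrog with half-step velocities; on-step kinetic energies are
reconstructed from the mean of adjacent half-step velocities. Electrostatic
forces come from the full mesh path each step; a soft-sphere `ε(σ/r)¹²`
repulsion (energy-shifted at its cutoff, defaults ε = 1, σ = 0.2,
r_cut = 0.6) keeps opposite charges from collapsing. Because the fixed grid
breaks continuous translation invariance, the mesh leaves a small net force
(~1e-3 of the per-particle scale at spacing 0.2); the driver removes the
mean force by default — standard center-of-mass motion removal — which
restores exact momentum conservation while changing individual forces
negligibly. The optional thermostat is plain velocity rescaling every k
steps; it is a crude equilibration device, not a canonical sampler.

Conservation measurements use a 32-ion melt in a 4³ box at `r_c = 1`,
`R_c = 2`, spacing 0.2, `dt = 0.001` (about 1/60 of the shortest collision
period at these parameters), 2000 steps: the relative NVE drift is ~2e-4
and scales as `dt²` as expected for a symplectic integrator.

## Numerical choices and edge cases

- Positions wrap into `[0, L)` on construction; minimum-image components
  reduce into `(−L/2, L/2]`.
- Strict `<` at every cutoff; ties go to the zero branch.
- `Φ*` inversion symmetry and the B-factor conjugate symmetry make the
  spectral energy real; the implementation takes real parts only after
  products that are analytically real.
- Degenerate inputs: single particles and all-zero charge sets short-circuit
  to exact zeros; non-finite positions or forces raise immediately.
- Problem sizes in the test suite and the verification script (N = 64
  frames, 10-charge gradient checks, 100×1000 Brownian paths, 2000-step
  melts) were chosen as the smallest systems at which each property is
  cleanly measurable at its stated tolerance.

## Known limitations

- Orthorhombic boxes only; no triclinic cells, no Verlet-skin management,
  no parallel decomposition.
- No lattice-sum (Ewald/SPME) reference: accuracy statements are relative
  to the direct pseudo-potential sum, not to an exact lattice sum.
- Published closed-form reaction-field coefficient sets are not bundled;
  `poly5` accepts them but correctness of any particular published set is
  the user's responsibility.
- Molecule-level force aggregation (site forces summed per molecule) is not
  implemented; all forces are per point charge.
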
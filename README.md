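# lipsfft

Fast evaluation of isotropic-periodic-sum (IPS/LIPS) electrostatics for
periodic point-charge systems, with an FFT-accelerated long-range path and a
direct pairwise oracle to verify it against.

## The problem

Cutoff-based electrostatics schemes built on the isotropic periodic sum
replace the anisotropic lattice images of a periodic box with isotropically
distributed images inside a cutoff sphere of radius `R_c`, producing a
*pseudo pair potential*

```
u_pseudo(r, R_c) = u(r) + phi(r, R_c)
```

where `u(r) = 1/r` is the bare Coulomb interaction (per unit charge
product) and `phi` is a smooth periodic reaction field. These potentials
are accurate when `R_c` is large — typically half the box length — which
makes a naive real-space sum over all pairs inside `R_c` the performance
bottleneck. This package removes that bottleneck the same way smooth
particle-mesh Ewald treats the Ewald reciprocal sum: the pseudo potential is
split *exactly* into

```
u_S(r) = u_pseudo(r, r_c) - u_pseudo(r_c, r_c)      r < r_c   (short range)
u_B(r) = u_pseudo(R_c, R_c)                         r < R_c   (boundary)
u_L(r) = u_pseudo(r, R_c) - u_S(r) - u_B(r)         r < R_c   (long range)
```

`u_S` is summed in real space with a cell list, `u_B` is a force-free
constant term, and `u_L` — which is *bounded* on `[0, R_c]` because the
`1/r` singularities cancel — is evaluated on a mesh: charges are spread
with cardinal B-splines of order `n` (charge array `Q`), `u_L` is tabulated
at grid-node displacements (energy array `Φ*`), the spline spreading is
deconvolved with the squared B-spline structure factors
`B = |b₁|²|b₂|²|b₃|²`, and

```
U_L = 1/(2 K₁K₂K₃) Σ_m B(m) |F(Q)(m)|² F(Φ*)(m)
```

with forces from the analytic B-spline derivative — the exact gradient of
the discrete mesh energy. The grid sum includes the `i = j` self pair; its
value `½ (Σ qᵢ²) u_L(0)` is finite and is subtracted by default so the
method reproduces the pairwise sum.

The reaction field `phi` is a plug-in: shipped are `null` (`phi ≡ 0`,
shifted truncated Coulomb), `poly5` (`phi = Σ c_k (r/R_c)^k`, into which
published polynomial reaction-field coefficients can be entered) and `rf`
(the classic Coulomb reaction field, force-continuous at `R_c`).

Everything is cross-checked against a brute-force `O(N²)` minimum-image
oracle, and the package ships the standard evaluation machinery: force
RMSD `δ_f` (with its `3N − 1` denominator) and max error `e_f,max`, radial
distribution function, velocity autocorrelation, Einstein-relation
diffusion, density and electrostatic-potential profiles, plus a toy
leapfrog MD loop for conservation tests.

Intended users: people developing or validating long-range interaction
schemes for molecular simulation, and anyone needing a small, well-tested
reference implementation of B-spline particle-mesh machinery.

## Worked example

Generate a 64-charge neutral box (reduced units, box 4×4×4, charges ±1),
evaluate it with the mesh path and with the direct oracle, and compare
forces:

```sh
lipsfft gen random --n 64 --box 4,4,4 --seed 1 -o f.xyz
lipsfft energy f.xyz --potential rf --rc 1.0 --Rc 2.0 --spacing 0.1 -o e.json
lipsfft oracle f.xyz --potential rf --rc 1.0 --Rc 2.0 -o o.json
lipsfft compare e.json o.json
```

prints

```json
{
  "N": 64,
  "delta_f": 0.010569885487030105,
  "e_f_max": 0.03874264247374137
}
```

and the two JSON results hold `U_total = -1.0697…` (mesh, grid spacing 0.1)
vs `-1.0750…` (oracle): at spacing 0.1 the FFT path reproduces the direct
`O(N²)` sum to 0.5% in energy, with a force RMSD of ~0.01 in reduced force
units; halving the spacing shrinks both further (see the acceptance
script). Each result file also carries the component breakdown
`U_S`, `U_L`, `U_B` and the per-particle force array.

The same objects are available from Python:

```python
import lipsfft as lf

sys = lf.random_neutral_system(64, (4., 4., 4.), seed=1)
sp = lf.SplitPotential(lf.get_potential("rf"), r_c=1.0, R_c=2.0)
res = lf.total_energy_forces(sys, sp, lf.MeshConfig(target_spacing=0.1))
ref = lf.direct_lips(sys, sp)
print(res.U_total, ref.U_total, lf.force_rmsd(res.forces, ref.forces))
```

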
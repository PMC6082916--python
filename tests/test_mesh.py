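"""B-spline kernels, charge spreading, structure factors, FFT energy/forces."""

import numpy as np
import pytest

from lipsfft import (ChargeSystem, MeshConfig, SplitPotential, bspline,
                     bspline_derivative, build_energy_array, compute_bfactors,
                     dipole_pair, get_potential, long_range_energy,
                     long_range_forces, spread_charges, total_energy_forces,
                     force_rmsd, random_neutral_system)
from lipsfft.oracle import direct_lips, direct_long_range

BOX = np.array([4.0, 4.0, 4.0])


# -- B-spline kernels ---------------------------------------------------------

def test_triangle_spline_peak():
    assert bspline(2, 1.0) == pytest.approx(1.0)


@pytest.mark.parametrize("n", [2, 4, 6, 8])
def test_compact_support(n):
    w = np.array([-1.0, -1e-9, 0.0, float(n), n + 1e-9, n + 3.0])
    np.testing.assert_array_equal(bspline(n, w), 0.0)


@pytest.mark.parametrize("n", [2, 4, 6, 8])
def test_partition_of_unity(n):
    rng = np.random.default_rng(n)
    for w in rng.uniform(0, 1, 100):
        total = sum(bspline(n, w + k) for k in range(n))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_derivative_identity_base_case():
    # n = 2, w = 0.5: M_1(0.5) - M_1(-0.5) = 1 - 0 = 1
    assert bspline_derivative(2, 0.5) == pytest.approx(1.0)


@pytest.mark.parametrize("n", [4, 6, 8])
def test_derivative_matches_finite_differences(n):
    w = np.linspace(-0.5, n + 0.5, 37)
    h = 1e-6
    num = (bspline(n, w + h) - bspline(n, w - h)) / (2 * h)
    np.testing.assert_allclose(bspline_derivative(n, w), num, atol=1e-6)


def test_derivative_integrates_to_zero():
    w = np.linspace(-1, 9, 20001)
    integral = np.trapezoid(bspline_derivative(8, w), w)
    assert integral == pytest.approx(0.0, abs=1e-10)


# -- charge spreading ---------------------------------------------------------

def test_spread_conserves_total_charge():
    rng = np.random.default_rng(4)
    for seed in range(3):
        pos = rng.uniform(0, 1, (1, 3)) * BOX
        sys = ChargeSystem(pos, np.array([1.0]), BOX)
        Q = spread_charges(sys, MeshConfig(target_spacing=0.25)).Q
        assert Q.sum() == pytest.approx(1.0, abs=1e-12)


def test_spread_matches_naive_deposition(small_random_system):
    mesh = MeshConfig(target_spacing=0.25, spline_order=4)
    sys = small_random_system
    K = mesh.grid_shape(sys.box)
    n = mesh.spline_order
    Q_ref = np.zeros(K)
    for i in range(sys.n):
        w = np.array(K) * sys.positions[i] / sys.box
        for kx in range(K[0]):
            wx = sum(bspline(n, w[0] - kx - s * K[0]) for s in (-1, 0, 1))
            if wx == 0:
                continue
            for ky in range(K[1]):
                wy = sum(bspline(n, w[1] - ky - s * K[1]) for s in (-1, 0, 1))
                if wy == 0:
                    continue
                for kz in range(K[2]):
                    wz = sum(bspline(n, w[2] - kz - s * K[2]) for s in (-1, 0, 1))
                    Q_ref[kx, ky, kz] += sys.charges[i] * wx * wy * wz
    Q = spread_charges(sys, mesh).Q
    np.testing.assert_allclose(Q, Q_ref, atol=1e-13)


def test_grid_cell_translation_permutes_charge_array(neutral64):
    mesh = MeshConfig(target_spacing=0.25, spline_order=8)
    K = mesh.grid_shape(neutral64.box)
    Q0 = spread_charges(neutral64, mesh).Q
    shift = neutral64.box[0] / K[0]
    moved = ChargeSystem(neutral64.positions + [shift, 0, 0],
                         neutral64.charges, neutral64.box)
    Q1 = spread_charges(moved, mesh).Q
    np.testing.assert_allclose(Q1, np.roll(Q0, 1, axis=0), atol=1e-12)


def test_mesh_config_validation():
    with pytest.raises(ValueError):
        MeshConfig(K=(16, 16, 16), spline_order=7)   # odd order
    with pytest.raises(ValueError):
        MeshConfig(K=(8, 16, 16), spline_order=8)    # K < 2n
    with pytest.raises(ValueError):
        MeshConfig()                                  # neither K nor spacing
    mesh = MeshConfig(target_spacing=0.1, spline_order=8)
    K = mesh.grid_shape((4.0, 4.0, 4.0))
    assert all(4.0 / k <= 0.1 for k in K)


# -- structure factors --------------------------------------------------------

@pytest.mark.parametrize("n", [2, 4, 8])
def test_bfactor_dc_mode_is_unity(n):
    mesh = MeshConfig(K=(32, 32, 32), spline_order=n)
    B = compute_bfactors(mesh, (32, 32, 32)).B
    assert B[0, 0, 0] == pytest.approx(1.0)
    assert np.all(B >= 0)


def test_bfactor_conjugate_symmetry():
    mesh = MeshConfig(K=(20, 24, 28), spline_order=8)
    B = compute_bfactors(mesh, (20, 24, 28)).B
    idx = np.indices(B.shape)
    B_rev = B[tuple((-idx[i]) % B.shape[i] for i in range(3))]
    np.testing.assert_allclose(B, B_rev, rtol=1e-12)


# -- energy array -------------------------------------------------------------

def test_energy_array_origin_is_long_range_limit(rf_split):
    mesh = MeshConfig(target_spacing=0.25, spline_order=8)
    Pg = build_energy_array(BOX, mesh, rf_split)
    assert Pg.Phi_star[0, 0, 0] == pytest.approx(rf_split.long_range_at_zero())


def test_energy_array_zero_beyond_cutoff(rf_split):
    mesh = MeshConfig(target_spacing=0.25, spline_order=8)
    Pg = build_energy_array(BOX, mesh, rf_split)
    K = Pg.Phi_star.shape
    idx = np.indices(K).reshape(3, -1).T
    frac = idx / np.array(K)
    d = np.minimum(frac, 1 - frac) * BOX    # min-image node displacement
    r = np.linalg.norm(d, axis=1)
    outside = (r >= rf_split.R_c).reshape(K)
    np.testing.assert_array_equal(Pg.Phi_star[outside], 0.0)


def test_energy_array_inversion_symmetry(rf_split):
    mesh = MeshConfig(K=(20, 24, 32), spline_order=8)
    Pg = build_energy_array(BOX, mesh, rf_split)
    P = Pg.Phi_star
    idx = np.indices(P.shape)
    P_rev = P[tuple((-idx[i]) % P.shape[i] for i in range(3))]
    np.testing.assert_allclose(P, P_rev, atol=1e-14)


# -- FFT energy ---------------------------------------------------------------

def _grids(sys, sp, spacing=0.2, order=8):
    mesh = MeshConfig(target_spacing=spacing, spline_order=order)
    K = mesh.grid_shape(sys.box)
    return (mesh, spread_charges(sys, mesh), build_energy_array(sys.box, mesh, sp),
            compute_bfactors(mesh, K))


def test_zero_charges_zero_energy_and_forces(rf_split):
    sys = ChargeSystem(np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 0.5]]),
                       np.zeros(2), BOX)
    mesh, Qg, Pg, Bg = _grids(sys, rf_split)
    assert long_range_energy(Qg, Pg, Bg) == 0.0
    np.testing.assert_array_equal(long_range_forces(sys, mesh, Pg, Bg), 0.0)


def test_energy_bilinear_in_charges(small_random_system, rf_split):
    sys = small_random_system
    mesh, Qg, Pg, Bg = _grids(sys, rf_split)
    U1 = long_range_energy(Qg, Pg, Bg)
    doubled = ChargeSystem(sys.positions, 2 * sys.charges, sys.box)
    U4 = long_range_energy(spread_charges(doubled, mesh), Pg, Bg)
    assert U4 == pytest.approx(4 * U1, rel=1e-12)


def test_mesh_energy_converges_to_direct_self_inclusive_sum(rf_split):
    rng = np.random.default_rng(8)
    pos = rng.uniform(0, 1, (16, 3)) * BOX
    q = rng.normal(size=16)
    q -= q.mean()
    sys = ChargeSystem(pos, q, BOX)
    U_ref, _ = direct_long_range(sys, rf_split, include_self=True)
    errors = []
    for spacing in (0.25, 0.125, 0.0625):
        _, Qg, Pg, Bg = _grids(sys, rf_split, spacing=spacing)
        errors.append(abs(long_range_energy(Qg, Pg, Bg) - U_ref))
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 1e-3 * abs(U_ref)


def test_mismatched_grid_shapes_rejected(small_random_system, rf_split):
    sys = small_random_system
    _, Qg, Pg, _ = _grids(sys, rf_split, spacing=0.2)
    _, _, _, Bg_small = _grids(sys, rf_split, spacing=0.25)
    with pytest.raises(ValueError):
        long_range_energy(Qg, Pg, Bg_small)


# -- FFT forces ---------------------------------------------------------------

def test_mesh_forces_match_energy_gradient(rf_split):
    rng = np.random.default_rng(12)
    pos = rng.uniform(0, 1, (10, 3)) * BOX
    q = rng.normal(size=10)
    q -= q.mean()
    sys = ChargeSystem(pos, q, BOX)
    mesh, Qg, Pg, Bg = _grids(sys, rf_split, spacing=0.2)
    F = long_range_forces(sys, mesh, Pg, Bg, Qg=Qg)
    h = 1e-6
    F_num = np.zeros_like(F)
    for i in range(sys.n):
        for a in range(3):
            for s, sign in ((h, 1.0), (-h, -1.0)):
                p = sys.positions.copy()
                p[i, a] += s
                shifted = ChargeSystem(p, q, BOX)
                U = long_range_energy(spread_charges(shifted, mesh), Pg, Bg)
                F_num[i, a] -= sign * U / (2 * h)
    scale = np.max(np.abs(F))
    np.testing.assert_allclose(F, F_num, atol=1e-5 * scale)


def test_symmetric_opposite_charges_have_opposite_forces(rf_split):
    sys = dipole_pair(1.2, offset=BOX / 2 - [0.6, 0, 0], box=BOX)
    mesh, Qg, Pg, Bg = _grids(sys, rf_split, spacing=0.1)
    F = long_range_forces(sys, mesh, Pg, Bg, Qg=Qg)
    assert np.linalg.norm(F[0] + F[1]) < 1e-8 * np.linalg.norm(F[0])


# -- assembly -----------------------------------------------------------------

def test_two_body_total_matches_closed_form(rf_split):
    d = 1.4
    sys = dipole_pair(d, box=BOX)
    res = total_energy_forces(sys, rf_split, MeshConfig(target_spacing=0.05))
    expected = -(float(rf_split.u_S(d)) + float(rf_split.u_L(d))
                 + float(rf_split.u_B(d)))
    assert res.U_total == pytest.approx(expected, rel=1e-4)
    assert res.U_total == pytest.approx(res.U_S + res.U_L + res.U_B)


def test_force_error_decreases_with_grid_refinement(neutral64, rf_split):
    ref = direct_lips(neutral64, rf_split)
    errs = [force_rmsd(
        total_energy_forces(neutral64, rf_split,
                            MeshConfig(target_spacing=s)).forces, ref.forces)
        for s in (0.2, 0.1)]
    assert errs[1] < errs[0]


def test_particle_reordering_invariance(rf_split):
    sys = random_neutral_system(16, BOX, seed=5)
    perm = np.random.default_rng(1).permutation(16)
    permuted = ChargeSystem(sys.positions[perm], sys.charges[perm], sys.box)
    mesh = MeshConfig(target_spacing=0.2)
    r1 = total_energy_forces(sys, rf_split, mesh)
    r2 = total_energy_forces(permuted, rf_split, mesh)
    assert r2.U_total == pytest.approx(r1.U_total, rel=1e-12)
    np.testing.assert_allclose(r2.forces, r1.forces[perm], atol=1e-10)


def test_self_term_flag_shifts_by_constant(neutral64, rf_split):
    mesh = MeshConfig(target_spacing=0.2)
    on = total_energy_forces(neutral64, rf_split, mesh)
    off = total_energy_forces(neutral64, rf_split, mesh,
                              self_term_correction=False)
    shift = 0.5 * np.sum(neutral64.charges**2) * rf_split.long_range_at_zero()
    assert off.U_L - on.U_L == pytest.approx(shift, rel=1e-12)
    np.testing.assert_allclose(on.forces, off.forces)
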
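"""Brute-force O(N^2) minimum-image reference energies and forces.

The ground truth every mesh result is tested against: the pairwise sum

    U = 1/2 sum_{i != j, r_ij < R_c} q_i q_j u_pseudo(r_ij, R_c)

(whose split into U_S + U_L + U_B is an algebraic identity), with forces
from the analytic pair derivative (a finite-difference fallback covers
plug-in reaction fields without derivatives).  Valid whenever minimum image
suffices, i.e. R_c <= min(L)/2.
"""

from __future__ import annotations

import numpy as np

from .potentials import SplitPotential
from .realspace import ChargeSystem, ForceEnergyResult, minimum_image, \
    short_range_sum, boundary_sum

__all__ = ["direct_lips", "direct_long_range"]


def _pair_table(sys: ChargeSystem):
    iu, ju = np.triu_indices(sys.n, k=1)
    d = minimum_image(sys.positions[iu], sys.positions[ju], sys.box)
    r = np.linalg.norm(d, axis=1)
    return iu, ju, d, r


def direct_lips(sys: ChargeSystem, sp: SplitPotential) -> ForceEnergyResult:
    """Direct pairwise pseudo-potential sum, decomposed as U_S + U_L + U_B."""
    if sp.R_c > np.min(sys.box) / 2 + 1e-12:
        raise ValueError("R_c must not exceed half the shortest box length")
    n = sys.n
    forces = np.zeros((n, 3))
    if n == 1:
        return ForceEnergyResult(0.0, 0.0, 0.0, 0.0, forces,
                                 {"method": "direct"})
    iu, ju, d, r = _pair_table(sys)
    qq = sys.charges[iu] * sys.charges[ju]
    inside = r < sp.R_c
    U_S = float(np.sum(qq * sp.u_S(r)))
    U_L = float(np.sum(qq * sp.u_L(r)))
    U_B = float(np.sum(qq[inside]) * sp.boundary_constant())
    # force = -qq * d/dr[u_S + u_L](r) * rhat  (u_B is flat inside R_c)
    du = sp.du_S(r) + sp.du_L(r)
    fmag = np.where(inside, -qq * du / np.where(r > 0, r, 1.0), 0.0)
    fvec = fmag[:, None] * d
    np.add.at(forces, iu, fvec)
    np.add.at(forces, ju, -fvec)
    return ForceEnergyResult(U_S, U_L, U_B, U_S + U_L + U_B, forces,
                             {"method": "direct", "r_c": sp.r_c, "R_c": sp.R_c,
                              "potential": sp.base.label})


def direct_long_range(sys: ChargeSystem, sp: SplitPotential,
                      include_self: bool = False):
    """Pairwise long-range sum (1/2) sum_{i,j} q_i q_j u_L(r_ij).

    With ``include_self`` the j = i term (1/2)(sum q_i^2) u_L(0) is added —
    the quantity the uncorrected mesh convolution approximates.  Returns
    ``(U_L, forces)``.
    """
    n = sys.n
    forces = np.zeros((n, 3))
    U = 0.0
    if n > 1:
        iu, ju, d, r = _pair_table(sys)
        qq = sys.charges[iu] * sys.charges[ju]
        U = float(np.sum(qq * sp.u_L(r)))
        inside = r < sp.R_c
        fmag = np.where(inside, -qq * sp.du_L(r) / np.where(r > 0, r, 1.0), 0.0)
        fvec = fmag[:, None] * d
        np.add.at(forces, iu, fvec)
        np.add.at(forces, ju, -fvec)
    if include_self:
        U += 0.5 * float(np.sum(sys.charges ** 2)) * sp.long_range_at_zero()
    return U, forces
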
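"""Pseudo pair potentials and their short/long/boundary split.

An isotropic-periodic-sum (IPS/LIPS) pseudo pair potential augments the bare
Coulomb interaction with a periodic reaction field::

    u_pseudo(r, R_c) = u(r) + phi(r, R_c)

where ``u(r) = 1/r`` (per unit charge product, times an optional unit-system
prefactor) and ``phi`` is a smooth, singularity-free reaction-field term that
encodes the isotropically distributed periodic images inside the cutoff
sphere of radius ``R_c``.  The closed forms of the published LIPS reaction
fields are not reproduced here; ``phi`` is a plug-in satisfying the
:class:`PairPotential` contract, and three built-ins are registered:

``null``
    phi == 0: the shifted, truncated Coulomb baseline.
``poly5``
    phi(r, R_c) = sum_{k=0..5} c_k (r/R_c)^k with user-supplied coefficients,
    into which published polynomial reaction-field coefficients can be
    entered (coefficients carry energy units; no implicit 1/R_c scale).
``rf``
    the classic Coulomb reaction field phi = r^2/(2 R_c^3) - 3/(2 R_c),
    whose force is continuous at R_c (useful for dynamics).

For fast evaluation the pseudo potential is split exactly into three parts:
a short-range part that vanishes beyond an auxiliary cutoff ``r_c`` (summed
directly in real space), a bounded long-range part that vanishes beyond
``R_c`` (evaluated on a mesh by FFT convolution), and a constant boundary
part inside ``R_c``::

    u_S(r) = u_pseudo(r, r_c) - u_pseudo(r_c, r_c)        (r < r_c), else 0
    u_B(r) = u_pseudo(R_c, R_c)                           (r < R_c), else 0
    u_L(r) = u_pseudo(r, R_c) - u_S(r) - u_B(r)           (r < R_c), else 0

The 1/r singularities of u_pseudo(r, R_c) and u_S(r) cancel in u_L, which is
therefore finite at r = 0 -- the property the mesh path relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "PairPotential",
    "NullField",
    "PolynomialField",
    "ReactionField",
    "SplitPotential",
    "evaluate_lips",
    "get_potential",
    "register_potential",
    "available_potentials",
]


class PairPotential:
    """Bare Coulomb interaction plus a pluggable reaction field.

    Subclasses implement ``phi(r, R_c)`` (finite on [0, R_c], no singularity
    at r = 0) and, when available, its analytic radial derivative
    ``dphi(r, R_c)``.  All methods accept scalars or ndarrays.
    """

    label = "abstract"
    has_analytic_derivative = False

    @staticmethod
    def u(r):
        return 1.0 / np.asarray(r, dtype=float)

    @staticmethod
    def du(r):
        r = np.asarray(r, dtype=float)
        return -1.0 / (r * r)

    def phi(self, r, R_c):
        raise NotImplementedError

    def dphi(self, r, R_c):
        raise NotImplementedError

    def phi_at_zero(self, R_c: float) -> float:
        """phi(0, R_c); overridden when a cheaper closed form exists."""
        return float(self.phi(0.0, R_c))


class NullField(PairPotential):
    """phi == 0: shifted truncated Coulomb, the degenerate baseline."""

    label = "null"
    has_analytic_derivative = True

    def phi(self, r, R_c):
        return np.zeros_like(np.asarray(r, dtype=float))

    def dphi(self, r, R_c):
        return np.zeros_like(np.asarray(r, dtype=float))

    def phi_at_zero(self, R_c):
        return 0.0


class PolynomialField(PairPotential):
    """phi(r, R_c) = sum_k c_k (r/R_c)^k, k = 0..5.

    The generic polynomial family into which published reaction-field
    coefficients can be entered.  Coefficients carry energy units (per unit
    charge product).
    """

    label = "poly5"
    has_analytic_derivative = True

    def __init__(self, coefficients):
        c = np.asarray(coefficients, dtype=float)
        if c.ndim != 1 or c.size > 6:
            raise ValueError("poly5 expects at most 6 coefficients c0..c5")
        self.coefficients = np.zeros(6)
        self.coefficients[: c.size] = c

    def phi(self, r, R_c):
        s = np.asarray(r, dtype=float) / R_c
        return np.polynomial.polynomial.polyval(s, self.coefficients)

    def dphi(self, r, R_c):
        s = np.asarray(r, dtype=float) / R_c
        dc = self.coefficients[1:] * np.arange(1, 6)
        return np.polynomial.polynomial.polyval(s, dc) / R_c

    def phi_at_zero(self, R_c):
        return float(self.coefficients[0])


class ReactionField(PairPotential):
    """Classic Coulomb reaction field: phi = r^2/(2 R_c^3) - 3/(2 R_c).

    Chosen so that both the pseudo potential and its derivative vanish at
    r = R_c, giving a continuous force across the cutoff.
    """

    label = "rf"
    has_analytic_derivative = True

    def phi(self, r, R_c):
        r = np.asarray(r, dtype=float)
        return r * r / (2.0 * R_c**3) - 1.5 / R_c

    def dphi(self, r, R_c):
        return np.asarray(r, dtype=float) / R_c**3

    def phi_at_zero(self, R_c):
        return -1.5 / R_c


_REGISTRY: dict[str, type] = {}


def register_potential(name: str, cls) -> None:
    """Register a PairPotential subclass under a config-file name."""
    _REGISTRY[name] = cls


def available_potentials():
    return sorted(_REGISTRY)


def get_potential(name: str, **kwargs) -> PairPotential:
    """Instantiate a registered reaction-field plug-in by name.

    ``poly5`` takes ``coefficients=[c0..c5]``; the others take no arguments.
    """
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown potential {name!r}; available: {available_potentials()}"
        ) from None
    return cls(**kwargs)


register_potential("null", NullField)
register_potential("poly5", PolynomialField)
register_potential("rf", ReactionField)


def evaluate_lips(pot: PairPotential, r, R_c: float, prefactor: float = 1.0):
    """Pseudo pair potential u(r) + phi(r, R_c), per unit charge product.

    Raises ValueError for non-positive r or R_c.
    """
    r = np.asarray(r, dtype=float)
    if R_c <= 0:
        raise ValueError("R_c must be positive")
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    return prefactor * (pot.u(r) + pot.phi(r, R_c))


class SplitPotential:
    """A pseudo pair potential with its exact three-way cutoff split.

    Parameters
    ----------
    base : PairPotential
        Bare interaction plus reaction field.
    r_c : float
        Short-range cutoff (real-space sum), 0 < r_c < R_c.
    R_c : float
        Pseudo-potential cutoff (mesh sum); must satisfy R_c <= min(L)/2
        downstream.
    coulomb_prefactor : float
        Unit-system constant multiplying every pair energy (1 in reduced
        units; e.g. 1/(4 pi eps0) in SI-derived systems).

    All ``u_*`` methods are vectorized over r and return energies per unit
    charge product, prefactor included.  At r exactly equal to a cutoff the
    zero branch is taken (measure-zero convention; u_S is continuous there
    anyway).
    """

    def __init__(self, base: PairPotential, r_c: float, R_c: float,
                 coulomb_prefactor: float = 1.0):
        if not (0.0 < r_c < R_c):
            raise ValueError("cutoffs must satisfy 0 < r_c < R_c")
        self.base = base
        self.r_c = float(r_c)
        self.R_c = float(R_c)
        self.coulomb_prefactor = float(coulomb_prefactor)

    # -- raw pseudo potential ------------------------------------------------

    def u_lips(self, r, cutoff: float | None = None):
        """u_pseudo(r, cutoff); cutoff defaults to R_c. No branch applied."""
        return evaluate_lips(self.base, r, self.R_c if cutoff is None else cutoff,
                             self.coulomb_prefactor)

    def du_lips(self, r, cutoff: float | None = None):
        """d/dr of the pseudo potential (analytic when the plug-in allows)."""
        Rc = self.R_c if cutoff is None else cutoff
        r = np.asarray(r, dtype=float)
        if self.base.has_analytic_derivative:
            return self.coulomb_prefactor * (self.base.du(r) + self.base.dphi(r, Rc))
        h = 1e-6 * self.r_c
        # 5-point central difference fallback for derivative-free plug-ins
        num = (self.u_lips(r - 2 * h, Rc) - 8 * self.u_lips(r - h, Rc)
               + 8 * self.u_lips(r + h, Rc) - self.u_lips(r + 2 * h, Rc))
        return num / (12 * h)

    def boundary_constant(self) -> float:
        """u_pseudo(R_c, R_c): the constant value of u_B inside R_c."""
        return float(self.u_lips(self.R_c))

    # -- the split -----------------------------------------------------------

    def u_S(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        m = r < self.r_c
        if np.any(m):
            out[m] = self.u_lips(r[m], self.r_c) - self.u_lips(self.r_c, self.r_c)
        return out if out.ndim else float(out)

    def du_S(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        m = r < self.r_c
        if np.any(m):
            out[m] = self.du_lips(r[m], self.r_c)
        return out if out.ndim else float(out)

    def u_B(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        out[r < self.R_c] = self.boundary_constant()
        return out if out.ndim else float(out)

    def u_L(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        m = r < self.R_c
        if np.any(m):
            out[m] = self.u_lips(r[m]) - self.u_S(r[m]) - self.u_B(r[m])
        return out if out.ndim else float(out)

    def du_L(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        m = r < self.R_c
        if np.any(m):
            out[m] = self.du_lips(r[m]) - self.du_S(r[m])
        return out if out.ndim else float(out)

    def split_components(self, r):
        """(u_S, u_L, u_B) at r; components sum to u_pseudo(r, R_c) for r < R_c."""
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise ValueError("r must be positive")
        return self.u_S(r), self.u_L(r), self.u_B(r)

    def long_range_at_zero(self) -> float:
        """The finite limit of u_L as r -> 0 (the mesh self-term constant).

        The Coulomb singularities of u_pseudo(r, R_c) and u_S(r) cancel,
        leaving  phi(0,R_c) - phi(0,r_c) + u_pseudo(r_c,r_c) - u_pseudo(R_c,R_c).
        Evaluated analytically via ``phi_at_zero``; plug-ins without it fall
        back to Richardson extrapolation of u_L at r = 1e-3 r_c and 1e-4 r_c.
        """
        try:
            val = self.coulomb_prefactor * (
                self.base.phi_at_zero(self.R_c) - self.base.phi_at_zero(self.r_c)
            ) + float(self.u_lips(self.r_c, self.r_c)) - float(self.u_lips(self.R_c, self.R_c))
        except NotImplementedError:
            r1, r2 = 1e-3 * self.r_c, 1e-4 * self.r_c
            f1, f2 = float(self.u_L(r1)), float(self.u_L(r2))
            # u_L(r) = u_L(0) + O(r): Richardson step eliminates the linear term
            val = (10.0 * f2 - f1) / 9.0
        if not np.isfinite(val):
            raise ValueError(
                "long-range limit at r=0 is not finite; the plugged-in "
                "reaction field violates the PairPotential contract"
            )
        return float(val)

    def __repr__(self):
        return (f"SplitPotential({self.base.label}, r_c={self.r_c}, "
                f"R_c={self.R_c}, prefactor={self.coulomb_prefactor})")
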
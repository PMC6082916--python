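"""Deterministic synthetic systems and trajectories.

Every generator is a pure function of its arguments including the seed
(`numpy.random.default_rng`; no global state), so tests and examples run
bit-reproducibly with no external data.
"""

from __future__ import annotations

import numpy as np

from .metrics import Trajectory
from .realspace import ChargeSystem, minimum_image

__all__ = [
    "random_neutral_system",
    "slab_system",
    "dipole_pair",
    "brownian_trajectory",
]

_MAX_REJECT = 100_000


def random_neutral_system(N: int, box, seed: int) -> ChargeSystem:
    """N/2 unit positive and N/2 unit negative charges at uniform random
    positions with a minimum-separation rejection radius of 0.05 min(L).

    Raises RuntimeError when the packing is infeasible within the rejection
    budget.
    """
    if N % 2 != 0:
        raise ValueError("N must be even for a neutral +1/-1 system")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    rmin = 0.05 * float(np.min(box))
    pos = np.empty((N, 3))
    placed = 0
    rejections = 0
    while placed < N:
        cand = rng.uniform(0.0, 1.0, 3) * box
        if placed:
            d = minimum_image(cand[None, :], pos[:placed], box)
            if np.min(np.linalg.norm(d, axis=1)) < rmin:
                rejections += 1
                if rejections > _MAX_REJECT:
                    raise RuntimeError(
                        f"could not place {N} particles with separation "
                        f">= {rmin:g} after {_MAX_REJECT} rejections")
                continue
        pos[placed] = cand
        placed += 1
    charges = np.array([1.0, -1.0] * (N // 2))
    return ChargeSystem(pos, charges, box)


def slab_system(N: int, box, slab_fraction: float = 0.5,
                seed: int = 0) -> ChargeSystem:
    """Neutral +1/-1 dipolar pairs confined to a central slab along z.

    Emulates a liquid film in vacuum: all particles lie within the central
    ``slab_fraction`` of L_z, the rest of the box is empty.
    """
    if N % 2 != 0:
        raise ValueError("N must be even (dipolar pairs)")
    if not 0 < slab_fraction <= 1:
        raise ValueError("slab_fraction must be in (0, 1]")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    Lz = box[2]
    z_lo = 0.5 * Lz * (1 - slab_fraction)
    z_hi = 0.5 * Lz * (1 + slab_fraction)
    npair = N // 2
    pos = np.empty((N, 3))
    # each pair: a + charge with a - partner displaced by a short random bond
    bond = 0.04 * float(np.min(box))
    plus = rng.uniform(0.0, 1.0, (npair, 3)) * box
    plus[:, 2] = rng.uniform(z_lo + bond, z_hi - bond, npair)
    direction = rng.normal(size=(npair, 3))
    direction /= np.linalg.norm(direction, axis=1)[:, None]
    minus = plus + bond * direction
    minus[:, 2] = np.clip(minus[:, 2], z_lo, z_hi)
    pos[0::2], pos[1::2] = plus, minus
    charges = np.array([1.0, -1.0] * npair)
    return ChargeSystem(pos, charges, box)


def dipole_pair(separation: float, offset=None, box=(4.0, 4.0, 4.0)) -> ChargeSystem:
    """One +1/-1 pair at a controlled separation along x.

    The canonical two-body input for closed-form checks.  ``offset`` places
    the + charge (box center by default); the - charge sits at
    offset + (separation, 0, 0).
    """
    box = np.asarray(box, dtype=float)
    if offset is None:
        offset = box / 2
    offset = np.asarray(offset, dtype=float)
    pos = np.array([offset, offset + [separation, 0.0, 0.0]])
    return ChargeSystem(pos, np.array([1.0, -1.0]), box)


def brownian_trajectory(n_walkers: int, n_steps: int, D0: float, dt: float,
                        box, seed: int) -> tuple[Trajectory, np.ndarray]:
    """Ideal Brownian walkers: Gaussian steps of variance 2 D0 dt per axis.

    Ground truth for Einstein-relation recovery.  Returns ``(traj, unwrapped)``
    where traj holds box-wrapped frames (charges zero) and unwrapped is the
    (n_steps+1, n_walkers, 3) true path.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, 1.0, (n_walkers, 3)) * box
    steps = rng.normal(0.0, np.sqrt(2.0 * D0 * dt),
                       (n_steps, n_walkers, 3))
    unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    charges = np.zeros(n_walkers)
    frames = [ChargeSystem(unwrapped[t] % box, charges, box)
              for t in range(n_steps + 1)]
    return Trajectory(frames, timestep=dt), unwrapped
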
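"""Periodic point-charge frames and the real-space energy/force sums.

Covers the two parts of the split that stay in real space: the short-range
energy

    U_S = 1/2 sum_i q_i sum_{r_ij < r_c, j != i} q_j u_S(r_ij)

evaluated with a cell list, and the boundary energy

    U_B = 1/2 u_pseudo(R_c, R_c) sum_i q_i sum_{r_ij < R_c, j != i} q_j

which is force-free because u_B is constant inside R_c.  Self-interaction
(j = i) is excluded here; it enters only through the mesh path, where it is
corrected analytically.

Boxes are orthorhombic.  Frames are read and written in an extended-XYZ
dialect with a charge column:

    line 1: N
    line 2: Lattice="Lx 0 0 0 Ly 0 0 0 Lz" Properties=species:S:1:pos:R:3:charge:R:1
    data:   symbol x y z q

Non-diagonal lattices are rejected.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np

from .potentials import SplitPotential

__all__ = [
    "ChargeSystem",
    "ForceEnergyResult",
    "minimum_image",
    "short_range_sum",
    "boundary_sum",
    "read_xyz",
    "write_xyz",
]


@dataclass
class ChargeSystem:
    """One periodic frame: positions (nm), charges (e), orthorhombic box.

    Positions are wrapped into [0, L) on construction.  Velocities and
    masses are optional (masses default to 1, reduced units).
    """

    positions: np.ndarray
    charges: np.ndarray
    box: np.ndarray
    velocities: np.ndarray | None = None
    masses: np.ndarray | None = None
    species: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        self.box = np.asarray(self.box, dtype=float)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        if self.charges.shape != (n,):
            raise ValueError("charges must be length N")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if n < 1:
            raise ValueError("need at least one particle")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite position")
        self.positions = np.mod(self.positions, self.box)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != (n, 3):
                raise ValueError("velocities must be (N, 3)")
        if self.masses is None:
            self.masses = np.ones(n)
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (n,):
                raise ValueError("masses must be length N")
        if not self.species:
            self.species = ["X"] * n

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.positions.tobytes())
        h.update(self.charges.tobytes())
        h.update(self.box.tobytes())
        return h.hexdigest()[:16]

    def copy(self) -> "ChargeSystem":
        return ChargeSystem(
            self.positions.copy(), self.charges.copy(), self.box.copy(),
            None if self.velocities is None else self.velocities.copy(),
            self.masses.copy(), list(self.species),
        )


@dataclass
class ForceEnergyResult:
    """Per-component energies and per-particle forces of one evaluation."""

    U_S: float
    U_L: float
    U_B: float
    U_total: float
    forces: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "U_S": self.U_S, "U_L": self.U_L, "U_B": self.U_B,
            "U_total": self.U_total,
            "forces": self.forces.tolist(),
            **({"metadata": self.metadata} if self.metadata else {}),
        }


def minimum_image(ri, rj, box):
    """Displacement ri - rj with each component reduced into (-L/2, L/2]."""
    box = np.asarray(box, dtype=float)
    d = np.asarray(ri, dtype=float) - np.asarray(rj, dtype=float)
    return d - box * np.round(d / box)


def _check_cutoff(cutoff: float, box: np.ndarray, name: str) -> None:
    if cutoff > np.min(box) / 2 + 1e-12:
        raise ValueError(f"{name} = {cutoff} exceeds half the shortest box "
                         f"length ({np.min(box) / 2}); minimum image invalid")


def _cell_pairs(pos: np.ndarray, box: np.ndarray, cutoff: float):
    """Candidate i<j pairs from a cell list with cell edge >= cutoff.

    Falls back to all pairs when the box fits fewer than 3 cells per axis
    (the cell list would then enumerate every pair anyway).
    """
    n = pos.shape[0]
    ncell = np.maximum(1, np.floor(box / cutoff).astype(int))
    if np.any(ncell < 3) or n < 64:
        iu, ju = np.triu_indices(n, k=1)
        return iu, ju
    cell_of = np.minimum((pos / (box / ncell)).astype(int), ncell - 1)
    flat = (cell_of[:, 0] * ncell[1] + cell_of[:, 1]) * ncell[2] + cell_of[:, 2]
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    starts = np.searchsorted(sorted_flat, np.arange(ncell.prod()))
    ends = np.searchsorted(sorted_flat, np.arange(ncell.prod()), side="right")

    members = [order[starts[c]:ends[c]] for c in range(ncell.prod())]
    offsets = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                   indexing="ij")).reshape(3, -1).T
    ii, jj = [], []
    for cx in range(ncell[0]):
        for cy in range(ncell[1]):
            for cz in range(ncell[2]):
                c = (cx * ncell[1] + cy) * ncell[2] + cz
                a = members[c]
                if a.size == 0:
                    continue
                # pairs within the cell
                iu, ju = np.triu_indices(a.size, k=1)
                ii.append(a[iu]); jj.append(a[ju])
                # pairs with half the neighbor cells (avoid double count)
                for off in offsets:
                    nc = (cx + off[0], cy + off[1], cz + off[2])
                    ncf = ((nc[0] % ncell[0]) * ncell[1] + nc[1] % ncell[1]) \
                        * ncell[2] + nc[2] % ncell[2]
                    if ncf <= c:
                        continue
                    b = members[ncf]
                    if b.size == 0:
                        continue
                    ii.append(np.repeat(a, b.size))
                    jj.append(np.tile(b, a.size))
    if not ii:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(ii), np.concatenate(jj)


def short_range_sum(sys: ChargeSystem, sp: SplitPotential):
    """Real-space short-range energy and its exact negative gradient.

    Returns ``(U_S, forces)`` with forces shaped (N, 3).
    """
    _check_cutoff(sp.r_c, sys.box, "r_c")
    pos, q, box = sys.positions, sys.charges, sys.box
    n = sys.n
    forces = np.zeros((n, 3))
    if n == 1:
        return 0.0, forces
    ii, jj = _cell_pairs(pos, box, sp.r_c)
    d = minimum_image(pos[ii], pos[jj], box)
    r = np.linalg.norm(d, axis=1)
    m = r < sp.r_c
    ii, jj, d, r = ii[m], jj[m], d[m], r[m]
    if r.size == 0:
        return 0.0, forces
    qq = q[ii] * q[jj]
    U = float(np.sum(qq * sp.u_S(r)))
    # f_i = -qq * u_S'(r) * (d/r); d = r_i - r_j
    fmag = -qq * sp.du_S(r) / r
    fvec = fmag[:, None] * d
    np.add.at(forces, ii, fvec)
    np.add.at(forces, jj, -fvec)
    return U, forces


def boundary_sum(sys: ChargeSystem, sp: SplitPotential) -> float:
    """Boundary energy: constant u_pseudo(R_c,R_c) times the in-range pair
    charge sum.  Contributes no force.  Direct double loop (at R_c ~ L/2
    nearly every pair is inside the cutoff, so a cell list gains nothing).
    """
    _check_cutoff(sp.R_c, sys.box, "R_c")
    n = sys.n
    if n == 1:
        return 0.0
    pos, q = sys.positions, sys.charges
    iu, ju = np.triu_indices(n, k=1)
    d = minimum_image(pos[iu], pos[ju], sys.box)
    r = np.linalg.norm(d, axis=1)
    m = r < sp.R_c
    return float(sp.boundary_constant() * np.sum(q[iu[m]] * q[ju[m]]))


# -- extended-XYZ I/O --------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def write_xyz(path, sys: ChargeSystem, comment_extra: str = "") -> None:
    """Write one frame in the charge-column extended-XYZ dialect."""
    with open(path, "w") as fh:
        _write_frame(fh, sys, comment_extra)


def _write_frame(fh, sys: ChargeSystem, comment_extra: str = "") -> None:
    L = sys.box
    fh.write(f"{sys.n}\n")
    fh.write(
        f'Lattice="{L[0]:.12g} 0 0 0 {L[1]:.12g} 0 0 0 {L[2]:.12g}" '
        'Properties=species:S:1:pos:R:3:charge:R:1'
        + (f" {comment_extra}" if comment_extra else "") + "\n"
    )
    for s, p, q in zip(sys.species, sys.positions, sys.charges):
        fh.write(f"{s} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g} {q:.12g}\n")


def write_trajectory_xyz(path, frames) -> None:
    """Write a sequence of frames to one multi-frame extended-XYZ file."""
    with open(path, "w") as fh:
        for fr in frames:
            _write_frame(fh, fr)


def read_xyz(path) -> list[ChargeSystem]:
    """Read all frames from an extended-XYZ file with a charge column.

    Rejects non-diagonal lattices.  Returns a list of frames (a single-frame
    file yields a one-element list).
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        header = lines[i + 1]
        m = _LATTICE_RE.search(header)
        if not m:
            raise ValueError("missing Lattice specification in XYZ header")
        lat = np.array([float(x) for x in m.group(1).split()]).reshape(3, 3)
        if not np.allclose(lat, np.diag(np.diag(lat))):
            raise ValueError("non-diagonal lattice not supported "
                             "(orthorhombic boxes only)")
        box = np.diag(lat)
        species, pos, q = [], [], []
        for line in lines[i + 2: i + 2 + n]:
            parts = line.split()
            species.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
            q.append(float(parts[4]))
        frames.append(ChargeSystem(np.array(pos), np.array(q), box,
                                   species=species))
        i += 2 + n
    if not frames:
        raise ValueError("no frames in file")
    return frames
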
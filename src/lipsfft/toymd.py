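"""Minimal leapfrog molecular dynamics over the split-potential forces.

A Verlet leapfrog integrator drives toy ionic systems with electrostatics
from the FFT mesh path plus a soft-sphere r^-12 repulsion for short-range
stability (energy-shifted at its cutoff).  Enough machinery for energy
conservation and equilibration checks; no constraints, barostats or
production-quality thermostatting — the optional thermostat is plain
velocity rescaling.

Units are reduced: the per-particle kinetic temperature is defined by
<m v^2> = 3 k_B T with k_B = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import MeshConfig, total_energy_forces
from .metrics import Trajectory
from .potentials import SplitPotential
from .realspace import ChargeSystem, minimum_image

__all__ = ["MDState", "SoftSphere", "leapfrog_step", "run"]


@dataclass
class SoftSphere:
    """Purely repulsive eps (sigma/r)^12 pair term, shifted to zero at r_cut."""

    epsilon: float = 1.0
    sigma: float = 0.2
    r_cut: float = 0.6

    def energy_forces(self, sys: ChargeSystem):
        n = sys.n
        forces = np.zeros((n, 3))
        if n < 2:
            return 0.0, forces
        iu, ju = np.triu_indices(n, k=1)
        d = minimum_image(sys.positions[iu], sys.positions[ju], sys.box)
        r = np.linalg.norm(d, axis=1)
        m = r < self.r_cut
        iu, ju, d, r = iu[m], ju[m], d[m], r[m]
        if r.size == 0:
            return 0.0, forces
        sr12 = (self.sigma / r) ** 12
        shift = (self.sigma / self.r_cut) ** 12
        U = float(self.epsilon * np.sum(sr12 - shift))
        fmag = 12.0 * self.epsilon * sr12 / (r * r)  # -dU/dr / r
        fvec = fmag[:, None] * d
        np.add.at(forces, iu, fvec)
        np.add.at(forces, ju, -fvec)
        return U, forces


@dataclass
class MDState:
    """Positions, half-step velocities, and bookkeeping of one MD system."""

    system: ChargeSystem
    velocities: np.ndarray          # v(t - dt/2), leapfrog convention
    time: float = 0.0

    def kinetic_energy(self) -> float:
        m = self.system.masses
        return 0.5 * float(np.sum(m[:, None] * self.velocities ** 2))

    def temperature(self) -> float:
        return 2.0 * self.kinetic_energy() / (3.0 * self.system.n)


def leapfrog_step(state: MDState, forces: np.ndarray, dt: float) -> MDState:
    """One Verlet leapfrog update: v(t+dt/2) = v(t-dt/2) + a dt, then
    r(t+dt) = r(t) + v(t+dt/2) dt, positions wrapped into the box."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite force: integration aborted")
    sys = state.system
    a = forces / sys.masses[:, None]
    v_new = state.velocities + a * dt
    new_sys = sys.copy()
    new_sys.positions = np.mod(sys.positions + v_new * dt, sys.box)
    new_sys.velocities = v_new
    return MDState(new_sys, v_new, state.time + dt)


def _total(sys, sp, mesh, repulsion, self_term_correction=True,
           remove_net_force=False):
    res = total_energy_forces(sys, sp, mesh,
                              self_term_correction=self_term_correction)
    U_rep, f_rep = repulsion.energy_forces(sys)
    forces = res.forces + f_rep
    if remove_net_force:
        # the grid breaks exact translation invariance, leaving a small net
        # mesh force; removing the mean (standard COM-motion removal)
        # restores exact momentum conservation in the integrator
        forces = forces - forces.mean(axis=0)
    return res.U_total + U_rep, forces, res


def run(sys: ChargeSystem, sp: SplitPotential, mesh: MeshConfig,
        n_steps: int, dt: float, thermostat=None,
        repulsion: SoftSphere | None = None,
        velocities: np.ndarray | None = None, seed: int = 0,
        sample_every: int = 10, target_T: float | None = None,
        remove_net_force: bool = True):
    """Integrate a toy ionic melt; NVE unless a thermostat is requested.

    Parameters
    ----------
    thermostat : None or ("rescale", T, interval)
        Velocity rescaling to temperature T every ``interval`` steps.
    velocities : initial half-step velocities; Maxwell-distributed at
        ``target_T`` (default 1.0) when omitted, with zero net momentum.
    sample_every : stride at which frames and energies are recorded.

    Returns ``(trajectory, log)`` where log is a dict of per-sample arrays
    (time, potential, kinetic, total, temperature).
    """
    rng = np.random.default_rng(seed)
    sys = sys.copy()
    n = sys.n
    if velocities is None:
        T0 = 1.0 if target_T is None else target_T
        velocities = rng.normal(0.0, 1.0, (n, 3)) * np.sqrt(
            T0 / sys.masses)[:, None]
        velocities -= np.mean(sys.masses[:, None] * velocities,
                              axis=0) / np.mean(sys.masses)
    if repulsion is None:
        repulsion = SoftSphere()
    state = MDState(sys, np.asarray(velocities, dtype=float))
    frames, log = [], {"time": [], "potential": [], "kinetic": [],
                       "total": [], "temperature": []}
    for step in range(n_steps):
        U, forces, _ = _total(state.system, sp, mesh, repulsion,
                              remove_net_force=remove_net_force)
        if step % sample_every == 0:
            # on-step kinetic energy from the average of half-step velocities
            a = forces / state.system.masses[:, None]
            v_on = state.velocities + 0.5 * a * dt
            KE = 0.5 * float(np.sum(state.system.masses[:, None] * v_on ** 2))
            fr = state.system.copy()
            fr.velocities = v_on
            frames.append(fr)
            log["time"].append(state.time)
            log["potential"].append(U)
            log["kinetic"].append(KE)
            log["total"].append(U + KE)
            log["temperature"].append(2 * KE / (3 * n))
        state = leapfrog_step(state, forces, dt)
        if thermostat is not None:
            kind, T_target, interval = thermostat
            if kind != "rescale":
                raise ValueError(f"unknown thermostat {kind!r}")
            if (step + 1) % interval == 0:
                T_now = state.temperature()
                if T_now > 0:
                    state.velocities *= np.sqrt(T_target / T_now)
                    state.system.velocities = state.velocities
    log = {k: np.asarray(v) for k, v in log.items()}
    return Trajectory(frames, timestep=dt * sample_every), log
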
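"""Minimal CG simulation core: toy force field, steepest-descent
minimization, BAOAB Langevin dynamics, ramp schedules and auxiliary
restraints.

Units: nm / ps / u / kJ·mol⁻¹ throughout; k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹.
A force provider is any object with ``evaluate(coords, step) ->
(energy, forces)`` where forces are −∇energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cgnmr.errors import SimulationError
from cgnmr.io_formats import Trajectory

KB = 0.0083144621          # kJ mol^-1 K^-1
DEFAULT_MASS = 72.0        # u, the common CG bead mass


@dataclass
class SimState:
    """Coordinates, velocities, masses and integrator bookkeeping."""

    coords: np.ndarray                 # (n, 3) nm
    velocities: np.ndarray = None      # (n, 3) nm/ps
    masses: np.ndarray = None          # (n,) u
    step: int = 0
    temperature: float = 300.0         # K
    rng: np.random.Generator = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float).copy()
        n = len(self.coords)
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        self.velocities = np.asarray(self.velocities, float).copy()
        if self.masses is None:
            self.masses = np.full(n, DEFAULT_MASS)
        self.masses = np.asarray(self.masses, float)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be > 0")
        if self.rng is None:
            self.rng = np.random.default_rng(0)

    @classmethod
    def from_structure(cls, structure, temperature=300.0, seed=0,
                       thermalize=False):
        state = cls(coords=structure.coords, temperature=temperature,
                    rng=np.random.default_rng(seed))
        if thermalize:
            sigma = np.sqrt(KB * temperature / state.masses)[:, None]
            state.velocities = sigma * state.rng.standard_normal(
                state.coords.shape)
        return state

    def kinetic_temperature(self) -> float:
        ke = 0.5 * np.sum(self.masses[:, None] * self.velocities ** 2)
        dof = 3 * len(self.coords)
        return float(2.0 * ke / (dof * KB))


def total_energy_forces(providers, coords, step=0):
    energy = 0.0
    forces = np.zeros_like(coords)
    for p in providers:
        e, f = p.evaluate(coords, step)
        energy += e
        forces += f
    return energy, forces


# ---------------------------------------------------------------------------
# Toy force field
# ---------------------------------------------------------------------------

@dataclass
class ToyForceFieldParams:
    bb_bond_length: float = 0.35       # nm
    bb_bond_k: float = 5000.0          # kJ/mol/nm^2
    bb_angle_deg: float = 127.0
    bb_angle_k: float = 25.0           # kJ/mol/rad^2
    sc_bond_k: float = 5000.0
    ev_sigma: float = 0.4              # nm, excluded-volume onset
    ev_k: float = 100.0                # kJ/mol/nm^2, repulsion stiffness


class ToyForceField:
    """Desk-scale bonded + repulsive bead force field over a CGStructure.

    Harmonic BB–BB bonds along each chain, harmonic BB–BB–BB angles,
    BB–SC1 bonds at their input-geometry lengths, and a purely repulsive
    harmonic excluded volume ½k(σ−r)² for r < σ between nonbonded pairs.
    """

    def __init__(self, structure, params=None):
        from cgnmr.geometry import angle_batch, angle_gradient_batch, \
            neighbor_position
        self._angle_batch = angle_batch
        self._angle_gradient_batch = angle_gradient_batch
        self.params = params or ToyForceFieldParams()
        p = self.params

        bonds = []          # (i, j, b0, k)
        for pos in range(structure.n_residues):
            nxt = neighbor_position(structure, pos, 1)
            bi = structure.bead_index(pos, "BB")
            if nxt is not None:
                bonds.append((bi, structure.bead_index(nxt, "BB"),
                              p.bb_bond_length, p.bb_bond_k))
            sc = structure.bead_index(pos, "SC1")
            if sc is not None:
                b0 = float(np.linalg.norm(
                    structure.coords[bi] - structure.coords[sc]))
                bonds.append((bi, sc, b0, p.sc_bond_k))
        self.bonds = bonds

        angles = []         # (i, j, k) BB triples
        for pos in range(structure.n_residues):
            prv = neighbor_position(structure, pos, -1)
            nxt = neighbor_position(structure, pos, 1)
            if prv is not None and nxt is not None:
                angles.append((structure.bead_index(prv, "BB"),
                               structure.bead_index(pos, "BB"),
                               structure.bead_index(nxt, "BB")))
        self.angles = np.array(angles, dtype=int).reshape(len(angles), 3)
        self.theta0 = np.deg2rad(p.bb_angle_deg)

        bonded = {(min(i, j), max(i, j)) for i, j, _, _ in bonds}
        for a in angles:
            bonded.add((min(a[0], a[2]), max(a[0], a[2])))
        n = structure.n_beads
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if (i, j) not in bonded]
        self.ev_pairs = np.array(pairs, dtype=int).reshape(len(pairs), 2)

        self.bond_idx = np.array([(b[0], b[1]) for b in bonds], dtype=int)
        self.bond_b0 = np.array([b[2] for b in bonds])
        self.bond_k = np.array([b[3] for b in bonds])

    def evaluate(self, coords, step=None):
        coords = np.asarray(coords, float)
        energy = 0.0
        forces = np.zeros_like(coords)
        p = self.params

        if len(self.bond_idx):
            d = coords[self.bond_idx[:, 1]] - coords[self.bond_idx[:, 0]]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.bond_b0
            energy += float(np.sum(0.5 * self.bond_k * dr ** 2))
            f = (self.bond_k * dr / r)[:, None] * d       # on bead i → +f
            np.add.at(forces, self.bond_idx[:, 0], f)
            np.add.at(forces, self.bond_idx[:, 1], -f)

        if len(self.angles):
            p1 = coords[self.angles[:, 0]]
            p2 = coords[self.angles[:, 1]]
            p3 = coords[self.angles[:, 2]]
            theta = self._angle_batch(p1, p2, p3)
            dth = theta - self.theta0
            energy += float(np.sum(0.5 * p.bb_angle_k * dth ** 2))
            g1, g2, g3 = self._angle_gradient_batch(p1, p2, p3)
            w = (p.bb_angle_k * dth)[:, None]
            np.add.at(forces, self.angles[:, 0], -w * g1)
            np.add.at(forces, self.angles[:, 1], -w * g2)
            np.add.at(forces, self.angles[:, 2], -w * g3)

        if len(self.ev_pairs):
            d = coords[self.ev_pairs[:, 1]] - coords[self.ev_pairs[:, 0]]
            r = np.linalg.norm(d, axis=1)
            overlap = np.maximum(p.ev_sigma - r, 0.0)
            active = overlap > 0
            if np.any(active):
                energy += float(np.sum(0.5 * p.ev_k * overlap[active] ** 2))
                f = (p.ev_k * overlap[active] / r[active])[:, None] * d[active]
                np.add.at(forces, self.ev_pairs[active, 0], -f)
                np.add.at(forces, self.ev_pairs[active, 1], f)

        return energy, forces


def toy_forcefield(structure, params=None) -> ToyForceField:
    return ToyForceField(structure, params)


# ---------------------------------------------------------------------------
# Auxiliary restraints
# ---------------------------------------------------------------------------

class ZFlatBottomRestraint:
    """Upper-bound restraint on one bead's z coordinate."""

    def __init__(self, bead, z_max, k):
        if k < 0:
            raise ValueError("k must be >= 0")
        self.bead = int(bead)
        self.z_max = float(z_max)
        self.k = float(k)

    def evaluate(self, coords, step=None):
        coords = np.asarray(coords, float)
        forces = np.zeros_like(coords)
        z = coords[self.bead, 2]
        if z <= self.z_max:
            return 0.0, forces
        dz = z - self.z_max
        forces[self.bead, 2] = -self.k * dz
        return 0.5 * self.k * dz ** 2, forces


def z_flat_bottom_restraint(bead, z_max, k) -> ZFlatBottomRestraint:
    return ZFlatBottomRestraint(bead, z_max, k)


class PositionalRestraint:
    """Harmonic tether of selected beads to reference positions."""

    def __init__(self, reference, k=1000.0, selection=None):
        self.reference = np.asarray(reference, float).copy()
        self.k = float(k)
        self.selection = (np.arange(len(self.reference))
                          if selection is None else np.asarray(selection, int))

    def evaluate(self, coords, step=None):
        coords = np.asarray(coords, float)
        forces = np.zeros_like(coords)
        d = coords[self.selection] - self.reference[self.selection]
        forces[self.selection] = -self.k * d
        return float(0.5 * self.k * np.sum(d ** 2)), forces


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

class RampSchedule:
    """Drives ``target.attr = min(step·rate, maximum)`` each step."""

    def __init__(self, target, attr, rate, maximum):
        if rate <= 0:
            raise ValueError("rate must be > 0")
        self.target = target
        self.attr = attr
        self.rate = rate
        self.maximum = maximum

    def apply(self, step):
        value = min(step * self.rate, self.maximum)
        setattr(self.target, self.attr, value)
        return value


# ---------------------------------------------------------------------------
# Minimization and dynamics
# ---------------------------------------------------------------------------

def minimize(state: SimState, providers, max_steps=1000, tol=10.0,
             initial_step=0.01):
    """Steepest descent with adaptive step; energy is monotone non-increasing.

    Stops when the maximum force component drops below ``tol``
    (kJ·mol⁻¹·nm⁻¹) or after ``max_steps``.
    """
    energy, forces = total_energy_forces(providers, state.coords, state.step)
    if not np.isfinite(energy):
        raise SimulationError("non-finite starting energy", step=state.step)
    h = initial_step
    for _ in range(max_steps):
        fmax = np.max(np.abs(forces))
        if fmax < tol:
            break
        trial = state.coords + h * forces / fmax
        e_trial, f_trial = total_energy_forces(providers, trial, state.step)
        if not np.isfinite(e_trial):
            raise SimulationError("non-finite energy in minimization",
                                  step=state.step)
        if e_trial < energy:
            state.coords = trial
            energy, forces = e_trial, f_trial
            h *= 1.2
        else:
            h *= 0.2
            if h < 1e-10:
                break
    return state


def langevin_step(state: SimState, providers, dt=0.01, gamma=0.01,
                  forces=None):
    """One BAOAB Langevin step; deterministic given the state's RNG.

    Returns the forces at the new coordinates so callers can reuse them.
    """
    m = state.masses[:, None]
    if forces is None:
        _, forces = total_energy_forces(providers, state.coords, state.step)
    # B: half kick
    state.velocities += 0.5 * dt * forces / m
    # A: half drift
    state.coords += 0.5 * dt * state.velocities
    # O: Ornstein-Uhlenbeck
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 ** 2) * KB * state.temperature / state.masses)
    state.velocities = (c1 * state.velocities
                        + c2[:, None] * state.rng.standard_normal(
                            state.velocities.shape))
    # A: half drift
    state.coords += 0.5 * dt * state.velocities
    # B: half kick with new forces
    state.step += 1
    energy, forces = total_energy_forces(providers, state.coords, state.step)
    if not np.all(np.isfinite(forces)):
        raise SimulationError("non-finite forces", step=state.step)
    state.velocities += 0.5 * dt * forces / m
    return state, energy, forces


def run(state: SimState, providers, schedules=(), n_steps=0, report_every=100,
        dt=0.01, gamma=0.01, frame_spacing=None):
    """Integrate with per-step ramp schedules, recording frames and energies.

    Returns (Trajectory, report) where the report maps provider index →
    recorded energy series, plus ``"k"`` traces for each schedule and
    ``"total"``.
    """
    frames = [state.coords.copy()]
    for s in schedules:
        s.apply(state.step)
    energies = {i: [] for i in range(len(providers))}
    k_traces = [[] for _ in schedules]
    totals = []

    def record():
        e_sum = 0.0
        for i, p in enumerate(providers):
            e, _ = p.evaluate(state.coords, state.step)
            energies[i].append(e)
            e_sum += e
        totals.append(e_sum)
        for trace, s in zip(k_traces, schedules):
            trace.append(getattr(s.target, s.attr))

    record()
    forces = None
    for _ in range(n_steps):
        try:
            state, energy, forces = langevin_step(
                state, providers, dt=dt, gamma=gamma, forces=forces)
        except SimulationError:
            raise
        except Exception as exc:
            raise SimulationError(f"provider failure: {exc}",
                                  step=state.step) from exc
        # K(step) applies to the step that starts here and is what the
        # trace reports: min(step·rate, maximum) at every recorded step
        changed = False
        for s in schedules:
            s.apply(state.step)
            changed = True
        if changed:
            forces = None               # K changed; stale forces invalid
        if state.step % report_every == 0:
            frames.append(state.coords.copy())
            record()

    spacing = frame_spacing or report_every * dt
    traj = Trajectory(frames=np.array(frames), frame_spacing=spacing)
    report = {
        "energies": {i: np.array(v) for i, v in energies.items()},
        "total": np.array(totals),
        "k_traces": [np.array(t) for t in k_traces],
        "frame_steps": np.arange(len(frames)) * report_every,
    }
    return traj, report
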
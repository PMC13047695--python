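"""Atomistic→CG NOE mapping and the piecewise distance-restraint potential.

The pipeline maps each atomistic NOE record onto bead pairs (offsetting the
reported distance by the bead geometry), condenses multi-atom contributions
with r⁻⁶ weighting, averages signals landing on the same bead pair, and
evaluates a piecewise restraint (harmonic below r0, flat on [r0, r1),
harmonic on [r1, r2), linear beyond r2). Restraints may act on an
exponentially time-averaged distance instead of the instantaneous one, with
the running average kept in r⁻³ space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cgnmr.errors import DegenerateGeometryError
from cgnmr.io_formats import NOETable

_TINY = 1e-12


# ---------------------------------------------------------------------------
# Distance algebra
# ---------------------------------------------------------------------------

def map_atom_pair(bead_i_pos, bead_j_pos, atom_i_pos, atom_j_pos, d_ij):
    """CG distance for one atom pair: |A_i→a_i + d·û(a_i→a_j) + a_j→A_j|."""
    Ai, Aj = np.asarray(bead_i_pos, float), np.asarray(bead_j_pos, float)
    ai, aj = np.asarray(atom_i_pos, float), np.asarray(atom_j_pos, float)
    if d_ij <= 0:
        raise ValueError("d_ij must be > 0")
    sep = aj - ai
    norm = np.linalg.norm(sep)
    if norm < _TINY:
        raise DegenerateGeometryError("NOE atoms coincide")
    vec = (ai - Ai) + d_ij * sep / norm + (Aj - aj)
    return float(np.linalg.norm(vec))


def apparent_distance(distances):
    """r⁻⁶-apparent distance (Σ d⁻⁶)^(−1/6) of a set of distances."""
    d = np.asarray(distances, float)
    if d.size == 0:
        raise ValueError("empty distance set")
    if np.any(d <= 0):
        raise ValueError("distances must be > 0")
    return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


def condense_group(mapped_distances, atomistic_distances):
    """r⁻⁶-weighted mean of mapped CG distances within one NOE record."""
    D = np.asarray(mapped_distances, float)
    r = np.asarray(atomistic_distances, float)
    if D.size == 0:
        raise ValueError("no contributing atom pairs")
    if np.any(r <= 0):
        raise DegenerateGeometryError("zero atomistic distance in condensation")
    w = r ** -6.0
    return float(np.sum(D * w) / np.sum(w))


def aggregate_bead_pair(condensed_distances):
    """Arithmetic mean of condensed distances landing on one bead pair."""
    D = np.asarray(condensed_distances, float)
    if D.size == 0:
        raise ValueError("no signals for bead pair")
    return float(np.mean(D))


# ---------------------------------------------------------------------------
# Record filtering and restraint construction
# ---------------------------------------------------------------------------

def filter_conflicts(table: NOETable, reference, slack=0.2):
    """Drop contributors whose reference distance exceeds d + slack.

    Applies only within records where multiple residue pairs contribute.
    Returns (filtered NOETable, report dict with dropped counts).
    """
    from cgnmr.io_formats import NOERecord

    out = NOETable()
    report = {"dropped_contributors": 0, "dropped_records": 0}
    for rec in table:
        pairs = [(ai, aj) for ai in rec.group_i for aj in rec.group_j]
        residue_pairs = {((ai[0], ai[1]), (aj[0], aj[1])) for ai, aj in pairs}
        if len(residue_pairs) <= 1:
            out.records.append(rec)
            continue
        kept = []
        for ai, aj in pairs:
            pi = reference.coords[reference.atom_index(*ai)]
            pj = reference.coords[reference.atom_index(*aj)]
            if np.linalg.norm(pi - pj) <= rec.d + slack:
                kept.append((ai, aj))
            else:
                report["dropped_contributors"] += 1
        if not kept:
            report["dropped_records"] += 1
            continue
        gi = list(dict.fromkeys(ai for ai, _ in kept))
        gj = list(dict.fromkeys(aj for _, aj in kept))
        out.records.append(NOERecord(gi, gj, rec.d, rec.r0, rec.r1, rec.r2))
    return out, report


@dataclass
class CGRestraint:
    """A bead-pair distance restraint with bounds and running-average state."""

    bead_i: int
    bead_j: int
    r0: float                           # nm
    r1: float
    r2: float
    k: float = 250.0                    # kJ·mol⁻¹·nm⁻²
    tau: float = 0.05                   # ps, averaging memory
    ramp_tau: float = 0.05              # ps, force-constant ramp
    rbar: float = None                  # running average, set at t=0

    def __post_init__(self):
        if not (0 <= self.r0 <= self.r1 <= self.r2):
            raise ValueError(f"bounds must satisfy 0<=r0<=r1<=r2, got "
                             f"{(self.r0, self.r1, self.r2)}")


def build_cg_restraints(atomistic, mapping, cg, noe: NOETable, k_noe=250.0,
                        reference=None, slack=None, **kwargs):
    """Full mapping pipeline: map → condense → aggregate → one restraint
    per bead pair.

    Bounds are shifted by the bead-geometry offset (D′ − d̄) so the
    flat-bottom width is preserved; when several records with different
    bounds land on one bead pair their shifted bounds are averaged.
    With ``slack`` set, conflict filtering against ``reference`` (defaults
    to ``atomistic``) runs first.
    """
    if slack is not None:
        noe, _ = filter_conflicts(noe, reference or atomistic, slack)

    per_pair = {}
    for rec in noe:
        # group every contributing atom pair by the bead pair it maps to
        by_beads = {}
        for ai in rec.group_i:
            for aj in rec.group_j:
                chain_i, resid_i, name_i = ai
                chain_j, resid_j, name_j = aj
                ka = atomistic.atom_index(chain_i, resid_i, name_i)
                kb = atomistic.atom_index(chain_j, resid_j, name_j)
                rtype_i = atomistic.residue_types[ka]
                rtype_j = atomistic.residue_types[kb]
                bead_name_i = mapping.bead_for(rtype_i, name_i)
                bead_name_j = mapping.bead_for(rtype_j, name_j)
                try:
                    pos_i = cg.residue_position(chain_i, resid_i)
                    pos_j = cg.residue_position(chain_j, resid_j)
                    bi = cg.bead_index(pos_i, bead_name_i)
                    bj = cg.bead_index(pos_j, bead_name_j)
                except KeyError:
                    bi = bj = None
                if bi is None or bj is None:
                    raise KeyError(
                        f"atom {ai} maps to bead {bead_name_i!r} absent from "
                        "the CG structure")
                pa, pb = atomistic.coords[ka], atomistic.coords[kb]
                D = map_atom_pair(cg.coords[bi], cg.coords[bj], pa, pb, rec.d)
                r_atom = np.linalg.norm(pa - pb)
                by_beads.setdefault((bi, bj), []).append((D, r_atom))
        for (bi, bj), contribs in by_beads.items():
            Ds = [c[0] for c in contribs]
            rs = [c[1] for c in contribs]
            D_hat = condense_group(Ds, rs)
            key = (min(bi, bj), max(bi, bj))
            per_pair.setdefault(key, []).append(
                (D_hat, rec.d, rec.r0, rec.r1, rec.r2))

    restraints = []
    for (bi, bj), signals in sorted(per_pair.items()):
        D_prime = aggregate_bead_pair([s[0] for s in signals])
        # shift each record's bounds by its own bead-geometry offset, then
        # average across signals
        bounds = np.array([
            (max(s[2] + (s[0] - s[1]), 0.0) if s[2] > 0 else 0.0,
             s[3] + (s[0] - s[1]),
             s[4] + (s[0] - s[1]))
            for s in signals
        ])
        r0, r1, r2 = bounds.mean(axis=0)
        r0 = min(max(r0, 0.0), r1)
        restraints.append(CGRestraint(bi, bj, float(r0), float(r1), float(r2),
                                      k=k_noe, **kwargs))
    return restraints


def restraints_from_bead_table(cg, noe: NOETable, k_noe=250.0, **kwargs):
    """Build restraints from a bead-resolved NOE table.

    Atom names in the records are taken to be bead names of ``cg``
    directly (the fixture convention), bypassing the atomistic mapping.
    """
    restraints = []
    for rec in noe:
        chain_i, resid_i, bead_i = rec.group_i[0]
        chain_j, resid_j, bead_j = rec.group_j[0]
        bi = cg.bead_index(cg.residue_position(chain_i, resid_i), bead_i)
        bj = cg.bead_index(cg.residue_position(chain_j, resid_j), bead_j)
        if bi is None or bj is None:
            raise KeyError(f"bead not found for NOE record {rec}")
        restraints.append(CGRestraint(bi, bj, rec.r0, rec.r1, rec.r2,
                                      k=k_noe, **kwargs))
    return restraints


# ---------------------------------------------------------------------------
# Potential
# ---------------------------------------------------------------------------

def noe_energy(r, restraint: CGRestraint) -> float:
    """Piecewise restraint energy at distance r (nm)."""
    if r <= 0:
        raise ValueError("r must be > 0")
    k, r0, r1, r2 = restraint.k, restraint.r0, restraint.r1, restraint.r2
    if r < r0:
        return 0.5 * k * (r - r0) ** 2
    if r < r1:
        return 0.0
    if r < r2:
        return 0.5 * k * (r - r1) ** 2
    return 0.5 * k * (r2 - r1) * (2.0 * r - r2 - r1)


def noe_force_magnitude(r, restraint: CGRestraint) -> float:
    """Instantaneous −dV/dr; positive values push r larger."""
    k, r0, r1, r2 = restraint.k, restraint.r0, restraint.r1, restraint.r2
    if r < r0:
        return k * (r0 - r)
    if r < r1:
        return 0.0
    if r < r2:
        return -k * (r - r1)
    return -k * (r2 - r1)


def update_running_average(rbar, r, dt, tau):
    """Exponential running average kept in r⁻³ space."""
    if rbar is None:
        return float(r)
    if rbar <= 0:
        raise ValueError("running average must stay > 0")
    decay = np.exp(-dt / tau)
    inv3 = decay * rbar ** -3.0 + (1.0 - decay) * float(r) ** -3.0
    return float(inv3 ** (-1.0 / 3.0))


def noe_timeavg_force(restraint: CGRestraint, r, dt, t=None,
                      cap_mode="effective", update=True):
    """Time-averaged restraint force magnitude along the bead axis.

    Updates the restraint's running average r̄ with memory e^(−Δt/τ) and
    ramps the force constant as K·(1 − e^(−t/ramp_tau)). The force acts
    only when the instantaneous *and* averaged distance violate the same
    bound; positive values push the beads apart.

    ``cap_mode="effective"`` uses the instantaneous violation as the
    displacement (so the memoryless limit recovers the instantaneous
    force); ``cap_mode="literal"`` keeps the printed (r−r1)(r̄−r1)
    product. The pulling branch is capped at (r2 − r1) either way.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if restraint.rbar is None:
        restraint.rbar = float(r)       # average starts at r(t=0)
    elif update:
        restraint.rbar = update_running_average(restraint.rbar, r, dt,
                                                restraint.tau)
    rbar = restraint.rbar
    if t is None:
        kt = restraint.k
    else:
        kt = restraint.k * (1.0 - np.exp(-t / restraint.ramp_tau))
    r0, r1, r2 = restraint.r0, restraint.r1, restraint.r2
    if r < r0 and rbar < r0:
        if cap_mode == "literal":
            return kt * (r0 - r) * (r0 - rbar)
        return kt * (r0 - r)
    if r > r1 and rbar > r1:
        if cap_mode == "literal":
            stretch = (r - r1) * (rbar - r1)
        else:
            stretch = r - r1
        return -kt * min(stretch, r2 - r1)
    return 0.0


class NOEForceProvider:
    """Engine force provider evaluating a set of CG restraints.

    ``time_averaged=False`` uses the instantaneous potential (energy and
    exact −∇V forces). ``time_averaged=True`` applies the running-average
    force law above; the reported energy is then the instantaneous
    potential evaluated at r̄ (bookkeeping only — the time-averaged force
    is not the gradient of a state function).
    """

    def __init__(self, restraints, dt=0.01, time_averaged=False,
                 cap_mode="effective"):
        self.restraints = list(restraints)
        self.dt = dt
        self.time_averaged = time_averaged
        self.cap_mode = cap_mode
        self.k_scale = 1.0              # ramp schedules may drive this
        self._last_step = None          # running average advances once/step

    def evaluate(self, coords, step=None):
        coords = np.asarray(coords, float)
        energy = 0.0
        forces = np.zeros_like(coords)
        t = None if step is None else step * self.dt
        update = step is None or step != self._last_step
        if step is not None:
            self._last_step = step
        for rst in self.restraints:
            delta = coords[rst.bead_j] - coords[rst.bead_i]
            r = float(np.linalg.norm(delta))
            if r < _TINY:
                raise DegenerateGeometryError("restrained beads coincide")
            unit = delta / r
            scaled = CGRestraint(rst.bead_i, rst.bead_j, rst.r0, rst.r1,
                                 rst.r2, k=rst.k * self.k_scale,
                                 tau=rst.tau, ramp_tau=rst.ramp_tau,
                                 rbar=rst.rbar)
            if self.time_averaged:
                mag = noe_timeavg_force(scaled, r, self.dt, t=t,
                                        cap_mode=self.cap_mode,
                                        update=update)
                rst.rbar = scaled.rbar
                energy += noe_energy(max(scaled.rbar, _TINY), scaled)
            else:
                mag = noe_force_magnitude(r, scaled)
                energy += noe_energy(r, scaled)
            # positive magnitude pushes beads apart
            forces[rst.bead_j] += mag * unit
            forces[rst.bead_i] -= mag * unit
        return energy, forces
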
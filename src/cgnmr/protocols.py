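"""Composite runbooks: restrained production and the detachment assay."""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from cgnmr import engine
from cgnmr.engine import (
    PositionalRestraint,
    RampSchedule,
    SimState,
    minimize,
    run,
    toy_forcefield,
)
from cgnmr.io_formats import ATOM_TYPES
from cgnmr.restraint_cs import CSRestraint
from cgnmr.restraint_noe import NOEForceProvider


@dataclass
class ProductionConfig:
    """Stages and schedules of the standard restrained-production run."""

    temperature: float = 300.0
    dt: float = 0.01                   # ps
    gamma: float = 0.01                # ps^-1
    minimize_steps: int = 500
    minimize_tol: float = 10.0
    equil_steps: int = 500
    posres_k: float = 1000.0
    ramp_rate: float = 0.001           # K_CS units per step
    k_cs_max: float = 25.0
    k_noe: float = 250.0
    production_steps: int = 2000
    report_every: int = 50
    seed: int = 0
    time_averaged_noe: bool = False


def scaled_cs_rmsd_series(cs_restraint: CSRestraint, frames,
                          per_atom_sd=None):
    """Mean scaled per-atom CS RMSD at each frame of an ensemble."""
    from cgnmr.shiftnet import forward

    sd = np.ones(len(ATOM_TYPES)) if per_atom_sd is None \
        else np.asarray(per_atom_sd, float)
    out = []
    for frame in np.asarray(frames, float):
        preds = forward(cs_restraint.model,
                        cs_restraint.featurizer.features(frame))
        diff = np.where(cs_restraint.exp_mask,
                        preds - cs_restraint.exp_values, 0.0)
        ratios = []
        for a in range(len(ATOM_TYPES)):
            m = cs_restraint.exp_mask[:, a]
            if m.any():
                ratios.append(np.sqrt(np.mean(diff[m, a] ** 2)) / sd[a])
        out.append(np.mean(ratios))
    return np.asarray(out)


def restrained_production(structure, model=None, exp_shifts=None,
                          noe_restraints=None, config=None,
                          per_atom_sd=None, extra_providers=()):
    """Minimize → positional-restrained equilibration → ramped production.

    Any of the restraint inputs may be omitted; with none given this
    reduces to plain toy-force-field dynamics. Returns (trajectory,
    reports) where reports carry the CS-RMSD and restraint-energy time
    series and the recorded K_CS trace.
    """
    cfg = config or ProductionConfig()
    providers = [toy_forcefield(structure)]
    schedules = []
    cs = None
    if model is not None and exp_shifts is not None:
        cs = CSRestraint(model, structure, exp_shifts)
        cs.k = 0.0
        providers.append(cs)
        schedules.append(RampSchedule(cs, "k", cfg.ramp_rate, cfg.k_cs_max))
    if noe_restraints:
        for r in noe_restraints:
            r.k = cfg.k_noe
        providers.append(NOEForceProvider(
            noe_restraints, dt=cfg.dt,
            time_averaged=cfg.time_averaged_noe))
    providers.extend(extra_providers)

    state = SimState.from_structure(structure, temperature=cfg.temperature,
                                    seed=cfg.seed, thermalize=True)
    # stage 1: minimization on the unrestrained toy potential
    minimize(state, providers[:1], max_steps=cfg.minimize_steps,
             tol=cfg.minimize_tol)
    # stage 2: positionally restrained equilibration
    posres = PositionalRestraint(state.coords, k=cfg.posres_k)
    for _ in range(cfg.equil_steps):
        engine.langevin_step(state, providers[:1] + [posres],
                             dt=cfg.dt, gamma=cfg.gamma)
    state.step = 0                      # ramps start counting at production
    # stage 3: production with restraint ramp
    traj, report = run(state, providers, schedules,
                       n_steps=cfg.production_steps,
                       report_every=cfg.report_every,
                       dt=cfg.dt, gamma=cfg.gamma)
    traj.topology = structure
    if cs is not None:
        report["cs_rmsd"] = scaled_cs_rmsd_series(cs, traj.frames,
                                                  per_atom_sd)
    return traj, report


@dataclass
class DetachmentResult:
    detached: list                     # per-replica bool
    min_contacts: list                 # per-replica min contact count
    contact_series: list               # per-replica per-frame counts
    histograms: list                   # per-replica (counts, bin_edges)

    @property
    def detachment_fraction(self):
        return float(np.mean(self.detached))


def count_contacts(coords, group_a, group_b, cutoff=0.8):
    """Number of bead pairs across the two groups closer than ``cutoff``.

    The boundary is strict: a pair exactly at the cutoff is not a contact.
    """
    a = np.asarray(coords, float)[np.asarray(group_a, int)]
    b = np.asarray(coords, float)[np.asarray(group_b, int)]
    d = np.sqrt(np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2))
    return int(np.sum(d < cutoff))


def detachment_assay(structure, monomer_selection, noe_restraints,
                     n_replicas=3, contact_cutoff=0.8, config=None,
                     drop_intermolecular=True):
    """Run replicas probing whether a monomer detaches from the remainder.

    NOE restraints bridging the monomer and the remainder are removed
    (unless ``drop_intermolecular=False``); each replica runs the standard
    production protocol with seed base_seed + replica index. A replica is
    flagged detached if any frame shows zero monomer↔remainder contacts.
    """
    cfg = config or ProductionConfig()
    monomer = np.asarray(monomer_selection, int)
    if monomer.size == 0:
        raise ValueError("empty monomer selection")
    rest = np.setdiff1d(np.arange(structure.n_beads), monomer)
    if rest.size == 0:
        raise ValueError("monomer selection covers the whole system")

    mono = set(monomer.tolist())
    if drop_intermolecular:
        kept = [r for r in noe_restraints
                if (r.bead_i in mono) == (r.bead_j in mono)]
    else:
        kept = list(noe_restraints)

    results = DetachmentResult([], [], [], [])
    base_seed = cfg.seed
    for rep in range(n_replicas):
        rep_cfg = ProductionConfig(**{**cfg.__dict__, "seed": base_seed + rep})
        traj, _ = restrained_production(structure, noe_restraints=kept,
                                        config=rep_cfg)
        series = np.array([
            count_contacts(frame, monomer, rest, contact_cutoff)
            for frame in traj.frames
        ])
        results.contact_series.append(series)
        results.min_contacts.append(int(series.min()))
        results.detached.append(bool((series == 0).any()))
        hist, edges = np.histogram(series,
                                   bins=np.arange(series.max() + 2) - 0.5)
        results.histograms.append((hist, edges))
    return results
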
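"""Flat-bottom chemical-shift restraint: energy, forces, ramp and metrics.

The restraint energy is ``K · Σ_residues Σ_atoms δ²`` where δ is the
prediction−experiment difference clipped by a per-atom-type tolerance ε
(the flat bottom). K carries kJ·mol⁻¹ with the ppm² of the residual
absorbed, matching the source convention. Forces follow from the network's
coordinate Jacobian; they vanish identically inside the flat bottom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cgnmr.io_formats import ATOM_TYPES
from cgnmr.shiftnet import Featurizer, ShiftModel, elu, elu_grad


@dataclass
class CSRestraintConfig:
    """Force constant, ramp schedule and flat-bottom widths."""

    k_cs: float = 25.0                  # kJ/mol (ppm² absorbed)
    ramp_rate: float = 0.001            # K units per integration step
    k_max: float = 25.0
    epsilon: np.ndarray = None          # (6,) ppm

    def __post_init__(self):
        if self.epsilon is None:
            self.epsilon = np.zeros(6)
        self.epsilon = np.asarray(self.epsilon, float)
        if self.k_cs < 0 or self.ramp_rate < 0 or self.k_max < 0:
            raise ValueError("config values must be non-negative")
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be non-negative")


def cs_residual(pred, exp, eps):
    """Flat-bottom clipped residual: 0 within ±eps, shifted outside.

    Strict inequalities bound the flat bottom, so a residual exactly at
    ±eps is clipped to 0.
    """
    d = np.asarray(pred, float) - np.asarray(exp, float)
    eps = np.asarray(eps, float)
    if np.any(eps < 0):
        raise ValueError("eps must be >= 0")
    out = np.where(d > eps, d - eps, np.where(d < -eps, d + eps, 0.0))
    return out if out.ndim else float(out)


def ramp_k(step, rate, k_max):
    """Ramped force constant min(step·rate, K_max)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return float(min(step * rate, k_max))


def _experimental_matrix(structure, exp):
    """(n_res, 6) experimental shifts + availability mask from a ShiftTable."""
    n = structure.n_residues
    values = np.zeros((n, 6))
    mask = np.zeros((n, 6), dtype=bool)
    for pos in range(n):
        chain = structure.chain_ids[pos]
        resid = structure.residue_indices[pos]
        for a, atom in enumerate(ATOM_TYPES):
            v = exp.get(chain, resid, atom)
            if v is not None:
                values[pos, a] = v
                mask[pos, a] = True
    return values, mask


class CSRestraint:
    """Stateful evaluator bound to one structure/model/shift-table triple.

    Precomputes the featurizer and experimental matrix; ``evaluate`` then
    returns (energy, forces) for arbitrary coordinates. Implements the
    engine's force-provider contract.
    """

    def __init__(self, model: ShiftModel, structure, exp, config=None):
        model.check_layout()
        self.model = model
        self.structure = structure
        self.config = config or CSRestraintConfig(epsilon=model.epsilon)
        self.featurizer = Featurizer(structure)
        self.exp_values, self.exp_mask = _experimental_matrix(structure, exp)
        self.k = self.config.k_cs

    def residuals(self, coords=None):
        """(n_res, 6) clipped residuals; unavailable entries are 0."""
        from cgnmr.shiftnet import forward

        preds = forward(self.model, self.featurizer.features(coords))
        res = cs_residual(preds, self.exp_values, self.config.epsilon)
        return np.where(self.exp_mask, res, 0.0)

    def energy(self, coords=None):
        res = self.residuals(coords)
        return float(self.k * np.sum(res ** 2))

    def evaluate(self, coords=None, step=None):
        """(energy, per-bead forces). Forces are −∇V via the chain rule."""
        c = self.structure.coords if coords is None else np.asarray(coords, float)
        fz = self.featurizer
        model = self.model
        f = fz.features(c)
        z = f @ model.W_hidden.T + model.b_hidden
        preds = elu(z) @ model.W_out.T + model.b_out
        res = cs_residual(preds, self.exp_values, self.config.epsilon)
        res = np.where(self.exp_mask, res, 0.0)
        energy = float(self.k * np.sum(res ** 2))
        forces = np.zeros_like(c)
        if np.any(res):
            # dV/dpred = 2 K δ (zero inside flat bottom)
            g_pred = 2.0 * self.k * res
            g_hidden = (g_pred @ model.W_out) * elu_grad(z)
            G = g_hidden @ model.W_hidden                   # dV/dfeatures
            dV_dangle = fz.dangle_from_dfeatures(c, G)
            fz.angle_force_accumulate(c, dV_dangle, forces)
        return energy, forces


def cs_energy(model, structure, exp, config) -> float:
    """V_CS = K · Σ clipped residual² over residues and atom types."""
    return CSRestraint(model, structure, exp, config).energy()


def cs_forces(model, structure, exp, config) -> np.ndarray:
    """Per-bead forces −∇V_CS (kJ·mol⁻¹·nm⁻¹)."""
    return CSRestraint(model, structure, exp, config).evaluate()[1]


def cs_rmsd_scaled(pred, exp, per_atom_sd) -> float:
    """Mean over atom types of (per-type RMSD of pred−exp) / reference SD.

    ``pred`` and ``exp`` are ShiftTables; atom types without common
    entries are omitted.
    """
    ratios = []
    for a, atom in enumerate(ATOM_TYPES):
        diffs = [
            pred.entries[key] - v
            for key, v in exp.entries.items()
            if key[2] == atom and key in pred.entries
        ]
        if not diffs:
            continue
        sd = per_atom_sd[atom] if isinstance(per_atom_sd, dict) else per_atom_sd[a]
        ratios.append(np.sqrt(np.mean(np.square(diffs))) / sd)
    if not ratios:
        raise ValueError("no common entries between pred and exp")
    return float(np.mean(ratios))


def scan_kcs(make_run, candidates, per_atom_sd=None):
    """Pick the smallest K_CS achieving the minimal mean CS RMSE.

    ``make_run(k)`` runs a short restrained simulation at force constant k
    and returns the mean scaled CS RMSE over its frames (or NaN/raises on
    divergence, which marks the candidate invalid). Ties go to the
    smallest K; candidates must be sorted ascending.
    """
    candidates = list(candidates)
    if candidates != sorted(candidates):
        raise ValueError("candidates must be sorted ascending")
    if len(candidates) == 1:
        return candidates[0]
    results = {}
    for k in candidates:
        try:
            rmse = make_run(k)
        except Exception:
            continue
        if np.isfinite(rmse):
            results[k] = rmse
    if not results:
        raise ValueError("all candidates diverged")
    best = min(results.values())
    for k in candidates:           # ascending → first at the minimum wins
        if k in results and results[k] <= best + 1e-12:
            return k
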
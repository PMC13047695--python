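"""Bead angles/dihedrals and their analytic Cartesian gradients.

All scalar operations are thin wrappers over vectorized batch forms that the
restraint force code uses directly. Angles are in radians: bond angles in
[0, π], dihedrals signed in (−π, π] (cis = 0, trans = π).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from cgnmr.errors import DegenerateGeometryError

_EPS = 1e-12

#: Order of the per-residue angle features.
ANGLE_NAMES = ("alpha", "beta", "gamma", "theta1", "theta2")


# ---------------------------------------------------------------------------
# Batch primitives
# ---------------------------------------------------------------------------

def angle_batch(p1, p2, p3):
    """Interior angles at p2 for stacked (m, 3) point triples."""
    u = np.asarray(p1, float) - p2
    v = np.asarray(p3, float) - p2
    cross = np.cross(u, v)
    sin = np.linalg.norm(cross, axis=-1)
    cos = np.einsum("...i,...i->...", u, v)
    return np.arctan2(sin, cos)


def angle_gradient_batch(p1, p2, p3):
    """d(angle)/d(p1,p2,p3) for stacked triples; returns three (m,3) arrays."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    p3 = np.asarray(p3, float)
    u = p1 - p2
    v = p3 - p2
    nu = np.linalg.norm(u, axis=-1, keepdims=True)
    nv = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(nu < _EPS) or np.any(nv < _EPS):
        raise DegenerateGeometryError("coincident points in angle gradient")
    uh = u / nu
    vh = v / nv
    cos = np.einsum("...i,...i->...", uh, vh)[..., None]
    sin2 = 1.0 - cos * cos
    if np.any(sin2 < _EPS):
        raise DegenerateGeometryError("collinear points in angle gradient")
    sin = np.sqrt(sin2)
    g1 = (uh * cos - vh) / (nu * sin)
    g3 = (vh * cos - uh) / (nv * sin)
    g2 = -(g1 + g3)
    return g1, g2, g3


def dihedral_batch(p1, p2, p3, p4):
    """Signed torsions for stacked (m, 3) quadruples, in (−π, π]."""
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    b3 = np.asarray(p4, float) - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", np.cross(n1, n2), b2) / np.where(
        nb2 > 0, nb2, 1.0)
    phi = np.arctan2(y, x)
    # map −π to π so the range is half-open (−π, π]
    return np.where(np.isclose(phi, -np.pi), np.pi, phi)


def dihedral_gradient_batch(p1, p2, p3, p4):
    """d(dihedral)/d(points) for stacked quadruples; four (m,3) arrays."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    p3 = np.asarray(p3, float)
    p4 = np.asarray(p4, float)
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.einsum("...i,...i->...", n1, n1)[..., None]
    n2sq = np.einsum("...i,...i->...", n2, n2)[..., None]
    nb2 = np.linalg.norm(b2, axis=-1)[..., None]
    if np.any(n1sq < _EPS) or np.any(n2sq < _EPS) or np.any(nb2 < _EPS):
        raise DegenerateGeometryError("collinear points in dihedral gradient")
    g1 = -nb2 / n1sq * n1
    g4 = nb2 / n2sq * n2
    db1 = np.einsum("...i,...i->...", b1, b2)[..., None] / (nb2 * nb2)
    db3 = np.einsum("...i,...i->...", b3, b2)[..., None] / (nb2 * nb2)
    g2 = -g1 - db1 * g1 + db3 * g4
    g3 = -g4 + db1 * g1 - db3 * g4
    return g1, g2, g3, g4


# ---------------------------------------------------------------------------
# Scalar API
# ---------------------------------------------------------------------------

def angle(p1, p2, p3):
    """Interior angle at p2, in [0, π]. Raises on coincident points."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    if (np.linalg.norm(p1 - p2) < _EPS) or (np.linalg.norm(p3 - p2) < _EPS):
        raise DegenerateGeometryError("coincident points in angle")
    return float(angle_batch(p1, p2, p3))


def dihedral(p1, p2, p3, p4):
    """Signed torsion in (−π, π]; raises on a collinear middle bond."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if (np.linalg.norm(np.cross(b1, b2)) < _EPS
            or np.linalg.norm(np.cross(b2, b3)) < _EPS):
        raise DegenerateGeometryError("collinear points in dihedral")
    return float(dihedral_batch(p1, p2, p3, p4))


def angle_gradient(p1, p2, p3):
    g1, g2, g3 = angle_gradient_batch(
        *(np.asarray(p, float) for p in (p1, p2, p3)))
    return g1, g2, g3


def dihedral_gradient(p1, p2, p3, p4):
    g1, g2, g3, g4 = dihedral_gradient_batch(
        *(np.asarray(p, float) for p in (p1, p2, p3, p4)))
    return g1, g2, g3, g4


# ---------------------------------------------------------------------------
# Per-residue angle features
# ---------------------------------------------------------------------------

@dataclass
class ResidueAngles:
    """Five local angles of one residue; absent angles are masked."""

    alpha: Optional[float] = None
    beta: Optional[float] = None
    gamma: Optional[float] = None
    theta1: Optional[float] = None
    theta2: Optional[float] = None

    def mask(self):
        return tuple(getattr(self, n) is not None for n in ANGLE_NAMES)

    def values(self):
        """Angle values with masked entries as 0 (the feature convention)."""
        return tuple(
            0.0 if getattr(self, n) is None else getattr(self, n)
            for n in ANGLE_NAMES
        )


#: Bead requirements per angle, as offsets of (BB, SC1) beads relative to i.
#: alpha = angle(SC1_i, BB_i, BB_{i-1}); beta = angle(BB_{i-1}, BB_i, BB_{i+1})
#: gamma = angle(SC1_i, BB_i, BB_{i+1});
#: theta1 = dihedral(BB_{i-2}, BB_{i-1}, BB_i, BB_{i+1})
#: theta2 = dihedral(BB_{i-1}, BB_i, BB_{i+1}, BB_{i+2})
ANGLE_BEADS = {
    "alpha": (("SC1", 0), ("BB", 0), ("BB", -1)),
    "beta": (("BB", -1), ("BB", 0), ("BB", 1)),
    "gamma": (("SC1", 0), ("BB", 0), ("BB", 1)),
    "theta1": (("BB", -2), ("BB", -1), ("BB", 0), ("BB", 1)),
    "theta2": (("BB", -1), ("BB", 0), ("BB", 1), ("BB", 2)),
}


def neighbor_position(structure, pos, offset):
    """Residue position at sequence offset within the same chain, or None."""
    q = pos + offset
    if q < 0 or q >= structure.n_residues:
        return None
    if structure.chain_ids[q] != structure.chain_ids[pos]:
        return None
    return q


def angle_bead_indices(structure, pos, name):
    """Global bead indices realizing angle ``name`` at residue ``pos``.

    Returns None if any required bead is absent (chain end, GLY's SC1).
    """
    indices = []
    for bead, offset in ANGLE_BEADS[name]:
        q = neighbor_position(structure, pos, offset)
        if q is None:
            return None
        k = structure.bead_index(q, bead)
        if k is None:
            return None
        indices.append(k)
    return tuple(indices)


def residue_angles(structure, pos, coords=None) -> ResidueAngles:
    """The five local angles of residue ``pos``; missing beads mask angles."""
    c = structure.coords if coords is None else np.asarray(coords, float)
    out = ResidueAngles()
    for name in ANGLE_NAMES:
        idx = angle_bead_indices(structure, pos, name)
        if idx is None:
            continue
        pts = [c[k] for k in idx]
        value = angle(*pts) if len(idx) == 3 else dihedral(*pts)
        setattr(out, name, value)
    return out
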
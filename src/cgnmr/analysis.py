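"""Ensemble metrics, each a pure function over trajectories/ensembles.

Coordinate inputs are (n_frames, n_beads, 3) arrays or
:class:`~cgnmr.io_formats.Trajectory` objects; angles are reported in
degrees, energies in kJ·mol⁻¹, distances in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from cgnmr.engine import KB
from cgnmr.errors import DegenerateGeometryError, DegenerateInputError
from cgnmr.geometry import angle_bead_indices, dihedral_batch


def _frames_of(ensemble) -> np.ndarray:
    if hasattr(ensemble, "frames"):
        return np.asarray(ensemble.frames, float)
    arr = np.asarray(ensemble, float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


# ---------------------------------------------------------------------------
# Superposition-based metrics
# ---------------------------------------------------------------------------

def kabsch(mobile, target):
    """Optimal rotation+translation of ``mobile`` onto ``target`` (n, 3)."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, tc - R @ mc


def align_frames(frames, reference, selection=None):
    """Superpose every frame onto ``reference`` using ``selection`` beads."""
    frames = _frames_of(frames)
    reference = np.asarray(reference, float)
    sel = (np.arange(frames.shape[1]) if selection is None
           else np.asarray(selection, int))
    if len(sel) < 3:
        raise ValueError("need at least 3 beads for superposition")
    out = np.empty_like(frames)
    for k, frame in enumerate(frames):
        R, t = kabsch(frame[sel], reference[sel])
        out[k] = frame @ R.T + t
    return out


def rmsd_coords(ensemble, reference, selection=None, align=True):
    """Per-frame RMSD (nm) over ``selection`` after optimal superposition."""
    frames = _frames_of(ensemble)
    reference = np.asarray(reference, float)
    sel = (np.arange(frames.shape[1]) if selection is None
           else np.asarray(selection, int))
    if len(sel) < 3:
        raise ValueError("need at least 3 beads in the selection")
    if align:
        frames = align_frames(frames, reference, sel)
    diff = frames[:, sel] - reference[sel]
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))


def rmsf(ensemble, selection=None, align_selection=None):
    """Per-bead RMS fluctuation (nm) around the mean aligned position.

    ``align_selection`` (default: ``selection``) controls superposition
    separately, e.g. to align on a rigid core while measuring flexible
    beads.
    """
    frames = _frames_of(ensemble)
    if frames.shape[0] < 2:
        raise DegenerateInputError("RMSF needs at least 2 frames")
    sel = (np.arange(frames.shape[1]) if selection is None
           else np.asarray(selection, int))
    asel = sel if align_selection is None else np.asarray(align_selection, int)
    aligned = align_frames(frames, frames[0], asel)
    mean = aligned[:, sel].mean(axis=0)
    dev = aligned[:, sel] - mean
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# Dihedral metrics
# ---------------------------------------------------------------------------

def _dihedral_indices(structure):
    """Bead index quadruples for every defined backbone dihedral (θ1, θ2)."""
    quads, owners = [], []
    for pos in range(structure.n_residues):
        for name in ("theta1", "theta2"):
            idx = angle_bead_indices(structure, pos, name)
            if idx is not None:
                quads.append(idx)
                owners.append((pos, name))
    return np.array(quads, int).reshape(len(quads), 4), owners


def backbone_dihedrals(structure, frames):
    """(n_frames, n_dihedrals) backbone torsions in degrees, plus owners."""
    frames = _frames_of(frames)
    quads, owners = _dihedral_indices(structure)
    if len(quads) == 0:
        return np.zeros((frames.shape[0], 0)), owners
    out = np.empty((frames.shape[0], len(quads)))
    for k, frame in enumerate(frames):
        pts = frame[quads]
        out[k] = np.rad2deg(dihedral_batch(pts[:, 0], pts[:, 1],
                                           pts[:, 2], pts[:, 3]))
    return out, owners


def wrap_degrees(delta):
    """Wrap angle differences into (−180°, 180°]."""
    wrapped = np.mod(np.asarray(delta, float) + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def dihedral_rmsd(structure, ensemble, reference_coords):
    """Per-frame RMSD (degrees) of backbone dihedrals vs a reference."""
    angles, _ = backbone_dihedrals(structure, ensemble)
    ref, _ = backbone_dihedrals(structure, reference_coords[None]
                                if np.asarray(reference_coords).ndim == 2
                                else reference_coords)
    if angles.shape[1] == 0:
        raise DegenerateInputError("no defined backbone dihedrals")
    diff = wrap_degrees(angles - ref[0])
    return np.sqrt(np.mean(diff ** 2, axis=1))


def pseudo_ramachandran(structure, ensemble):
    """{residue position: (m, 2) array of (θ1, θ2) degree samples}.

    Residues lacking either dihedral (chain termini) are excluded.
    """
    angles, owners = backbone_dihedrals(structure, ensemble)
    per_res = {}
    for col, (pos, name) in enumerate(owners):
        per_res.setdefault(pos, {})[name] = angles[:, col]
    return {
        pos: np.column_stack([d["theta1"], d["theta2"]])
        for pos, d in per_res.items()
        if "theta1" in d and "theta2" in d
    }


# ---------------------------------------------------------------------------
# S-matrix
# ---------------------------------------------------------------------------

@dataclass
class SMatrix:
    values: np.ndarray                 # (N, N) in [0, 2]
    bin_edges: np.ndarray

    @property
    def n_residues(self):
        return self.values.shape[0]


def s_matrix(ens_a, ens_b, bead_indices=None, bin_width=0.1,
             bin_range=None) -> SMatrix:
    """L1 distance between per-pair distance distributions of two ensembles.

    ``bead_indices`` selects one bead per residue (default: all beads are
    residues). Bins are fixed a priori and shared; data outside the bin
    range is an error.
    """
    A = _frames_of(ens_a)
    B = _frames_of(ens_b)
    if bead_indices is not None:
        sel = np.asarray(bead_indices, int)
        A, B = A[:, sel], B[:, sel]
    if A.shape[1] != B.shape[1]:
        raise ValueError("ensembles map to different residue counts")
    n = A.shape[1]
    iu = np.triu_indices(n, k=1)

    def pair_distances(frames):
        diff = frames[:, :, None, :] - frames[:, None, :, :]
        d = np.sqrt(np.sum(diff ** 2, axis=3))
        return d[:, iu[0], iu[1]]          # (n_frames, n_pairs)

    da, db = pair_distances(A), pair_distances(B)
    if bin_range is None:
        top = max(da.max(), db.max()) if da.size else 1.0
        bin_range = (0.0, np.ceil(top / bin_width) * bin_width + bin_width)
    edges = np.arange(bin_range[0], bin_range[1] + 0.5 * bin_width, bin_width)
    if (da.size and (da.min() < edges[0] or da.max() > edges[-1])) or \
       (db.size and (db.min() < edges[0] or db.max() > edges[-1])):
        raise ValueError("distance data outside the fixed bin range")

    values = np.zeros((n, n))
    for p, (i, j) in enumerate(zip(*iu)):
        ha, _ = np.histogram(da[:, p], bins=edges)
        hb, _ = np.histogram(db[:, p], bins=edges)
        pa = ha / ha.sum()
        pb = hb / hb.sum()
        s = np.abs(pa - pb).sum()
        values[i, j] = values[j, i] = s
    return SMatrix(values=values, bin_edges=edges)


# ---------------------------------------------------------------------------
# Helix-bundle angles
# ---------------------------------------------------------------------------

@dataclass
class HelixBundleSpec:
    """Per-helix (start_bead, end_bead) indices and the membrane normal."""

    helices: Sequence                  # [(start_bead, end_bead), ...]
    b0: np.ndarray                     # unit 3-vector

    def __post_init__(self):
        self.b0 = np.asarray(self.b0, float)
        self.b0 = self.b0 / np.linalg.norm(self.b0)
        for s, e in self.helices:
            if s == e:
                raise ValueError("helix start and end bead coincide")


def _vec_angle_deg(u, v):
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise DegenerateGeometryError("zero-length helix vector")
    cos = np.clip(np.einsum("...i,...i->...", u, v) / (nu * nv), -1.0, 1.0)
    return np.rad2deg(np.arccos(cos))


def tau_omega(frames, spec: HelixBundleSpec):
    """Per-frame (τ, ω): mean helix angles to the membrane normal and to
    the bundle axis.

    Note the conventions are as printed in the source method: each helix
    vector is end − start while the bundle axis is mean(start) − mean(end),
    so a single helix yields ω = 180° (the bundle axis is antiparallel).
    """
    frames = _frames_of(frames)
    starts = np.array([s for s, _ in spec.helices])
    ends = np.array([e for _, e in spec.helices])
    h = frames[:, ends] - frames[:, starts]             # (f, n_helix, 3)
    bundle = frames[:, starts].mean(axis=1) - frames[:, ends].mean(axis=1)
    tau = _vec_angle_deg(np.broadcast_to(spec.b0, h.shape), h).mean(axis=1)
    omega = _vec_angle_deg(bundle[:, None, :], h).mean(axis=1)
    return tau, omega


# ---------------------------------------------------------------------------
# Free energy
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray
    free_energy: np.ndarray            # kJ/mol, NaN for empty bins
    sigma: np.ndarray                  # kJ/mol bootstrap errors
    temperature: float


def free_energy_profile(samples, bins, temperature=300.0, n_bootstrap=100,
                        seed=0) -> FreeEnergyProfile:
    """F_i = −k_B·T·ln(H_i) over normalized bin densities with bootstrap σ.

    Empty bins are masked (NaN), not ±inf. σ_i is k_B·T times the
    bootstrap standard error of H_i divided by its bootstrap mean.
    """
    samples = np.asarray(samples, float)
    if samples.size == 0:
        raise DegenerateInputError("no samples")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    H, edges = np.histogram(samples, bins=bins)
    density = H / H.sum()
    with np.errstate(divide="ignore"):
        F = np.where(density > 0, -KB * temperature * np.log(
            np.where(density > 0, density, 1.0)), np.nan)

    rng = np.random.default_rng(seed)
    n = len(samples)
    boots = np.empty((n_bootstrap, len(density)))
    for b in range(n_bootstrap):
        resample = samples[rng.integers(0, n, n)]
        Hb, _ = np.histogram(resample, bins=edges)
        boots[b] = Hb / Hb.sum()
    mean = boots.mean(axis=0)
    var = (boots ** 2).mean(axis=0) - mean ** 2
    se = np.sqrt(np.maximum(var, 0.0) / max(n_bootstrap - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.where(mean > 0, KB * temperature * se / mean, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FreeEnergyProfile(centers, F, sigma, temperature)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactEvents:
    lifetimes: np.ndarray              # ps, completed events only
    censored: int                      # events still open at trajectory end

    def mean_lifetime(self):
        return float(np.mean(self.lifetimes)) if len(self.lifetimes) else np.nan


def contact_lifetimes_from_series(distances, frame_spacing, r0=0.8, r1=1.0
                                  ) -> ContactEvents:
    """Transition-based contact events from a min-distance series.

    A contact opens when the distance drops below r0 and closes the next
    time it exceeds r1 (hysteresis). Events still open at the end are
    censored and excluded from lifetimes.
    """
    distances = np.asarray(distances, float)
    lifetimes = []
    open_at = None
    for k, d in enumerate(distances):
        if open_at is None:
            if d < r0:
                open_at = k
        else:
            if d > r1:
                lifetimes.append((k - open_at) * frame_spacing)
                open_at = None
    return ContactEvents(np.array(lifetimes), censored=int(open_at is not None))


def contact_lifetimes(traj, group_pairs, r0=0.8, r1=1.0):
    """Per-pair contact events over a trajectory.

    ``group_pairs`` is a list of (beads_a, beads_b) index arrays; the
    per-frame distance of a pair is the minimum over all bead pairs.
    Returns a list of :class:`ContactEvents` aligned with ``group_pairs``.
    """
    frames = _frames_of(traj)
    spacing = traj.frame_spacing if hasattr(traj, "frame_spacing") else 1.0
    events = []
    for beads_a, beads_b in group_pairs:
        a = frames[:, np.asarray(beads_a, int)]
        b = frames[:, np.asarray(beads_b, int)]
        diff = a[:, :, None, :] - b[:, None, :, :]
        dmin = np.sqrt(np.sum(diff ** 2, axis=3)).min(axis=(1, 2))
        events.append(contact_lifetimes_from_series(dmin, spacing, r0, r1))
    return events


# ---------------------------------------------------------------------------
# Diffusion
# ---------------------------------------------------------------------------

@dataclass
class DiffusionResult:
    D: np.ndarray                      # nm²/ps per bead
    pearson_r: np.ndarray
    exponent: np.ndarray               # log-log MSD slope over the window
    superdiffusive: np.ndarray         # exponent > 1.5
    lags: np.ndarray                   # ps
    msd: np.ndarray                    # (n_beads, n_lags)


def msd_diffusion(traj, selection, core_selection, lag_min=10.0,
                  fit_window=(100.0, 500.0)) -> DiffusionResult:
    """Per-bead diffusion coefficients from the linear MSD regime.

    Frames are aligned on ``core_selection``; MSD(τ) is averaged over all
    time origins; D = slope / 6 from a linear fit inside ``fit_window``
    (ps). A log-log exponent > 1.5 over the window flags superdiffusive
    (e.g. ballistic) motion.
    """
    frames = _frames_of(traj)
    spacing = traj.frame_spacing if hasattr(traj, "frame_spacing") else 1.0
    sel = np.asarray(selection, int)
    aligned = align_frames(frames, frames[0], np.asarray(core_selection, int))
    pos = aligned[:, sel]                              # (f, m, 3)

    max_lag_frames = int(np.floor(fit_window[1] / spacing))
    min_lag_frames = max(int(np.ceil(lag_min / spacing)), 1)
    if max_lag_frames >= frames.shape[0]:
        raise DegenerateInputError("trajectory shorter than the fit window")
    lags_f = np.arange(min_lag_frames, max_lag_frames + 1)
    msd = np.empty((len(sel), len(lags_f)))
    for li, lag in enumerate(lags_f):
        disp = pos[lag:] - pos[:-lag]
        msd[:, li] = np.mean(np.sum(disp ** 2, axis=2), axis=0)
    lags_ps = lags_f * spacing

    in_window = (lags_ps >= fit_window[0]) & (lags_ps <= fit_window[1])
    if in_window.sum() < 2:
        raise DegenerateInputError("fit window contains fewer than 2 lags")
    x = lags_ps[in_window]
    D = np.empty(len(sel))
    r = np.empty(len(sel))
    expo = np.empty(len(sel))
    for b in range(len(sel)):
        y = msd[b, in_window]
        slope, _, pr, _, _ = stats.linregress(x, y)
        D[b] = max(slope, 0.0) / 6.0
        r[b] = pr
        if np.all(y > 0):
            ls, _, _, _, _ = stats.linregress(np.log(x), np.log(y))
            expo[b] = ls
        else:
            expo[b] = 0.0
    return DiffusionResult(D, r, expo, expo > 1.5, lags_ps, msd)


# ---------------------------------------------------------------------------
# Radial profile and twist
# ---------------------------------------------------------------------------

def radial_profile(traj, selection, attachment_points, z_min, z_max,
                   bin_edges, excluded_fraction=0.5):
    """Radial concentration of selected beads around attachment points.

    c(r_i) = ΔC / [π(r_i² − r_{i−1}²)·(1−f)·(z_max−z_min)], with beads
    outside the z slab excluded and counts averaged over frames and
    attachment points. ``excluded_fraction`` f is the area fraction
    occupied by the structured core.
    """
    if not 0 <= excluded_fraction < 1:
        raise ValueError("excluded_fraction must be in [0, 1)")
    if z_max <= z_min:
        raise ValueError("z_max must exceed z_min")
    frames = _frames_of(traj)
    sel = np.asarray(selection, int)
    points = np.atleast_2d(np.asarray(attachment_points, float))
    edges = np.asarray(bin_edges, float)
    counts = np.zeros(len(edges) - 1)
    n_samples = 0
    for frame in frames:
        beads = frame[sel]
        in_slab = (beads[:, 2] >= z_min) & (beads[:, 2] <= z_max)
        beads = beads[in_slab]
        for pt in points:
            r = np.hypot(beads[:, 0] - pt[0], beads[:, 1] - pt[1])
            h, _ = np.histogram(r, bins=edges)
            counts += h
            n_samples += 1
    counts /= max(n_samples, 1)
    shell_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    volume = shell_area * (1.0 - excluded_fraction) * (z_max - z_min)
    return counts / volume


def twist_angle(frames, layer_beads):
    """Per-frame mean inter-layer twist (degrees).

    ``layer_beads`` lists, per layer, the (bead_a, bead_b) reference beads
    of its two chains, or None when unresolved (the adjacent interfaces
    are then skipped with a warning). The twist of interface i is the
    dihedral over (a_i, b_i, b_{i+1}, a_{i+1}), which is 0° for purely
    translated layers and the rotation angle for layers twisted about the
    fibril axis.
    """
    frames = _frames_of(frames)
    quads = []
    for i in range(len(layer_beads) - 1):
        if layer_beads[i] is None or layer_beads[i + 1] is None:
            warnings.warn(f"interface {i}: missing reference bead, skipped")
            continue
        a, b = layer_beads[i]
        c, d = layer_beads[i + 1]
        quads.append((a, b, d, c))
    if not quads:
        raise DegenerateInputError("fewer than 2 resolvable layers")
    quads = np.array(quads, int)
    out = np.empty(frames.shape[0])
    for k, frame in enumerate(frames):
        pts = frame[quads]
        phi = dihedral_batch(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        out[k] = np.rad2deg(phi).mean()
    return out


# ---------------------------------------------------------------------------
# Convergence and representatives
# ---------------------------------------------------------------------------

def stationarity_test(timeseries):
    """Augmented Dickey-Fuller unit-root test → (statistic, p-value)."""
    series = np.asarray(timeseries, float)
    if len(series) < 20:
        raise DegenerateInputError("ADF test needs at least 20 points")
    if np.ptp(series) == 0:
        raise DegenerateInputError("constant series has no ADF statistic")
    stat, pvalue = adfuller(series)[:2]
    return float(stat), float(pvalue)


def representative_structure(ensemble, n_components=None) -> int:
    """Index of the frame closest to the ensemble mean in PCA space.

    Frames are aligned to the first frame; ties resolve to the lowest
    index.
    """
    frames = _frames_of(ensemble)
    if frames.shape[0] < 2:
        raise DegenerateInputError("need at least 2 frames")
    aligned = align_frames(frames, frames[0])
    X = aligned.reshape(frames.shape[0], -1)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or min(10, len(S))
    proj = Xc @ Vt[:k].T
    target = proj.mean(axis=0)
    dist = np.linalg.norm(proj - target, axis=1)
    return int(np.argmin(dist))
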
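"""Synthetic-data generators: toy peptides, teacher networks, shift/NOE
tables and scripted trajectories.

Every generator is a pure function of its seed, so tests and examples are
reproducible with no external data.
"""

from __future__ import annotations

import numpy as np

from cgnmr.errors import DegenerateInputError
from cgnmr.io_formats import (
    AtomisticStructure,
    CGStructure,
    MappingTable,
    NOERecord,
    NOETable,
    ShiftTable,
    STANDARD_RESIDUES,
    Trajectory,
)
from cgnmr import shiftnet

BB_SPACING = 0.35          # nm between consecutive backbone beads
SC_OFFSET = 0.30           # nm from BB to its SC1 bead
MIN_SEPARATION = 0.2       # nm self-avoidance radius


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_toy_peptide(n_residues, sequence=None, seed=0,
                     chain_id="A") -> CGStructure:
    """Self-avoiding BB chain at 0.35 nm spacing with SC1 beads.

    GLY residues carry no SC1. The chain grows by rejection sampling with a
    mild directional persistence; deterministic per seed.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = [STANDARD_RESIDUES[k]
                    for k in rng.integers(0, len(STANDARD_RESIDUES), n_residues)]
    elif len(sequence) != n_residues:
        raise ValueError("sequence length mismatch")
    sequence = list(sequence)

    bb = [np.zeros(3)]
    direction = _random_unit(rng)
    for _ in range(1, n_residues):
        for _attempt in range(200):
            step = direction + 0.8 * rng.normal(size=3)
            step /= np.linalg.norm(step)
            candidate = bb[-1] + BB_SPACING * step
            if all(np.linalg.norm(candidate - p) > MIN_SEPARATION
                   for p in bb[:-1]):
                break
        else:
            raise DegenerateInputError("could not grow self-avoiding chain")
        bb.append(candidate)
        direction = step

    bead_names, bead_res, coords = [], [], []
    all_points = list(bb)
    for i, rtype in enumerate(sequence):
        bead_names.append("BB")
        bead_res.append(i)
        coords.append(bb[i])
        if rtype == "GLY":
            continue
        for _attempt in range(200):
            sc = bb[i] + SC_OFFSET * _random_unit(rng)
            if all(np.linalg.norm(sc - p) > MIN_SEPARATION for p in all_points):
                break
        else:
            raise DegenerateInputError("could not place SC1 bead")
        all_points.append(sc)
        bead_names.append("SC1")
        bead_res.append(i)
        coords.append(sc)

    return CGStructure(
        chain_ids=[chain_id] * n_residues,
        residue_indices=np.arange(1, n_residues + 1),
        residue_types=sequence,
        bead_names=bead_names,
        bead_residue=np.array(bead_res),
        coords=np.array(coords),
    ).validate()


def make_teacher_model(seed=0, scale=1.0) -> shiftnet.ShiftModel:
    """Random frozen network of the production architecture; ε = 0."""
    rng = np.random.default_rng(seed)
    model = shiftnet.ShiftModel(
        W_hidden=scale * rng.normal(size=(shiftnet.N_HIDDEN,
                                          shiftnet.N_FEATURES))
        / np.sqrt(shiftnet.N_FEATURES),
        b_hidden=0.1 * rng.normal(size=shiftnet.N_HIDDEN),
        W_out=scale * rng.normal(size=(shiftnet.N_OUT, shiftnet.N_HIDDEN))
        / np.sqrt(shiftnet.N_HIDDEN),
        b_out=0.1 * rng.normal(size=shiftnet.N_OUT),
        epsilon=np.zeros(shiftnet.N_OUT),
    )
    return model


def synth_shift_table(teacher, target: CGStructure, noise_sd=0.0,
                      seed=0) -> ShiftTable:
    """Teacher predictions on a target structure plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    table = shiftnet.predict_shifts(teacher, target)
    if noise_sd > 0:
        for key in table.entries:
            table.entries[key] += rng.normal(0.0, noise_sd)
    return table


def synth_noe_table(target: CGStructure, n_pairs, bound_width=0.05,
                    max_distance=1.2, seed=0, min_sequence_sep=3,
                    two_sided=False) -> NOETable:
    """Bead-resolved NOE records generated from a target's own geometry.

    Picks BB pairs separated in sequence by at least ``min_sequence_sep``
    residues and closer than ``max_distance`` nm; d is the actual distance
    and r1 = d + bound_width, so the target satisfies every restraint.
    With ``two_sided`` the lower bound is r0 = max(d − bound_width, 0)
    (explicit bounds as read from data); otherwise r0 = 0.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    eligible = []
    for i in range(target.n_residues):
        for j in range(i + min_sequence_sep, target.n_residues):
            bi = target.bead_index(i, "BB")
            bj = target.bead_index(j, "BB")
            d = np.linalg.norm(target.coords[bi] - target.coords[bj])
            if d <= max_distance:
                eligible.append((i, j, d))
    if len(eligible) < n_pairs:
        raise DegenerateInputError(
            f"only {len(eligible)} eligible pairs for {n_pairs} requested")
    picks = rng.choice(len(eligible), size=n_pairs, replace=False)
    table = NOETable()
    for k in sorted(picks):
        i, j, d = eligible[k]
        r1 = d + bound_width
        r0 = max(d - bound_width, 0.0) if two_sided else 0.0
        table.records.append(NOERecord(
            group_i=[(target.chain_ids[i], int(target.residue_indices[i]), "BB")],
            group_j=[(target.chain_ids[j], int(target.residue_indices[j]), "BB")],
            d=float(d), r0=float(r0), r1=float(r1), r2=float(r1 + 0.5),
        ))
    return table


def steering_fixture(n_residues=12, target_seed=11, teacher_seed=5,
                     noe_seed=3, perturb_seed=123, perturb_sd=0.12,
                     n_pairs=25):
    """Target conformation + restraints derived from it + a perturbed start.

    Returns (target, start, teacher, shift_table, noe_table, bb_indices).
    The target is, by construction, a zero-energy point of both restraint
    sets; the perturbed start drifts away under plain toy dynamics, so
    restrained runs should recover/retain the target while unrestrained
    runs do not.
    """
    target = make_toy_peptide(n_residues, seed=target_seed)
    teacher = make_teacher_model(teacher_seed)
    shifts = synth_shift_table(teacher, target)
    noe = synth_noe_table(target, n_pairs=n_pairs, max_distance=2.0,
                          bound_width=0.03, seed=noe_seed,
                          min_sequence_sep=2, two_sided=True)
    rng = np.random.default_rng(perturb_seed)
    start = target.with_coords(
        target.coords + perturb_sd * rng.normal(size=target.coords.shape))
    bb = [target.bead_index(i, "BB") for i in range(target.n_residues)]
    return target, start, teacher, shifts, noe, bb


def pseudo_atomistic(structure: CGStructure):
    """Atoms placed exactly at bead centers, plus the identity mapping.

    Exercises the atomistic→CG NOE mapping pipeline on the identity case.
    """
    atoms = AtomisticStructure(
        chain_ids=[structure.chain_ids[r] for r in structure.bead_residue],
        residue_indices=np.array(
            [structure.residue_indices[r] for r in structure.bead_residue]),
        residue_types=[structure.residue_types[r]
                       for r in structure.bead_residue],
        atom_names=list(structure.bead_names),
        elements=["C"] * structure.n_beads,
        coords=structure.coords.copy(),
    )
    mapping = MappingTable()
    for r, name in zip(structure.bead_residue, structure.bead_names):
        mapping.entries[(structure.residue_types[r], name)] = name
    return atoms, mapping


def synth_training_set(teacher, n_structures, residues_per_structure,
                       noise_sd=0.0, seed=0,
                       fractions=(0.8, 0.1, 0.1)) -> shiftnet.TrainingSet:
    """Random toy peptides featurized, targets = teacher output + noise."""
    if n_structures < 1 or residues_per_structure < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    feats, targets, masks, sids = [], [], [], []
    for sid in range(n_structures):
        peptide = make_toy_peptide(residues_per_structure,
                                   seed=int(rng.integers(2 ** 31)))
        F = shiftnet.Featurizer(peptide).features()
        Y = shiftnet.forward(teacher, F)
        if noise_sd > 0:
            Y = Y + rng.normal(0.0, noise_sd, Y.shape)
        feats.append(F)
        targets.append(Y)
        masks.append(np.ones_like(Y, dtype=bool))
        sids.extend([sid] * len(F))
    sids = np.array(sids)
    unique = np.unique(sids)
    order = rng.permutation(unique)
    n_train = int(round(fractions[0] * len(unique)))
    n_val = max(int(round(fractions[1] * len(unique))), 1)
    assignment = {}
    for k, sid in enumerate(order):
        if k < n_train:
            assignment[sid] = "train"
        elif k < n_train + n_val:
            assignment[sid] = "validation"
        else:
            assignment[sid] = "test"
    partition = np.array([assignment[s] for s in sids])
    ts = shiftnet.TrainingSet(
        np.concatenate(feats), np.concatenate(targets),
        np.concatenate(masks), sids, partition)
    ts.check_disjoint()
    return ts


def scripted_trajectory(distance_script=None, displacement_script=None,
                        frame_spacing=10.0) -> Trajectory:
    """Two-bead (or n-bead) trajectory realizing a script exactly.

    ``distance_script``: sequence of inter-bead distances (nm); bead 0 is
    fixed at the origin and bead 1 moves along +x.
    ``displacement_script``: (n_frames, n_beads, 3) absolute positions.
    """
    if (distance_script is None) == (displacement_script is None):
        raise ValueError("give exactly one of distance/displacement script")
    if distance_script is not None:
        distances = np.asarray(distance_script, float)
        if distances.size == 0 or np.any(distances < 0):
            raise DegenerateInputError("infeasible distance script")
        frames = np.zeros((len(distances), 2, 3))
        frames[:, 1, 0] = distances
    else:
        frames = np.asarray(displacement_script, float)
        if frames.ndim != 3 or frames.size == 0:
            raise DegenerateInputError("infeasible displacement script")
    return Trajectory(frames=frames, frame_spacing=frame_spacing)


def brownian_trajectory(n_beads, n_frames, D, frame_spacing=10.0, seed=0,
                        n_static=4, static_extent=1.0) -> Trajectory:
    """Brownian walkers with diffusion coefficient D (nm²/ps) plus a static
    reference core (first ``n_static`` beads) usable as an alignment anchor.

    Per-axis increments are N(0, 2·D·Δt).
    """
    rng = np.random.default_rng(seed)
    frames = np.zeros((n_frames, n_static + n_beads, 3))
    # static core at fixed, non-degenerate positions
    core = rng.normal(scale=static_extent, size=(n_static, 3))
    frames[:, :n_static] = core
    sigma = np.sqrt(2.0 * D * frame_spacing)
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_beads, 3))
    walks = np.concatenate(
        [np.zeros((1, n_beads, 3)), np.cumsum(steps, axis=0)], axis=0)
    start = rng.normal(scale=static_extent, size=(n_beads, 3))
    frames[:, n_static:] = start + walks
    return Trajectory(frames=frames, frame_spacing=frame_spacing)
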
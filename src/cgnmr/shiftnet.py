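"""Secondary-shift prediction from bead geometry with a small dense network.

A residue is encoded as 32 features — a 22-value substitution-matrix
embedding of its type plus sine/cosine of five local angles — and
concatenated with its sequence neighbors into a 96-feature tripeptide
vector. A single ELU hidden layer of 26 units maps this to six secondary
shifts (N, C, CA, CB, H, HA) at once. Because every feature is a smooth
function of bead coordinates, predictions are differentiable and the
Jacobian w.r.t. coordinates is available for force evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from cgnmr.errors import DegenerateInputError, LayoutMismatchError
from cgnmr.geometry import (
    ANGLE_NAMES,
    angle_batch,
    angle_bead_indices,
    angle_gradient_batch,
    dihedral_batch,
    dihedral_gradient_batch,
    neighbor_position,
)
from cgnmr.io_formats import ATOM_TYPES, RESIDUE_CODES, STANDARD_RESIDUES

#: Version tag tying trained weights to the featurization convention.
FEATURE_LAYOUT_VERSION = "tripeptide-32x3-v1"

N_FEATURES = 96
N_HIDDEN = 26
N_OUT = 6
BLOCK = 32          # features per residue block
EMB = 22            # embedding slots per block; angle slots follow

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "CYO": "C", "PRC": "P",
}


def default_embedding_table() -> dict:
    """22-vector substitution-matrix embedding per residue code.

    The 20 standard rows come from BLOSUM62. CYO and PRC copy the CYS and
    PRO rows/columns, with the diagonal entry of each copy incremented by 1
    so the codes remain distinguishable. Deterministic and symmetric.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(RESIDUE_CODES)
    matrix = np.zeros((n, n))
    for i, ri in enumerate(RESIDUE_CODES):
        for j, rj in enumerate(RESIDUE_CODES):
            matrix[i, j] = blosum[_THREE_TO_ONE[ri]][_THREE_TO_ONE[rj]]
    for code in ("CYO", "PRC"):
        k = RESIDUE_CODES.index(code)
        matrix[k, k] += 1.0
    assert np.allclose(matrix, matrix.T)
    return {code: matrix[i].copy() for i, code in enumerate(RESIDUE_CODES)}


_DEFAULT_EMBEDDING = None


def get_embedding_table() -> dict:
    global _DEFAULT_EMBEDDING
    if _DEFAULT_EMBEDDING is None:
        _DEFAULT_EMBEDDING = default_embedding_table()
    return _DEFAULT_EMBEDDING


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))

def elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


@dataclass
class ShiftModel:
    """Weights of the 96→26→6 network plus per-atom tolerances ε (ppm)."""

    W_hidden: np.ndarray               # (26, 96)
    b_hidden: np.ndarray               # (26,)
    W_out: np.ndarray                  # (6, 26)
    b_out: np.ndarray                  # (6,)
    epsilon: np.ndarray = None         # (6,) ppm, ≥ 0
    layout: str = FEATURE_LAYOUT_VERSION

    def __post_init__(self):
        self.W_hidden = np.asarray(self.W_hidden, float)
        self.b_hidden = np.asarray(self.b_hidden, float)
        self.W_out = np.asarray(self.W_out, float)
        self.b_out = np.asarray(self.b_out, float)
        if self.epsilon is None:
            self.epsilon = np.zeros(N_OUT)
        self.epsilon = np.asarray(self.epsilon, float)
        if self.W_hidden.shape != (N_HIDDEN, N_FEATURES):
            raise ValueError(f"W_hidden must be {(N_HIDDEN, N_FEATURES)}")
        if self.W_out.shape != (N_OUT, N_HIDDEN):
            raise ValueError(f"W_out must be {(N_OUT, N_HIDDEN)}")
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be non-negative")

    def check_layout(self, layout=FEATURE_LAYOUT_VERSION):
        if self.layout != layout:
            raise LayoutMismatchError(
                f"model layout {self.layout!r} != featurizer {layout!r}")


def forward(model: ShiftModel, features) -> np.ndarray:
    """Predict six secondary shifts (ppm) from feature vector(s)."""
    f = np.asarray(features, float)
    if f.shape[-1] != N_FEATURES:
        raise ValueError(f"feature vector must have length {N_FEATURES}")
    h = elu(f @ model.W_hidden.T + model.b_hidden)
    return h @ model.W_out.T + model.b_out


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

class Featurizer:
    """Precomputed feature layout of one CGStructure.

    Caches, per residue, the global bead indices that realize each of the
    five angles, so that features — and their coordinate gradients — can be
    evaluated on arbitrary coordinate arrays without re-resolving topology.
    """

    def __init__(self, structure, embedding=None):
        self.structure = structure
        embedding = embedding or get_embedding_table()
        n = structure.n_residues
        self.embeddings = np.stack(
            [embedding[t] for t in structure.residue_types])
        # per angle name: residue positions where defined + bead index columns
        from cgnmr.geometry import ANGLE_BEADS

        self.angle_index = {}
        for name in ANGLE_NAMES:
            rows, cols = [], []
            for pos in range(n):
                idx = angle_bead_indices(structure, pos, name)
                if idx is not None:
                    rows.append(pos)
                    cols.append(idx)
            arity = len(ANGLE_BEADS[name])
            self.angle_index[name] = (
                np.array(rows, dtype=int),
                np.array(cols, dtype=int).reshape(len(rows), arity),
            )
        # neighbor positions (or -1) used to assemble tripeptide blocks
        self.prev = np.array(
            [p if (p := neighbor_position(structure, i, -1)) is not None else -1
             for i in range(n)])
        self.next = np.array(
            [p if (p := neighbor_position(structure, i, 1)) is not None else -1
             for i in range(n)])

    # -- angles ------------------------------------------------------------

    def angles(self, coords=None):
        """(n_res, 5) angle values with mask; masked entries are 0."""
        c = self.structure.coords if coords is None else np.asarray(coords, float)
        n = self.structure.n_residues
        values = np.zeros((n, 5))
        mask = np.zeros((n, 5), dtype=bool)
        for a, name in enumerate(ANGLE_NAMES):
            rows, cols = self.angle_index[name]
            if len(rows) == 0:
                continue
            pts = c[cols]                      # (m, 3 or 4, 3)
            if cols.shape[1] == 3:
                vals = angle_batch(pts[:, 0], pts[:, 1], pts[:, 2])
            else:
                vals = dihedral_batch(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
            values[rows, a] = vals
            mask[rows, a] = True
        return values, mask

    # -- features ----------------------------------------------------------

    def residue_blocks(self, coords=None):
        """(n_res, 32) per-residue blocks: embedding + masked sin/cos pairs."""
        values, mask = self.angles(coords)
        n = self.structure.n_residues
        blocks = np.zeros((n, BLOCK))
        blocks[:, :EMB] = self.embeddings
        sin = np.where(mask, np.sin(values), 0.0)
        cos = np.where(mask, np.cos(values), 0.0)
        blocks[:, EMB::2] = sin
        blocks[:, EMB + 1::2] = cos
        return blocks

    def features(self, coords=None):
        """(n_res, 96) tripeptide feature matrix."""
        blocks = self.residue_blocks(coords)
        n = self.structure.n_residues
        out = np.zeros((n, N_FEATURES))
        has_prev = self.prev >= 0
        has_next = self.next >= 0
        out[has_prev, :BLOCK] = blocks[self.prev[has_prev]]
        out[:, BLOCK:2 * BLOCK] = blocks
        out[has_next, 2 * BLOCK:] = blocks[self.next[has_next]]
        return out

    # -- gradients ---------------------------------------------------------

    def angle_force_accumulate(self, coords, dV_dangle, forces):
        """Add −dV/dx to ``forces`` given per-(residue, angle) dV/dangle.

        ``dV_dangle`` is (n_res, 5); entries at masked angles are ignored.
        """
        for a, name in enumerate(ANGLE_NAMES):
            rows, cols = self.angle_index[name]
            if len(rows) == 0:
                continue
            w = dV_dangle[rows, a]
            if not np.any(w):
                continue
            pts = coords[cols]
            if cols.shape[1] == 3:
                grads = angle_gradient_batch(pts[:, 0], pts[:, 1], pts[:, 2])
            else:
                grads = dihedral_gradient_batch(
                    pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
            for p, grad in enumerate(grads):
                np.add.at(forces, cols[:, p], -w[:, None] * grad)

    def dangle_from_dfeatures(self, coords, G):
        """Convert dV/dfeatures (n_res, 96) into dV/dangle (n_res, 5).

        Feature slot ``32·b + 22 + 2a`` of residue r is sin(angle a) of
        residue r + (b − 1); the chain rule through sin/cos lands on the
        owning residue's angle.
        """
        values, mask = self.angles(coords)
        sin = np.sin(values)
        cos = np.cos(values)
        n = self.structure.n_residues
        dV = np.zeros((n, 5))
        for b, owner_of in enumerate((self.prev,
                                      np.arange(n),
                                      self.next)):
            base = BLOCK * b + EMB
            valid = owner_of >= 0
            rows = np.nonzero(valid)[0]
            owners = owner_of[rows]
            for a in range(5):
                contrib = (G[rows, base + 2 * a] * cos[owners, a]
                           - G[rows, base + 2 * a + 1] * sin[owners, a])
                np.add.at(dV, (owners, a), contrib * mask[owners, a])
        return dV


def build_feature_vector(structure, pos, embedding=None) -> np.ndarray:
    """The 96-value tripeptide feature vector of residue ``pos``."""
    return Featurizer(structure, embedding).features()[pos]


def predict_shifts(model: ShiftModel, structure, featurizer=None, coords=None):
    """Predict secondary shifts for every residue of a structure.

    Returns a :class:`~cgnmr.io_formats.ShiftTable` (synthetic provenance);
    the CB prediction of GLY is masked.
    """
    from cgnmr.io_formats import ShiftTable

    model.check_layout()
    fz = featurizer or Featurizer(structure)
    preds = forward(model, fz.features(coords))
    table = ShiftTable(provenance="synthetic")
    cb = ATOM_TYPES.index("CB")
    for pos in range(structure.n_residues):
        for a, atom in enumerate(ATOM_TYPES):
            if a == cb and structure.residue_types[pos] == "GLY":
                continue
            table.set(structure.chain_ids[pos],
                      structure.residue_indices[pos], atom, preds[pos, a])
    return table


def prediction_matrix(model, featurizer, coords=None):
    """(n_res, 6) prediction matrix plus hidden pre-activations (n_res, 26)."""
    f = featurizer.features(coords)
    z = f @ model.W_hidden.T + model.b_hidden
    preds = elu(z) @ model.W_out.T + model.b_out
    return preds, z


def shift_coordinate_jacobian(model: ShiftModel, structure, pos,
                              featurizer=None) -> dict:
    """Partials of residue ``pos``'s six predictions w.r.t. bead coordinates.

    Returns {global bead index: (6, 3) array}. Only beads that enter the
    residue's feature vector (its own and its neighbors' angle beads)
    appear; masked angle slots contribute exactly zero.
    """
    model.check_layout()
    fz = featurizer or Featurizer(structure)
    coords = structure.coords
    f = fz.features()[pos]
    z = model.W_hidden @ f + model.b_hidden
    # d pred / d feature: (6, 96)
    J_feat = (model.W_out * elu_grad(z)) @ model.W_hidden

    values, mask = fz.angles()
    sin = np.sin(values)
    cos = np.cos(values)
    out = {}
    owners = (fz.prev[pos], pos, fz.next[pos])
    for b, owner in enumerate(owners):
        if owner < 0:
            continue
        base = BLOCK * b + EMB
        for a, name in enumerate(ANGLE_NAMES):
            if not mask[owner, a]:
                continue
            idx = angle_bead_indices(structure, owner, name)
            # d pred / d angle: (6,)
            dpred = (J_feat[:, base + 2 * a] * cos[owner, a]
                     - J_feat[:, base + 2 * a + 1] * sin[owner, a])
            pts = [coords[k] for k in idx]
            if len(idx) == 3:
                grads = angle_gradient_batch(*pts)
            else:
                grads = dihedral_gradient_batch(*pts)
            for k, grad in zip(idx, grads):
                out.setdefault(k, np.zeros((N_OUT, 3)))
                out[k] += dpred[:, None] * grad[None, :]
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Featurized examples partitioned by source structure."""

    features: np.ndarray               # (m, 96)
    targets: np.ndarray                # (m, 6) ppm
    target_mask: np.ndarray            # (m, 6) bool
    structure_ids: np.ndarray          # (m,)
    partition: np.ndarray              # (m,) in {"train","validation","test"}
    excluded_outliers: int = 0

    def subset(self, name):
        sel = self.partition == name
        return (self.features[sel], self.targets[sel], self.target_mask[sel])

    def check_disjoint(self):
        parts = {}
        for sid, p in zip(self.structure_ids, self.partition):
            parts.setdefault(sid, set()).add(p)
        mixed = [s for s, ps in parts.items() if len(ps) > 1]
        if mixed:
            raise ValueError(f"structures in multiple partitions: {mixed}")
        return True


def prepare_training_set(structures, shift_tables, random_coil,
                         reference_stats, fractions=(0.9, 0.05, 0.05),
                         seed=0, embedding=None) -> TrainingSet:
    """Featurize structures and raw shift tables into a partitioned set.

    ``reference_stats`` maps atom type → (mean, SD) of raw shifts; entries
    farther than 3 SD from the mean are discarded (strict inequality, so a
    value exactly at 3 SD is retained). Raw shifts are converted to
    secondary shifts with ``random_coil``. Partitioning is by structure so
    no structure contributes to two partitions.
    """
    rng = np.random.default_rng(seed)
    feats, targets, masks, sids = [], [], [], []
    excluded = 0
    for sid, (structure, table) in enumerate(zip(structures, shift_tables)):
        fz = Featurizer(structure, embedding)
        F = fz.features()
        for pos in range(structure.n_residues):
            y = np.zeros(N_OUT)
            m = np.zeros(N_OUT, dtype=bool)
            for a, atom in enumerate(ATOM_TYPES):
                raw = table.get(structure.chain_ids[pos],
                                structure.residue_indices[pos], atom)
                if raw is None:
                    continue
                mean, sd = reference_stats[atom]
                if abs(raw - mean) > 3.0 * sd:
                    excluded += 1
                    continue
                rtype = structure.residue_types[pos]
                coil_type = rtype if rtype in STANDARD_RESIDUES else \
                    {"CYO": "CYS", "PRC": "PRO"}[rtype]
                y[a] = raw - random_coil.get(coil_type, atom)
                m[a] = True
            if m.any():
                feats.append(F[pos])
                targets.append(y)
                masks.append(m)
                sids.append(sid)
    if not feats:
        raise DegenerateInputError("no training examples survive filtering")

    sids = np.array(sids)
    unique = np.unique(sids)
    order = rng.permutation(unique)
    n_train = int(round(fractions[0] * len(unique)))
    n_val = int(round(fractions[1] * len(unique)))
    assignment = {}
    for k, sid in enumerate(order):
        if k < n_train:
            assignment[sid] = "train"
        elif k < n_train + n_val:
            assignment[sid] = "validation"
        else:
            assignment[sid] = "test"
    partition = np.array([assignment[s] for s in sids])
    ts = TrainingSet(np.array(feats), np.array(targets),
                     np.array(masks), sids, partition, excluded)
    ts.check_disjoint()
    return ts


def _init_model(rng) -> ShiftModel:
    # Glorot-uniform initialization
    lim1 = np.sqrt(6.0 / (N_FEATURES + N_HIDDEN))
    lim2 = np.sqrt(6.0 / (N_HIDDEN + N_OUT))
    return ShiftModel(
        W_hidden=rng.uniform(-lim1, lim1, (N_HIDDEN, N_FEATURES)),
        b_hidden=np.zeros(N_HIDDEN),
        W_out=rng.uniform(-lim2, lim2, (N_OUT, N_HIDDEN)),
        b_out=np.zeros(N_OUT),
    )


def _masked_mse(model, F, Y, M):
    pred = forward(model, F)
    diff = np.where(M, pred - Y, 0.0)
    denom = max(M.sum(), 1)
    return float((diff ** 2).sum() / denom)


def train(training_set: TrainingSet, lr=0.001, patience=5, seed=0,
          batch_size=64, max_epochs=500, standardize=True) -> ShiftModel:
    """Fit a ShiftModel by Adam on masked mean-squared error.

    Early stopping: if the validation loss is not strictly lower than the
    best seen for ``patience`` consecutive epochs, training halts and the
    best-validation parameters are returned. Deterministic per seed.

    With ``standardize`` the features are whitened per column during
    optimization only; the scaling is folded back into the hidden-layer
    weights, so the returned model operates on raw features. Targets stay
    in raw ppm.
    """
    rng = np.random.default_rng(seed)
    F, Y, M = training_set.subset("train")
    Fv, Yv, Mv = training_set.subset("validation")
    if len(F) == 0 or len(Fv) == 0:
        raise DegenerateInputError("empty train or validation partition")

    if standardize:
        mu = F.mean(axis=0)
        scale = F.std(axis=0)
        scale[scale < 1e-8] = 1.0
        F = (F - mu) / scale
        Fv = (Fv - mu) / scale

    model = _init_model(rng)
    params = [model.W_hidden, model.b_hidden, model.W_out, model.b_out]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    t = 0

    best_loss = np.inf
    best_params = [p.copy() for p in params]
    stale = 0

    n = len(F)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            f, y, mask = F[idx], Y[idx], M[idx]
            z = f @ model.W_hidden.T + model.b_hidden
            h = elu(z)
            pred = h @ model.W_out.T + model.b_out
            diff = np.where(mask, pred - y, 0.0)
            denom = max(mask.sum(), 1)
            # gradients of sum(diff^2)/denom
            g_pred = 2.0 * diff / denom
            gW_out = g_pred.T @ h
            gb_out = g_pred.sum(axis=0)
            g_h = g_pred @ model.W_out
            g_z = g_h * elu_grad(z)
            gW_hidden = g_z.T @ f
            gb_hidden = g_z.sum(axis=0)
            grads = [gW_hidden, gb_hidden, gW_out, gb_out]
            if any(not np.all(np.isfinite(g)) for g in grads):
                raise DegenerateInputError(
                    f"divergent loss (NaN gradient) at epoch {epoch}")
            t += 1
            for p, g, m1, v1 in zip(params, grads, m_t, v_t):
                m1 += (1 - beta1) * (g - m1)
                v1 += (1 - beta2) * (g * g - v1)
                mhat = m1 / (1 - beta1 ** t)
                vhat = v1 / (1 - beta2 ** t)
                p -= lr * mhat / (np.sqrt(vhat) + adam_eps)

        val_loss = _masked_mse(model, Fv, Yv, Mv)
        if not np.isfinite(val_loss):
            raise DegenerateInputError(f"divergent loss at epoch {epoch}")
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = [p.copy() for p in params]
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break

    W_hidden, b_hidden, W_out, b_out = best_params
    if standardize:
        W_hidden = W_hidden / scale
        b_hidden = b_hidden - W_hidden @ mu
    return ShiftModel(W_hidden, b_hidden, W_out, b_out)


def evaluate(model: ShiftModel, test_set, store=False):
    """Per-atom RMSE (ppm) over a test partition; candidates for ε.

    ``test_set`` is a TrainingSet (its "test" partition is used) or a
    (features, targets, mask) triple. Atom types with zero targets get NaN.
    """
    if isinstance(test_set, TrainingSet):
        F, Y, M = test_set.subset("test")
    else:
        F, Y, M = test_set
    if len(F) == 0:
        raise DegenerateInputError("empty test set")
    pred = forward(model, F)
    rmse = np.full(N_OUT, np.nan)
    for a in range(N_OUT):
        sel = M[:, a]
        if sel.any():
            rmse[a] = np.sqrt(np.mean((pred[sel, a] - Y[sel, a]) ** 2))
    if store:
        model.epsilon = np.where(np.isnan(rmse), 0.0, rmse)
    return rmse
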
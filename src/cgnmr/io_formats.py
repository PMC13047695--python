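"""Domain types and readers/writers for every on-disk artifact.

Internal unit system is nm / ps / kJ·mol⁻¹ / ppm everywhere; the only unit
conversions happen at file boundaries (PDB files are in Å).

Dialects
--------
* CG PDB: bead name (``BB``, ``SC1``..``SC4``) in the atom-name column,
  residue names as standard 3-letter codes plus ``CYO`` (oxidized cysteine)
  and ``PRC`` (cis-proline). Trajectories are multi-model PDB.
* Shift tables: CSV with header ``chain,resid,atom,shift`` and an optional
  ``restype`` column (needed when subtracting random-coil values).
* Random-coil tables: CSV ``restype,atom,shift``.
* NOE tables: CSV ``chain_i,resid_i,atoms_i,chain_j,resid_j,atoms_j,d,r0,r1,r2``
  with "|"-separated atom names; an atom token may be ``resid:atom`` to
  reference a residue other than the row's.
* Mapping tables: CSV ``restype,atom,bead``.
* Model weights: JSON (documented key-value text format).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from cgnmr.errors import (
    DialectError,
    DuplicateKeyError,
    LayoutMismatchError,
    ModelFormatError,
    ParseError,
)

NM_PER_ANGSTROM = 0.1

#: The 20 standard residues in substitution-matrix order, plus oxidized
#: cysteine (CYO) and cis-proline (PRC).
STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
RESIDUE_CODES = STANDARD_RESIDUES + ("CYO", "PRC")

BEAD_NAMES = ("BB", "SC1", "SC2", "SC3", "SC4")

#: Backbone atom types for which shifts are predicted/restrained.
ATOM_TYPES = ("N", "C", "CA", "CB", "H", "HA")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class CGStructure:
    """A coarse-grained structure: typed beads grouped into residues.

    Residues are stored in file order; ``bead_residue[k]`` gives the
    0-based residue position of bead ``k``. Coordinates are in nm.
    """

    chain_ids: list
    residue_indices: np.ndarray        # (n_res,) 1-based PDB numbering
    residue_types: list                # (n_res,) 3-letter codes
    bead_names: list                   # (n_beads,)
    bead_residue: np.ndarray           # (n_beads,) residue position
    coords: np.ndarray                 # (n_beads, 3) nm

    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.bead_residue = np.asarray(self.bead_residue, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self._index = {
            (int(r), name): k
            for k, (r, name) in enumerate(zip(self.bead_residue, self.bead_names))
        }

    @property
    def n_residues(self) -> int:
        return len(self.residue_types)

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    def bead_index(self, res_pos: int, bead_name: str) -> Optional[int]:
        """Global bead index for (residue position, bead name), or None."""
        return self._index.get((int(res_pos), bead_name))

    def residue_position(self, chain_id: str, residue_index: int) -> int:
        """0-based position of a residue identified by chain and PDB index."""
        for pos, (c, r) in enumerate(zip(self.chain_ids, self.residue_indices)):
            if c == chain_id and r == residue_index:
                return pos
        raise KeyError(f"residue {chain_id}/{residue_index} not found")

    def with_coords(self, coords: np.ndarray) -> "CGStructure":
        """Copy of this structure with replaced coordinates."""
        return CGStructure(
            self.chain_ids, self.residue_indices, self.residue_types,
            self.bead_names, self.bead_residue, np.asarray(coords, float),
        )

    def validate(self):
        if not np.all(np.isfinite(self.coords)):
            raise DialectError("non-finite coordinates in CG structure")
        for pos, rtype in enumerate(self.residue_types):
            if rtype not in RESIDUE_CODES:
                raise DialectError(f"unknown residue type {rtype!r}")
            if self.bead_index(pos, "BB") is None:
                raise DialectError(f"residue position {pos} lacks a BB bead")
            if rtype == "GLY" and self.bead_index(pos, "SC1") is not None:
                raise DialectError("GLY carries a side-chain bead")
        for chain in set(self.chain_ids):
            idx = [r for c, r in zip(self.chain_ids, self.residue_indices)
                   if c == chain]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise DialectError(
                    f"residue indices not strictly increasing in chain {chain}")
        return self


@dataclass
class AtomisticStructure:
    """An all-atom structure with nm coordinates and unique atom keys."""

    chain_ids: list
    residue_indices: np.ndarray
    residue_types: list
    atom_names: list
    elements: list
    coords: np.ndarray

    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self._index = {}
        for k, key in enumerate(
                zip(self.chain_ids, self.residue_indices, self.atom_names)):
            key = (key[0], int(key[1]), key[2])
            if key in self._index:
                raise DuplicateKeyError(f"duplicate atom {key}")
            self._index[key] = k

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        key = (chain_id, int(residue_index), atom_name)
        if key not in self._index:
            raise KeyError(f"atom {key} not found")
        return self._index[key]


@dataclass
class Trajectory:
    """Time-ordered coordinate frames congruent with one CGStructure."""

    frames: np.ndarray                 # (n_frames, n_beads, 3) nm
    frame_spacing: float               # ps
    box: Optional[np.ndarray] = None   # (3,) nm
    topology: Optional[CGStructure] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_beads, 3)")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_spacing


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

@dataclass
class ShiftTable:
    """Per-residue, per-atom-type secondary chemical shifts in ppm."""

    entries: dict = field(default_factory=dict)  # (chain, resid, atom) -> ppm
    provenance: str = "experimental"             # or "synthetic"
    skipped_rows: int = 0

    def get(self, chain_id, residue_index, atom_type, default=None):
        return self.entries.get((chain_id, int(residue_index), atom_type), default)

    def set(self, chain_id, residue_index, atom_type, value):
        key = (chain_id, int(residue_index), atom_type)
        if key in self.entries:
            raise DuplicateKeyError(f"duplicate shift entry {key}")
        self.entries[key] = float(value)

    def __len__(self):
        return len(self.entries)


@dataclass
class RandomCoilTable:
    """(residue_type, atom_type) -> random-coil shift in ppm."""

    values: dict = field(default_factory=dict)

    def get(self, residue_type, atom_type):
        return self.values[(residue_type, atom_type)]

    def validate(self):
        missing = [
            (r, a) for r in STANDARD_RESIDUES for a in ATOM_TYPES
            if (r, a) not in self.values
        ]
        if missing:
            raise DialectError(f"random-coil table incomplete: missing {missing[:5]}")
        return self


@dataclass
class NOERecord:
    """One NOE signal: two atom groups, a distance and bounds (nm)."""

    group_i: list                      # [(chain, resid, atom_name), ...]
    group_j: list
    d: float
    r0: float
    r1: float
    r2: float
    unresolved: bool = False


@dataclass
class NOETable:
    records: list = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class MappingTable:
    """(residue_type, atom_name) -> bead_name. A function: one bead per atom."""

    entries: dict = field(default_factory=dict)

    def bead_for(self, residue_type, atom_name):
        key = (residue_type, atom_name)
        if key not in self.entries:
            raise KeyError(f"no mapping for {key}")
        return self.entries[key]


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def _atom_array_to_cg(array: bst.AtomArray) -> CGStructure:
    chain_ids, res_idx, res_types = [], [], []
    bead_names, bead_res = [], []
    current = None
    for k in range(array.array_length()):
        name = array.atom_name[k]
        if name not in BEAD_NAMES:
            raise DialectError(
                f"atom name {name!r} is not a bead name {BEAD_NAMES}")
        key = (str(array.chain_id[k]), int(array.res_id[k]))
        if key != current:
            current = key
            chain_ids.append(key[0])
            res_idx.append(key[1])
            res_types.append(str(array.res_name[k]))
        bead_names.append(name)
        bead_res.append(len(res_types) - 1)
    return CGStructure(
        chain_ids, np.array(res_idx), res_types, bead_names,
        np.array(bead_res), array.coord * NM_PER_ANGSTROM,
    )


def _atom_array_to_atomistic(array: bst.AtomArray) -> AtomisticStructure:
    return AtomisticStructure(
        [str(c) for c in array.chain_id],
        np.asarray(array.res_id, dtype=int),
        [str(r) for r in array.res_name],
        [str(a) for a in array.atom_name],
        [str(e) for e in array.element],
        array.coord * NM_PER_ANGSTROM,
    )


def read_structure(path, resolution="cg", all_models=False):
    """Read a PDB file as a CG or atomistic structure.

    With ``all_models=True`` a multi-model file yields a :class:`Trajectory`
    (CG only); otherwise the first model is returned. Coordinates are
    converted Å→nm.
    """
    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:  # biotite raises various subclasses
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    try:
        stack = pdb.get_structure()
    except Exception as exc:
        raise ParseError(f"malformed PDB records in {path}: {exc}") from exc
    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    first = stack[0]
    if resolution == "cg":
        structure = _atom_array_to_cg(first)
        if all_models:
            return Trajectory(
                frames=stack.coord * NM_PER_ANGSTROM,
                frame_spacing=1.0,
                topology=structure,
            )
        return structure
    elif resolution == "atomistic":
        if all_models:
            raise ValueError("all_models is only supported for CG structures")
        return _atom_array_to_atomistic(first)
    raise ValueError(f"unknown resolution {resolution!r}")


def _cg_to_atom_array(structure: CGStructure, coords=None) -> bst.AtomArray:
    n = structure.n_beads
    array = bst.AtomArray(n)
    res_pos = structure.bead_residue
    array.chain_id = np.array(
        [structure.chain_ids[r] for r in res_pos], dtype="U4")
    array.res_id = np.array(
        [structure.residue_indices[r] for r in res_pos], dtype=int)
    array.res_name = np.array(
        [structure.residue_types[r] for r in res_pos], dtype="U5")
    array.atom_name = np.array(structure.bead_names, dtype="U6")
    array.element = np.full(n, "C", dtype="U2")
    array.hetero = np.zeros(n, dtype=bool)
    c = structure.coords if coords is None else np.asarray(coords, float)
    array.coord = np.asarray(c / NM_PER_ANGSTROM, dtype=np.float32)
    return array


def write_structure(path, structure, coords=None):
    """Write a CGStructure (or Trajectory) as a (multi-model) PDB file."""
    pdb = PDBFile()
    if isinstance(structure, Trajectory):
        if structure.topology is None:
            raise ValueError("trajectory lacks a topology")
        arrays = [
            _cg_to_atom_array(structure.topology, frame)
            for frame in structure.frames
        ]
        pdb.set_structure(bst.stack(arrays))
    else:
        pdb.set_structure(_cg_to_atom_array(structure, coords))
    pdb.write(str(path))


def write_trajectory(path, trajectory):
    write_structure(path, trajectory)


def read_trajectory(path, frame_spacing=1.0):
    traj = read_structure(path, resolution="cg", all_models=True)
    traj.frame_spacing = frame_spacing
    return traj


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _restype_lookup(structure):
    lookup = {}
    if structure is not None:
        for c, r, t in zip(structure.chain_ids, structure.residue_indices,
                           structure.residue_types):
            lookup[(c, int(r))] = t
    return lookup


def read_shift_table(path, random_coil=None, structure=None) -> ShiftTable:
    """Read a CSV shift table, optionally converting raw→secondary shifts.

    When ``random_coil`` is given the stored value is raw − random-coil;
    the residue type is taken from a ``restype`` column or from
    ``structure``. Rows with unknown atom types are skipped (counted in
    ``skipped_rows``); duplicate keys raise.
    """
    df = pd.read_csv(path, dtype={"chain": str, "atom": str})
    required = {"chain", "resid", "atom", "shift"}
    if not required.issubset(df.columns):
        raise ParseError(f"shift table needs columns {sorted(required)}")
    lookup = _restype_lookup(structure)
    table = ShiftTable(provenance="experimental")
    skipped = 0
    for _, row in df.iterrows():
        atom = row["atom"]
        if atom not in ATOM_TYPES:
            skipped += 1
            continue
        value = float(row["shift"])
        if random_coil is not None:
            if "restype" in df.columns and isinstance(row.get("restype"), str):
                rtype = row["restype"]
            else:
                key = (row["chain"], int(row["resid"]))
                if key not in lookup:
                    raise ParseError(
                        f"cannot determine residue type for {key}; provide a "
                        "'restype' column or a structure")
                rtype = lookup[key]
            value -= random_coil.get(rtype, atom)
        table.set(row["chain"], int(row["resid"]), atom, value)
    if skipped:
        warnings.warn(f"skipped {skipped} shift rows with unknown atom types")
    table.skipped_rows = skipped
    return table


def write_shift_table(path, table: ShiftTable):
    rows = [
        {"chain": c, "resid": r, "atom": a, "shift": v}
        for (c, r, a), v in sorted(table.entries.items())
    ]
    pd.DataFrame(rows, columns=["chain", "resid", "atom", "shift"]).to_csv(
        path, index=False, float_format="%.6f")


def read_random_coil_table(path) -> RandomCoilTable:
    df = pd.read_csv(path, dtype={"restype": str, "atom": str})
    table = RandomCoilTable()
    for _, row in df.iterrows():
        key = (row["restype"], row["atom"])
        if key in table.values:
            raise DuplicateKeyError(f"duplicate random-coil entry {key}")
        table.values[key] = float(row["shift"])
    return table


DEFAULT_R2_PAD = 0.5  # nm added to r1 when r2 is absent


def _parse_group(chain, resid, atoms_field):
    group = []
    for token in str(atoms_field).split("|"):
        token = token.strip()
        if not token:
            continue
        if ":" in token:
            res_s, atom = token.split(":", 1)
            group.append((chain, int(res_s), atom))
        else:
            group.append((chain, int(resid), token))
    return group


def read_noe_table(path) -> NOETable:
    """Read a CSV NOE table; missing r0 → 0, missing r2 → r1 + 0.5 nm."""
    try:
        df = pd.read_csv(path, dtype={"chain_i": str, "chain_j": str})
    except pd.errors.EmptyDataError:
        return NOETable()
    if df.empty:
        return NOETable()
    table = NOETable()
    for k, row in df.iterrows():
        if "r1" not in df.columns or pd.isna(row["r1"]):
            raise ParseError("NOE record lacks r1", line=k + 2)
        r1 = float(row["r1"])
        r0 = 0.0 if ("r0" not in df.columns or pd.isna(row["r0"])) else float(row["r0"])
        r2 = (r1 + DEFAULT_R2_PAD
              if ("r2" not in df.columns or pd.isna(row["r2"]))
              else float(row["r2"]))
        if not (r0 <= r1 <= r2):
            raise ParseError(f"NOE bounds violate r0<=r1<=r2: {(r0, r1, r2)}",
                             line=k + 2)
        gi = _parse_group(row["chain_i"], row["resid_i"], row["atoms_i"])
        gj = _parse_group(row["chain_j"], row["resid_j"], row["atoms_j"])
        if not gi or not gj:
            raise ParseError("empty atom group in NOE record", line=k + 2)
        table.records.append(NOERecord(gi, gj, float(row["d"]), r0, r1, r2))
    return table


def write_noe_table(path, table: NOETable):
    rows = []
    for rec in table.records:
        rows.append({
            "chain_i": rec.group_i[0][0], "resid_i": rec.group_i[0][1],
            "atoms_i": "|".join(f"{r}:{a}" if r != rec.group_i[0][1] else a
                                for _, r, a in rec.group_i),
            "chain_j": rec.group_j[0][0], "resid_j": rec.group_j[0][1],
            "atoms_j": "|".join(f"{r}:{a}" if r != rec.group_j[0][1] else a
                                for _, r, a in rec.group_j),
            "d": rec.d, "r0": rec.r0, "r1": rec.r1, "r2": rec.r2,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mapping_table(path) -> MappingTable:
    df = pd.read_csv(path, dtype=str)
    table = MappingTable()
    for _, row in df.iterrows():
        key = (row["restype"], row["atom"])
        if key in table.entries and table.entries[key] != row["bead"]:
            raise DuplicateKeyError(f"atom {key} maps to two beads")
        table.entries[key] = row["bead"]
    return table


def write_mapping_table(path, table: MappingTable):
    rows = [{"restype": r, "atom": a, "bead": b}
            for (r, a), b in sorted(table.entries.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model weights
# ---------------------------------------------------------------------------

def save_model(path, model):
    """Serialize a ShiftModel to the JSON key-value weight format."""
    payload = {
        "format": "cgnmr-shift-model",
        "layout": model.layout,
        "W_hidden": model.W_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "W_out": model.W_out.tolist(),
        "b_out": model.b_out.tolist(),
        "epsilon": model.epsilon.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path, expected_layout=None):
    """Load a ShiftModel; refuses layout mismatches, tolerates missing ε."""
    from cgnmr.shiftnet import ShiftModel, FEATURE_LAYOUT_VERSION

    try:
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "cgnmr-shift-model":
            raise ModelFormatError(f"{path} is not a shift-model file")
        layout = payload["layout"]
        expected = expected_layout or FEATURE_LAYOUT_VERSION
        if layout != expected:
            raise LayoutMismatchError(
                f"model layout {layout!r} != featurizer layout {expected!r}")
        if "epsilon" in payload:
            epsilon = np.asarray(payload["epsilon"], dtype=float)
        else:
            warnings.warn(f"{path} lacks epsilon; defaulting to 0")
            epsilon = np.zeros(6)
        return ShiftModel(
            W_hidden=np.asarray(payload["W_hidden"], dtype=float),
            b_hidden=np.asarray(payload["b_hidden"], dtype=float),
            W_out=np.asarray(payload["W_out"], dtype=float),
            b_out=np.asarray(payload["b_out"], dtype=float),
            epsilon=epsilon,
            layout=layout,
        )
    except (LayoutMismatchError, ModelFormatError):
        raise
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"corrupted model file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"config {path} must be a YAML mapping")
    return cfg
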
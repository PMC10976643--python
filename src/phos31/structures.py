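"""Structure and trajectory data model.

A :class:`Snapshot` is one frame of a molecular system (coordinates in Å,
atom/residue metadata); an :class:`Ensemble` is an ordered series of
snapshots sharing one topology. PDB (single- and multi-model) I/O is
delegated to biotite; XYZ is read and written directly because the comment
line carries the frame time, a convention specific to this package.

Coordinates are assumed unwrapped/whole; periodic-boundary images are not
handled and wrapped trajectories are unsupported.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Snapshot",
    "Ensemble",
    "PhosphorusMap",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "map_phosphorus_topology",
    "infer_bonds",
    "covalent_topology",
    "extract_snapshots",
    "read_charge_table",
    "write_charge_table",
    "COVALENT_RADII",
    "DEFAULT_CHARGE_TABLE",
    "DEFAULT_NAMING_DIALECT",
    "STATES",
]

STATES = ("ATP", "ADP", "ADP.Pi")

# Cordero covalent radii, Å (subset relevant to nucleotide/protein/solvent
# systems plus common buffer ions).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "P": 1.07, "S": 1.05,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "NA": 1.66, "MG": 1.41, "K": 2.03, "CA": 1.76, "MN": 1.39,
    "FE": 1.32, "ZN": 1.22, "SE": 1.20,
}

VALID_ELEMENTS = frozenset(COVALENT_RADII) | frozenset(
    "HE LI BE B NE AL SI AR SC TI V CR CO NI CU GA GE AS KR RB SR".split()
)

# Formal charges by residue identity (chemical species, not per-atom).
DEFAULT_CHARGE_TABLE: dict[str, int] = {
    "ATP": -4, "ADP": -3, "PO4": -2, "HPO4": -2,
    "MG": 2, "NA": 1, "K": 1, "CL": -1, "HOH": 0, "WAT": 0, "SOL": 0,
    "ARG": 1, "LYS": 1, "HIS": 0, "ASP": -1, "GLU": -1,
    "ALA": 0, "GLY": 0, "SER": 0, "THR": 0, "CYS": 0, "VAL": 0, "LEU": 0,
    "ILE": 0, "MET": 0, "PRO": 0, "PHE": 0, "TYR": 0, "TRP": 0, "ASN": 0,
    "GLN": 0,
}

# Canonical nucleus/oxygen labels -> atom names (PDB v3 nucleotide naming).
# Alternative dialects (e.g. O5* for O5') are supplied as a mapping of the
# same shape without code changes.
DEFAULT_NAMING_DIALECT: dict[str, str] = {
    "P_alpha": "PA", "P_beta": "PB", "P_gamma": "PG",
    "O_5'": "O5'",
    "O_1A": "O1A", "O_2A": "O2A", "O_3A": "O3A",
    "O_1B": "O1B", "O_2B": "O2B", "O_3B": "O3B",
    "O_1G": "O1G", "O_2G": "O2G", "O_3G": "O3G",
}

#: residue names recognised as the detached inorganic phosphate
PI_RESIDUE_NAMES = ("PO4", "HPO", "PI")

#: labels present per nucleotide state
STATE_LABELS: dict[str, tuple[str, ...]] = {
    "ATP": (
        "P_alpha", "P_beta", "P_gamma", "O_5'",
        "O_1A", "O_2A", "O_3A", "O_1B", "O_2B", "O_3B",
        "O_1G", "O_2G", "O_3G",
    ),
    "ADP": (
        "P_alpha", "P_beta", "O_5'",
        "O_1A", "O_2A", "O_3A", "O_1B", "O_2B", "O_3B",
    ),
    "ADP.Pi": (
        "P_alpha", "P_beta", "P_i", "O_5'",
        "O_1A", "O_2A", "O_3A", "O_1B", "O_2B", "O_3B",
    ),
}

#: phosphorus nuclei per state, canonical (alpha -> gamma -> Pi) order
STATE_NUCLEI: dict[str, tuple[str, ...]] = {
    "ATP": ("P_alpha", "P_beta", "P_gamma"),
    "ADP": ("P_alpha", "P_beta"),
    "ADP.Pi": ("P_alpha", "P_beta", "P_i"),
}


class StructureError(ValueError):
    """Malformed structure file or inconsistent structural data."""


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership and position (Å)."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    formal_charge_group: str = ""

    def __post_init__(self) -> None:
        if self.element.upper() not in VALID_ELEMENTS:
            raise StructureError(f"unknown element symbol {self.element!r}")
        pos = np.asarray(self.position, float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.index}: non-finite position")


class Snapshot:
    """One frame: parallel per-atom arrays plus a frame index and time."""

    def __init__(
        self,
        frame_index: int,
        time_ns: float,
        names: Sequence[str],
        elements: Sequence[str],
        res_names: Sequence[str],
        res_ids: Sequence[int],
        chain_ids: Sequence[str],
        coords: np.ndarray,
    ) -> None:
        if time_ns < 0:
            raise StructureError("time_ns must be non-negative")
        self.frame_index = int(frame_index)
        self.time_ns = float(time_ns)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray([e.upper() for e in elements], dtype=object)
        self.res_names = np.asarray(res_names, dtype=object)
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.coords = np.asarray(coords, dtype=float)
        n = len(self.names)
        if self.coords.shape != (n, 3):
            raise StructureError("coordinate array shape mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        unknown = set(self.elements) - VALID_ELEMENTS
        if unknown:
            raise StructureError(f"unknown element symbol(s): {sorted(unknown)}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            index=i,
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_name=str(self.res_names[i]),
            residue_id=int(self.res_ids[i]),
            chain_id=str(self.chain_ids[i]),
            position=self.coords[i].copy(),
            formal_charge_group=str(self.res_names[i]),
        )

    def __iter__(self) -> Iterator[AtomRecord]:
        return (self.atom(i) for i in range(self.n_atoms))

    def __len__(self) -> int:
        return self.n_atoms

    def residue_keys(self) -> np.ndarray:
        """(chain_id, residue_id) key per atom, as an object array of tuples."""
        out = np.empty(self.n_atoms, dtype=object)
        for i, (c, r) in enumerate(zip(self.chain_ids, self.res_ids)):
            out[i] = (str(c), int(r))
        return out

    def with_coords(self, coords: np.ndarray, frame_index: int | None = None,
                    time_ns: float | None = None) -> "Snapshot":
        return Snapshot(
            self.frame_index if frame_index is None else frame_index,
            self.time_ns if time_ns is None else time_ns,
            self.names, self.elements, self.res_names, self.res_ids,
            self.chain_ids, coords,
        )


class Ensemble:
    """Ordered series of snapshots sharing one topology.

    ``topology`` is an undirected bond list of (i, j) atom-index pairs with
    i < j. ``metadata`` carries the nucleotide state label (ATP | ADP |
    ADP.Pi) and environment label (solution | pocket) when known.
    """

    def __init__(
        self,
        snapshots: Sequence[Snapshot],
        topology: Sequence[tuple[int, int]] | None = None,
        metadata: Mapping[str, object] | None = None,
    ) -> None:
        snapshots = list(snapshots)
        if not snapshots:
            raise StructureError("ensemble must contain at least one snapshot")
        n = snapshots[0].n_atoms
        for k, s in enumerate(snapshots):
            if s.n_atoms != n:
                raise StructureError(
                    f"frame {k}: atom count {s.n_atoms} != {n} of frame 0"
                )
        idx = [s.frame_index for s in snapshots]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError("frame_index must be strictly increasing")
        self.snapshots = snapshots
        self.topology = normalize_bonds(topology or [], n)
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[Snapshot]:
        return iter(self.snapshots)

    def __getitem__(self, k: int) -> Snapshot:
        return self.snapshots[k]

    @property
    def n_atoms(self) -> int:
        return self.snapshots[0].n_atoms

    def times(self) -> np.ndarray:
        return np.array([s.time_ns for s in self.snapshots])


def normalize_bonds(
    bonds: Sequence[tuple[int, int]], n_atoms: int
) -> list[tuple[int, int]]:
    """Canonicalise an undirected bond list: i < j, deduplicated, sorted."""
    out = set()
    for i, j in bonds:
        i, j = int(i), int(j)
        if i == j:
            raise StructureError(f"self-bond on atom {i}")
        if not (0 <= i < n_atoms and 0 <= j < n_atoms):
            raise StructureError(f"bond ({i},{j}) outside atom range")
        out.add((min(i, j), max(i, j)))
    return sorted(out)


def bond_neighbors(bonds: Sequence[tuple[int, int]], n_atoms: int) -> list[set[int]]:
    nb: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        nb[i].add(j)
        nb[j].add(i)
    return nb


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _guess_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    raise StructureError(f"cannot infer format from suffix {suffix!r}")


def _element_from_name(name: str) -> str:
    """Fallback element guess from an atom name (PDB files lacking the
    element column)."""
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        raise StructureError(f"cannot infer element from atom name {name!r}")
    two = stripped[:2].upper()
    if two in VALID_ELEMENTS and two in ("MG", "NA", "CL", "BR", "FE", "ZN",
                                         "MN", "SE", "CA", "K"):
        return two
    return stripped[0].upper()


def _snapshot_from_atom_array(arr, frame_index: int, time_ns: float) -> Snapshot:
    elements = []
    for el, nm in zip(arr.element, arr.atom_name):
        el = str(el).strip().upper()
        elements.append(el if el else _element_from_name(str(nm)))
    return Snapshot(
        frame_index=frame_index,
        time_ns=time_ns,
        names=[str(x) for x in arr.atom_name],
        elements=elements,
        res_names=[str(x) for x in arr.res_name],
        res_ids=arr.res_id.astype(int),
        chain_ids=[str(x) for x in arr.chain_id],
        coords=np.asarray(arr.coord, float),
    )


def _atom_array_from_snapshot(snapshot: Snapshot):
    import biotite.structure as struc

    arr = struc.AtomArray(snapshot.n_atoms)
    arr.coord = np.asarray(snapshot.coords, float)
    arr.atom_name = snapshot.names.astype("U6")
    arr.res_name = snapshot.res_names.astype("U5")
    arr.res_id = snapshot.res_ids
    arr.chain_id = snapshot.chain_ids.astype("U4")
    # biotite capitalises e.g. MG -> 'MG'; keep upper-case symbols
    arr.element = snapshot.elements.astype("U2")
    arr.hetero = np.ones(snapshot.n_atoms, bool)
    return arr


def _read_xyz_frames(path: str | Path, timestep_ns: float) -> list[Snapshot]:
    frames: list[Snapshot] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise StructureError(
                f"{path}: line {pos + 1}: expected atom count"
            ) from exc
        if pos + 1 + n >= len(lines) + 1 and n > 0:
            raise StructureError(f"{path}: truncated frame at line {pos + 1}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        time_ns = frame_index * timestep_ns
        if "t=" in comment:
            try:
                time_ns = float(comment.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        elements, coords = [], []
        for k in range(n):
            lineno = pos + 2 + k
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise StructureError(f"{path}: line {lineno + 1}: malformed XYZ record")
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError as exc:
                raise StructureError(
                    f"{path}: line {lineno + 1}: malformed coordinate"
                ) from exc
            elements.append(parts[0].upper())
            coords.append(xyz)
        frames.append(
            Snapshot(
                frame_index=frame_index,
                time_ns=time_ns,
                names=[f"{el}{i + 1}" for i, el in enumerate(elements)],
                elements=elements,
                res_names=["UNK"] * n,
                res_ids=[1] * n,
                chain_ids=["A"] * n,
                coords=np.array(coords, float).reshape(n, 3),
            )
        )
        frame_index += 1
        pos += 2 + n
    if not frames:
        raise StructureError(f"{path}: no frames found")
    return frames


def read_structure(path: str | Path, format: str | None = None) -> Snapshot:
    """Read a single-frame structure (PDB or XYZ) into a Snapshot.

    Multi-model/multi-frame files are rejected with a pointer to
    :func:`read_trajectory`. XYZ atoms are assigned a single synthetic
    residue (UNK/1/A) since the format carries no residue information.
    """
    fmt = (format or _guess_format(path)).lower()
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        if pdb.get_model_count() > 1:
            raise StructureError(
                f"{path} contains {pdb.get_model_count()} MODEL blocks; "
                "use read_trajectory for multi-model files"
            )
        arr = pdb.get_structure(model=1)
        return _snapshot_from_atom_array(arr, frame_index=0, time_ns=0.0)
    if fmt == "xyz":
        frames = _read_xyz_frames(path, timestep_ns=1.0)
        if len(frames) > 1:
            raise StructureError(
                f"{path} contains {len(frames)} frames; use read_trajectory"
            )
        return frames[0]
    raise StructureError(f"unsupported format {fmt!r}")


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    timestep_ns: float = 1.0,
    metadata: Mapping[str, object] | None = None,
) -> Ensemble:
    """Read a multi-model PDB or multi-frame XYZ file into an Ensemble.

    Frame times are ``frame_index * timestep_ns`` unless the XYZ comment
    line carries an explicit ``t=<ns>`` tag. Every frame must have the same
    atom count; a mismatch is reported with the offending frame number.
    """
    fmt = (format or _guess_format(path)).lower()
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        frames = []
        n_atoms = None
        for m in range(1, n_models + 1):
            arr = pdb.get_structure(model=m)
            if n_atoms is None:
                n_atoms = arr.array_length()
            elif arr.array_length() != n_atoms:
                raise StructureError(
                    f"{path}: frame {m - 1} has {arr.array_length()} atoms, "
                    f"expected {n_atoms}"
                )
            frames.append(
                _snapshot_from_atom_array(
                    arr, frame_index=m - 1, time_ns=(m - 1) * timestep_ns
                )
            )
    elif fmt == "xyz":
        frames = _read_xyz_frames(path, timestep_ns=timestep_ns)
        n_atoms = frames[0].n_atoms
        for s in frames:
            if s.n_atoms != n_atoms:
                raise StructureError(
                    f"{path}: frame {s.frame_index} has {s.n_atoms} atoms, "
                    f"expected {n_atoms}"
                )
    else:
        raise StructureError(f"unsupported format {fmt!r}")
    return Ensemble(frames, metadata=metadata)


def write_structure(snapshot: Snapshot, path: str | Path,
                    format: str | None = None) -> None:
    """Write one Snapshot as PDB or XYZ (coordinates to format precision)."""
    fmt = (format or _guess_format(path)).lower()
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile()
        pdb.set_structure(_atom_array_from_snapshot(snapshot))
        pdb.write(str(path))
    elif fmt == "xyz":
        _write_xyz([snapshot], path)
    else:
        raise StructureError(f"unsupported format {fmt!r}")


def write_trajectory(ensemble: Ensemble, path: str | Path,
                     format: str | None = None) -> None:
    fmt = (format or _guess_format(path)).lower()
    if fmt == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        arrays = [_atom_array_from_snapshot(s) for s in ensemble]
        pdb = PDBFile()
        pdb.set_structure(struc.stack(arrays))
        pdb.write(str(path))
    elif fmt == "xyz":
        _write_xyz(list(ensemble), path)
    else:
        raise StructureError(f"unsupported format {fmt!r}")


def _write_xyz(frames: Sequence[Snapshot], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in frames:
            fh.write(f"{s.n_atoms}\n")
            fh.write(f"frame {s.frame_index} t= {s.time_ns:.6f} ns\n")
            for el, xyz in zip(s.elements, s.coords):
                fh.write(
                    f"{el:<2s} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}\n"
                )


# ---------------------------------------------------------------------------
# phosphorus-backbone mapping
# ---------------------------------------------------------------------------

class PhosphorusMap(dict):
    """Canonical nucleus/oxygen label -> atom index for one state.

    Keys: P_alpha, P_beta, P_gamma, P_i and the backbone oxygen labels
    (O_5', O_1A ... O_3G), as far as the state possesses them. ADP lacks
    the gamma phosphate; in ADP.Pi the inorganic phosphate is a separate
    residue whose phosphorus maps to P_i.
    """

    def __init__(self, mapping: Mapping[str, int], state: str):
        super().__init__(mapping)
        self.state = state

    @property
    def nuclei(self) -> tuple[str, ...]:
        return tuple(l for l in STATE_NUCLEI[self.state] if l in self)


def map_phosphorus_topology(
    snapshot: Snapshot,
    state: str,
    naming_dialect: Mapping[str, str] | None = None,
) -> PhosphorusMap:
    """Resolve the canonical phosphate-backbone labels of ``state`` to atom
    indices, using a configurable atom-name dialect (default: PDB v3)."""
    if state not in STATES:
        raise StructureError(f"unknown state {state!r}; expected one of {STATES}")
    dialect = dict(DEFAULT_NAMING_DIALECT)
    if naming_dialect:
        dialect.update(naming_dialect)

    want = STATE_LABELS[state]
    # candidate nucleotide residue: the one containing the P_alpha atom name
    pa_name = dialect["P_alpha"]
    nuc_hits = [
        (str(c), int(r))
        for c, r, nm in zip(snapshot.chain_ids, snapshot.res_ids, snapshot.names)
        if str(nm) == pa_name
    ]
    if not nuc_hits:
        raise StructureError(
            f"no nucleotide found: atom {pa_name!r} (P_alpha) absent"
        )
    if len(set(nuc_hits)) > 1:
        raise StructureError(
            f"multiple residues contain atom {pa_name!r}: {sorted(set(nuc_hits))}"
        )
    nuc_key = nuc_hits[0]

    keys = snapshot.residue_keys()
    mapping: dict[str, int] = {}
    unresolved: list[str] = []
    for label in want:
        if label == "P_i":
            continue
        name = dialect[label]
        idx = [
            i for i in range(snapshot.n_atoms)
            if keys[i] == nuc_key and str(snapshot.names[i]) == name
        ]
        if len(idx) != 1:
            unresolved.append(label)
            continue
        mapping[label] = idx[0]

    if state == "ADP.Pi":
        pi_idx = [
            i for i in range(snapshot.n_atoms)
            if str(snapshot.res_names[i]) in PI_RESIDUE_NAMES
            and str(snapshot.elements[i]) == "P"
        ]
        if len(pi_idx) != 1:
            unresolved.append("P_i")
        else:
            mapping["P_i"] = pi_idx[0]

    if unresolved:
        raise StructureError(
            f"state {state}: unresolved canonical labels {unresolved}"
        )
    for label, i in mapping.items():
        expected = "P" if label.startswith("P_") else "O"
        if str(snapshot.elements[i]) != expected:
            raise StructureError(
                f"label {label} maps to element {snapshot.elements[i]}, "
                f"expected {expected}"
            )
    return PhosphorusMap(mapping, state)


# ---------------------------------------------------------------------------
# bond inference and snapshot extraction
# ---------------------------------------------------------------------------

def infer_bonds(
    snapshot: Snapshot,
    radii_table: Mapping[str, float] | None = None,
    tolerance: float = 0.4,
) -> list[tuple[int, int]]:
    """Distance-based covalent bond inference.

    A pair (i, j) is bonded iff |r_i - r_j| <= R_i + R_j + tolerance, with
    R the per-element covalent radius. Returns a canonical undirected bond
    list (i < j, sorted); an empty list is valid.
    """
    radii = dict(COVALENT_RADII)
    if radii_table:
        radii.update({k.upper(): float(v) for k, v in radii_table.items()})
    try:
        r = np.array([radii[str(e)] for e in snapshot.elements])
    except KeyError as exc:
        raise StructureError(f"no covalent radius for element {exc}") from None
    tree = cKDTree(snapshot.coords)
    rmax = 2.0 * r.max() + tolerance
    bonds = []
    for i, j in tree.query_pairs(rmax):
        d = np.linalg.norm(snapshot.coords[i] - snapshot.coords[j])
        if d <= r[i] + r[j] + tolerance:
            bonds.append((min(i, j), max(i, j)))
    return sorted(bonds)


def covalent_topology(snapshot: Snapshot,
                      tolerance: float = 0.4) -> list[tuple[int, int]]:
    """Covalent bond list for a solvated/pocket system.

    Distance-inferred bonds restricted to what is covalent in such
    systems: bonds within one residue/molecule plus peptide C-N bonds
    between consecutive protein residues on one chain. Close
    inter-molecular contacts (metal coordination, hydrogen-bonding
    geometries) are excluded — plain distance inference would misread
    them as bonds.
    """
    keys = snapshot.residue_keys()
    out = []
    for i, j in infer_bonds(snapshot, tolerance=tolerance):
        if keys[i] == keys[j]:
            out.append((i, j))
            continue
        same_chain = keys[i][0] == keys[j][0]
        adjacent = abs(keys[i][1] - keys[j][1]) == 1
        names = {str(snapshot.names[i]), str(snapshot.names[j])}
        if same_chain and adjacent and names == {"C", "N"}:
            out.append((i, j))
    return out


def extract_snapshots(ensemble: Ensemble, interval_ns: float) -> Ensemble:
    """Evenly spaced frame extraction.

    For each multiple of ``interval_ns`` starting at t=0, the earliest frame
    at or after that time is kept. Extraction at the frame spacing is the
    identity, and re-extraction at the same interval is idempotent.
    """
    if interval_ns <= 0:
        raise StructureError("interval_ns must be positive")
    times = ensemble.times()
    if len(times) > 1:
        spacing = float(np.min(np.diff(times)))
        if interval_ns < spacing - 1e-12:
            raise StructureError(
                f"interval {interval_ns} ns is below the frame spacing "
                f"{spacing} ns"
            )
    picked: list[int] = []
    t_max = float(times[-1])
    k = 0
    eps = 1e-9
    while k * interval_ns <= t_max + eps:
        target = k * interval_ns
        idx = int(np.searchsorted(times, target - eps, side="left"))
        if idx < len(times) and (not picked or idx > picked[-1]):
            picked.append(idx)
        k += 1
    return Ensemble(
        [ensemble.snapshots[i] for i in picked],
        topology=ensemble.topology,
        metadata=ensemble.metadata,
    )


# ---------------------------------------------------------------------------
# charge table
# ---------------------------------------------------------------------------

def read_charge_table(path: str | Path) -> dict[str, int]:
    """Two-column delimited text: residue_name, integer formal charge.

    Comma or whitespace separated; ``#`` starts a comment.
    """
    table: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise StructureError(f"{path}: line {lineno}: expected 2 columns")
            try:
                table[parts[0].upper()] = int(parts[1])
            except ValueError as exc:
                raise StructureError(
                    f"{path}: line {lineno}: charge must be an integer"
                ) from exc
    return table


def write_charge_table(table: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue_name formal_charge\n")
        for name, q in table.items():
            fh.write(f"{name} {int(q)}\n")
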
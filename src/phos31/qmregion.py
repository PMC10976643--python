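"""QM-region carving with electrostatic embedding bookkeeping.

The quantum region is selected by a trajectory-union distance rule: a
residue/molecule belongs to the QM region iff any of its atoms comes within
the cutoff (inclusive) of any core atom — the phosphate backbone plus the
five-membered sugar ring — in any frame of the ensemble. Membership is
fixed ("static") from that union; only link-atom positions are recomputed
per snapshot. Boundary cuts sever only nonpolar C-C bonds: an isolated
member amino acid contributes its side chain (cut C_beta-C_alpha); runs of
consecutive member residues are cut at C_alpha-C_carbonyl bonds of the
backbone, keeping the peptide groups flanking the run intact on the QM
side. Hydrogen link atoms saturate each cut at a fixed distance along the
cut bond. The total QM charge of each snapshot is the integer sum of the
member units' formal charges; link atoms contribute zero.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import (
    DEFAULT_CHARGE_TABLE,
    Ensemble,
    PhosphorusMap,
    Snapshot,
    StructureError,
    bond_neighbors,
)

__all__ = [
    "QMRegionConfig",
    "QMRegionSpec",
    "core_atom_indices",
    "select_qm_union",
    "plan_boundary_cuts",
    "place_link_atoms",
    "compute_qm_charge",
    "converge_qm_size",
    "ConvergenceReport",
    "export_qm_region",
]

SUGAR_RING_NAMES = ("C1'", "C2'", "C3'", "C4'", "O4'")
BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclasses.dataclass(frozen=True)
class QMRegionConfig:
    """Distance cutoff (Å) for the union rule and the link-atom bond length."""

    cutoff_A: float = 3.8
    link_bond_length_A: float = 1.09
    core_labels: tuple[str, ...] = ()  # empty -> phosphate backbone + sugar ring

    def __post_init__(self) -> None:
        if self.cutoff_A <= 0:
            raise ValueError("cutoff_A must be positive")
        if self.link_bond_length_A <= 0:
            raise ValueError("link_bond_length_A must be positive")


@dataclasses.dataclass
class QMRegionSpec:
    """The carved quantum region.

    member_units: (chain_id, residue_id, residue_name) of every QM
    residue/molecule, in file order. boundary_cuts: (qm_atom, mm_atom)
    atom-index pairs. qm_atom_indices: the atom-level QM set (member atoms
    after backbone trimming at cuts). total_charge: per-snapshot integer
    charges (one per frame of the ensemble the spec was built from).
    """

    member_units: list[tuple[str, int, str]]
    boundary_cuts: list[tuple[int, int]]
    qm_atom_indices: np.ndarray
    total_charge: list[int] = dataclasses.field(default_factory=list)
    cutoff_A: float = 3.8

    def member_keys(self) -> set[tuple[str, int]]:
        return {(c, r) for c, r, _ in self.member_units}


def core_atom_indices(
    snapshot: Snapshot, pmap: PhosphorusMap,
    core_labels: Sequence[str] = (),
) -> np.ndarray:
    """Atom indices of the selection core.

    Default core: every mapped phosphorus/oxygen label of the phosphate
    backbone plus the sugar-ring atoms (C1'-C4', O4') of the nucleotide
    residue. Adenine base atoms are excluded. A custom label set may be
    supplied via ``core_labels`` (canonical labels and/or atom names).
    """
    idx: set[int] = set()
    if core_labels:
        names = set(core_labels)
        for label in names & set(pmap.keys()):
            idx.add(int(pmap[label]))
        plain = names - set(pmap.keys())
        if plain:
            nuc = _nucleotide_key(snapshot, pmap)
            keys = snapshot.residue_keys()
            for i in range(snapshot.n_atoms):
                if keys[i] == nuc and str(snapshot.names[i]) in plain:
                    idx.add(i)
    else:
        idx.update(int(i) for i in pmap.values())
        nuc = _nucleotide_key(snapshot, pmap)
        keys = snapshot.residue_keys()
        for i in range(snapshot.n_atoms):
            if keys[i] == nuc and str(snapshot.names[i]) in SUGAR_RING_NAMES:
                idx.add(i)
    if not idx:
        raise StructureError("empty core selection")
    return np.array(sorted(idx), int)


def _nucleotide_key(snapshot: Snapshot, pmap: PhosphorusMap) -> tuple[str, int]:
    i = pmap["P_alpha"]
    return (str(snapshot.chain_ids[i]), int(snapshot.res_ids[i]))


def select_qm_union(
    ensemble: Ensemble,
    pmap: PhosphorusMap,
    config: QMRegionConfig = QMRegionConfig(),
) -> QMRegionSpec:
    """Union-over-frames QM membership at residue/molecule granularity.

    A unit is a member iff any of its atoms lies within ``cutoff_A``
    (inclusive, <=) of any core atom in any snapshot. The nucleotide itself
    (and the inorganic phosphate plus its mapped phosphorus for ADP.Pi) is
    always a member. Membership is monotone in the cutoff and dominates
    membership computed from any single frame.
    """
    snap0 = ensemble.snapshots[0]
    core = core_atom_indices(snap0, pmap, config.core_labels)
    keys = snap0.residue_keys()
    unit_of_atom = keys  # (chain, res_id) per atom

    always: set[tuple[str, int]] = {_nucleotide_key(snap0, pmap)}
    if "P_i" in pmap:
        i = pmap["P_i"]
        always.add((str(snap0.chain_ids[i]), int(snap0.res_ids[i])))

    members: set[tuple[str, int]] = set(always)
    for snap in ensemble:
        tree = cKDTree(snap.coords[core])
        d, _ = tree.query(snap.coords, k=1)
        within = np.nonzero(d <= config.cutoff_A + 1e-12)[0]
        members.update(unit_of_atom[i] for i in within)

    order: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int]] = set()
    for i in range(snap0.n_atoms):
        key = unit_of_atom[i]
        if key in members and key not in seen:
            seen.add(key)
            order.append((key[0], key[1], str(snap0.res_names[i])))

    member_atoms = np.array(
        [i for i in range(snap0.n_atoms) if unit_of_atom[i] in members], int
    )
    return QMRegionSpec(
        member_units=order,
        boundary_cuts=[],
        qm_atom_indices=member_atoms,
        cutoff_A=config.cutoff_A,
    )


def _protein_residue_atoms(
    snapshot: Snapshot, key: tuple[str, int]
) -> dict[str, int]:
    keys = snapshot.residue_keys()
    return {
        str(snapshot.names[i]): i
        for i in range(snapshot.n_atoms)
        if keys[i] == key
    }


def plan_boundary_cuts(
    spec: QMRegionSpec,
    snapshot: Snapshot,
    topology: Sequence[tuple[int, int]],
) -> QMRegionSpec:
    """Plan C-C boundary cuts for member amino acids and trim the QM atom
    set accordingly.

    Rules (side-chain-in-QM convention):
      * isolated member amino acid (sequence neighbours not members): one
        cut (C_beta, C_alpha) with C_beta on the QM side; backbone atoms
        leave the QM set;
      * run of >= 2 consecutive member residues: terminal cuts at
        C_alpha-C_carbonyl bonds — the preceding residue's carbonyl group
        joins QM (cut at its C_alpha), the run's last carbonyl group leaves
        QM (cut at its own C_alpha);
      * no cut may sever a C-N bond or any bond involving a non-carbon
        atom.

    A member unit covalently connected to a non-member only through polar
    bonds (e.g. a glycine side chain, which has no C_beta) cannot be cut
    legally; this raises, demanding the neighbour be added to the region.
    Returns a new QMRegionSpec with cuts and trimmed qm_atom_indices.
    """
    nb = bond_neighbors(topology, snapshot.n_atoms)
    member_keys = spec.member_keys()
    keys = snapshot.residue_keys()

    qm_atoms = set(int(i) for i in spec.qm_atom_indices)
    cuts: list[tuple[int, int]] = []

    # member protein residues, grouped into runs of consecutive residue ids
    protein_members = sorted(
        (c, r)
        for c, r, name in spec.member_units
        if _is_amino(snapshot, (c, r))
    )
    runs: list[list[tuple[str, int]]] = []
    for key in protein_members:
        if runs and runs[-1][-1][0] == key[0] and runs[-1][-1][1] == key[1] - 1:
            runs[-1].append(key)
        else:
            runs.append([key])

    for run in runs:
        if len(run) == 1:
            cuts.extend(_cut_isolated(snapshot, run[0], nb, keys,
                                      member_keys, qm_atoms))
        else:
            cuts.extend(_cut_run(snapshot, run, nb, keys, member_keys,
                                 qm_atoms))

    # sanity: cuts sever only C-C bonds
    for q, m in cuts:
        if snapshot.elements[q] != "C" or snapshot.elements[m] != "C":
            raise StructureError(
                f"illegal cut through non-carbon bond ({q},{m})"
            )

    # any remaining covalent bond from a QM atom to a non-QM atom that is
    # not a planned cut means the unit connects only through polar bonds
    cut_set = {frozenset(c) for c in cuts}
    for i in sorted(qm_atoms):
        for j in nb[i]:
            if j in qm_atoms:
                continue
            if frozenset((i, j)) in cut_set:
                continue
            raise StructureError(
                f"member unit {keys[i]} bonded to non-member atom {j} "
                f"({snapshot.elements[i]}-{snapshot.elements[j]}): only a "
                "polar or unplanned bond crosses the boundary; add residue "
                f"{keys[j]} to the QM region"
            )

    return QMRegionSpec(
        member_units=spec.member_units,
        boundary_cuts=cuts,
        qm_atom_indices=np.array(sorted(qm_atoms), int),
        total_charge=list(spec.total_charge),
        cutoff_A=spec.cutoff_A,
    )


def _is_amino(snapshot: Snapshot, key: tuple[str, int]) -> bool:
    names = set(_protein_residue_atoms(snapshot, key))
    return set(BACKBONE_NAMES) <= names


def _side_chain_atoms(
    snapshot: Snapshot, key: tuple[str, int], nb: list[set[int]]
) -> set[int]:
    """Atoms reachable from C_beta without crossing C_alpha (within the
    residue)."""
    atoms = _protein_residue_atoms(snapshot, key)
    cb, ca = atoms.get("CB"), atoms.get("CA")
    if cb is None or ca is None:
        return set()
    keys = snapshot.residue_keys()
    seen = {cb}
    stack = [cb]
    while stack:
        i = stack.pop()
        for j in nb[i]:
            if j == ca or j in seen or keys[j] != key:
                continue
            seen.add(j)
            stack.append(j)
    return seen


def _cut_isolated(snapshot, key, nb, keys, member_keys, qm_atoms):
    atoms = _protein_residue_atoms(snapshot, key)
    residue_atoms = {i for i in range(snapshot.n_atoms) if keys[i] == key}
    # does any bond leave the residue towards a non-member?
    crossing = [
        (i, j)
        for i in residue_atoms
        for j in nb[i]
        if keys[j] != key and keys[j] not in member_keys
    ]
    if not crossing:
        return []  # floating fragment: wholly in QM, nothing to cut
    if "CB" not in atoms:
        raise StructureError(
            f"member residue {key} has no C_beta: it connects to the MM "
            "region only through polar backbone bonds; add its neighbours "
            "to the QM region instead"
        )
    side = _side_chain_atoms(snapshot, key, nb)
    qm_atoms.difference_update(residue_atoms - side)
    return [(atoms["CB"], atoms["CA"])]


def _cut_run(snapshot, run, nb, keys, member_keys, qm_atoms):
    cuts = []
    first, last = run[0], run[-1]
    # N-terminal side: preceding residue's carbonyl joins QM
    prev_key = (first[0], first[1] - 1)
    first_atoms = _protein_residue_atoms(snapshot, first)
    n_idx = first_atoms.get("N")
    prev_bonded = n_idx is not None and any(
        keys[j] == prev_key for j in nb[n_idx]
    )
    if prev_bonded and prev_key not in member_keys:
        prev_atoms = _protein_residue_atoms(snapshot, prev_key)
        if "C" in prev_atoms and "CA" in prev_atoms:
            cuts.append((prev_atoms["C"], prev_atoms["CA"]))
            qm_atoms.add(prev_atoms["C"])
            if "O" in prev_atoms:
                qm_atoms.add(prev_atoms["O"])
    # C-terminal side: the run's last carbonyl leaves QM
    last_atoms = _protein_residue_atoms(snapshot, last)
    c_idx = last_atoms.get("C")
    next_bonded = c_idx is not None and any(
        keys[j] == (last[0], last[1] + 1) for j in nb[c_idx]
    )
    if next_bonded and (last[0], last[1] + 1) not in member_keys:
        cuts.append((last_atoms["CA"], last_atoms["C"]))
        qm_atoms.discard(last_atoms["C"])
        if "O" in last_atoms:
            qm_atoms.discard(last_atoms["O"])
    return cuts


def place_link_atoms(
    cuts: Sequence[tuple[int, int]],
    snapshot: Snapshot,
    config: QMRegionConfig = QMRegionConfig(),
) -> np.ndarray:
    """Hydrogen link-atom positions for one snapshot.

    For each cut (q, m) a hydrogen is placed at
    position(q) + L * unit(q -> m), one per cut. Coincident q/m positions
    leave the direction undefined and raise.
    """
    out = np.empty((len(cuts), 3))
    for k, (q, m) in enumerate(cuts):
        v = snapshot.coords[m] - snapshot.coords[q]
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            raise StructureError(
                f"cut ({q},{m}): coincident atoms, link direction undefined"
            )
        out[k] = snapshot.coords[q] + config.link_bond_length_A * v / norm
    return out


def compute_qm_charge(
    spec: QMRegionSpec,
    charge_table: Mapping[str, int] | None,
    snapshot: Snapshot,
) -> int:
    """Integer total charge of the QM region for one snapshot: the sum of
    member units' formal charges from the charge table. Link atoms are
    neutral. Raises when a member residue has no table entry."""
    table = {k.upper(): int(v) for k, v in
             (charge_table or DEFAULT_CHARGE_TABLE).items()}
    total = 0
    for chain, res_id, res_name in spec.member_units:
        key = res_name.upper()
        if key not in table:
            raise StructureError(
                f"no charge-table entry for residue {res_name!r} "
                f"({chain}/{res_id})"
            )
        total += table[key]
    return int(total)


@dataclasses.dataclass
class ConvergenceReport:
    radii_A: list[float]
    mean_sigma: dict[float, dict[str, float]]  # radius -> nucleus -> ppm
    member_counts: dict[float, int]
    converged_radius_A: float | None
    tol_ppm: float
    flag: str = ""


def converge_qm_size(
    ensemble: Ensemble,
    pmap: PhosphorusMap,
    engine,
    radii_A: Sequence[float],
    tol_ppm: float,
    **engine_kwargs,
) -> ConvergenceReport:
    """QM-size convergence scan.

    For each cutoff radius, carves the union region and evaluates the
    per-nucleus ensemble-mean shieldings with ``engine`` (a callable
    ``engine(snapshot, spec, pmap, **kwargs) -> {nucleus: sigma}``).
    The converged radius r* is the smallest radius whose per-nucleus means
    change by at most ``tol_ppm`` relative to every larger tested radius.
    Member sets are monotone non-decreasing in the radius.
    """
    radii = [float(r) for r in radii_A]
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing")
    means: dict[float, dict[str, float]] = {}
    counts: dict[float, int] = {}
    for r in radii:
        spec = select_qm_union(ensemble, pmap, QMRegionConfig(cutoff_A=r))
        counts[r] = int(len(spec.qm_atom_indices))
        acc: dict[str, list[float]] = {}
        for snap in ensemble:
            sig = engine(snap, spec, pmap, **engine_kwargs)
            for nuc, s in sig.items():
                acc.setdefault(nuc, []).append(s)
        means[r] = {nuc: float(np.mean(v)) for nuc, v in acc.items()}

    flag = ""
    converged: float | None = None
    if len(radii) == 1:
        converged = radii[0]
        flag = "single radius supplied; convergence not assessable"
    else:
        # the largest radius has no larger evidence and cannot be certified
        for i, r in enumerate(radii[:-1]):
            ok = True
            for r2 in radii[i + 1:]:
                delta = max(
                    abs(means[r][n] - means[r2][n]) for n in means[r]
                )
                if delta > tol_ppm:
                    ok = False
                    break
            if ok:
                converged = r
                break
        if converged is None:
            flag = "no radius converged within tolerance"
    return ConvergenceReport(
        radii_A=radii, mean_sigma=means, member_counts=counts,
        converged_radius_A=converged, tol_ppm=float(tol_ppm), flag=flag,
    )


def export_qm_region(
    spec: QMRegionSpec,
    snapshot: Snapshot,
    charge_table: Mapping[str, int] | None,
    outdir: str | Path,
    prefix: str = "frame",
    config: QMRegionConfig = QMRegionConfig(),
) -> dict[str, Path]:
    """Write the per-snapshot QM/MM artefacts.

    ``<prefix>_qm.xyz``: QM atoms plus link atoms. ``<prefix>_mm.pc``: MM
    point charges, one ``x y z q`` line per atom outside the QM set, with
    the unit formal charge spread uniformly over the unit's atoms.
    ``<prefix>_manifest.tsv``: member units, cuts and the total charge.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    links = place_link_atoms(spec.boundary_cuts, snapshot, config)
    qm = sorted(int(i) for i in spec.qm_atom_indices)
    qm_path = outdir / f"{prefix}_qm.xyz"
    with open(qm_path, "w") as fh:
        fh.write(f"{len(qm) + len(links)}\n")
        fh.write(f"QM region, frame {snapshot.frame_index}, "
                 f"t= {snapshot.time_ns:.6f} ns\n")
        for i in qm:
            x, y, z = snapshot.coords[i]
            fh.write(f"{snapshot.elements[i]:<2s} {x:14.8f} {y:14.8f} {z:14.8f}\n")
        for pos in links:
            fh.write(f"H  {pos[0]:14.8f} {pos[1]:14.8f} {pos[2]:14.8f}\n")

    table = {k.upper(): int(v) for k, v in
             (charge_table or DEFAULT_CHARGE_TABLE).items()}
    keys = snapshot.residue_keys()
    qm_set = set(qm)
    # per-atom MM charge: unit formal charge spread uniformly over its atoms
    unit_atoms: dict[tuple[str, int], list[int]] = {}
    for i in range(snapshot.n_atoms):
        if i not in qm_set:
            unit_atoms.setdefault(keys[i], []).append(i)
    pc_path = outdir / f"{prefix}_mm.pc"
    with open(pc_path, "w") as fh:
        for key, atoms in unit_atoms.items():
            res_name = str(snapshot.res_names[atoms[0]]).upper()
            q = table.get(res_name, 0) / len(atoms)
            for i in atoms:
                x, y, z = snapshot.coords[i]
                fh.write(f"{x:14.8f} {y:14.8f} {z:14.8f} {q:12.8f}\n")

    man_path = outdir / f"{prefix}_manifest.tsv"
    total = compute_qm_charge(spec, charge_table, snapshot)
    with open(man_path, "w") as fh:
        fh.write("# section\tfields\n")
        for chain, rid, name in spec.member_units:
            fh.write(f"member\t{chain}\t{rid}\t{name}\n")
        for q, m in spec.boundary_cuts:
            fh.write(f"cut\t{q}\t{m}\n")
        fh.write(f"total_charge\t{total}\n")
    return {"qm_xyz": qm_path, "mm_pc": pc_path, "manifest": man_path}
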
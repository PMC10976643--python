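"""QM-region carving: union rule, boundary cuts, link atoms, charges,
size convergence."""

import numpy as np
import pytest

from phos31.qmregion import (
    QMRegionConfig,
    QMRegionSpec,
    compute_qm_charge,
    converge_qm_size,
    place_link_atoms,
    plan_boundary_cuts,
    select_qm_union,
)
from phos31.structures import (
    StructureError,
    infer_bonds,
    map_phosphorus_topology,
)

from conftest import ensemble_of, make_snapshot, with_environment


def _water_outward(res_id, o3b, u, dist, chain="W"):
    """Water whose O sits exactly `dist` Å from the O_3B anchor with both
    hydrogens further out along u."""
    o = o3b + dist * u
    return [
        ("O", "O", "HOH", res_id, chain, tuple(o)),
        ("H1", "H", "HOH", res_id, chain, tuple(o + 0.96 * u)),
        ("H2", "H", "HOH", res_id, chain, tuple(o + 0.96 * u + (0.1, 0, 0))),
    ]


def _outward_direction(template, pmap):
    o3b = template.coords[pmap["O_3B"]]
    centroid = template.coords.mean(axis=0)
    u = o3b - centroid
    return o3b, u / np.linalg.norm(u)


def test_union_threshold_is_inclusive(atp_template, atp_map):
    """With the anchor as selection core, a water at 3.7 Å joins the
    region (<= cutoff, inclusive) and one at 3.9 Å stays out."""
    o3b, u = _outward_direction(atp_template, atp_map)
    cfg = QMRegionConfig(core_labels=("O_3B",))
    near = with_environment(atp_template, _water_outward(50, o3b, u, 3.7))
    far = with_environment(atp_template, _water_outward(50, o3b, u, 3.9))
    spec_near = select_qm_union(ensemble_of([near]), atp_map, cfg)
    spec_far = select_qm_union(ensemble_of([far]), atp_map, cfg)
    assert ("W", 50) in spec_near.member_keys()
    assert ("W", 50) not in spec_far.member_keys()


def test_union_membership_from_single_visiting_frame(atp_template, atp_map):
    """An ion within the cutoff in one frame of ten is a member: the
    region is the union over the whole trajectory."""
    o3b, u = _outward_direction(atp_template, atp_map)
    cfg = QMRegionConfig(core_labels=("O_3B",))
    frames = []
    for k in range(10):
        dist = 3.2 if k == 7 else 6.0
        ion = [("MG", "MG", "MG", 90, "A", tuple(o3b + dist * u))]
        frames.append(with_environment(atp_template, ion, frame_index=k,
                                       time_ns=float(k)))
    spec = select_qm_union(ensemble_of(frames), atp_map, cfg)
    assert ("A", 90) in spec.member_keys()
    # any single non-visiting frame alone would exclude it
    solo = select_qm_union(ensemble_of([frames[0]]), atp_map, cfg)
    assert ("A", 90) not in solo.member_keys()


def test_membership_monotone_in_cutoff(atp_solution_ensemble):
    ens = atp_solution_ensemble
    pmap = map_phosphorus_topology(ens.snapshots[0], "ATP")
    previous = set()
    for cutoff in (2.5, 3.0, 3.8, 4.5, 6.0):
        spec = select_qm_union(ens, pmap, QMRegionConfig(cutoff_A=cutoff))
        members = spec.member_keys()
        assert previous <= members
        previous = members


def test_union_dominates_single_frames(atp_solution_ensemble):
    ens = atp_solution_ensemble
    pmap = map_phosphorus_topology(ens.snapshots[0], "ATP")
    union = select_qm_union(ens, pmap).member_keys()
    for snap in ens:
        single = select_qm_union(ensemble_of([
            snap.with_coords(snap.coords, frame_index=0, time_ns=0.0)
        ], topology=ens.topology), pmap).member_keys()
        assert single <= union


def test_empty_core_errors(atp_template, atp_map):
    with pytest.raises(StructureError, match="core"):
        select_qm_union(ensemble_of([atp_template]), atp_map,
                        QMRegionConfig(core_labels=("NOPE",)))


# ---------------------------------------------------------------------------
# boundary cuts
# ---------------------------------------------------------------------------

def _amino(res_name, res_id, chain, x, side=("CB",)):
    """Amino-acid stub with clean bonding geometry: only N-CA, CA-C, C=O,
    CA-CB, CB-CG... and the inter-residue C(i)-N(i+1) peptide bond fall
    within covalent distance."""
    atoms = [
        ("N", "N", res_name, res_id, chain, (x, 0.0, 0.0)),
        ("CA", "C", res_name, res_id, chain, (x + 1.2, 0.8, 0.0)),
        ("C", "C", res_name, res_id, chain, (x + 2.4, 0.0, 0.0)),
        ("O", "O", res_name, res_id, chain, (x + 2.1, -1.19, 0.0)),
    ]
    for k, name in enumerate(side):
        atoms.append((name, name[0], res_name, res_id, chain,
                      (x + 1.2, 0.8 + 1.53 * (k + 1), 0.0)))
    return atoms


def _peptide_chain(residue_specs, chain="B", x0=0.0):
    """Consecutive residues bonded via the C(i)-N(i+1) peptide bond
    (1.33 Å along x)."""
    atoms = []
    x = x0
    for res_name, res_id, side in residue_specs:
        atoms.extend(_amino(res_name, res_id, chain, x, side=side))
        x += 2.4 + 1.33
    return atoms


def _protein_fixture(members):
    """Tripeptide GLY-ARG-GLY; `members` lists member residue ids."""
    atoms = _peptide_chain([("GLY", 1, ()), ("ARG", 2, ("CB", "CG")),
                            ("GLY", 3, ())])
    snap = make_snapshot(atoms)
    topology = infer_bonds(snap)
    spec = QMRegionSpec(
        member_units=[(a[4], a[3], a[2]) for a in atoms
                      if a[3] in members and (a[4], a[3], a[2])],
        boundary_cuts=[],
        qm_atom_indices=np.array(
            [i for i, a in enumerate(atoms) if a[3] in members], int),
    )
    # deduplicate member units preserving order
    seen, units = set(), []
    for u in spec.member_units:
        if (u[0], u[1]) not in seen:
            seen.add((u[0], u[1]))
            units.append(u)
    spec.member_units = units
    return snap, topology, spec


def test_isolated_member_cut_is_cb_ca():
    """A lone member arginine contributes its side chain: one C_beta-
    C_alpha cut with C_beta on the QM side."""
    snap, topology, spec = _protein_fixture(members={2})
    out = plan_boundary_cuts(spec, snap, topology)
    assert len(out.boundary_cuts) == 1
    (q, m), = out.boundary_cuts
    assert str(snap.names[q]) == "CB" and str(snap.names[m]) == "CA"
    qm_names = {str(snap.names[i]) for i in out.qm_atom_indices}
    assert qm_names == {"CB", "CG"}  # backbone trimmed to MM


def test_run_of_two_members_cut_at_backbone_termini():
    """Consecutive member residues are cut at C_alpha-C_carbonyl bonds of
    the backbone, never through C-N."""
    atoms = _peptide_chain([("GLY", 1, ()), ("ARG", 2, ("CB",)),
                            ("LYS", 3, ("CB",)), ("GLY", 4, ())])
    snap = make_snapshot(atoms)
    topology = infer_bonds(snap)
    spec = QMRegionSpec(
        member_units=[("B", 2, "ARG"), ("B", 3, "LYS")],
        boundary_cuts=[],
        qm_atom_indices=np.array(
            [i for i, a in enumerate(atoms) if a[3] in (2, 3)], int),
    )
    out = plan_boundary_cuts(spec, snap, topology)
    assert len(out.boundary_cuts) == 2
    for q, m in out.boundary_cuts:
        assert {str(snap.names[q]), str(snap.names[m])} == {"CA", "C"}
        assert snap.elements[q] == "C" and snap.elements[m] == "C"
    qm_names = [str(snap.names[i]) for i in out.qm_atom_indices]
    # residue 1's carbonyl joins QM; residue 3's carbonyl leaves
    assert qm_names.count("C") == 2  # C(1) + C(2); C(3) trimmed


def test_no_protein_means_no_cuts(atp_solution_ensemble):
    ens = atp_solution_ensemble
    pmap = map_phosphorus_topology(ens.snapshots[0], "ATP")
    spec = select_qm_union(ens, pmap)
    out = plan_boundary_cuts(spec, ens.snapshots[0], ens.topology)
    assert out.boundary_cuts == []


def test_member_glycine_demands_region_growth():
    """A member residue without C_beta connects only through polar
    backbone bonds; the planner demands the neighbour join the region."""
    snap, topology, _ = _protein_fixture(members={2})
    spec = QMRegionSpec(
        member_units=[("B", 1, "GLY")],
        boundary_cuts=[],
        qm_atom_indices=np.array(
            [i for i in range(snap.n_atoms) if snap.res_ids[i] == 1], int),
    )
    with pytest.raises(StructureError, match="C_beta|polar"):
        plan_boundary_cuts(spec, snap, topology)


# ---------------------------------------------------------------------------
# link atoms
# ---------------------------------------------------------------------------

def test_link_atom_collinear_case():
    snap = make_snapshot([("CB", "C", "ARG", 1, "B", (0, 0, 0)),
                          ("CA", "C", "ARG", 1, "B", (2, 0, 0))])
    (pos,) = place_link_atoms([(0, 1)], snap)
    np.testing.assert_allclose(pos, [1.09, 0, 0], atol=1e-12)


def test_link_atoms_random_geometries_exact_length():
    """For arbitrary cut geometry the hydrogen is exactly the configured
    bond length from its QM anchor and collinear with the cut bond."""
    rng = np.random.default_rng(2)
    for _ in range(50):
        q, m = rng.normal(scale=5.0, size=(2, 3))
        snap = make_snapshot([("CB", "C", "ARG", 1, "B", tuple(q)),
                              ("CA", "C", "ARG", 1, "B", tuple(m))])
        (h,) = place_link_atoms([(0, 1)], snap)
        assert abs(np.linalg.norm(h - q) - 1.09) < 1e-9
        cross = np.cross(m - q, h - q)
        assert np.linalg.norm(cross) < 1e-8
        assert np.dot(m - q, h - q) > 0  # towards the MM atom


def test_zero_cuts_and_coincident_error(atp_template):
    assert place_link_atoms([], atp_template).shape == (0, 3)
    snap = make_snapshot([("CB", "C", "ARG", 1, "B", (1, 1, 1)),
                          ("CA", "C", "ARG", 1, "B", (1, 1, 1))])
    with pytest.raises(StructureError, match="coincident"):
        place_link_atoms([(0, 1)], snap)


# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------

def _spec_of(units):
    return QMRegionSpec(member_units=units, boundary_cuts=[],
                        qm_atom_indices=np.array([], int))


def test_charge_sums(atp_template):
    waters = [("W", i, "HOH") for i in range(12)]
    assert compute_qm_charge(
        _spec_of([("A", 1, "ATP"), ("A", 2, "MG")] + waters),
        None, atp_template) == -2
    assert compute_qm_charge(
        _spec_of([("A", 1, "ADP"), ("A", 2, "HPO4"), ("A", 3, "MG")]),
        None, atp_template) == -3
    assert compute_qm_charge(
        _spec_of([("B", 10, "ARG"), ("C", 20, "ARG"), ("A", 1, "ATP"),
                  ("A", 2, "MG")]),
        None, atp_template) == 0


def test_charge_missing_entry_names_residue(atp_template):
    with pytest.raises(StructureError, match="XYZ"):
        compute_qm_charge(_spec_of([("A", 1, "XYZ")]), {"ATP": -4},
                          atp_template)


def test_charge_matches_brute_force_manifest(adppi_pocket_ensemble):
    """Integer QM charge equals the explicit sum over the member units'
    charge-table entries, on every frame."""
    from phos31.structures import DEFAULT_CHARGE_TABLE

    ens = adppi_pocket_ensemble
    pmap = map_phosphorus_topology(ens.snapshots[0], "ADP.Pi")
    spec = select_qm_union(ens, pmap)
    expected = sum(DEFAULT_CHARGE_TABLE[name] for _, _, name
                   in spec.member_units)
    for snap in ens:
        assert compute_qm_charge(spec, None, snap) == expected


# ---------------------------------------------------------------------------
# size convergence
# ---------------------------------------------------------------------------

def test_convergence_scan_localised_engine(atp_template, atp_map):
    """With an engine only sensitive to the first shell, the scan stops at
    the smallest radius containing that shell."""
    from phos31.qmregion import core_atom_indices

    o3b = atp_template.coords[atp_map["O_3B"]]
    centroid = atp_template.coords.mean(axis=0)
    u = (o3b - centroid) / np.linalg.norm(o3b - centroid)
    extra = [("MG", "MG", "MG", 90, "A", tuple(o3b + 3.4 * u)),
             ("CL", "CL", "CL", 91, "A", tuple(o3b + 12.0 * u))]
    snap = with_environment(atp_template, extra)
    ens = ensemble_of([snap])
    pmap = map_phosphorus_topology(snap, "ATP")
    core = snap.coords[core_atom_indices(snap, pmap)]
    ion = np.asarray(extra[0][5])
    dmin = float(np.min(np.linalg.norm(core - ion, axis=1)))
    radii = [dmin - 0.5, dmin + 0.2, dmin + 1.5, dmin + 3.0]

    def engine(snapshot, spec, pm, **kwargs):
        near = sum(1 for chain, rid, name in spec.member_units
                   if name == "MG")
        return {"P_alpha": 300.0 + 5.0 * near}

    report = converge_qm_size(ens, pmap, engine, radii, 0.1)
    assert report.converged_radius_A == pytest.approx(dmin + 0.2)
    counts = [report.member_counts[r] for r in report.radii_A]
    assert counts == sorted(counts)  # monotone member sets


def test_convergence_infinite_tolerance_and_single_radius(
        atp_solution_ensemble):
    ens = atp_solution_ensemble
    pmap = map_phosphorus_topology(ens.snapshots[0], "ATP")

    def engine(snapshot, spec, pm, **kwargs):
        return {"P_alpha": float(len(spec.qm_atom_indices))}

    report = converge_qm_size(ens, pmap, engine, [2.0, 4.0, 6.0], np.inf)
    assert report.converged_radius_A == 2.0
    single = converge_qm_size(ens, pmap, engine, [3.8], 0.1)
    assert single.converged_radius_A == 3.8
    assert single.flag  # caveat: not assessable from one radius


def test_convergence_unconverged_flag(atp_solution_ensemble):
    ens = atp_solution_ensemble
    pmap = map_phosphorus_topology(ens.snapshots[0], "ATP")

    def engine(snapshot, spec, pm, **kwargs):
        return {"P_alpha": float(len(spec.qm_atom_indices))}

    report = converge_qm_size(ens, pmap, engine, [2.0, 3.0, 4.0, 5.0], 1e-9)
    assert report.converged_radius_A is None
    assert "no radius" in report.flag
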
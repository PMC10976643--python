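"""Core data model: file I/O, phosphorus mapping, bond inference,
snapshot extraction."""

import numpy as np
import pytest

from phos31.structures import (
    Ensemble,
    Snapshot,
    StructureError,
    extract_snapshots,
    infer_bonds,
    map_phosphorus_topology,
    read_charge_table,
    read_structure,
    read_trajectory,
    write_charge_table,
    write_structure,
    write_trajectory,
)

from conftest import make_snapshot, single_atom_snapshot


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def test_xyz_identity_read(tmp_path):
    """A 3-atom XYZ file reads back with exact positions and elements."""
    path = tmp_path / "tiny.xyz"
    path.write_text("3\ncomment\nP 0 0 0\nO 1.5 0 0\nO 0 1.5 0\n")
    snap = read_structure(path)
    assert snap.n_atoms == 3
    assert list(snap.elements) == ["P", "O", "O"]
    np.testing.assert_array_equal(snap.coords[0], [0, 0, 0])
    np.testing.assert_array_equal(snap.coords[1], [1.5, 0, 0])


def test_multi_model_pdb_rejected_as_structure(tmp_path, atp_template):
    """Multi-model files are trajectories; read_structure points there."""
    path = tmp_path / "two.pdb"
    ens = Ensemble([atp_template,
                    atp_template.with_coords(atp_template.coords + 1.0,
                                             frame_index=1, time_ns=1.0)])
    write_trajectory(ens, path)
    with pytest.raises(StructureError, match="read_trajectory"):
        read_structure(path)


def test_pdb_atom_count_matches_fixture_lines(tmp_path, atp_solution_ensemble):
    """Snapshot atom count equals the file's ATOM/HETATM line count."""
    path = tmp_path / "frame.pdb"
    write_structure(atp_solution_ensemble.snapshots[0], path)
    n_lines = sum(
        1 for line in path.read_text().splitlines()
        if line.startswith(("ATOM", "HETATM"))
    )
    snap = read_structure(path)
    assert snap.n_atoms == n_lines == atp_solution_ensemble.n_atoms


@pytest.mark.parametrize("fmt", ["pdb", "xyz"])
def test_round_trip_preserves_structure(tmp_path, atp_template, fmt):
    """Write-then-read preserves elements and coordinates to format
    precision (PDB: 1e-3 Å; XYZ: 1e-8 Å)."""
    path = tmp_path / f"t.{fmt}"
    write_structure(atp_template, path)
    back = read_structure(path)
    assert list(back.elements) == list(atp_template.elements)
    tol = 1.5e-3 if fmt == "pdb" else 1e-8
    np.testing.assert_allclose(back.coords, atp_template.coords, atol=tol)
    if fmt == "pdb":
        assert list(back.names) == list(atp_template.names)
        assert list(back.res_names) == list(atp_template.res_names)


def test_read_trajectory_multi_model(tmp_path, atp_template):
    path = tmp_path / "traj.pdb"
    frames = [atp_template.with_coords(atp_template.coords + k,
                                       frame_index=k, time_ns=float(k))
              for k in range(5)]
    write_trajectory(Ensemble(frames), path)
    ens = read_trajectory(path, timestep_ns=2.0)
    assert len(ens) == 5
    np.testing.assert_allclose(ens.times(), [0, 2, 4, 6, 8])


def test_read_trajectory_single_frame_ok(tmp_path, atp_template):
    path = tmp_path / "one.pdb"
    write_structure(atp_template, path)
    ens = read_trajectory(path)
    assert len(ens) == 1


def test_trajectory_atom_count_mismatch_names_frame(tmp_path):
    path = tmp_path / "bad.xyz"
    path.write_text("2\nt= 0 ns\nH 0 0 0\nH 1 0 0\n"
                    "3\nt= 1 ns\nH 0 0 0\nH 1 0 0\nH 2 0 0\n")
    with pytest.raises(StructureError, match="frame 1"):
        read_trajectory(path)


def test_xyz_malformed_record_names_line(tmp_path):
    path = tmp_path / "bad.xyz"
    path.write_text("2\ncomment\nH 0 0 0\nH 1 0 bogus\n")
    with pytest.raises(StructureError, match="line 4"):
        read_structure(path)


def test_unknown_element_rejected():
    with pytest.raises(StructureError, match="unknown element"):
        single_atom_snapshot(element="XX")


def test_non_finite_position_rejected():
    with pytest.raises(StructureError):
        single_atom_snapshot(pos=(np.nan, 0, 0))


def test_ensemble_invariants(atp_template):
    smaller = make_snapshot([("P", "P", "UNK", 1, "A", (0, 0, 0))],
                            frame_index=1)
    with pytest.raises(StructureError, match="atom count"):
        Ensemble([atp_template, smaller])
    with pytest.raises(StructureError, match="strictly increasing"):
        Ensemble([atp_template, atp_template])
    with pytest.raises(StructureError, match="self-bond"):
        Ensemble([atp_template], topology=[(3, 3)])


# ---------------------------------------------------------------------------
# phosphorus-backbone mapping
# ---------------------------------------------------------------------------

def test_map_atp_has_three_nuclei(atp_template):
    pmap = map_phosphorus_topology(atp_template, "ATP")
    assert pmap.nuclei == ("P_alpha", "P_beta", "P_gamma")
    for label in ("P_alpha", "P_beta", "P_gamma"):
        assert atp_template.elements[pmap[label]] == "P"
    assert str(atp_template.names[pmap["P_alpha"]]) == "PA"
    assert str(atp_template.names[pmap["O_5'"]]) == "O5'"


def test_map_adp_lacks_gamma(adp_template):
    """ADP has no gamma phosphate: the map holds two P nuclei."""
    pmap = map_phosphorus_topology(adp_template, "ADP")
    assert pmap.nuclei == ("P_alpha", "P_beta")
    assert "P_gamma" not in pmap and "O_1G" not in pmap


def test_map_adppi_finds_detached_phosphate(adppi_template):
    """The inorganic phosphate is a separate residue whose P maps to P_i."""
    pmap = map_phosphorus_topology(adppi_template, "ADP.Pi")
    assert "P_i" in pmap
    i = pmap["P_i"]
    assert str(adppi_template.res_names[i]) == "PO4"
    assert adppi_template.res_ids[i] != adppi_template.res_ids[pmap["P_alpha"]]


def test_map_missing_atom_lists_unresolved(atp_template):
    names = [("X" if str(n) == "PG" else str(n)) for n in atp_template.names]
    broken = Snapshot(0, 0.0, names, atp_template.elements,
                      atp_template.res_names, atp_template.res_ids,
                      atp_template.chain_ids, atp_template.coords)
    with pytest.raises(StructureError, match="P_gamma"):
        map_phosphorus_topology(broken, "ATP")


def test_map_alternative_naming_dialect(atp_template):
    """Star-convention names (O5*) resolve through a dialect table."""
    names = [str(n).replace("'", "*") for n in atp_template.names]
    starred = Snapshot(0, 0.0, names, atp_template.elements,
                       atp_template.res_names, atp_template.res_ids,
                       atp_template.chain_ids, atp_template.coords)
    pmap = map_phosphorus_topology(starred, "ATP",
                                   naming_dialect={"O_5'": "O5*"})
    assert str(starred.names[pmap["O_5'"]]) == "O5*"


# ---------------------------------------------------------------------------
# bond inference
# ---------------------------------------------------------------------------

def test_infer_bonds_thresholds():
    h2 = make_snapshot([("H1", "H", "UNK", 1, "A", (0, 0, 0)),
                        ("H2", "H", "UNK", 1, "A", (0.74, 0, 0))])
    assert infer_bonds(h2, tolerance=0.4) == [(0, 1)]
    far = make_snapshot([("H1", "H", "UNK", 1, "A", (0, 0, 0)),
                         ("H2", "H", "UNK", 1, "A", (5.0, 0, 0))])
    assert infer_bonds(far, tolerance=0.4) == []


def test_template_phosphates_have_four_oxygens(atp_template, atp_map):
    bonds = infer_bonds(atp_template)
    for nuc in ("P_alpha", "P_beta", "P_gamma"):
        p = atp_map[nuc]
        oxy = [j for i, j in bonds if i == p
               and atp_template.elements[j] == "O"]
        oxy += [i for i, j in bonds if j == p
                and atp_template.elements[i] == "O"]
        assert len(oxy) == 4, nuc


def test_infer_bonds_matches_brute_force(atp_solution_ensemble):
    """KD-tree inference agrees with the all-pairs distance oracle."""
    snap = atp_solution_ensemble.snapshots[0]
    from phos31.structures import COVALENT_RADII

    r = np.array([COVALENT_RADII[str(e)] for e in snap.elements])
    oracle = set()
    d = np.linalg.norm(
        snap.coords[:, None, :] - snap.coords[None, :, :], axis=-1)
    for i in range(snap.n_atoms):
        for j in range(i + 1, snap.n_atoms):
            if d[i, j] <= r[i] + r[j] + 0.4:
                oracle.add((i, j))
    assert set(infer_bonds(snap, tolerance=0.4)) == oracle


# ---------------------------------------------------------------------------
# snapshot extraction
# ---------------------------------------------------------------------------

def _uniform_ensemble(n, spacing=1.0):
    frames = [
        make_snapshot([("P", "P", "UNK", 1, "A", (k, 0, 0))],
                      frame_index=k, time_ns=k * spacing)
        for k in range(n)
    ]
    return Ensemble(frames)


def test_extract_every_other_frame():
    sub = extract_snapshots(_uniform_ensemble(10), 2.0)
    assert [s.frame_index for s in sub] == [0, 2, 4, 6, 8]


def test_extract_at_spacing_is_identity_and_idempotent():
    ens = _uniform_ensemble(10)
    sub = extract_snapshots(ens, 1.0)
    assert [s.frame_index for s in sub] == list(range(10))
    again = extract_snapshots(sub, 1.0)
    assert [s.frame_index for s in again] == [s.frame_index for s in sub]


def test_extract_solution_protocol_101_frames():
    """1 ns intervals over a 100 ns trajectory keep all 101 frames."""
    sub = extract_snapshots(_uniform_ensemble(101), 1.0)
    assert len(sub) == 101


def test_extract_idempotent_at_coarser_interval():
    ens = _uniform_ensemble(20)
    once = extract_snapshots(ens, 3.0)
    twice = extract_snapshots(once, 3.0)
    assert [s.frame_index for s in twice] == [s.frame_index for s in once]


def test_extract_interval_below_spacing_errors():
    with pytest.raises(StructureError, match="spacing"):
        extract_snapshots(_uniform_ensemble(5, spacing=2.0), 1.0)


# ---------------------------------------------------------------------------
# charge table
# ---------------------------------------------------------------------------

def test_charge_table_round_trip(tmp_path):
    table = {"ATP": -4, "MG": 2, "HOH": 0}
    path = tmp_path / "charges.txt"
    write_charge_table(table, path)
    assert read_charge_table(path) == table


def test_charge_table_rejects_non_integer(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("ATP -3.5\n")
    with pytest.raises(StructureError, match="integer"):
        read_charge_table(path)
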
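"""Geometric shielding surrogate and internal P_alpha referencing."""

import numpy as np
import pytest

from phos31.geometry import random_rotation
from phos31.qmregion import QMRegionSpec, select_qm_union
from phos31.shielding import (
    ENGINES,
    ShieldingRecord,
    SurrogateParams,
    compute_shieldings,
    geometric_surrogate,
    reference_shifts,
)
from phos31.structures import (
    StructureError,
    infer_bonds,
    map_phosphorus_topology,
)

from conftest import ensemble_of, with_environment


def test_ideal_template_gives_sigma_base(atp_template, adp_template,
                                         adppi_template):
    """All bonds at reference lengths, exact tetrahedra, no ions: every
    term vanishes and sigma equals sigma_base for every phosphorus."""
    for state, snap in (("ATP", atp_template), ("ADP", adp_template),
                        ("ADP.Pi", adppi_template)):
        pmap = map_phosphorus_topology(snap, state)
        sigma = geometric_surrogate(snap, None, pmap)
        for nuc, s in sigma.items():
            assert s == pytest.approx(300.0, abs=1e-9), (state, nuc)


def _stretch_bond(snap, p_idx, o_idx, delta):
    coords = snap.coords.copy()
    u = coords[o_idx] - coords[p_idx]
    u /= np.linalg.norm(u)
    coords[o_idx] = coords[o_idx] + delta * u
    return snap.with_coords(coords)


def test_bond_lengthening_moves_shift_downfield(atp_template, atp_map):
    """+0.10 Å on one P_beta-O bond lowers sigma(P_beta) by exactly
    10 ppm, i.e. a 10 ppm downfield shift of delta(P_beta)."""
    topology = infer_bonds(atp_template)
    base = geometric_surrogate(atp_template, None, atp_map,
                               topology=topology)
    stretched = _stretch_bond(atp_template, atp_map["P_beta"],
                              atp_map["O_1B"], 0.10)
    new = geometric_surrogate(stretched, None, atp_map, topology=topology)
    assert base["P_beta"] - new["P_beta"] == pytest.approx(10.0, abs=1e-9)
    # referencing flips the sign: delta = sigma_ref - sigma + delta_exp
    rec = lambda s, k: ShieldingRecord(k, s)
    series = reference_shifts([rec(base, 0)], [rec(base, 0), rec(new, 1)],
                              delta_exp_Palpha=-7.0)
    assert (series.delta["P_beta"][1] - series.delta["P_beta"][0]
            == pytest.approx(10.0, abs=1e-9))


def test_monotone_in_any_single_bond(atp_template, atp_map):
    """sigma strictly decreases as any single P-O bond lengthens."""
    topology = infer_bonds(atp_template)
    for o_label in ("O_1A", "O_3A"):
        last = np.inf
        for delta in (0.0, 0.02, 0.05, 0.09):
            s = geometric_surrogate(
                _stretch_bond(atp_template, atp_map["P_alpha"],
                              atp_map[o_label], delta),
                None, atp_map, topology=topology)["P_alpha"]
            assert s < last
            last = s


def test_point_charge_term(atp_template, atp_map):
    """A +2 ion at 2 Å from P_gamma adds charge_slope * q/r = +2 ppm."""
    pg = atp_template.coords[atp_map["P_gamma"]]
    centroid = atp_template.coords.mean(axis=0)
    u = (pg - centroid) / np.linalg.norm(pg - centroid)
    snap = with_environment(
        atp_template, [("MG", "MG", "MG", 90, "A", tuple(pg + 2.0 * u))])
    pmap = map_phosphorus_topology(snap, "ATP")
    spec = select_qm_union(ensemble_of([snap]), pmap)
    assert ("A", 90) in spec.member_keys()
    topology = infer_bonds(atp_template)  # exclude any spurious ion bond
    with_ion = geometric_surrogate(snap, spec, pmap, topology=topology)
    without = geometric_surrogate(snap, None, pmap, topology=topology)
    assert (with_ion["P_gamma"] - without["P_gamma"]
            == pytest.approx(2.0 * (2.0 / 2.0), abs=1e-9))
    # beyond the 6 Å horizon the ion contributes nothing
    params = SurrogateParams(ion_cutoff_A=1.5)
    capped = geometric_surrogate(snap, spec, pmap, params=params,
                                 topology=topology)
    assert capped["P_gamma"] == pytest.approx(without["P_gamma"], abs=1e-9)


def test_surrogate_rotation_translation_invariant(adppi_template, adppi_map):
    topology = infer_bonds(adppi_template)
    base = geometric_surrogate(adppi_template, None, adppi_map,
                               topology=topology)
    rng = np.random.default_rng(5)
    for _ in range(3):
        R = random_rotation(rng)
        t = rng.normal(scale=20.0, size=3)
        moved = adppi_template.with_coords(adppi_template.coords @ R.T + t)
        rotated = geometric_surrogate(moved, None, adppi_map,
                                      topology=topology)
        for nuc in base:
            assert rotated[nuc] == pytest.approx(base[nuc], abs=1e-8)


def test_wrong_oxygen_count_errors(atp_template, atp_map):
    """A phosphorus without exactly four oxygen neighbours is rejected
    (only the broken bridge of ADP.Pi is exempt)."""
    topology = [b for b in infer_bonds(atp_template)
                if set(b) != {atp_map["P_gamma"], atp_map["O_1G"]}]
    with pytest.raises(StructureError, match="4 oxygen"):
        geometric_surrogate(atp_template, None, atp_map, topology=topology)


def test_compute_shieldings_contract(atp_template, atp_map):
    spec = QMRegionSpec(member_units=[("A", 1, "ATP")], boundary_cuts=[],
                        qm_atom_indices=np.arange(atp_template.n_atoms))
    rec = compute_shieldings("geometric", atp_template, spec, atp_map)
    assert rec.frame_index == 0 and set(rec.sigma) == {
        "P_alpha", "P_beta", "P_gamma"}
    # nuclei must sit inside the QM region
    small = QMRegionSpec(member_units=[("A", 1, "ATP")], boundary_cuts=[],
                         qm_atom_indices=np.array([atp_map["P_alpha"]]))
    with pytest.raises(StructureError, match="outside"):
        compute_shieldings("geometric", atp_template, small, atp_map)
    with pytest.raises(NotImplementedError):
        ENGINES["dft"](atp_template, spec, atp_map)


# ---------------------------------------------------------------------------
# referencing
# ---------------------------------------------------------------------------

def _records(sigmas):
    return [ShieldingRecord(k, dict(s)) for k, s in enumerate(sigmas)]


def test_two_frame_toy_referencing():
    """sigma(P_alpha) = 300, 302 and sigma(P_beta) = 310 with
    delta_exp = -7 give sigma_ref = 301 and delta(P_beta) = -16."""
    recs = _records([{"P_alpha": 300.0, "P_beta": 310.0},
                     {"P_alpha": 302.0, "P_beta": 310.0}])
    series = reference_shifts(recs, recs, delta_exp_Palpha=-7.0)
    assert series.reference_sigma == pytest.approx(301.0)
    np.testing.assert_allclose(series.delta["P_beta"], [-16.0, -16.0])


def test_reference_state_pins_mean_palpha():
    """By construction the reference ensemble's mean delta(P_alpha)
    equals the supplied experimental value exactly."""
    rng = np.random.default_rng(0)
    recs = _records([{"P_alpha": 300 + x, "P_beta": 310 + y}
                     for x, y in rng.normal(size=(40, 2))])
    series = reference_shifts(recs, recs, delta_exp_Palpha=-7.4)
    assert abs(float(np.mean(series.delta["P_alpha"])) - (-7.4)) < 1e-12


def test_all_equal_sigmas_give_experimental_value():
    recs = _records([{"P_alpha": 305.0, "P_beta": 305.0}] * 5)
    series = reference_shifts(recs, recs, delta_exp_Palpha=-7.0)
    for nuc in series.nuclei:
        np.testing.assert_allclose(series.delta[nuc], -7.0)


def test_shift_differences_independent_of_reference():
    """delta_i - delta_j = sigma_j - sigma_i regardless of sigma_ref."""
    rng = np.random.default_rng(3)
    target = _records([{"P_alpha": 300 + x, "P_beta": 315 + y}
                       for x, y in rng.normal(size=(10, 2))])
    for ref_sigma in (280.0, 300.0, 331.7):
        ref = _records([{"P_alpha": ref_sigma}])
        series = reference_shifts(ref, target, delta_exp_Palpha=-7.0)
        for k, rec in enumerate(target):
            assert (series.delta["P_alpha"][k] - series.delta["P_beta"][k]
                    == pytest.approx(rec.sigma["P_beta"]
                                     - rec.sigma["P_alpha"], abs=1e-10))


def test_empty_reference_errors():
    with pytest.raises(ValueError, match="reference"):
        reference_shifts([], _records([{"P_alpha": 300.0}]), -7.0)


def test_series_round_trip_table():
    recs = _records([{"P_alpha": 300.0, "P_beta": 310.0}] * 3)
    series = reference_shifts(recs, recs, -7.0)
    df = series.to_frame()
    assert set(df.columns) == {"frame_index", "nucleus", "delta_ppm"}
    assert len(df) == 6
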
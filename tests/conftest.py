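"""Shared fixtures: idealized templates and small generated ensembles."""

import numpy as np
import pytest

from phos31.generate import GeneratorConfig, build_template, generate_ensemble
from phos31.structures import Ensemble, Snapshot, infer_bonds, map_phosphorus_topology


@pytest.fixture(scope="session")
def atp_template():
    return build_template("ATP")


@pytest.fixture(scope="session")
def adp_template():
    return build_template("ADP")


@pytest.fixture(scope="session")
def adppi_template():
    return build_template("ADP.Pi")


@pytest.fixture(scope="session")
def atp_map(atp_template):
    return map_phosphorus_topology(atp_template, "ATP")


@pytest.fixture(scope="session")
def adppi_map(adppi_template):
    return map_phosphorus_topology(adppi_template, "ADP.Pi")


@pytest.fixture(scope="session")
def atp_solution_ensemble():
    """Small solvated-ATP pseudo-trajectory (counter-ions + water shells)."""
    cfg = GeneratorConfig(state="ATP", environment="solution_minimal_ions",
                          n_frames=12, seed=11)
    return generate_ensemble(cfg)


@pytest.fixture(scope="session")
def adppi_pocket_ensemble():
    """Small ADP.Pi binding-pocket mimic with protein stubs."""
    cfg = GeneratorConfig(state="ADP.Pi", environment="pocket",
                          n_frames=12, seed=4)
    return generate_ensemble(cfg)


def single_atom_snapshot(element="P", pos=(0.0, 0.0, 0.0)):
    return Snapshot(0, 0.0, [element], [element], ["UNK"], [1], ["A"],
                    np.array([pos], float))


def make_snapshot(atoms, frame_index=0, time_ns=0.0):
    """atoms: list of (name, element, res_name, res_id, chain, xyz)."""
    names, elements, res_names, res_ids, chains, coords = zip(*[
        (a[0], a[1], a[2], a[3], a[4], a[5]) for a in atoms
    ])
    return Snapshot(frame_index, time_ns, list(names), list(elements),
                    list(res_names), list(res_ids), list(chains),
                    np.array(coords, float))


def with_environment(template, extra_atoms, frame_index=0, time_ns=0.0):
    """Template snapshot plus extra residues (same tuple format)."""
    atoms = [
        (str(template.names[i]), str(template.elements[i]),
         str(template.res_names[i]), int(template.res_ids[i]),
         str(template.chain_ids[i]), template.coords[i])
        for i in range(template.n_atoms)
    ]
    return make_snapshot(atoms + list(extra_atoms), frame_index, time_ns)


def ensemble_of(snapshots, topology=None, metadata=None):
    if topology is None:
        topology = infer_bonds(snapshots[0])
    return Ensemble(snapshots, topology=topology, metadata=metadata)
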
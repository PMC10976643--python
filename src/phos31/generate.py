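"""Synthetic nucleotide ensembles for pipeline testing and calibration.

Generates every input the pipeline needs without downloads: solvated
ATP/ADP/ADP.Pi systems with counter-ions and water shells, a two-protomer
binding-pocket mimic with dummy amino-acid residues, MM-like vs QM-like
P-O bond-length regimes, folded vs elongated phosphate-backbone
conformers, and planted classification effects.

Geometry is built from internal coordinates (a Z-matrix-style
construction), not a force field: phosphate groups are exact tetrahedra
with class-resolved P-O bond lengths (terminal 1.50 Å, bridging 1.60 Å),
the backbone-fold angle P-P-P (or P_i-P_beta-P_alpha) is solved to a
target by root finding on a placement dihedral, and the detached
inorganic phosphate of ADP.Pi sits at d(P_i-O_3B) = 3.42 Å with a
bridging Mg2+. Frame perturbations are independent Gaussian draws on the
bond lengths and fold angle; all randomness flows from one seed through a
counter-based per-frame stream, so any frame is reproducible in
isolation. Outputs are unwrapped (no periodic images).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import geometry
from .features import FeatureSpec, default_feature_spec
from .structures import (
    DEFAULT_CHARGE_TABLE,
    DEFAULT_NAMING_DIALECT,
    Ensemble,
    Snapshot,
    covalent_topology,
    write_charge_table,
    write_trajectory,
)

__all__ = [
    "GeneratorConfig",
    "build_template",
    "generate_ensemble",
    "TERMINAL_PO_A",
    "BRIDGING_PO_A",
    "PI_O3B_A",
    "PHI_ELONGATED_DEG",
    "PHI_FOLDED_DEG",
]

# --- study conditions -------------------------------------------------------
TERMINAL_PO_A = 1.50        # terminal P-O bond, QM-like reference
BRIDGING_PO_A = 1.60        # phosphoanhydride / ester P-O bond
PI_O3B_A = 3.42             # detachment distance of the inorganic phosphate
PHI_ELONGATED_DEG = 130.0   # elongated phosphate backbone
PHI_FOLDED_DEG = 90.0       # folded phosphate backbone
MM_SHIFT_A = -0.07          # MM-like general P-O mean shift
MM_KEY_SHIFT_A = -0.15      # MM-like shift of the most affected bridge bond
MM_SD_FACTOR = 2.0          # MM-like bond noise relative to QM-like
POP_ANGLE_DEG = 130.0       # P-O-P bridge angle
ANCHOR_ANGLE_DEG = 110.0    # P_alpha-P_beta-O_3B placement target

ENVIRONMENTS = ("solution_minimal_ions", "solution_high_ions", "pocket")
REGIMES = ("MM_like", "QM_like")
CONFORMERS = ("elongated", "folded", "mixed")


@dataclasses.dataclass
class GeneratorConfig:
    state: str = "ATP"
    environment: str = "solution_minimal_ions"
    n_frames: int = 100
    regime: str = "QM_like"
    conformer: str = "elongated"
    bond_noise_sd: float = 0.01
    planted_effect: tuple[str, float] | None = None
    seed: int = 0
    # secondary conditions
    timestep_ns: float = 1.0
    phi_noise_sd_deg: float = 3.0
    pi_o3b_sd_A: float = 0.05
    jitter_sd_A: float = 0.03
    conformer_block: int = 50

    def __post_init__(self) -> None:
        if self.state not in ("ATP", "ADP", "ADP.Pi"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.conformer not in CONFORMERS:
            raise ValueError(f"unknown conformer {self.conformer!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.bond_noise_sd < 0:
            raise ValueError("bond_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# bond bookkeeping
# ---------------------------------------------------------------------------

def phosphate_bond_classes(state: str) -> dict[str, str]:
    """Builder bond key ('<Patom>-<Oatom>') -> class (terminal|bridging)."""
    pa = {"PA-O5'": "bridging", "PA-O1A": "terminal", "PA-O2A": "terminal",
          "PA-O3A": "bridging"}
    if state == "ATP":
        pb = {"PB-O3A": "bridging", "PB-O1B": "terminal",
              "PB-O2B": "terminal", "PB-O3B": "bridging"}
        pg = {"PG-O3B": "bridging", "PG-O1G": "terminal",
              "PG-O2G": "terminal", "PG-O3G": "terminal"}
        return {**pa, **pb, **pg}
    # post-cleavage: O3B stays with the beta phosphate as a terminal oxygen
    pb = {"PB-O3A": "bridging", "PB-O1B": "terminal",
          "PB-O2B": "terminal", "PB-O3B": "terminal"}
    out = {**pa, **pb}
    if state == "ADP.Pi":
        out.update({f"PI-O{k}P": "terminal" for k in (1, 2, 3, 4)})
    return out


def ideal_bonds(state: str) -> dict[str, float]:
    refs = {"terminal": TERMINAL_PO_A, "bridging": BRIDGING_PO_A}
    return {k: refs[c] for k, c in phosphate_bond_classes(state).items()}


def _regime_means(state: str, regime: str) -> dict[str, float]:
    means = ideal_bonds(state)
    if regime == "MM_like":
        special = {"PB-O3A"}
        if state == "ATP":
            special.add("PG-O3B")  # the gamma bridge changes the most in ATP
        for k in means:
            means[k] += MM_KEY_SHIFT_A if k in special else MM_SHIFT_A
    return means


# ---------------------------------------------------------------------------
# scaffold: ribose + adenine placeholder (fixed template coordinates)
# ---------------------------------------------------------------------------

_ADENINE_2D = {
    "C8": (0.72, 1.17), "N7": (2.07, 1.04), "C5": (2.47, -0.28),
    "C4": (1.31, -1.08), "N3": (1.33, -2.45), "C2": (0.13, -3.08),
    "N1": (-1.07, -2.46), "C6": (-1.16, -1.09), "N6": (-2.40, -0.50),
}


def _ribose_scaffold() -> dict[str, np.ndarray]:
    """Fixed sugar + base-placeholder coordinates (Å).

    A regular-pentagon ribose ring (side 1.45 Å) in the xy plane, the
    exocyclic substituents tilted out of plane, and a planar adenine
    placeholder hung off N9.
    """
    r = 1.45 / (2.0 * np.sin(np.radians(36.0)))
    ring_names = ("C1'", "C2'", "C3'", "C4'", "O4'")
    pos: dict[str, np.ndarray] = {}
    for name, ang in zip(ring_names, (90.0, 162.0, 234.0, 306.0, 18.0)):
        a = np.radians(ang)
        pos[name] = np.array([r * np.cos(a), r * np.sin(a), 0.0])

    def outward(name: str) -> np.ndarray:
        v = pos[name].copy()
        v /= np.linalg.norm(v)
        return v

    up = np.array([0.0, 0.0, 1.0])
    d5 = outward("C4'") + 1.2 * up
    pos["C5'"] = pos["C4'"] + 1.51 * d5 / np.linalg.norm(d5)
    d2 = outward("C2'") - 0.9 * up
    pos["O2'"] = pos["C2'"] + 1.41 * d2 / np.linalg.norm(d2)
    d3 = outward("C3'") + np.array([0.3, -0.3, -1.1])
    pos["O3'"] = pos["C3'"] + 1.41 * d3 / np.linalg.norm(d3)
    d9 = outward("C1'") + 0.3 * up
    pos["N9"] = pos["C1'"] + 1.47 * d9 / np.linalg.norm(d9)

    e1 = pos["N9"] - pos["C1'"]
    e1 /= np.linalg.norm(e1)
    e2 = up - np.dot(up, e1) * e1
    e2 /= np.linalg.norm(e2)
    for name, (x, y) in _ADENINE_2D.items():
        pos[name] = pos["N9"] + x * e1 + y * e2

    pos["O5'"] = geometry.place_atom(
        pos["O4'"], pos["C4'"], pos["C5'"],
        1.43, geometry.TETRAHEDRAL_ANGLE_DEG, 60.0,
    )
    return pos


def _solve_placement_dihedral(build, vertex, fixed, target_deg,
                              grid_step=5.0):
    """Find tau such that angle(fixed, vertex, build(tau)) == target_deg.

    ``build(tau)`` returns the candidate position. Root-finds on a coarse
    bracket; if the target is outside the attainable range, returns the
    tau of closest approach (the achieved angle is then reported by the
    caller's manifest)."""
    from scipy.optimize import brentq

    taus = np.arange(-180.0, 180.0 + grid_step, grid_step)

    def f(tau: float) -> float:
        return geometry.angle(fixed, vertex, build(tau)) - target_deg

    vals = np.array([f(t) for t in taus])
    best = float(taus[np.argmin(np.abs(vals))])
    for k in range(len(taus) - 1):
        if vals[k] == 0.0:
            return float(taus[k])
        if vals[k] * vals[k + 1] < 0.0:
            return float(brentq(f, taus[k], taus[k + 1], xtol=1e-10))
    return best


def build_phosphate_chain(
    state: str,
    scaffold: Mapping[str, np.ndarray],
    bonds: Mapping[str, float],
    phi_deg: float,
    pi_o3b: float = PI_O3B_A,
    pop_angle: float = POP_ANGLE_DEG,
) -> dict[str, np.ndarray]:
    """Place the phosphate backbone (and, for ADP.Pi, the detached
    phosphate) onto the sugar scaffold with the given bond lengths and
    fold-angle target. O-P-O angles are exactly tetrahedral."""
    tet = geometry.TETRAHEDRAL_ANGLE_DEG
    p: dict[str, np.ndarray] = {}
    c4, c5, o5 = scaffold["C4'"], scaffold["C5'"], scaffold["O5'"]
    p["PA"] = geometry.place_atom(c4, c5, o5, bonds["PA-O5'"], 120.0, 180.0)
    p["O3A"] = geometry.place_atom(c5, o5, p["PA"], bonds["PA-O3A"], tet, 60.0)
    u = (o5 - p["PA"]) / np.linalg.norm(o5 - p["PA"])
    v = (p["O3A"] - p["PA"]) / np.linalg.norm(p["O3A"] - p["PA"])
    w1, w2 = geometry.tetrahedral_completion(u, v)
    p["O1A"] = p["PA"] + bonds["PA-O1A"] * w1
    p["O2A"] = p["PA"] + bonds["PA-O2A"] * w2

    p["PB"] = geometry.place_atom(o5, p["PA"], p["O3A"], bonds["PB-O3A"],
                                  pop_angle, 180.0)

    def build_o3b(tau: float) -> np.ndarray:
        return geometry.place_atom(p["PA"], p["O3A"], p["PB"],
                                   bonds["PB-O3B"], tet, tau)

    tau3 = _solve_placement_dihedral(build_o3b, p["PB"], p["PA"],
                                     ANCHOR_ANGLE_DEG)
    p["O3B"] = build_o3b(tau3)
    u = (p["O3A"] - p["PB"]) / np.linalg.norm(p["O3A"] - p["PB"])
    v = (p["O3B"] - p["PB"]) / np.linalg.norm(p["O3B"] - p["PB"])
    w1, w2 = geometry.tetrahedral_completion(u, v)
    p["O1B"] = p["PB"] + bonds["PB-O1B"] * w1
    p["O2B"] = p["PB"] + bonds["PB-O2B"] * w2

    if state == "ATP":
        def build_pg(tau: float) -> np.ndarray:
            return geometry.place_atom(p["O3A"], p["PB"], p["O3B"],
                                       bonds["PG-O3B"], pop_angle, tau)

        tau4 = _solve_placement_dihedral(build_pg, p["PB"], p["PA"], phi_deg)
        p["PG"] = build_pg(tau4)
        axis = (p["O3B"] - p["PG"]) / np.linalg.norm(p["O3B"] - p["PG"])
        fan = geometry.tetrahedral_fan(axis, p["PB"] - p["PG"])
        for name, d in zip(("O1G", "O2G", "O3G"), fan):
            p[name] = p["PG"] + bonds[f"PG-{name}"] * d
    elif state == "ADP.Pi":
        def build_pi(tau: float) -> np.ndarray:
            return geometry.place_atom(p["O3A"], p["PB"], p["O3B"],
                                       pi_o3b, 120.0, tau)

        tau5 = _solve_placement_dihedral(build_pi, p["PB"], p["PA"], phi_deg)
        p["PI"] = build_pi(tau5)
        away = (p["PI"] - p["O3B"]) / np.linalg.norm(p["PI"] - p["O3B"])
        p["O1P"] = p["PI"] + bonds["PI-O1P"] * away
        fan = geometry.tetrahedral_fan(away, p["O3B"] - p["PI"])
        for name, d in zip(("O2P", "O3P", "O4P"), fan):
            p[name] = p["PI"] + bonds[f"PI-{name}"] * d
        hop = (p["O4P"] - p["PI"]) / np.linalg.norm(p["O4P"] - p["PI"])
        p["HOP"] = p["O4P"] + 0.96 * hop
        p["MG_BRIDGE"] = _bridge_mg(p)
    return p


def _bridge_mg(p: Mapping[str, np.ndarray]) -> np.ndarray:
    """Mg2+ bridging the beta phosphate and the inorganic phosphate:
    equidistant (2.05 Å) from the closest beta-oxygen / P_i-oxygen pair."""
    beta = [p[n] for n in ("O1B", "O2B", "O3B")]
    pio = [p[n] for n in ("O1P", "O2P", "O3P", "O4P")]
    pairs = [(a, b, np.linalg.norm(a - b)) for a in beta for b in pio]
    a, b, d = min(pairs, key=lambda t: t[2])
    mid = 0.5 * (a + b)
    if d >= 2 * 2.05:
        return mid
    e = (b - a) / d
    w = mid - 0.5 * (p["PB"] + p["PI"])
    perp = w - np.dot(w, e) * e
    n = np.linalg.norm(perp)
    if n < 1e-8:
        probe = np.array([0.0, 0.0, 1.0])
        perp = probe - np.dot(probe, e) * e
        n = np.linalg.norm(perp)
    perp /= n
    h = np.sqrt(max(0.0, 2.05**2 - (d / 2.0) ** 2))
    return mid + h * perp


_NUC_ATOM_ORDER = {
    "ATP": ["PG", "O1G", "O2G", "O3G", "PB", "O1B", "O2B", "O3B",
            "PA", "O1A", "O2A", "O3A", "O5'"],
    "ADP": ["PB", "O1B", "O2B", "O3B", "PA", "O1A", "O2A", "O3A", "O5'"],
}
_SUGAR_BASE_ORDER = ["C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
                     "N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3",
                     "C4"]
_PI_ORDER = ["P", "O1P", "O2P", "O3P", "O4P", "HOP"]


def _element_of(name: str) -> str:
    if name.startswith("HOP") or name.startswith("H"):
        return "H"
    return name[0]


ResidueAtoms = list[tuple[str, str, np.ndarray]]  # (atom_name, element, pos)
ResidueSpec = tuple[str, str, int, ResidueAtoms]  # res_name, chain, res_id


def _nucleotide_residues(state: str, chain_positions: Mapping[str, np.ndarray],
                         scaffold: Mapping[str, np.ndarray]) -> list[ResidueSpec]:
    nuc_name = "ATP" if state == "ATP" else "ADP"
    order = _NUC_ATOM_ORDER["ATP" if state == "ATP" else "ADP"]
    atoms: ResidueAtoms = []
    for name in order:
        src = chain_positions if name in chain_positions else scaffold
        atoms.append((name, _element_of(name), np.asarray(src[name], float)))
    for name in _SUGAR_BASE_ORDER:
        atoms.append((name, _element_of(name), np.asarray(scaffold[name], float)))
    residues: list[ResidueSpec] = [(nuc_name, "A", 1, atoms)]
    if state == "ADP.Pi":
        pi_atoms: ResidueAtoms = [
            ("P", "P", chain_positions["PI"]),
            ("O1P", "O", chain_positions["O1P"]),
            ("O2P", "O", chain_positions["O2P"]),
            ("O3P", "O", chain_positions["O3P"]),
            ("O4P", "O", chain_positions["O4P"]),
            ("HOP", "H", chain_positions["HOP"]),
        ]
        residues.append(("PO4", "A", 2, pi_atoms))
        residues.append(
            ("MG", "A", 3, [("MG", "MG", chain_positions["MG_BRIDGE"])])
        )
    return residues


def _assemble_snapshot(residues: Sequence[ResidueSpec], frame_index: int,
                       time_ns: float) -> Snapshot:
    names, elements, res_names, res_ids, chain_ids, coords = [], [], [], [], [], []
    for res_name, chain, res_id, atoms in residues:
        for atom_name, element, pos in atoms:
            names.append(atom_name)
            elements.append(element)
            res_names.append(res_name)
            res_ids.append(res_id)
            chain_ids.append(chain)
            coords.append(np.asarray(pos, float))
    return Snapshot(frame_index, time_ns, names, elements, res_names,
                    res_ids, chain_ids, np.array(coords))


def build_template(state: str, conformer: str = "elongated") -> Snapshot:
    """Idealized single-snapshot template for a state.

    All P-O bonds sit exactly at their class reference length (terminal
    1.50 Å, bridging 1.60 Å), all O-P-O angles are exactly tetrahedral,
    and the fold angle is at the conformer target (elongated 130°, folded
    90°). For ADP.Pi the inorganic phosphate sits at
    d(P_i-O_3B) = 3.42 Å with a bridging Mg2+.
    """
    phi = PHI_FOLDED_DEG if conformer == "folded" else PHI_ELONGATED_DEG
    scaffold = _ribose_scaffold()
    chain = build_phosphate_chain(state, scaffold, ideal_bonds(state), phi)
    residues = _nucleotide_residues(state, chain, scaffold)
    return _assemble_snapshot(residues, 0, 0.0)


# ---------------------------------------------------------------------------
# environment construction
# ---------------------------------------------------------------------------

_RESIDUE_SIDE_CHAINS = {
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "THR": ["CB", "OG1", "CG2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
}

_POCKET_RESIDUE_SET = (
    ["ARG"] * 4 + ["LYS"] * 2 + ["THR"] * 4 + ["ASN"] * 3 + ["LEU"] * 3
)

INNER_SHELL_A = (2.9, 3.5)      # guaranteed QM members (cutoff 3.8)
EXCHANGE_SHELL_A = (5.0, 7.5)   # base band of exchanging member waters
OUTER_MIN_A = 5.0               # guaranteed MM (margin for frame noise + H)
OUTER_MAX_A = 8.5
CLASH_A = 2.4
APPROACH_A = 3.2                # first-shell visit distance of an exchange

N_QM_WATERS = {"solution": 64, "pocket": 164}
N_STATIC_INNER = {"solution": 20, "pocket": 10}
N_OUTER_WATERS = {"solution": 40, "pocket": 60}


def _counterion_plan(state: str, environment: str) -> list[tuple[str, str, bool]]:
    """(residue/element name, element, inner?) per ion."""
    if state == "ATP":
        ions = [("MG", "MG", True), ("MG", "MG", True)]
    elif state == "ADP":
        ions = [("MG", "MG", True), ("NA", "NA", True)]
    else:  # ADP.Pi: the bridging Mg2+ is built with the template
        ions = [("MG", "MG", True), ("NA", "NA", True)]
    if environment == "solution_high_ions" or environment == "pocket":
        ions += [("NA", "NA", True), ("K", "K", True)]
    if environment == "solution_high_ions":
        ions += [("CL", "CL", False), ("CL", "CL", False),
                 ("NA", "NA", False), ("K", "K", False),
                 ("CL", "CL", False), ("CL", "CL", False)]
    return ions


def _water_geometry(center: np.ndarray, rng: np.random.Generator) -> ResidueAtoms:
    """Rigid 3-site water with a random (frame-fixed) orientation."""
    rot = geometry.random_rotation(rng)
    half = np.radians(104.52 / 2.0)
    d1 = rot @ np.array([np.sin(half), np.cos(half), 0.0])
    d2 = rot @ np.array([-np.sin(half), np.cos(half), 0.0])
    return [
        ("O", "O", center),
        ("H1", "H", center + 0.9572 * d1),
        ("H2", "H", center + 0.9572 * d2),
    ]


def _min_dist(point: np.ndarray, coords: np.ndarray) -> float:
    if len(coords) == 0:
        return np.inf
    return float(np.min(np.linalg.norm(coords - point, axis=1)))


class _Placer:
    """Rejection-sampling placement around the template core atoms."""

    def __init__(self, core_coords: np.ndarray, all_coords: np.ndarray,
                 rng: np.random.Generator):
        self.core = core_coords
        self.placed = list(all_coords)
        self.rng = rng

    def occupied(self) -> np.ndarray:
        return np.asarray(self.placed)

    def sample_shell(self, band: str, max_tries: int = 20000) -> np.ndarray:
        """Sample a clash-free point in a distance band from the core.

        Bands: 'inner' (guaranteed within the QM cutoff), 'exchange' (base
        position of a water that visits the first shell in one frame) and
        'outer' (never within the cutoff)."""
        lo, hi = {
            "inner": INNER_SHELL_A,
            "exchange": EXCHANGE_SHELL_A,
            "outer": (OUTER_MIN_A, OUTER_MAX_A),
        }[band]
        for _ in range(max_tries):
            anchor = self.core[self.rng.integers(len(self.core))]
            u = self.rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = anchor + self.rng.uniform(lo, hi) * u
            dmin_core = _min_dist(pos, self.core)
            if band == "inner" and not (lo - 0.2 <= dmin_core <= hi):
                continue
            if band != "inner" and dmin_core < lo:
                continue
            if _min_dist(pos, self.occupied()) < CLASH_A:
                continue
            self.placed.append(pos)
            return pos
        raise RuntimeError("shell placement failed: region too crowded")


def _place_ions(placer: _Placer, plan, rng, next_res_id: int
                ) -> tuple[list[ResidueSpec], int]:
    out = []
    for res_name, element, inner in plan:
        pos = placer.sample_shell("inner" if inner else "outer")
        out.append((res_name, "A", next_res_id, [(element, element, pos)]))
        next_res_id += 1
    return out, next_res_id


def _place_waters(placer: _Placer, n_member: int, n_static: int, n_outer: int,
                  n_frames: int, rng, next_res_id: int, chain: str = "W"
                  ) -> tuple[list[ResidueSpec], dict[int, tuple[int, np.ndarray]], int]:
    """Place member waters (static first shell + exchanging), then outer
    waters.

    Exchanging waters sit outside the cutoff at their base position and
    visit the first shell (APPROACH_A from their anchor core atom) in one
    randomly assigned frame — the solvent exchange that makes trajectory-
    union membership much larger than any single frame's shell. Returns
    the residue list and {residue index in list: (visit frame,
    translation vector)}."""
    out: list[ResidueSpec] = []
    visits: dict[int, tuple[int, np.ndarray]] = {}
    n_static = min(n_static, n_member)
    for k in range(n_member + n_outer):
        if k < n_static:
            band = "inner"
        elif k < n_member:
            band = "exchange"
        else:
            band = "outer"
        pos = placer.sample_shell(band)
        atoms = _water_geometry(pos, rng)
        if band == "exchange":
            anchor = placer.core[int(np.argmin(
                np.linalg.norm(placer.core - pos, axis=1)))]
            u = (pos - anchor) / np.linalg.norm(pos - anchor)
            target = anchor + APPROACH_A * u
            visits[len(out)] = (int(rng.integers(n_frames)), target - pos)
        out.append(("HOH", chain, next_res_id, atoms))
        next_res_id += 1
    return out, visits, next_res_id


def _build_tripeptide(res_name: str, core: np.ndarray, occupied: np.ndarray,
                      rng: np.random.Generator, chain: str, mid_res_id: int,
                      tip_clash: float = 2.6,
                      tip_window: tuple[float, float] = (3.0, 3.5),
                      ) -> list[ResidueSpec] | None:
    """One pocket-lining stub: a middle residue whose side chain points
    into the pocket (tip 3.0-3.5 Å from a core atom) flanked by two
    glycine neighbours bonded through the backbone, all well outside the
    cutoff. Side chains are extended linear stubs, not rotamer-correct."""
    side = _RESIDUE_SIDE_CHAINS[res_name]
    anchor = core[rng.integers(len(core))]
    centroid = core.mean(axis=0)
    u = anchor - centroid
    nu = np.linalg.norm(u)
    u = (u / nu) if nu > 1e-6 else np.array([1.0, 0.0, 0.0])
    u = u + 0.25 * rng.normal(size=3)
    u /= np.linalg.norm(u)
    tip = anchor + rng.uniform(*tip_window) * u
    if _min_dist(tip, occupied) < tip_clash or not (
            tip_window[0] - 0.2 <= _min_dist(tip, core) <= tip_window[1]):
        return None
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(u, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)

    step = 1.5
    positions: dict[str, np.ndarray] = {}
    # side chain runs tip -> CB going away from the pocket
    for k, name in enumerate(reversed(side)):
        positions[name] = tip + k * step * u + 0.15 * ((-1) ** k) * perp
    cb = positions["CB"]
    ca = cb + 1.53 * u
    n_dir = np.cos(np.radians(70)) * u + np.sin(np.radians(70)) * perp
    c_dir = np.cos(np.radians(70)) * u - np.sin(np.radians(70)) * perp
    positions["CA"] = ca
    positions["N"] = ca + 1.46 * n_dir
    positions["C"] = ca + 1.53 * c_dir
    positions["O"] = positions["C"] + 1.23 * (u + perp) / np.linalg.norm(u + perp)

    mid_atoms: ResidueAtoms = [
        (nm, _element_of(nm), positions[nm])
        for nm in ["N", "CA", "C", "O"] + side
    ]
    all_pos = np.array([p for _, _, p in mid_atoms])
    if np.min([_min_dist(p, occupied) for p in all_pos]) < 2.4:
        return None

    def gly(attach: np.ndarray, direction: np.ndarray, towards_n: bool
            ) -> ResidueAtoms:
        d = direction / np.linalg.norm(direction)
        a0 = attach + 1.33 * d          # peptide bond partner
        a1 = a0 + 1.50 * d              # CA
        a2 = a1 + 1.48 * (d + 0.3 * perp) / np.linalg.norm(d + 0.3 * perp)
        o = a0 + 1.23 * perp
        if towards_n:   # previous residue: C, CA, N, O
            return [("N", "N", a2), ("CA", "C", a1), ("C", "C", a0),
                    ("O", "O", o)]
        return [("N", "N", a0), ("CA", "C", a1), ("C", "C", a2),
                ("O", "O", o)]

    prev_atoms = gly(positions["N"], u + 0.6 * perp, towards_n=True)
    next_atoms = gly(positions["C"], u - 0.6 * perp, towards_n=False)
    for atoms in (prev_atoms, next_atoms):
        for _, _, p in atoms:
            if _min_dist(p, core) < 4.3:
                return None
    return [
        ("GLY", chain, mid_res_id - 1, prev_atoms),
        (res_name, chain, mid_res_id, mid_atoms),
        ("GLY", chain, mid_res_id + 1, next_atoms),
    ]


def _place_pocket_residues(placer: _Placer, rng: np.random.Generator
                           ) -> list[ResidueSpec]:
    out: list[ResidueSpec] = []
    res_id = 100
    chains = ("B", "C")  # two-protomer mimic
    # progressively relaxed tip constraints keep placement seed-robust
    phases = [
        (2.6, (3.0, 3.5), 1500),
        (2.4, (2.9, 3.7), 1500),
        (2.2, (2.8, 3.75), 3000),
    ]
    for k, res_name in enumerate(_POCKET_RESIDUE_SET):
        chain = chains[k % 2]
        trip = None
        for clash, window, tries in phases:
            for _ in range(tries):
                trip = _build_tripeptide(
                    res_name, placer.core, placer.occupied(), rng, chain,
                    res_id, tip_clash=clash, tip_window=window,
                )
                if trip is not None:
                    break
            if trip is not None:
                break
        if trip is None:
            raise RuntimeError(f"could not place pocket residue {res_name}")
        for _, _, _, atoms in trip:
            placer.placed.extend(p for _, _, p in atoms)
        out.extend(trip)
        res_id += 10
    return out


# ---------------------------------------------------------------------------
# ensemble generation
# ---------------------------------------------------------------------------

def _core_coords(template: Snapshot, state: str) -> np.ndarray:
    """Phosphate backbone + sugar-ring coordinates of the template."""
    from .qmregion import core_atom_indices
    from .structures import map_phosphorus_topology

    pmap = map_phosphorus_topology(template, state)
    idx = core_atom_indices(template, pmap)
    return template.coords[idx]


def _conformer_phi(config: GeneratorConfig, frame: int) -> float:
    if config.conformer == "elongated":
        return PHI_ELONGATED_DEG
    if config.conformer == "folded":
        return PHI_FOLDED_DEG
    block = (frame // config.conformer_block) % 2
    return PHI_ELONGATED_DEG if block == 0 else PHI_FOLDED_DEG


def _planted_parameter(config: GeneratorConfig) -> tuple[str, str] | None:
    """Map the planted feature name onto a builder parameter.

    Returns (kind, key) with kind in {'phi', 'pi_o3b', 'bond'}.
    """
    if config.planted_effect is None:
        return None
    name, _gap = config.planted_effect
    spec: FeatureSpec = default_feature_spec(config.state)
    if name not in spec:
        raise ValueError(
            f"planted feature {name!r} is not in the default FeatureSpec "
            f"for state {config.state}"
        )
    feat = spec.get(name)
    if name.startswith("phi("):
        return ("phi", "")
    if feat.kind == "distance" and set(feat.labels) == {"P_i", "O_3B"}:
        return ("pi_o3b", "")
    if feat.kind == "distance":
        a, b = feat.labels
        names = {DEFAULT_NAMING_DIALECT.get(l, l) for l in (a, b)}
        p = [n for n in names if n in ("PA", "PB", "PG")]
        o = [n for n in names if n.startswith("O")]
        if p and o:
            key = f"{p[0]}-{o[0]}"
            if key in phosphate_bond_classes(config.state):
                return ("bond", key)
    raise ValueError(
        f"planting is supported for the fold angle, d(P_i-O_3B) and P-O "
        f"bond features, not {name!r}"
    )


def generate_ensemble(
    config: GeneratorConfig,
    outdir: str | Path | None = None,
) -> Ensemble:
    """Generate a synthetic pseudo-trajectory under the configured
    conditions.

    MM_like frames draw P-O bonds with the mean shifted -0.07 Å (the most
    affected bridge bond -0.15 Å) and twice the QM_like noise SD; QM_like
    frames use the reference means and SD = bond_noise_sd. The fold angle
    follows the conformer schedule with Gaussian noise; for ADP.Pi the
    detachment distance is drawn around 3.42 Å. A planted effect shifts
    the named feature by the class gap in the frames destined to be
    downfield under the surrogate bond-shift coupling (the half of the
    frames with the longest summed P_beta-O bonds). Fully deterministic
    given the seed; frame k draws from its own counter-based stream.

    When ``outdir`` is given, writes trajectory.pdb (multi-model),
    charges.txt and manifest.yaml there.
    """
    state, env = config.state, config.environment
    template = build_template(state, "folded" if config.conformer == "folded"
                              else "elongated")
    scaffold = _ribose_scaffold()
    core = _core_coords(template, state)

    rng_env = np.random.default_rng([config.seed % (2**31), 17, 1])
    placer = _Placer(core, template.coords, rng_env)
    env_residues: list[ResidueSpec] = []
    next_res_id = 10
    ions, next_res_id = _place_ions(
        placer, _counterion_plan(state, env), rng_env, next_res_id
    )
    env_residues.extend(ions)
    if env == "pocket":
        env_residues.extend(_place_pocket_residues(placer, rng_env))
    shell = "pocket" if env == "pocket" else "solution"
    waters, visits, _ = _place_waters(
        placer, N_QM_WATERS[shell], N_STATIC_INNER[shell],
        N_OUTER_WATERS[shell], config.n_frames, rng_env, 1000,
    )
    water_offset = len(env_residues)
    env_residues.extend(waters)
    visit_by_residue = {water_offset + k: v for k, v in visits.items()}

    # per-frame draws (own stream per frame so frames rebuild in isolation)
    means = _regime_means(state, config.regime)
    sd = config.bond_noise_sd * (MM_SD_FACTOR if config.regime == "MM_like"
                                 else 1.0)
    frame_bonds: list[dict[str, float]] = []
    frame_phi: list[float] = []
    frame_pi: list[float] = []
    for k in range(config.n_frames):
        rng_k = np.random.default_rng([config.seed % (2**31), 29, k])
        frame_bonds.append(
            {key: float(rng_k.normal(mu, sd)) for key, mu in means.items()}
        )
        frame_phi.append(float(rng_k.normal(
            _conformer_phi(config, k), config.phi_noise_sd_deg)))
        frame_pi.append(float(rng_k.normal(PI_O3B_A, config.pi_o3b_sd_A)))

    # downfield destiny under the surrogate: frames whose beta-phosphate
    # bonds are longest (lowest sigma -> most downfield delta)
    classes = phosphate_bond_classes(state)
    refs = {"terminal": TERMINAL_PO_A, "bridging": BRIDGING_PO_A}
    proxy = np.array([
        sum(b[key] - refs[classes[key]] for key in b if key.startswith("PB-"))
        for b in frame_bonds
    ])
    n_down = config.n_frames // 2
    downfield_frames = set(np.argsort(-proxy, kind="stable")[:n_down].tolist())

    planted = _planted_parameter(config)
    if planted is not None:
        kind, key = planted
        gap = float(config.planted_effect[1])
        for k in downfield_frames:
            if kind == "phi":
                frame_phi[k] += gap
            elif kind == "pi_o3b":
                frame_pi[k] += gap
            else:
                frame_bonds[k][key] += gap

    jitter_clip = 3.0 * config.jitter_sd_A
    snapshots: list[Snapshot] = []
    for k in range(config.n_frames):
        chain = build_phosphate_chain(
            state, scaffold, frame_bonds[k], frame_phi[k], frame_pi[k]
        )
        residues = _nucleotide_residues(state, chain, scaffold)
        rng_j = np.random.default_rng([config.seed % (2**31), 31, k])
        for r_idx, (res_name, chain_id, res_id, atoms) in enumerate(env_residues):
            if res_name == "HOH":
                shift = np.clip(rng_j.normal(0, config.jitter_sd_A, 3),
                                -jitter_clip, jitter_clip)
                visit = visit_by_residue.get(r_idx)
                if visit is not None and visit[0] == k:
                    shift = shift + visit[1]  # first-shell visit this frame
                moved = [(nm, el, p + shift) for nm, el, p in atoms]
            else:
                moved = [
                    (nm, el, p + np.clip(
                        rng_j.normal(0, config.jitter_sd_A, 3),
                        -jitter_clip, jitter_clip))
                    for nm, el, p in atoms
                ]
            residues.append((res_name, chain_id, res_id, moved))
        snapshots.append(
            _assemble_snapshot(residues, k, k * config.timestep_ns)
        )

    # topology from the ideal-geometry frame (shared across the ensemble)
    ideal_chain = build_phosphate_chain(
        state, scaffold, ideal_bonds(state),
        _conformer_phi(config, 0), PI_O3B_A,
    )
    ideal_residues = _nucleotide_residues(state, ideal_chain, scaffold)
    ideal_residues.extend(env_residues)
    ideal_snapshot = _assemble_snapshot(ideal_residues, 0, 0.0)
    topology = covalent_topology(ideal_snapshot)

    manifest = {
        "state": state,
        "environment": env,
        "regime": config.regime,
        "conformer": config.conformer,
        "n_frames": config.n_frames,
        "seed": config.seed,
        "bond_means_A": means,
        "bond_noise_sd_A": sd,
        "phi_targets_deg": [round(x, 6) for x in frame_phi],
        "pi_o3b_targets_A": ([round(x, 6) for x in frame_pi]
                             if state == "ADP.Pi" else None),
        "downfield_frames": sorted(int(i) for i in downfield_frames),
        "planted_effect": (list(config.planted_effect)
                           if config.planted_effect else None),
        "n_qm_waters": N_QM_WATERS[shell],
        "n_outer_waters": N_OUTER_WATERS[shell],
    }
    ensemble = Ensemble(
        snapshots,
        topology=topology,
        metadata={
            "state": state, "environment": "pocket" if env == "pocket"
            else "solution", "regime": config.regime,
            "timestep_ns": config.timestep_ns, "seed": config.seed,
            "manifest": manifest,
        },
    )
    if outdir is not None:
        import yaml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trajectory(ensemble, outdir / "trajectory.pdb")
        write_charge_table(DEFAULT_CHARGE_TABLE, outdir / "charges.txt")
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return ensemble
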
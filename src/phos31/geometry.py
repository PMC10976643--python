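"""Internal-coordinate geometry primitives.

Distances, bond angles, proper dihedrals, Z-matrix-style atom placement
(the NeRF construction), and exact tetrahedral direction frames used by
the synthetic structure builder.

Conventions: lengths in Å, angles in degrees. Dihedrals follow the IUPAC
right-handed sign convention and lie in (-180, 180].
"""

from __future__ import annotations

import numpy as np

TETRAHEDRAL_ANGLE_DEG = float(np.degrees(np.arccos(-1.0 / 3.0)))  # 109.4712...


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance |a - b| in Å."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c at vertex b, in degrees within [0, 180]."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle undefined: coincident atoms")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Proper dihedral a-b-c-d in degrees, right-handed, in (-180, 180].

    Raises ValueError when a-b-c or b-c-d are collinear (torsion undefined).
    """
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: collinear atoms")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    ang_deg: float,
    dih_deg: float,
) -> np.ndarray:
    """Place atom D with |D-c| = bond, angle(b,c,D) = ang_deg and
    dihedral(a,b,c,D) = dih_deg (NeRF construction)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.radians(ang_deg)
    phi = np.radians(dih_deg)
    # local displacement in the frame of the b->c bond
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("cannot place atom: reference atoms collinear")
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def tetrahedral_completion(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Given two unit directions u, v from a center at the exact tetrahedral
    angle, return the remaining two unit directions of the tetrahedron.

    Both returned directions w satisfy w·u = w·v = -1/3 exactly (up to
    floating point), so completing a phosphate with them yields exact
    tetrahedral O-P-O angles.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    b1 = u + v
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(u, v)
    b2 /= np.linalg.norm(b2)
    # w = alpha*b1 + beta*b2 with w·u = w·v = cos(tet) = -1/3
    cos_uv = float(np.dot(u, v))
    alpha = (-1.0 / 3.0) / np.sqrt((1.0 + cos_uv) / 2.0)
    beta = np.sqrt(max(0.0, 1.0 - alpha * alpha))
    return alpha * b1 + beta * b2, alpha * b1 - beta * b2


def tetrahedral_fan(axis: np.ndarray, reference: np.ndarray) -> list[np.ndarray]:
    """Three unit directions at the exact tetrahedral angle from ``axis``,
    spaced 120 degrees apart about it, phased against ``reference``.

    Used to cap a phosphorus that has a single fixed neighbour (e.g. the
    three terminal oxygens of the gamma phosphate around the P-O3B axis).
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    ref = np.asarray(reference, float)
    perp = ref - np.dot(ref, axis) * axis
    n = np.linalg.norm(perp)
    if n < 1e-10:
        # reference parallel to axis: pick any perpendicular
        probe = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(probe, axis)) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        perp = probe - np.dot(probe, axis) * axis
        n = np.linalg.norm(perp)
    perp /= n
    other = np.cross(axis, perp)
    theta = np.radians(TETRAHEDRAL_ANGLE_DEG)
    out = []
    for k in range(3):
        phi = np.radians(120.0 * k)
        w = (
            np.cos(theta) * axis
            + np.sin(theta) * (np.cos(phi) * perp + np.sin(phi) * other)
        )
        out.append(w / np.linalg.norm(w))
    return out


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (QR-based)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q
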
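"""Structural features of the phosphate backbone.

Internal-coordinate measurement (distances, angles, dihedrals), the named
feature vector describing the chemical environment of the P_beta nucleus,
and distribution summaries in the boxplot convention (quartiles by linear
interpolation, whiskers at 1.5 x IQR).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import geometry
from .structures import Ensemble, PhosphorusMap, Snapshot

__all__ = [
    "Feature",
    "FeatureSpec",
    "BoxplotSummary",
    "default_feature_spec",
    "measure_internal_coordinate",
    "extract_feature_vector",
    "extract_feature_matrix",
    "boxplot_stats",
]

KINDS = ("distance", "angle", "dihedral")


@dataclasses.dataclass(frozen=True)
class Feature:
    """One named internal coordinate, expressed in canonical backbone labels."""

    name: str
    kind: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        expected = {"distance": 2, "angle": 3, "dihedral": 4}[self.kind]
        if len(self.labels) != expected:
            raise ValueError(
                f"{self.name}: {self.kind} needs {expected} labels, "
                f"got {len(self.labels)}"
            )


class FeatureSpec:
    """Ordered list of named features with a declared count."""

    def __init__(self, features: Sequence[Feature], declared_count: int | None = None):
        self.features = list(features)
        self.declared_count = (
            len(self.features) if declared_count is None else int(declared_count)
        )
        if len(self.features) != self.declared_count:
            raise ValueError(
                f"feature list has {len(self.features)} entries, "
                f"declared {self.declared_count}"
            )
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def _dist(a: str, b: str) -> Feature:
    return Feature(f"d({a}-{b})", "distance", (a, b))


def _ang(a: str, b: str, c: str) -> Feature:
    return Feature(f"angle({a}-{b}-{c})", "angle", (a, b, c))


def _dih(a: str, b: str, c: str, d: str) -> Feature:
    return Feature(f"dihedral({a}-{b}-{c}-{d})", "dihedral", (a, b, c, d))


def default_feature_spec(state: str = "ADP.Pi") -> FeatureSpec:
    """The default feature list describing the P_beta environment.

    For ADP.Pi (the classification state) the list has 24 entries: the
    backbone-fold angle phi(P_i-P_beta-P_alpha), all P-O bonds of the
    phosphate backbone, the detachment distance d(P_i-O_3B), P-P
    separations, the six O-P_beta-O angles and backbone dihedrals. ATP
    substitutes P_gamma for P_i; ADP, lacking a third phosphorus, has a
    shorter (17-entry) list. The list is configuration, not a constant:
    callers may substitute their own spec.
    """
    pa_bonds = [_dist("P_alpha", o) for o in ("O_5'", "O_1A", "O_2A", "O_3A")]
    pb_bonds = [_dist("P_beta", o) for o in ("O_3A", "O_1B", "O_2B", "O_3B")]
    opbo = [
        _ang(a, "P_beta", b)
        for a, b in (
            ("O_1B", "O_2B"), ("O_1B", "O_3B"), ("O_2B", "O_3B"),
            ("O_3A", "O_1B"), ("O_3A", "O_2B"), ("O_3A", "O_3B"),
        )
    ]
    backbone_dih = [
        _dih("O_5'", "P_alpha", "O_3A", "P_beta"),
        _dih("P_alpha", "O_3A", "P_beta", "O_3B"),
        _dih("O_1A", "P_alpha", "O_3A", "P_beta"),
    ]
    if state == "ADP.Pi":
        third = "P_i"
        third_feats = [
            Feature("phi(P_i-P_beta-P_alpha)", "angle",
                    ("P_i", "P_beta", "P_alpha")),
            _dist("P_i", "O_3B"),
            _dist("P_i", "P_beta"),
            _dist("P_i", "P_alpha"),
            _ang("P_i", "O_3B", "P_beta"),
        ]
    elif state == "ATP":
        third = "P_gamma"
        third_feats = [
            Feature("phi(P_gamma-P_beta-P_alpha)", "angle",
                    ("P_gamma", "P_beta", "P_alpha")),
            _dist("P_gamma", "O_3B"),
            _dist("P_gamma", "P_beta"),
            _dist("P_gamma", "P_alpha"),
            _ang("P_gamma", "O_3B", "P_beta"),
        ]
    elif state == "ADP":
        feats = (
            pa_bonds + pb_bonds + opbo + backbone_dih
            + [_dist("P_alpha", "P_beta"), _ang("P_alpha", "O_3A", "P_beta")]
        )
        return FeatureSpec(feats)
    else:
        raise ValueError(f"unknown state {state!r}")
    feats = (
        third_feats
        + pa_bonds
        + pb_bonds
        + [_dist("P_alpha", "P_beta"), _ang("P_alpha", "O_3A", "P_beta")]
        + opbo
        + backbone_dih
    )
    assert len(feats) == 24, len(feats)
    return FeatureSpec(feats, declared_count=24)


def _resolve(atoms: Iterable, snapshot: Snapshot,
             pmap: PhosphorusMap | None) -> list[int]:
    out = []
    for a in atoms:
        if isinstance(a, (int, np.integer)):
            out.append(int(a))
        else:
            if pmap is None:
                raise ValueError(
                    f"label {a!r} given without a PhosphorusMap to resolve it"
                )
            if a not in pmap:
                raise KeyError(f"label {a!r} not present in the map "
                               f"(state {pmap.state})")
            out.append(int(pmap[a]))
    if len(set(out)) != len(out):
        raise ValueError("internal coordinate requires distinct atoms")
    return out


def measure_internal_coordinate(
    snapshot: Snapshot,
    kind: str,
    atoms: Sequence,
    pmap: PhosphorusMap | None = None,
) -> float:
    """Measure a distance (Å), bond angle ([0, 180] deg) or proper dihedral
    ((-180, 180] deg, IUPAC right-handed) on one snapshot.

    ``atoms`` may be atom indices or canonical labels (resolved through
    ``pmap``). A collinear triple makes the dihedral undefined and raises.
    """
    idx = _resolve(atoms, snapshot, pmap)
    pos = [snapshot.coords[i] for i in idx]
    if kind == "distance":
        return geometry.distance(*pos)
    if kind == "angle":
        return geometry.angle(*pos)
    if kind == "dihedral":
        return geometry.dihedral(*pos)
    raise ValueError(f"unknown kind {kind!r}")


def extract_feature_vector(
    snapshot: Snapshot,
    pmap: PhosphorusMap,
    spec: FeatureSpec,
) -> np.ndarray:
    """Feature vector for one snapshot, in spec order."""
    vec = np.empty(len(spec))
    for k, feat in enumerate(spec):
        try:
            vec[k] = measure_internal_coordinate(
                snapshot, feat.kind, feat.labels, pmap
            )
        except KeyError as exc:
            raise KeyError(
                f"feature {feat.name!r}: unresolvable label {exc}"
            ) from None
    return vec


def extract_feature_matrix(
    ensemble: Ensemble,
    pmap: PhosphorusMap,
    spec: FeatureSpec,
) -> pd.DataFrame:
    """Per-snapshot feature matrix, rows indexed by frame_index."""
    rows = [extract_feature_vector(s, pmap, spec) for s in ensemble]
    return pd.DataFrame(
        np.asarray(rows),
        index=pd.Index([s.frame_index for s in ensemble], name="frame_index"),
        columns=spec.names(),
    )


@dataclasses.dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")


def boxplot_stats(values: Sequence[float]) -> BoxplotSummary:
    """Five-number boxplot summary.

    Quartiles use the linear-interpolation convention; whiskers are clipped
    to the most extreme datum within 1.5 x IQR of the quartiles; points
    beyond the whiskers are outliers.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("boxplot_stats requires at least one value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    wlo = float(inside.min())
    whi = float(inside.max())
    outliers = np.sort(v[(v < lo_fence) | (v > hi_fence)])
    return BoxplotSummary(
        median=float(med), q1=float(q1), q3=float(q3), iqr=float(iqr),
        whisker_low=wlo, whisker_high=whi, outliers=outliers,
    )
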
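"""End-to-end orchestration: simulate -> extract -> carve -> shieldings ->
reference -> analyze -> classify.

A run is fully described by a :class:`RunConfig`; every stage is a pure
function of its inputs, intermediates are serialized as delimited tables,
and re-running an identical config reproduces all outputs (stochastic
steps are seeded from the config). The results bundle is a directory of
delimited tables plus a provenance record (config hash, seed, package
version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ImportanceReport,
    PopulationSplit,
    feature_correlations,
    feature_importance,
    select_extreme_populations,
)
from .features import FeatureSpec, default_feature_spec, extract_feature_matrix
from .generate import GeneratorConfig, generate_ensemble
from .qmregion import (
    QMRegionConfig,
    QMRegionSpec,
    compute_qm_charge,
    plan_boundary_cuts,
    place_link_atoms,
    select_qm_union,
)
from .shielding import (
    ShiftSeries,
    SurrogateParams,
    compute_shieldings,
    reference_shifts,
)
from .stats import (
    DeviationRow,
    RollingConfig,
    deviation_table,
    ensemble_summary,
    peak_order,
    rolling_average,
)
from .structures import (
    Ensemble,
    extract_snapshots,
    map_phosphorus_topology,
    read_trajectory,
    write_trajectory,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "DEFAULT_EXPERIMENTAL_SHIFTS"]

logger = logging.getLogger("phos31.pipeline")

# Representative experimental 31P shifts (ppm) used as defaults for the
# deviation tables; these are inputs, not computed quantities, and are
# normally supplied per study in the run config.
DEFAULT_EXPERIMENTAL_SHIFTS: dict[str, dict[str, float]] = {
    "ATP": {"P_alpha": -7.0, "P_beta": -16.09, "P_gamma": -5.0},
    "ADP": {"P_alpha": -7.0, "P_beta": -4.0},
    "ADP.Pi": {"P_alpha": -7.0, "P_beta": -15.85, "P_i": 2.5},
}


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``generator`` defines the synthetic input (or ``input_trajectory``
    points at an existing multi-model PDB); the remaining fields carry the
    stage parameters. ``n_per_side`` is clamped to half the frame count
    when the ensemble is too short for the requested populations.
    """

    generator: GeneratorConfig = dataclasses.field(
        default_factory=GeneratorConfig)
    input_trajectory: str | None = None
    extract_interval_ns: float | None = None
    qm: QMRegionConfig = dataclasses.field(default_factory=QMRegionConfig)
    surrogate: SurrogateParams = dataclasses.field(
        default_factory=SurrogateParams)
    rolling: RollingConfig = dataclasses.field(default_factory=RollingConfig)
    experimental_shifts: Mapping[str, float] | None = None
    n_per_side: int = 150
    feature_spec: FeatureSpec | None = None
    engine: str = "geometric"
    write_ensemble: bool = False

    def resolved_experimental(self) -> dict[str, float]:
        if self.experimental_shifts is not None:
            return dict(self.experimental_shifts)
        return dict(DEFAULT_EXPERIMENTAL_SHIFTS[self.generator.state])

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in
                        dataclasses.asdict(obj).items()}
            if isinstance(obj, FeatureSpec):
                return [dataclasses.asdict(f) for f in obj]
            if isinstance(obj, Mapping):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "generator": enc(self.generator),
            "input_trajectory": self.input_trajectory,
            "extract_interval_ns": self.extract_interval_ns,
            "qm": enc(self.qm),
            "surrogate": enc(self.surrogate),
            "rolling": enc(self.rolling),
            "experimental_shifts": self.resolved_experimental(),
            "n_per_side": self.n_per_side,
            "engine": self.engine,
            "feature_spec": (enc(self.feature_spec)
                             if self.feature_spec else None),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class PipelineResult:
    ensemble: Ensemble
    qm_spec: QMRegionSpec
    charges: list[int]
    shift_series: ShiftSeries
    summary: pd.DataFrame
    deviation: DeviationRow
    rolling: dict[str, np.ndarray]
    peak_order: list[str]
    split: PopulationSplit | None
    importance: ImportanceReport | None
    correlations: pd.DataFrame | None
    outdir: Path | None


def _stage(name: str):
    """Decorator tagging a stage so failures name the stage."""
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig, outdir: str | Path | None = None
                 ) -> PipelineResult:
    """Execute the full analysis and (optionally) write the results
    bundle. Deterministic given the config: all randomness flows from
    ``config.generator.seed``."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
    try:
        return _run(config, out)
    finally:
        if out is not None:
            logger.removeHandler(handler)
            handler.close()


def _run(config: RunConfig, out: Path | None) -> PipelineResult:
    state = config.generator.state

    # -- simulate / load ----------------------------------------------------
    if config.input_trajectory:
        ensemble = _stage("simulate")(read_trajectory)(
            config.input_trajectory,
            timestep_ns=config.generator.timestep_ns,
            metadata={"state": state},
        )
    else:
        ensemble = _stage("simulate")(generate_ensemble)(config.generator)

    # -- extract ------------------------------------------------------------
    if config.extract_interval_ns is not None:
        ensemble = _stage("extract")(extract_snapshots)(
            ensemble, config.extract_interval_ns)
    logger.info("ensemble: %d frames, %d atoms", len(ensemble),
                ensemble.n_atoms)

    pmap = map_phosphorus_topology(ensemble.snapshots[0], state)

    # -- carve --------------------------------------------------------------
    @_stage("carve")
    def carve():
        spec = select_qm_union(ensemble, pmap, config.qm)
        spec = plan_boundary_cuts(spec, ensemble.snapshots[0],
                                  ensemble.topology)
        charges = [compute_qm_charge(spec, None, s) for s in ensemble]
        spec.total_charge = charges
        # link atoms are recomputed per snapshot; validate on every frame
        for s in ensemble:
            place_link_atoms(spec.boundary_cuts, s, config.qm)
        return spec, charges

    qm_spec, charges = carve()
    logger.info("QM region: %d atoms, %d cuts, charge %s",
                len(qm_spec.qm_atom_indices), len(qm_spec.boundary_cuts),
                charges[0])

    # -- shieldings + referencing -------------------------------------------
    @_stage("shieldings")
    def shield():
        records = [
            compute_shieldings(config.engine, s, qm_spec, pmap,
                               params=config.surrogate,
                               topology=ensemble.topology)
            for s in ensemble
        ]
        exp = config.resolved_experimental()
        return records, reference_shifts(records, records, exp["P_alpha"],
                                         state=state)

    records, series = shield()

    # -- analyze ------------------------------------------------------------
    @_stage("analyze")
    def analyze():
        summary = ensemble_summary(series).table
        exp = config.resolved_experimental()
        deviation = deviation_table(series.means(), exp)
        rolling = {
            nuc: rolling_average(series.delta[nuc], config.rolling)
            for nuc in series.nuclei
        }
        order, _tie = peak_order(series)
        return summary, deviation, rolling, order

    summary, deviation, rolling, order = analyze()

    # -- classify -----------------------------------------------------------
    @_stage("classify")
    def classify():
        n = min(config.n_per_side, len(ensemble) // 2)
        if n < 2:
            logger.warning("too few frames for classification; skipping")
            return None, None, None
        if n < config.n_per_side:
            logger.warning("n_per_side clamped from %d to %d",
                           config.n_per_side, n)
        beta = series.delta["P_beta"]
        split = select_extreme_populations(beta, n, series.frame_indices)
        spec = config.feature_spec or default_feature_spec(state)
        frames, y = split.labels()
        by_index = {s.frame_index: s for s in ensemble}
        sel = Ensemble([by_index[int(f)] for f in sorted(frames)],
                       topology=ensemble.topology,
                       metadata=ensemble.metadata)
        feats = extract_feature_matrix(sel, pmap, spec)
        feats = feats.loc[[int(f) for f in frames]]
        report = feature_importance(feats, y, seed=config.generator.seed)
        corr = feature_correlations(feats)
        return split, report, corr

    split, importance, correlations = classify()

    result = PipelineResult(
        ensemble=ensemble, qm_spec=qm_spec, charges=charges,
        shift_series=series, summary=summary, deviation=deviation,
        rolling=rolling, peak_order=order, split=split,
        importance=importance, correlations=correlations, outdir=out,
    )
    if out is not None:
        _write_bundle(result, records, config, out)
    return result


def _write_bundle(result: PipelineResult, records, config: RunConfig,
                  out: Path) -> None:
    series = result.shift_series
    series.to_frame().to_csv(out / "shifts.tsv", sep="\t", index=False)
    sig_rows = [
        (r.frame_index, nuc, sigma)
        for r in records for nuc, sigma in r.sigma.items()
    ]
    pd.DataFrame(sig_rows, columns=["frame_index", "nucleus", "sigma_ppm"]
                 ).to_csv(out / "shieldings.tsv", sep="\t", index=False)
    result.summary.to_csv(out / "summary.tsv", sep="\t")

    dev = pd.DataFrame(
        [{**result.deviation.deviations, "P_bar": result.deviation.p_bar}],
        index=[config.generator.state],
    )
    dev.to_csv(out / "deviations.tsv", sep="\t")

    roll = pd.DataFrame(result.rolling)
    roll.insert(0, "frame_index", series.frame_indices)
    roll.to_csv(out / "rolling.tsv", sep="\t", index=False)

    with open(out / "qm_manifest.tsv", "w") as fh:
        for chain, rid, name in result.qm_spec.member_units:
            fh.write(f"member\t{chain}\t{rid}\t{name}\n")
        for q, m in result.qm_spec.boundary_cuts:
            fh.write(f"cut\t{q}\t{m}\n")
        for k, q in enumerate(result.charges):
            fh.write(f"charge\t{k}\t{q}\n")

    if result.split is not None:
        frames, y = result.split.labels()
        pd.DataFrame({"frame_index": frames, "downfield": y}).to_csv(
            out / "population_split.tsv", sep="\t", index=False)
        result.importance.table.to_csv(out / "importance.tsv", sep="\t",
                                       index=False)
        result.correlations.to_csv(out / "correlations.tsv", sep="\t")

    if config.write_ensemble:
        write_trajectory(result.ensemble, out / "ensemble.pdb")

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.generator.seed,
        "version": __version__,
        "peak_order": result.peak_order,
        "n_frames": len(result.ensemble),
        "qm_atoms": int(len(result.qm_spec.qm_atom_indices)),
        "accuracy": (None if result.importance is None
                     else result.importance.accuracy),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML (the CLI entry point's config format)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen = GeneratorConfig(**{
        **raw.get("generator", {}),
        "planted_effect": tuple(raw["generator"]["planted_effect"])
        if raw.get("generator", {}).get("planted_effect") else None,
    }) if "generator" in raw else GeneratorConfig()
    kwargs: dict = {"generator": gen}
    if "qm" in raw:
        kwargs["qm"] = QMRegionConfig(**raw["qm"])
    if "surrogate" in raw:
        kwargs["surrogate"] = SurrogateParams(**raw["surrogate"])
    if "rolling" in raw:
        kwargs["rolling"] = RollingConfig(**raw["rolling"])
    for key in ("input_trajectory", "extract_interval_ns",
                "experimental_shifts", "n_per_side", "engine",
                "write_ensemble"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)
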
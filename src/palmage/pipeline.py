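"""End-to-end pipeline driver: simulate -> mosaic -> classify ->
postprocess -> age -> validate -> summarize.

Every stage is deterministic in (config, seed); intermediate inputs that
are cheap to regenerate (SAR scenes, the lazy optical archive) are
re-derived from the configuration rather than serialized, so the stage
commands of the CLI stay exact. A run manifest (config hash, seed,
library versions, per-stage pixel counts) is written alongside the
artifacts; reruns with the same config produce bit-identical rasters and
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age import (BsiAgeModel, build_bsi_series, smooth_median_12mo)
from .ensemble import GridClusterEnsemble
from .mosaic import MosaicConfig, build_annual_mosaic
from .postprocess import MapPostProcessor, compute_ndvi
from .raster_io import (write_age_map, write_points_geojson, write_raster)
from .synthetic import (ConfigurationError, ScenarioConfig, generate_landscape,
                        simulate_optical_series, simulate_sar_stack,
                        synthetic_dem)
from .validation import (build_strata, consensus_label, design_sample,
                         simulate_raters, stratified_accuracy,
                         summarize_extent_by_period)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "mosaic", "classify", "postprocess", "age",
          "validate", "summarize")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class EnsembleSection:
    n_grids: int = 12
    n_train: int = 50_000
    k_min: int = 10
    k_max: int = 16
    vote_threshold: int = 7
    min_ref: int = 10
    n_ref: int = 2000
    n_init: int = 3
    renormalize_votes: bool = False


@dataclass(frozen=True)
class PostprocessSection:
    ndvi_min: float = 0.5
    fill_window: int = 3
    slope_max: float = 20.0
    look_direction: float = 90.0


@dataclass(frozen=True)
class AgeSection:
    percentile: float = 95.0
    min_obs: int = 3
    min_calibration_pixels: int = 100


@dataclass(frozen=True)
class ValidationSection:
    n_points: int = 1000
    allocation: tuple = (0.25, 0.25, 0.50)
    rater_error_rate: float = 0.10
    maybe_rate: float = 0.05
    min_raters: int = 5
    max_raters: int = 8
    min_agreement: float = 0.8
    comparison_error_rates: tuple = (0.05, 0.08, 0.10)  # synthetic "other maps"


@dataclass(frozen=True)
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    mosaic: MosaicConfig = field(default_factory=MosaicConfig)
    ensemble: EnsembleSection = field(default_factory=EnsembleSection)
    postprocess: PostprocessSection = field(default_factory=PostprocessSection)
    age: AgeSection = field(default_factory=AgeSection)
    validation: ValidationSection = field(default_factory=ValidationSection)
    seed: int = 0

    def __post_init__(self) -> None:
        e = self.ensemble
        if not (1 <= e.vote_threshold <= e.n_grids):
            raise ConfigurationError(
                f"ensemble.vote_threshold: {e.vote_threshold} outside "
                f"[1, ensemble.n_grids={e.n_grids}]")
        if not (e.k_min <= e.k_max):
            raise ConfigurationError("ensemble.k_min must be <= ensemble.k_max")
        v = self.validation
        if abs(sum(v.allocation) - 1.0) > 1e-9:
            raise ConfigurationError("validation.allocation must sum to 1")
        if not (1 <= v.min_raters <= v.max_raters):
            raise ConfigurationError("validation: need 1 <= min_raters <= max_raters")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # dataclass objects inside ScenarioConfig dicts -> plain dicts
        sc = d["scenario"]
        sc["sar_params"] = {k: dataclasses.asdict(p) if dataclasses.is_dataclass(p) else p
                            for k, p in self.scenario.sar_params.items()}
        sc["optical_params"] = {k: dataclasses.asdict(p) if dataclasses.is_dataclass(p) else p
                                for k, p in self.scenario.optical_params.items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict, seed: int | None = None) -> "PipelineConfig":
        from .synthetic import ClassOpticalParams, ClassSarParams

        def build(section_cls, payload, path):
            fields = {f.name: f for f in dataclasses.fields(section_cls)}
            unknown = set(payload) - set(fields)
            if unknown:
                raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
            coerced = {}
            for key, value in payload.items():
                # YAML has no tuples; restore them where the field expects one.
                f = fields[key]
                if isinstance(value, list) and (
                        isinstance(f.default, tuple) or f.type == "tuple"):
                    value = tuple(value)
                coerced[key] = value
            try:
                return section_cls(**coerced)
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(f"{path}: {exc}") from exc

        d = dict(d or {})
        sc = dict(d.get("scenario", {}))
        if "sar_params" in sc:
            sc["sar_params"] = {k: ClassSarParams(**v) for k, v in sc["sar_params"].items()}
        if "optical_params" in sc:
            sc["optical_params"] = {k: ClassOpticalParams(**v)
                                    for k, v in sc["optical_params"].items()}
        if "bare_phase_range" in sc:
            sc["bare_phase_range"] = tuple(sc["bare_phase_range"])
        if "incidence_span_deg" in sc:
            sc["incidence_span_deg"] = tuple(sc["incidence_span_deg"])
        mo = dict(d.get("mosaic", {}))
        if "byte_ranges" in mo:
            mo["byte_ranges"] = {k: tuple(v) for k, v in mo["byte_ranges"].items()}
        va = dict(d.get("validation", {}))
        for key in ("allocation", "comparison_error_rates"):
            if key in va:
                va[key] = tuple(va[key])
        cfg = cls(
            scenario=build(ScenarioConfig, sc, "scenario"),
            mosaic=build(MosaicConfig, mo, "mosaic"),
            ensemble=build(EnsembleSection, dict(d.get("ensemble", {})), "ensemble"),
            postprocess=build(PostprocessSection, dict(d.get("postprocess", {})), "postprocess"),
            age=build(AgeSection, dict(d.get("age", {})), "age"),
            validation=build(ValidationSection, va, "validation"),
            seed=int(d.get("seed", 0)),
        )
        if seed is not None:
            cfg = cfg.with_seed(seed)
        return cfg

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=int(seed), scenario=self.scenario.with_seed(seed))

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload, seed=seed)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True,
                                             default_flow_style=False))


def _ndvi_map_year_median(optical, year: int) -> np.ndarray:
    """Per-pixel median NDVI over the cloud-free observations of one year."""
    idx = [i for i, t in enumerate(optical.times) if int(t) == year]
    stack = np.full((len(idx),) + optical.grid.shape, np.nan, np.float32)
    for k, i in enumerate(idx):
        obs = optical.observation(i)
        ndvi, ok = compute_ndvi(obs.red, obs.nir)
        ndvi[~(ok & obs.valid)] = np.nan
        stack[k] = ndvi
    with np.errstate(all="ignore"):
        return np.nanmedian(stack, axis=0)


def _degrade_map(palm: np.ndarray, error_rate: float, rng) -> np.ndarray:
    """Synthetic stand-in for an independent oil-palm product: the truth
    map with a fraction of pixels flipped."""
    flip = rng.random(palm.shape) < error_rate
    return np.where(flip, 1 - palm, palm).astype(np.uint8)


def run_pipeline(config: PipelineConfig, out_dir, upto: str | None = None) -> dict:
    """Execute the pipeline and write all artifacts under ``out_dir``.

    ``upto`` truncates execution after the named stage (used by the
    per-stage CLI commands). Returns the manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if upto is not None and upto not in STAGES:
        raise ConfigurationError(f"unknown stage {upto!r}; stages are {STAGES}")
    last = len(STAGES) - 1 if upto is None else STAGES.index(upto)

    manifest = {
        "package": "palmage",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _library_versions(),
        "stages": [],
    }
    ctx: dict = {}
    for stage in STAGES[:last + 1]:
        fn = globals()[f"_stage_{stage}"]
        try:
            counts = fn(config, out, ctx)
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise PipelineStageError(stage, exc) from exc
        manifest["stages"].append({"stage": stage, "counts": counts})
        logger.info("stage %s complete: %s", stage, counts)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return manifest


def _library_versions() -> dict:
    import scipy
    import sklearn
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__, "pandas": pd.__version__}


def _stage_simulate(config: PipelineConfig, out: Path, ctx: dict) -> dict:
    sc = config.scenario
    truth = generate_landscape(sc)
    ctx["truth"] = truth
    ctx["scenes"] = simulate_sar_stack(truth, sc)
    ctx["optical"] = simulate_optical_series(truth, sc)
    ctx["dem"] = synthetic_dem(sc.grid, sc.seed)
    prov = {"stage": "simulate", "config_hash": config.config_hash()}
    write_raster(out / "truth_class.tif", truth.class_raster, sc.grid,
                 provenance=prov)
    write_raster(out / "truth_planting_year.tif", truth.planting_year_raster,
                 sc.grid, nodata=0, dtype=np.int16, provenance=prov)
    write_raster(out / "dem.tif", ctx["dem"].astype(np.float32), sc.grid,
                 provenance=prov)
    pd.DataFrame({
        "date": [str(s.date) for s in ctx["scenes"]],
        "mean_incidence_deg": [float(s.incidence_angle.mean()) for s in ctx["scenes"]],
    }).to_csv(out / "sar_scene_metadata.csv", index=False)
    return {"palm_pixels": int(truth.palm_mask.sum()),
            "sar_scenes": len(ctx["scenes"]),
            "optical_observations": len(ctx["optical"])}


def _stage_mosaic(config: PipelineConfig, out: Path, ctx: dict) -> dict:
    mosaic = build_annual_mosaic(ctx["scenes"], config.mosaic)
    ctx["mosaic"] = mosaic
    prov = {"stage": "mosaic", "config_hash": config.config_hash(),
            "trim_fraction": config.mosaic.trim_fraction}
    bands = np.stack([mosaic.vv_mean, mosaic.vh_mean, mosaic.vhvv_diff,
                      mosaic.savg_vv, mosaic.savg_vh, mosaic.savg_diff]
                     ).astype(np.float32)
    write_raster(out / "annual_mosaic.tif", bands, mosaic.grid,
                 band_names=("vv_mean", "vh_mean", "vhvv_diff",
                             "savg_vv", "savg_vh", "savg_diff"),
                 provenance=prov)
    return {"valid_pixels": int(mosaic.valid.sum()),
            "texture_valid_pixels": int(mosaic.feature_valid.sum())}


def _stage_classify(config: PipelineConfig, out: Path, ctx: dict) -> dict:
    e = config.ensemble
    truth = ctx["truth"]
    mosaic = ctx["mosaic"]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10]))
    ref_idx = rng.choice(mosaic.grid.n_pixels, size=e.n_ref, replace=False)
    ref_palm = truth.palm_mask.ravel()[ref_idx]
    clf = GridClusterEnsemble(
        n_grids=e.n_grids, n_train=e.n_train, k_min=e.k_min, k_max=e.k_max,
        vote_threshold=e.vote_threshold, min_ref=e.min_ref, n_init=e.n_init,
        renormalize_votes=e.renormalize_votes, random_state=config.seed)
    clf.fit(mosaic, (ref_idx, ref_palm))
    maps, gaps = clf.predict_members(mosaic)
    from .ensemble import majority_vote
    raw = majority_vote(maps, e.vote_threshold, gaps,
                        renormalize=e.renormalize_votes)
    ctx["classifier"] = clf
    ctx["raw_map"] = raw
    ctx["ensemble_gaps"] = np.logical_and.reduce(gaps)
    prov = {"stage": "classify", "config_hash": config.config_hash(),
            "selected_k": clf.selected_k_, "vote_threshold": e.vote_threshold}
    write_raster(out / "extent_raw.tif", raw, mosaic.grid, nodata=255,
                 dtype=np.uint8, provenance=prov)
    return {"palm_pixels_raw": int(raw.sum()),
            "selected_k": clf.selected_k_}


def _stage_postprocess(config: PipelineConfig, out: Path, ctx: dict) -> dict:
    sc = config.scenario
    pp = config.postprocess
    ndvi = _ndvi_map_year_median(ctx["optical"], sc.map_year)
    ctx["ndvi"] = ndvi
    mangrove = ctx["truth"].class_mask("mangrove").astype(np.uint8)
    proc = MapPostProcessor(pp.ndvi_min, pp.fill_window, pp.slope_max,
                            pp.look_direction)
    clean, provenance = proc.transform(
        ctx["raw_map"], ndvi, mangrove=mangrove,
        gap_mask=ctx["ensemble_gaps"], dem=ctx["dem"],
        pixel_size=sc.grid.pixel_size)
    ctx["extent_map"] = clean
    provenance.update({"stage": "postprocess", "config_hash": config.config_hash()})
    write_raster(out / "extent_final.tif", clean, sc.grid, nodata=255,
                 dtype=np.uint8, provenance=provenance)
    (out / "postprocess_provenance.json").write_text(json.dumps(provenance, indent=2))
    return {"palm_pixels_final": int((clean == 1).sum()),
            "pixels_changed": {r["rule"]: r["pixels_changed"]
                               for r in provenance["rules"]}}


def _stage_age(config: PipelineConfig, out: Path, ctx: dict) -> dict:
    sc = config.scenario
    palm = ctx["extent_map"] == 1
    codes = np.zeros(sc.grid.shape, np.uint16)
    threshold = None
    if palm.any():
        series = build_bsi_series(ctx["optical"], pixel_mask=palm)
        smoothed = smooth_median_12mo(series, config.age.min_obs)
        model = BsiAgeModel(config.age.percentile, config.age.min_obs,
                            config.age.min_calibration_pixels)
        model.fit(smoothed, np.ones(int(palm.sum()), bool))
        threshold = model.threshold_
        codes[palm] = model.predict(smoothed, np.ones(int(palm.sum()), bool))
    ctx["age_codes"] = codes
    write_age_map(out / "age_map.tif", codes, sc.grid, sc.archive_start,
                  sc.map_year,
                  provenance={"stage": "age", "config_hash": config.config_hash(),
                              "bsi_threshold": threshold,
                              "percentile": config.age.percentile})
    return {"dated_pixels": int((codes >= 4).sum()),
            "bsi_threshold": None if threshold is None else round(threshold, 4)}


def _stage_validate(config: PipelineConfig, out: Path, ctx: dict) -> dict:
    v = config.validation
    truth_palm = ctx["truth"].palm_mask.astype(np.uint8)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20]))
    others = [_degrade_map(truth_palm, r, rng) for r in v.comparison_error_rates]
    strata = build_strata(*others)
    points = design_sample(strata, v.n_points, v.allocation,
                           seed=int(rng.integers(2 ** 31)))
    final = ctx["extent_map"]
    for p in points:
        p.map_label = int(final[p.row, p.col])
        p.true_label = int(truth_palm[p.row, p.col])
        n_raters = int(rng.integers(v.min_raters, v.max_raters + 1))
        p.votes = simulate_raters(p.true_label, n_raters, v.rater_error_rate,
                                  v.maybe_rate, rng)
        p.consensus = consensus_label(p.votes, v.min_agreement, v.min_raters)
    report = stratified_accuracy(points, strata)
    ctx["accuracy_report"] = report
    ctx["validation_points"] = points

    write_points_geojson(out / "validation_points.geojson", points,
                         ctx["truth"].grid)
    pd.DataFrame([{
        "row": p.row, "col": p.col, "stratum": p.stratum,
        "map_label": p.map_label, "true_label": p.true_label,
        "consensus": p.consensus, "votes": "|".join(p.votes),
    } for p in points]).to_csv(out / "validation_points.csv", index=False)

    summary = {
        "overall_accuracy": report.overall_accuracy,
        "overall_se": report.overall_se,
        "ci95": [report.ci_low, report.ci_high],
        "users_accuracy": report.users_accuracy,
        "producers_accuracy": report.producers_accuracy,
        "n_retained": int(sum(p.consensus is not None for p in points)),
        "n_points": len(points),
        "estimator": report.estimator,
    }
    (out / "accuracy_report.json").write_text(json.dumps(summary, indent=2))
    with open(out / "accuracy_report.txt", "w") as fh:
        fh.write(_format_report(report, summary))
    return {"n_points": len(points), "n_retained": summary["n_retained"],
            "overall_accuracy": round(report.overall_accuracy, 4)}


def _format_report(report, summary) -> str:
    lines = [
        "Stratified accuracy assessment (agreement strata, 25/25/50 design)",
        f"Overall accuracy: {report.overall_accuracy:.2%} "
        f"(95% CI {report.ci_low:.2%} - {report.ci_high:.2%})",
    ]
    for cls in ("oil_palm", "not_palm"):
        lines.append(
            f"{cls:>9}: user's {report.users_accuracy[cls]:.2%} "
            f"(SE {report.users_se[cls]:.2%}), producer's "
            f"{report.producers_accuracy[cls]:.2%} (SE {report.producers_se[cls]:.2%})")
    lines.append(f"Points retained: {summary['n_retained']}/{summary['n_points']}")
    return "\n".join(lines) + "\n"


def _stage_summarize(config: PipelineConfig, out: Path, ctx: dict) -> dict:
    sc = config.scenario
    table = summarize_extent_by_period(ctx["age_codes"],
                                       pixel_area_m2=sc.grid.pixel_area_m2,
                                       archive_start=sc.archive_start,
                                       map_year=sc.map_year)
    table.to_csv(out / "extent_by_period.csv", index=False)
    return {"palm_area_ha": float(table["palm_area_ha"].iloc[0])}
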
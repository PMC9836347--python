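"""End-to-end pipeline driver: simulate -> extract -> decompose -> features
-> predict -> compare, with a machine-readable run manifest.

The :class:`PipelineConfig` mirrors the CLI flags and can be loaded from a
YAML file. Each enabled stage consumes either the outputs of an earlier
enabled stage or explicit input paths; this is validated before anything
runs. A manifest (JSON) records package and library versions, the seed,
SHA-256 hashes of every written file and the resolved configuration, which
suffices to re-execute the run byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .features import assemble_feature_matrix, fit_weibull
from .imaging import build_phenomic_table
from .predict import (CV_SCHEMES, ModelSpec, grm_vanraden, make_split_plan,
                      compare_methods, run_cv_scheme)
from .simdata import SimConfig, render_band_stacks, simulate
from .temporal_model import (NestedModelSpec, fit_nested_model,
                             temporal_repeatability, variance_percentages)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "decompose", "features", "predict", "compare")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "phenoflight_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    sim: dict[str, Any] = field(default_factory=dict)
    phenomic_path: str | None = None       # input when simulate disabled
    trait_path: str | None = None
    marker_path: str | None = None
    estimation: str = "em_reml"
    traits_to_predict: list[str] = field(default_factory=lambda: ["GY"])
    models: list[dict[str, Any]] = field(default_factory=lambda: [
        {"family": "ridge"}, {"family": "gblup"}])
    schemes: list[str] = field(default_factory=lambda: ["CV1", "CV2", "CV4"])
    n_iter: int = 50
    train_frac: float = 0.7
    include_auc: bool = True
    include_weibull: bool = True
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
        enabled = set(self.stages)
        if "decompose" in enabled and "simulate" not in enabled \
                and "extract" not in enabled and not self.phenomic_path:
            raise ValueError("decompose needs the simulate/extract stage or phenomic_path")
        if "features" in enabled and "decompose" not in enabled:
            raise ValueError("features stage requires the decompose stage")
        if "predict" in enabled:
            if "features" not in enabled:
                raise ValueError("predict stage requires the features stage")
            if "simulate" not in enabled and not self.trait_path:
                raise ValueError("predict needs simulate stage or trait_path")
            wants_gblup = any(m.get("family") == "gblup" for m in self.models)
            if wants_gblup and "simulate" not in enabled and not self.marker_path:
                raise ValueError("gblup model needs simulate stage or marker_path")
        if "compare" in enabled and "predict" not in enabled:
            raise ValueError("compare stage requires the predict stage")
        unknown_schemes = [s for s in self.schemes if s not in CV_SCHEMES]
        if unknown_schemes:
            raise ValueError(f"unknown CV schemes {unknown_schemes}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in order and write a run manifest.

    Returns the manifest dict; raises :class:`PipelineError` naming the
    failing stage on any error.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    enabled = set(config.stages)

    trial = None
    phenomic = traits = markers = None
    blups: dict[str, pd.DataFrame] = {}
    features = None
    results = []

    def emit(name: str, path: Path) -> None:
        written[name] = path

    try:
        if "simulate" in enabled:
            stage = "simulate"
            sim_cfg = SimConfig(seed=config.seed, **config.sim)
            trial = simulate(sim_cfg)
            phenomic, traits, markers = trial.phenomic, trial.traits, trial.markers
            emit("phenomic", pio.write_phenomic_table(phenomic, outdir / "phenomic.tsv"))
            emit("traits", pio.write_trait_table(traits, outdir / "traits.tsv"))
            emit("markers", pio.write_marker_table(markers, outdir / "markers.tsv"))
            emit("layout", pio.write_layout(trial.layout, outdir / "layout.geojson"))
            truth = pd.concat({t: m.stack() for t, m in
                               trial.truth.temporal_genetic_values.items()})
            truth.rename_axis(["trait_id", "genotype", "flight_day"]) \
                 .to_frame("genetic_value").reset_index() \
                 .to_csv(outdir / "truth.tsv", sep="\t", index=False)
            emit("truth", outdir / "truth.tsv")

        if "extract" in enabled:
            stage = "extract"
            if trial is None:
                raise ValueError("extract without simulate requires raster paths "
                                 "(not configured); enable simulate")
            rasters = render_band_stacks(trial, trial.config)
            rdir = outdir / "rasters"
            rdir.mkdir(exist_ok=True)
            stacks, heights = [], {}
            for fr in rasters:
                emit(f"stack_{fr.flight_day}",
                     pio.write_band_stack(fr.stack, rdir / f"flight_{fr.flight_day}.tif"))
                emit(f"height_{fr.flight_day}",
                     pio.write_height_grid(fr.height, fr.flight_day,
                                           rdir / f"height_{fr.flight_day}.tif"))
                stacks.append(fr.stack)
                heights[fr.flight_day] = fr.height
            layout_om = type(trial.layout)([p for p in trial.layout if p.trial == "OM"])
            extracted = build_phenomic_table(stacks, heights, layout_om,
                                             panel=["NGRDI"])
            emit("extracted", pio.write_phenomic_table(extracted, outdir / "extracted.tsv"))

        if "decompose" in enabled:
            stage = "decompose"
            if phenomic is None:
                phenomic = pio.read_phenomic_table(config.phenomic_path)
            spec = NestedModelSpec(estimation=config.estimation)
            comp_rows = []
            om = phenomic[phenomic.trial == "OM"]
            for trait_id in sorted(om.trait_id.unique()):
                fit = fit_nested_model(om, trait_id, spec)
                pct = variance_percentages(fit)
                tr = temporal_repeatability(fit)
                comp_rows.append({"trait_id": trait_id, **{f"var_{k}": v for k, v
                                                           in fit.components.items()},
                                  **{f"pct_{k}": v for k, v in pct.items()},
                                  "TR": tr.tr, "converged": fit.converged})
                blups[trait_id] = fit.blups
                emit(f"blup_{trait_id}",
                     pio.write_blup_matrix(fit.blups, outdir / f"blup_{trait_id}.tsv"))
            comp = pd.DataFrame(comp_rows)
            comp.to_csv(outdir / "variance_components.tsv", sep="\t", index=False)
            emit("variance_components", outdir / "variance_components.tsv")

        if "features" in enabled:
            stage = "features"
            growth = None
            if config.include_weibull and "CHM" in blups:
                growth = {}
                chm = blups["CHM"]
                days = [int(c) for c in chm.columns]
                for g in chm.index:
                    row = chm.loc[g].to_numpy(dtype=float)
                    if np.isnan(row).any():
                        continue
                    try:
                        growth[g] = fit_weibull(days, np.clip(row, 0, None))
                    except (ValueError, RuntimeError):
                        continue
            features = assemble_feature_matrix(
                blups, growth_fits=growth,
                include_auc=config.include_auc,
                include_weibull=config.include_weibull and growth is not None,
                strict=config.strict, platform="TPP_RGB")
            emit("features", pio.write_feature_matrix(features, outdir / "features.tsv"))

        if "predict" in enabled:
            stage = "predict"
            if traits is None:
                traits = pio.read_trait_table(config.trait_path)
            wants_gblup = any(m.get("family") == "gblup" for m in config.models)
            kernel = None
            if wants_gblup:
                if markers is None:
                    markers = pio.read_marker_table(config.marker_path)
                kernel = grm_vanraden(markers)
            om_tr = traits[traits.trial == "OM"].set_index("genotype")
            sm_tr = traits[traits.trial == "SM"].set_index("genotype")
            genos = [g for g in features.genotypes if g in om_tr.index]
            needs_sm = any(CV_SCHEMES[s].test_env == "SM" for s in config.schemes)
            if needs_sm:
                genos = [g for g in genos if g in sm_tr.index]
            plan = make_split_plan(genos, config.train_frac, config.n_iter,
                                   seed=config.seed)
            emit("plan", pio.write_split_plan(plan, outdir / "plan.json"))
            for trait_name in config.traits_to_predict:
                y_om = om_tr[trait_name].astype(float)
                y_sm = sm_tr[trait_name].astype(float) if trait_name in sm_tr else None
                for mdict in config.models:
                    mspec = ModelSpec(**{k: v for k, v in mdict.items()})
                    data = kernel if mspec.family == "gblup" else features
                    for scheme in config.schemes:
                        results.append(run_cv_scheme(scheme, mspec, data, y_om,
                                                     y_sm, plan, trait_name))
            rec = pd.concat([r.records for r in results], ignore_index=True)
            rec.to_csv(outdir / "prediction_results.tsv", sep="\t", index=False)
            emit("prediction_results", outdir / "prediction_results.tsv")

        if "compare" in enabled:
            stage = "compare"
            comparison = compare_methods(results, seed=config.seed)
            comparison.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
            emit("comparison", outdir / "comparison.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    import phenoflight
    manifest = {
        "package_version": getattr(phenoflight, "__version__", "unknown"),
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {k: str(v) for k, v in written.items()},
        "hashes": {k: _sha256(v) for k, v in written.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
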
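"""End-to-end pipeline: simulate -> screen -> fit -> evaluate -> risk -> exposure.

One :class:`RunConfig` drives the whole analysis reproducibly.  Every
stochastic stage receives a seed derived deterministically from the master
seed, the stage name and (where applicable) the species id, so adding a
species never perturbs another species' results, and re-running with the
same master seed reproduces every CSV/JSON output byte for byte.
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
from .exposure import ExposureTable, suitable_area, villages_at_risk
from .predictors import screen_stack
from .raster import EnvStack
from .risk import (RiskSurface, binarize, classify_risk,
                   default_class_thresholds, risk_product)
from .sdm import METHODS, EnsembleSDM
from .synthetic import (DEFAULT_LAYER_NAMES, OccurrenceSet, VillagePoints,
                        default_layer_specs, define_virtual_species,
                        generate_landscape, generate_villages,
                        occurrences_from_csv, sample_presences,
                        villages_from_csv, villages_to_csv, occurrences_to_csv)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def derive_seed(master_seed: int, stage: str, species: str = "") -> int:
    """Deterministic per-stage seed from the master seed."""
    key = f"{master_seed}:{stage}:{species}".encode()
    digest = hashlib.blake2b(key, digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclass
class SpeciesSpec:
    """Synthetic species definition: which layers drive it and how hard."""

    species_id: str
    coefficients: dict[str, float]
    intercept: float = -0.5
    n_presence: int = 80


def default_species_specs() -> list[SpeciesSpec]:
    """Four virtual species emulating the study's four venomous snakes.

    A shared dominant driver (precipitation seasonality for three species,
    driest-quarter precipitation for the fourth) plus a weaker secondary
    variable each; a sharp response with moderate prevalence (~0.28); and
    presence record counts mirroring the study (89, 68, 54, 37).
    """
    return [
        SpeciesSpec("species_1", {"bio15": 4.0, "bio4": 2.0}, -3.0, 89),
        SpeciesSpec("species_2", {"bio15": 4.0, "bio12": -2.0}, -3.0, 68),
        SpeciesSpec("species_3", {"bio15": 4.0, "HFP": 2.0}, -3.0, 54),
        SpeciesSpec("species_4", {"bio17": 4.0, "NDVI": 2.0}, -3.0, 37),
    ]


@dataclass
class SyntheticBlock:
    """Synthetic-landscape settings used when no raster paths are given."""

    n_rows: int = 150
    n_cols: int = 150
    layer_names: list[str] = field(default_factory=lambda: list(DEFAULT_LAYER_NAMES))
    autocorrelation_length: float = 10.0
    target_correlation: float = 0.3
    n_villages: int = 1850
    species: list[SpeciesSpec] = field(default_factory=default_species_specs)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Either ``synthetic`` is set (virtual landscape and species) or the three
    path fields point at a saved stack directory and occurrence/village CSVs.
    """

    master_seed: int = 0
    methods: tuple[str, ...] = METHODS
    n_background: int = 10_000
    train_fraction: float = 0.8
    vif_threshold: float = 5.0
    n_permutations: int = 10
    n_importance_rows: int = 500
    ensemble_weighting: str = "equal"  # or "tss"
    cell_area_km2: float = 1.0
    #: thresholds for classifying the multi-species risk product
    risk_t_suitable: float = 0.05
    risk_t_high: float = 0.25
    write_rasters: bool = True
    #: also serialize each fitted model's state per (species, method)
    write_models: bool = False
    synthetic: SyntheticBlock | None = field(default_factory=SyntheticBlock)
    stack_path: str | None = None
    occurrences_path: str | None = None
    villages_path: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in d.items() if k in
                     {f.name for f in dataclasses.fields(cls)} - {"synthetic"}})
        if syn is None and cfg.stack_path is None:
            syn = {}
        if syn is not None:
            species = [SpeciesSpec(**s) for s in syn.pop("species", [])] or None
            block = SyntheticBlock(**syn)
            if species:
                block.species = species
            cfg.synthetic = block
        else:
            cfg.synthetic = None
        cfg.methods = tuple(cfg.methods)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _simulate_inputs(cfg: RunConfig) -> tuple[EnvStack, list[OccurrenceSet],
                                              VillagePoints, dict]:
    syn = cfg.synthetic
    specs = default_layer_specs(syn.layer_names, syn.autocorrelation_length,
                                syn.target_correlation)
    stack = generate_landscape(syn.n_rows, syn.n_cols, specs,
                               seed=derive_seed(cfg.master_seed, "landscape"))
    occurrences = []
    truths = {}
    for sp in syn.species:
        vs = define_virtual_species(stack, sp.coefficients, sp.intercept,
                                    sp.species_id)
        truths[sp.species_id] = vs
        occ = sample_presences(vs, sp.n_presence,
                               seed=derive_seed(cfg.master_seed, "presences",
                                                sp.species_id),
                               transform=stack.transform)
        occurrences.append(occ)
    villages = generate_villages(stack, syn.n_villages,
                                 seed=derive_seed(cfg.master_seed, "villages"))
    return stack, occurrences, villages, truths


def _load_inputs(cfg: RunConfig) -> tuple[EnvStack, list[OccurrenceSet],
                                          VillagePoints, dict]:
    stack = EnvStack.load(cfg.stack_path)
    occurrences = occurrences_from_csv(cfg.occurrences_path)
    villages = villages_from_csv(cfg.villages_path)
    return stack, occurrences, villages, {}


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run the full analysis; returns the run directory.

    Emits per species the five method surfaces, the ensemble surface, the
    binary (maxSSS) map, an evaluation report and an importance table; plus
    the multi-species risk surface, its class map, the exposure table and a
    run manifest.  Any stage failure raises :class:`PipelineStageError`
    naming the stage; outputs of completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, exc) from exc
                logger.info("stage %s: done", name)
        return _Ctx()

    with stage("inputs"):
        if config.synthetic is not None:
            stack, occurrences, villages, truths = _simulate_inputs(config)
            if config.write_rasters:
                stack.save(outdir / "landscape")
            villages_to_csv(villages, outdir / "villages.csv")
            for occ in occurrences:
                occurrences_to_csv(occ, outdir / f"occurrences_{occ.species_id}.csv")
        else:
            stack, occurrences, villages, truths = _load_inputs(config)
        if len(occurrences) == 0:
            raise ValueError("no occurrence sets available")

    with stage("screen"):
        vif_report = screen_stack(stack, threshold=config.vif_threshold,
                                  seed=derive_seed(config.master_seed, "vif"))
        vif_report.to_json(outdir / "vif_report.json")
        vif_report.to_frame().to_csv(outdir / "vif_table.csv", index=False)
        retained = vif_report.retained

    species_results = {}
    ensemble_surfaces = []
    eval_rows = []
    with stage("fit-evaluate"):
        for occ in occurrences:
            sid = occ.species_id
            model = EnsembleSDM.from_points(
                stack, occ, species_id=sid,
                n_background=config.n_background,
                seed=derive_seed(config.master_seed, "background", sid),
                layers=retained, methods=config.methods,
                train_fraction=config.train_fraction,
                n_permutations=config.n_permutations,
                n_importance_rows=config.n_importance_rows)
            results = model.fit(seed=derive_seed(config.master_seed, "fit", sid))
            species_results[sid] = results
            spdir = outdir / sid
            spdir.mkdir(exist_ok=True)
            if config.write_rasters:
                for m, surf in results.method_surfaces(stack).items():
                    surf.save(spdir / f"{sid}_{m}.asc")
            if config.write_models:
                for m, fitted in results.models.items():
                    fitted.save(spdir / f"{sid}_{m}.model.pkl")
            ens = results.ensemble_surface(stack, weighting=config.ensemble_weighting)
            ensemble_surfaces.append(ens)
            if config.write_rasters:
                ens.save(spdir / f"{sid}_ensemble.asc")
            evaluations = {m: e.to_dict() for m, e in results.evaluations.items()}
            (spdir / "evaluation.json").write_text(json.dumps(evaluations, indent=2))
            results.importance.to_frame().to_csv(spdir / "importance.csv", index=False)
            (spdir / "summary.txt").write_text(results.summary() + "\n")
            for e in results.evaluations.values():
                eval_rows.append(e.to_frame())
        pd.concat(eval_rows, ignore_index=True).to_csv(
            outdir / "evaluations.csv", index=False)

    with stage("binarize-exposure"):
        exposure = ExposureTable()
        class_maps = {}
        for sid, results in species_results.items():
            ens = next(s for s in ensemble_surfaces if s.species_id == sid)
            t_sss = results.evaluations["ensemble"].max_sss_threshold
            t_sss = min(max(t_sss, 1e-6), 1 - 1e-6)
            binary = binarize(ens, t_sss)
            if config.write_rasters:
                from .raster import write_ascii_grid
                write_ascii_grid(outdir / sid / f"{sid}_binary.asc", binary,
                                 ens.transform, ens.nodata_mask)
            t_suit, t_high = default_class_thresholds(ens, t_sss)
            cmap = classify_risk(ens, t_suit, t_high)
            class_maps[sid] = cmap
            n_high, n_mod = villages_at_risk(villages, cmap)
            area = suitable_area(binary, cell_area_km2=config.cell_area_km2)
            exposure.add(sid, n_high, n_mod, area)
        exposure.to_csv(outdir / "exposure.csv")
        exposure.to_json(outdir / "exposure.json")

    with stage("risk"):
        if len(ensemble_surfaces) < 2:
            raise ValueError("risk surface needs at least 2 species; configure "
                             "two or more species or skip the risk stage")
        risk = risk_product(ensemble_surfaces)
        if config.write_rasters:
            risk.save(outdir / "risk_surface.asc")
        risk_classes = classify_risk(risk, config.risk_t_suitable,
                                     config.risk_t_high)
        if config.write_rasters:
            risk_classes.save(outdir / "risk_class.asc")

    with stage("manifest"):
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "stage_seeds": {
                "landscape": derive_seed(config.master_seed, "landscape"),
                "vif": derive_seed(config.master_seed, "vif"),
                "villages": derive_seed(config.master_seed, "villages"),
                **{f"fit:{sid}": derive_seed(config.master_seed, "fit", sid)
                   for sid in species_results},
            },
            "species": list(species_results),
            "vif_retained": retained,
            "risk_thresholds": {"t_suitable": config.risk_t_suitable,
                                "t_high": config.risk_t_high},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
    return outdir
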
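"""End-to-end pipeline: simulate -> calibrate -> segment -> preprocess
-> split -> fit -> evaluate -> map.

Everything is driven by one :class:`PipelineConfig` (constructible from
a YAML file) and a single seed.  Each stage persists its intermediate
(mean-spectra CSVs, split CSVs, model JSONs, evaluation reports, maps)
and a manifest records parameters plus SHA-256 content hashes of every
artifact, so a rerun with the same seed/config is byte-identical and
every reported number is recomputable from the persisted files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .chemometrics import (
    CALIBRATION,
    PREDICTION,
    LSSVMRegressor,
    PLSRegressor,
    SpectralDataset,
    rank_split,
    save_model,
)
from .evaluation import (
    DEFAULT_PSEUDOCOLOR_BANDS_NM,
    EvaluationReport,
    evaluate_model,
    render_prediction_map,
    render_pseudocolor,
    save_map_png,
)
from .hypercube import calibrate_reflectance
from .preprocessing import PreprocessSpec, apply_chain
from .segmentation import SegmentationParams, segment
from .synthetic import SceneConfig, SimulatedDataset, simulate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "compare_models", "extract_spectra"]

log = logging.getLogger("chrysaspec.pipeline")

ANALYTE_COLUMNS = {"polysaccharides": "poly_pct", "flavonoids": "flav_pct"}


@dataclass
class PipelineConfig:
    """Run configuration; every field has a study-condition default."""

    out_dir: str = "chrysaspec_run"
    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    chains: tuple = (("wt",), ("wt", "snv"))
    models: tuple = ("pls", "lssvm")
    analytes: tuple = ("polysaccharides", "flavonoids")
    cv: object = "loo"
    max_lvs: int = 20
    pseudocolor_bands_nm: tuple = DEFAULT_PSEUDOCOLOR_BANDS_NM
    write_maps: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.analytes, str):
            self.analytes = (tuple(ANALYTE_COLUMNS) if self.analytes == "both"
                             else (self.analytes,))
        for a in self.analytes:
            if a not in ANALYTE_COLUMNS:
                raise ValueError(f"unknown analyte '{a}'")
        self.chains = tuple(tuple(c) for c in self.chains)
        # seed flows into the scene config so one integer governs all
        # randomness in the run
        self.scene = dataclasses.replace(self.scene, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "scene" in kwargs:
            kwargs["scene"] = SceneConfig(**kwargs["scene"])
        if "segmentation" in kwargs:
            kwargs["segmentation"] = SegmentationParams(**kwargs["segmentation"])
        return cls(**kwargs)

    def preprocess_specs(self) -> list[PreprocessSpec]:
        return [PreprocessSpec(chain=c) for c in self.chains]


@dataclass
class PipelineResult:
    config: PipelineConfig
    ground_truth: pd.DataFrame
    spectra: dict            # chain tag -> (sample_ids, X)
    datasets: dict           # (analyte, chain tag) -> SpectralDataset
    reports: list            # EvaluationReport
    winners: dict            # analyte -> EvaluationReport
    map_tables: dict         # analyte -> per-scene flower value tables
    manifest: dict


def extract_spectra(sim: SimulatedDataset, seg: SegmentationParams,
                    specs: list[PreprocessSpec]) -> dict:
    """Render each sample's scene, calibrate, segment, and compute the
    sample mean spectrum for every preprocessing chain.

    The sample spectrum averages preprocessed pixel spectra over the
    union of that scene's segmented flowers (pixel-wise preprocessing
    strictly precedes averaging).  Returns {chain tag: (ids, X)}.
    """
    per_chain: dict = {s.tag: [] for s in specs}
    ids = []
    for scene in sim.iter_scenes():
        cube = calibrate_reflectance(scene.raw, scene.dark, scene.white,
                                     axis=scene.axis)
        regions = segment(cube, seg)
        if not regions:
            raise RuntimeError(f"no flowers segmented in sample {scene.sample_id}")
        coords = np.vstack([r.coords for r in regions])
        pix = cube.data[coords[:, 0], coords[:, 1], :]
        for spec in specs:
            per_chain[spec.tag].append(apply_chain(pix, spec).mean(axis=0))
        ids.append(scene.sample_id)
    return {tag: (np.array(ids), np.vstack(rows))
            for tag, rows in per_chain.items()}


def _fit_model(family: str, X, y, config: PipelineConfig):
    if family == "pls":
        return PLSRegressor(max_lvs=config.max_lvs, cv=config.cv).fit(X, y)
    if family == "lssvm":
        return LSSVMRegressor(cv=config.cv).fit(X, y)
    raise ValueError(f"unknown model family '{family}'")


def _model_params(family: str, model) -> dict:
    if family == "pls":
        return {"n_lvs": model.n_lvs_}
    return {"gamma": model.gamma_, "sigma2": model.sigma2_}


def compare_models(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Rank reports by RPD (descending), ties by RMSEP (ascending).

    All reports must score the same prediction set; the winner (first
    row) is the model used for prediction maps.
    """
    if not reports:
        raise ValueError("no reports to compare")
    ns = {r.n_prediction for r in reports}
    if len(ns) != 1:
        raise ValueError("reports score different prediction sets")
    analytes = {r.analyte for r in reports}
    if len(analytes) != 1:
        raise ValueError("reports mix analytes")
    df = pd.DataFrame([r.to_dict() for r in reports])
    df = df.sort_values(["rpd", "rmsep"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["winner"] = False
    df.loc[0, "winner"] = True
    return df


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _map_sample_ids(truth: pd.DataFrame, labels_by_analyte: dict) -> list[int]:
    """One representative prediction-set sample per flower class.

    Maps are rendered for a "common" (typical) image of each class: the
    sample, preferably in every analyte's prediction set, whose contents
    lie closest to its class means in pooled-SD units.
    """
    out = []
    for cls in truth.class_name.unique():
        sub = truth[truth.class_name == cls]
        mask = np.ones(len(sub), bool)
        for labels in labels_by_analyte.values():
            mask &= labels[sub.index] == PREDICTION
        chosen = sub[mask] if mask.any() else sub
        dist = np.zeros(len(chosen))
        for col in ("poly_pct", "flav_pct"):
            sd = truth[col].std(ddof=1)
            dist += ((chosen[col] - sub[col].mean()) / sd) ** 2
        out.append(int(chosen.sample_id.iloc[int(np.argmin(dist.values))]))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and persist all intermediates."""
    t0 = time.time()
    out = cio.ensure_dir(config.out_dir)
    artifacts: dict[str, str] = {}

    def persist(name: str, path: str) -> None:
        artifacts[name] = path

    log.info("simulating dataset (seed=%d)", config.seed)
    sim = simulate_dataset(config.scene)
    truth = sim.ground_truth.samples
    gt_path = os.path.join(out, "ground_truth.csv")
    truth.to_csv(gt_path, index=False, float_format="%.12g")
    persist("ground_truth", gt_path)

    log.info("rendering %d scenes and extracting spectra", sim.n_samples)
    specs = config.preprocess_specs()
    spectra = extract_spectra(sim, config.segmentation, specs)
    axis = config.scene.axis()
    for tag, (ids, X) in spectra.items():
        p = os.path.join(out, f"mean_spectra_{tag}.csv")
        cio.write_spectra_csv(p, ids, X, axis.wavelengths_nm)
        persist(f"mean_spectra_{tag}", p)

    # rank-based split, per analyte (the ranking differs per constituent)
    labels_by_analyte = {}
    for analyte in config.analytes:
        y = truth[ANALYTE_COLUMNS[analyte]].to_numpy()
        labels = rank_split(y)
        labels_by_analyte[analyte] = labels
        p = os.path.join(out, f"split_{analyte}.csv")
        pd.DataFrame({"sample_id": truth.sample_id, "set": labels}).to_csv(
            p, index=False)
        persist(f"split_{analyte}", p)

    datasets: dict = {}
    reports: list[EvaluationReport] = []
    for analyte in config.analytes:
        y = truth[ANALYTE_COLUMNS[analyte]].to_numpy()
        labels = labels_by_analyte[analyte]
        for spec in specs:
            ids, X = spectra[spec.tag]
            ds = SpectralDataset(X, y, labels, sample_ids=ids)
            datasets[(analyte, spec.tag)] = ds
            Xc, yc = ds.calibration
            Xp, yp = ds.prediction
            for family in config.models:
                log.info("fitting %s / %s / %s", analyte, spec.tag, family)
                model = _fit_model(family, Xc, yc, config)
                report = evaluate_model(
                    model, Xp, yp, family=family, chain=spec.tag,
                    analyte=analyte, params=_model_params(family, model))
                reports.append(report)
                stem = f"model_{analyte}_{spec.tag}_{family}"
                persist(stem, save_model(model, os.path.join(out, stem + ".json")))
                report._model = model          # kept for map rendering
                report._spec = spec

    winners: dict = {}
    map_tables: dict = {}
    for analyte in config.analytes:
        sub = [r for r in reports if r.analyte == analyte]
        ranked = compare_models(sub)
        p = os.path.join(out, f"report_{analyte}.csv")
        ranked.drop(columns=["params"]).assign(
            params=[json.dumps(d) for d in ranked["params"]]
        ).to_csv(p, index=False, float_format="%.6g")
        persist(f"report_{analyte}", p)
        win_family = ranked.loc[0, "family"]
        win_chain = ranked.loc[0, "chain"]
        winner = next(r for r in sub
                      if r.family == win_family and r.chain == win_chain)
        winners[analyte] = winner

    if config.write_maps:
        map_ids = _map_sample_ids(truth, labels_by_analyte)
        for analyte, winner in winners.items():
            tables = []
            for sid in map_ids:
                scene = sim.scene(sid)
                cube = calibrate_reflectance(scene.raw, scene.dark,
                                             scene.white, axis=scene.axis)
                regions = segment(cube, config.segmentation)
                pmap = render_prediction_map(cube, regions, winner._model,
                                             winner._spec, analyte=analyte)
                stem = f"map_{analyte}_sample{sid}"
                persist(stem + "_png",
                        save_map_png(pmap, os.path.join(out, stem + ".png")))
                tbl = pmap.flower_values.assign(
                    sample_id=sid,
                    class_name=truth.loc[truth.sample_id == sid,
                                         "class_name"].iloc[0])
                tp = os.path.join(out, stem + ".csv")
                tbl.to_csv(tp, index=False, float_format="%.12g")
                persist(stem + "_csv", tp)
                tables.append(tbl)
                rgb = render_pseudocolor(cube, config.pseudocolor_bands_nm)
                np.save(os.path.join(out, f"pseudocolor_sample{sid}.npy"), rgb)
            map_tables[analyte] = pd.concat(tables, ignore_index=True)

    manifest = {
        "seed": config.seed,
        "scene": dataclasses.asdict(config.scene),
        "segmentation": dataclasses.asdict(config.segmentation),
        "chains": [list(c) for c in config.chains],
        "models": list(config.models),
        "analytes": list(config.analytes),
        "cv": config.cv,
        "max_lvs": config.max_lvs,
        "artifacts": {k: {"path": os.path.basename(v), "sha256": _sha256(v)}
                      for k, v in sorted(artifacts.items())},
    }
    man_path = os.path.join(out, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return PipelineResult(config, truth, spectra, datasets, reports,
                          winners, map_tables, manifest)
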
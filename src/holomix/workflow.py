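"""End-to-end orchestration of the three-step integration workflow.

1. *ingest*: read matrices and metadata, harmonize samples, prefilter
   (microbiome blocks get the compositional transform, oversized blocks the
   MAD cap);
2. *single-omics*: per block, PCA (80 % variance rule + tuned sPCA) or
   PLS-DA (CV-BER-tuned sPLS-DA) feature selection, producing reduced
   tables;
3. *multi-omics*: pairwise sPLS with the Q² component rule and
   score-correlation keep tuning, and/or the multiblock discriminant model
   with a data-driven design matrix, both under the near-zero-variance
   repair loop; association networks are exported.

Everything a run decides — filters, removed columns, seeds, grids, design
values — lands in machine-readable JSON artifacts in the output directory.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import models as M
from . import selection as S
from .datasets import (MetadataTable, OmicsDataset, ValidationError, harmonize,
                       read_metadata, read_omics_table, write_table)
from .networks import build_network, circos_edges, export_network, similarity_matrix
from .preprocess import prefilter

logger = logging.getLogger(__name__)


@dataclass
class DatasetConfig:
    name: str
    path: str | None = None
    microbiome: bool = False
    transpose: bool = False
    method: str = "plsda"          # single-omics path: pca | plsda
    ncomp: int = 4                 # pre-selected components

    def __post_init__(self) -> None:
        if self.method not in ("pca", "plsda"):
            raise ValidationError(f"method must be pca|plsda, got {self.method!r}")
        if self.ncomp < 1:
            raise ValidationError("pre-selected components must be >= 1")


@dataclass
class WorkflowConfig:
    datasets: list = field(default_factory=list)
    metadata: str | None = None
    pairs: list = field(default_factory=list)      # [{x, y, mode, bidirectional}]
    diablo_blocks: list = field(default_factory=list)
    design_value: float | None = None
    folds: int | None = None
    repeats: int = 10
    seed: int = 0
    keep_grid: list = field(default_factory=lambda: list(S.DEFAULT_KEEP_GRID))
    network_cutoff: float = 0.5
    circos_cutoff: float = 0.8
    outdir: str = "holomix_out"

    def __post_init__(self) -> None:
        self.datasets = [d if isinstance(d, DatasetConfig) else DatasetConfig(**d)
                         for d in self.datasets]
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate dataset names in config: {names}")

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def dataset(self, name: str) -> DatasetConfig:
        for d in self.datasets:
            if d.name == name:
                return d
        raise ValidationError(f"dataset {name!r} not in config")


def _dump_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not serializable: {type(o)}")


def model_summary(model: M.LatentModel) -> dict:
    out = {"algorithm": model.algorithm, "mode": model.mode,
           "ncomp": model.ncomp, "blocks": {}}
    if model.explained_variance is not None:
        out["explained_variance"] = list(map(float, model.explained_variance))
    if model.design is not None:
        out["design_value"] = float(model.design.values.max())
    for name, blk in model.blocks.items():
        out["blocks"][name] = {
            "keep": list(blk.keep),
            "selected_features": blk.selected_features(),
            "scores": blk.scores.tolist(),
            "loadings": blk.weights.tolist(),
            "feature_ids": list(blk.feature_ids),
        }
    return out


def ingest(config: WorkflowConfig, datasets: list[OmicsDataset] | None = None,
           metadata: MetadataTable | None = None, outdir: Path | None = None):
    """Read (or accept), harmonize and prefilter all configured blocks.

    Returns (blocks dict, metadata, labels array, filter reports).
    Pre-loaded datasets/metadata bypass the file reads (used by the
    simulation path and the tests).
    """
    if datasets is None:
        datasets = [read_omics_table(d.path, d.name, is_microbiome=d.microbiome,
                                     transpose=d.transpose)
                    for d in config.datasets]
    if metadata is None:
        if config.metadata is None:
            raise ValidationError("no metadata configured")
        metadata = read_metadata(config.metadata)
    datasets = harmonize(datasets, metadata)
    blocks, reports = {}, {}
    for ds in datasets:
        filtered, reps = prefilter(ds)
        if reps:
            logger.info("prefilter %s: %d -> %d features", ds.name,
                        ds.n_features, filtered.n_features)
        else:
            logger.info("prefilter %s: no-op (%d features, not microbiome)",
                        ds.name, ds.n_features)
        blocks[ds.name] = filtered
        reports[ds.name] = [r.to_dict() for r in reps]
    labels = metadata.labels_for(next(iter(blocks.values())).sample_ids)
    if outdir is not None:
        _dump_json(reports, Path(outdir) / "prefilter_reports.json")
    return blocks, metadata, labels, reports


def run_single(config: WorkflowConfig, blocks: dict, labels,
               outdir: Path | None = None) -> dict:
    """Single-omics feature selection for every configured block.

    Returns name -> {"reduced": OmicsDataset, "model": ..., "tune": ...};
    a failing block is logged and skipped, the others continue.
    """
    outdir = Path(outdir or config.outdir)
    results = {}
    for dcfg in config.datasets:
        if dcfg.name not in blocks:
            continue
        ds = blocks[dcfg.name]
        try:
            if dcfg.method == "pca":
                full_rank = min(ds.n_samples - 1, ds.n_features)
                pca = M.fit_pca(ds, ncomp=full_rank)
                ncomp = S.select_ncomp_variance(pca)
                tune = S.tune_spca_keep(ds, ncomp=ncomp, grid=config.keep_grid,
                                        folds=min(5, ds.n_samples),
                                        repeats=config.repeats, seed=config.seed)
                model = M.fit_spca(ds, ncomp=ncomp,
                                   keep=tune.selected_keep[ds.name])
            else:
                def task(dss, _cfg=dcfg):
                    d = dss[_cfg.name]
                    tune = S.tune_splsda(d, labels, ncomp_max=_cfg.ncomp,
                                         grid=config.keep_grid,
                                         folds=config.folds,
                                         repeats=config.repeats,
                                         seed=config.seed)
                    keeps = tune.selected_keep[d.name][:tune.selected_ncomp]
                    model = M.fit_splsda(d, labels, ncomp=tune.selected_ncomp,
                                         keep=keeps)
                    return d, tune, model

                (ds, tune, model), repair_log = S.nzv_repair(task,
                                                             {dcfg.name: ds})
                tune.repair_log.extend(repair_log)
            reduced = S.reduce_dataset(ds, model, tune)
            results[dcfg.name] = {"reduced": reduced, "model": model,
                                  "tune": tune}
            ddir = outdir / "single" / dcfg.name
            ddir.mkdir(parents=True, exist_ok=True)
            write_table(reduced, ddir / "reduced.csv")
            _dump_json(model_summary(model), ddir / "model.json")
            _dump_json(tune.to_dict(), ddir / "tune.json")
            logger.info("single-omics %s (%s): %d -> %d features, ncomp=%d",
                        dcfg.name, dcfg.method, ds.n_features,
                        reduced.n_features, tune.selected_ncomp)
        except (ValidationError, S.RepairAborted) as exc:
            logger.error("single-omics failed for %s: %s", dcfg.name, exc)
    return results


def run_pairwise(config: WorkflowConfig, blocks: dict,
                 outdir: Path | None = None) -> dict:
    """Pairwise sPLS per configured (x, y) pair; both orders when the pair
    is flagged bidirectional."""
    outdir = Path(outdir or config.outdir)
    results = {}
    for pair in config.pairs:
        x, y = pair["x"], pair["y"]
        mode = pair.get("mode", "canonical")
        orders = [(x, y), (y, x)] if pair.get("bidirectional") else [(x, y)]
        ncomp_pre = int(pair.get("ncomp", 4))
        for xa, ya in orders:
            key = f"{xa}__vs__{ya}"
            try:
                def task(dss, _xa=xa, _ya=ya):
                    X, Y = dss[_xa], dss[_ya]
                    nmax = min(ncomp_pre, X.n_samples - 1, X.n_features,
                               Y.n_features)
                    q2 = S.q2_scores(X, Y, ncomp=nmax, folds=config.folds or 5,
                                     repeats=config.repeats, seed=config.seed,
                                     mode=mode)
                    ncomp = S.select_ncomp_q2(q2)
                    tune = S.tune_spls_keep(X, Y, ncomp=ncomp,
                                            gridX=config.keep_grid,
                                            gridY=config.keep_grid,
                                            folds=config.folds or 5,
                                            repeats=config.repeats,
                                            seed=config.seed, mode=mode)
                    model = M.fit_spls(X, Y, ncomp=ncomp,
                                       keepX=tune.selected_keep[X.name],
                                       keepY=tune.selected_keep[Y.name],
                                       mode=mode)
                    return q2, tune, model

                (q2, tune, model), repair_log = S.nzv_repair(
                    task, {xa: blocks[xa], ya: blocks[ya]})
                tune.repair_log.extend(repair_log)
                sim = similarity_matrix(model, model.data_block_names[0],
                                        model.y_block)
                net = build_network(sim, config.network_cutoff, blocks=(xa, ya))
                pdir = outdir / "pairwise" / key
                pdir.mkdir(parents=True, exist_ok=True)
                sim.to_csv(pdir / "similarity.csv")
                _dump_json({"q2": list(map(float, q2)),
                            **tune.to_dict()}, pdir / "tune.json")
                _dump_json(model_summary(model), pdir / "model.json")
                export_network(net, pdir / "network.graphml", "graphml")
                export_network(net, pdir / "network.json", "json")
                results[key] = {"q2": q2, "tune": tune, "model": model,
                                "network": net}
                logger.info("pairwise %s: ncomp=%d keeps=%s", key,
                            tune.selected_ncomp, tune.selected_keep)
            except (ValidationError, S.RepairAborted, KeyError) as exc:
                logger.error("pairwise %s failed: %s", key, exc)
    return results


def run_diablo(config: WorkflowConfig, blocks: dict, labels,
               metadata: MetadataTable | None = None,
               outdir: Path | None = None) -> dict:
    """Multiblock discriminant integration across the configured blocks."""
    outdir = Path(outdir or config.outdir)
    names = config.diablo_blocks or list(blocks)
    if len(names) < 2:
        raise ValidationError(
            "the multiblock analysis needs >= 2 blocks; use the single-omics "
            "path for one dataset")
    use = {n: blocks[n] for n in names}
    if config.design_value is not None:
        design = S.DesignMatrix.uniform(names, float(config.design_value))
    else:
        design = S.data_driven_design(use)
    pre = [int(cfg.ncomp) for cfg in config.datasets if cfg.name in names]
    ncomp_max = max(2, min(pre)) if pre else 2
    tune = S.tune_diablo(use, labels, ncomp_max=ncomp_max,
                         grids={n: config.keep_grid for n in names},
                         folds=config.folds, repeats=config.repeats,
                         seed=config.seed, design=design)
    model = M.fit_diablo(use, labels, ncomp=tune.selected_ncomp, design=design,
                         keep={n: tune.selected_keep[n][:tune.selected_ncomp]
                               for n in names})
    net = circos_edges(model, cutoff=config.circos_cutoff)
    ddir = outdir / "diablo"
    ddir.mkdir(parents=True, exist_ok=True)
    _dump_json({"design_value": float(design.values.max()),
                "raw_minimum": design.raw_minimum,
                "pairwise_correlations": design.pairwise_correlations},
               ddir / "design.json")
    _dump_json(tune.to_dict(), ddir / "tune.json")
    _dump_json(model_summary(model), ddir / "model.json")
    export_network(net, ddir / "circos.graphml", "graphml", metadata=metadata)
    export_network(net, ddir / "circos.json", "json", metadata=metadata)
    logger.info("diablo: ncomp=%d keeps=%s design=%.2f", tune.selected_ncomp,
                tune.selected_keep, design.values.max())
    return {"design": design, "tune": tune, "model": model, "network": net}
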
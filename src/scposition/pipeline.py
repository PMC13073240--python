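"""End-to-end pipeline: data → features → model → validation → readouts.

``run_pipeline`` wires the modules into the standard workflow — load or
simulate compartment-labeled datasets, QC-filter and log-normalize, select
a candidate gene set (method per config), train the position classifier on
the declared training datasets, validate externally on the held-out
datasets, optionally harmonize across species, and write the downstream
readouts.  Every output file is recorded in a manifest with a SHA-256
content hash, so a rerun with the same config can be checked for exact
reproduction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    EvaluationReport,
    TrainingConfig,
    evaluate,
    predict,
    train_position_model,
)
from .containers import CellAnnotation, ExpressionMatrix, FormatError, GeneSet
from .features import (
    de_markers,
    detected_universe,
    hvg_rank,
    merge_union,
    mi_rank,
    random_set,
    rfe_select,
)
from .homology import harmonize_matrix
from .io import (
    read_annotations,
    read_counts,
    read_gmt,
    read_homology_table,
    save_model,
    write_annotations,
    write_gmt,
)
from .preprocess import log_normalize, qc_filter
from .simulate import SimConfig, simulate
from .spatial import assign_positions, compartment_fractions, module_score

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration schema violation, reported with its field path."""


def concatenate_cells(
    matrices: List[ExpressionMatrix],
) -> ExpressionMatrix:
    """Stack datasets cell-wise over their shared genes (first matrix's order)."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    shared = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        shared &= set(m.gene_ids)
    genes = [g for g in matrices[0].gene_ids if g in shared]
    if not genes:
        raise ValueError("datasets share no genes")
    parts = [m.reindex_genes(genes) for m in matrices]
    return ExpressionMatrix(
        np.concatenate([p.cell_ids for p in parts]),
        genes,
        np.vstack([p.values for p in parts]),
        matrices[0].layer,
    )


def concatenate_annotations(anns: List[CellAnnotation]) -> CellAnnotation:
    labels = tuple(sorted(set().union(*(set(a.label_set) for a in anns))))
    shared_cov = set(anns[0].covariates)
    for a in anns[1:]:
        shared_cov &= set(a.covariates)
    return CellAnnotation(
        np.concatenate([a.cell_ids for a in anns]),
        np.concatenate([a.compartment for a in anns]),
        {k: np.concatenate([a.covariates[k] for a in anns]) for k in sorted(shared_cov)},
        labels,
    )


def _require(config: dict, path: str):
    node = config
    for part in path.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"missing required config field: {path}")
        node = node[part]
    return node


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def quickstart_config(seed: int = 0) -> dict:
    """A self-contained simulated two-dataset run (train on ds1, validate on ds2)."""
    return {
        "seed": seed,
        "simulate": {"n_datasets": 2},
        "train_datasets": ["ds1"],
        "validate_datasets": ["ds2"],
        "select": {"method": "hvg", "n_top": 100},
        "train": {},
        "apply": {"group_by": ["dataset"]},
    }


def _load_datasets(
    config: dict, seed: int
) -> Tuple[Dict[str, ExpressionMatrix], Dict[str, CellAnnotation]]:
    matrices: Dict[str, ExpressionMatrix] = {}
    annotations: Dict[str, CellAnnotation] = {}
    if "simulate" in config:
        sim_kwargs = dict(config["simulate"] or {})
        sim_kwargs.setdefault("seed", seed)
        try:
            sim_cfg = SimConfig(**sim_kwargs)
        except TypeError as exc:
            raise ConfigError(f"simulate: {exc}") from exc
        datasets, _ = simulate(sim_cfg)
        for d, (m, ann) in enumerate(datasets):
            matrices[f"ds{d + 1}"] = m
            annotations[f"ds{d + 1}"] = ann
    elif "datasets" in config:
        for i, entry in enumerate(config["datasets"]):
            for key in ("name", "counts", "annotations"):
                if key not in entry:
                    raise ConfigError(f"datasets[{i}].{key}: missing")
            counts_path = Path(entry["counts"])
            ann_path = Path(entry["annotations"])
            for p in (counts_path, ann_path):
                if not p.exists():
                    raise ConfigError(f"datasets[{i}]: path does not exist: {p}")
            matrices[entry["name"]] = read_counts(counts_path)
            annotations[entry["name"]] = read_annotations(ann_path)
    else:
        raise ConfigError("config needs either 'simulate' or 'datasets'")
    return matrices, annotations


def _select_features(
    config: dict,
    train_names: List[str],
    lognorm: Dict[str, ExpressionMatrix],
    annotations: Dict[str, CellAnnotation],
    seed: int,
) -> GeneSet:
    sel = config.get("select", {}) or {}
    method = sel.get("method", "hvg")
    n_top = int(sel.get("n_top", 100))
    if method == "hvg":
        per_dataset = [
            hvg_rank(lognorm[n], n_top=n_top, name=f"hvg_{n}")[0] for n in train_names
        ]
        return merge_union(per_dataset, name="hvg_union")
    joint = concatenate_cells([lognorm[n] for n in train_names])
    joint_ann = concatenate_annotations(
        [annotations[n].aligned_to(lognorm[n].cell_ids) for n in train_names]
    )
    if method == "fam":
        return de_markers(
            joint,
            joint_ann,
            min_logfc=float(sel.get("min_logfc", 0.25)),
            max_fdr=float(sel.get("max_fdr", 0.05)),
            top_per_class=sel.get("top_per_class"),
        )
    if method in ("rfe", "mir"):
        base = merge_union(
            [hvg_rank(lognorm[n], n_top=2 * n_top, name=f"hvg_{n}")[0] for n in train_names],
            name="hvg_wide",
        )
        if method == "rfe":
            return rfe_select(joint, joint_ann, base, target_size=n_top, seed=seed)
        return mi_rank(joint, joint_ann, base, target_size=n_top)
    if method == "random":
        universe = detected_universe(joint)
        return random_set(universe, n_top, seed)
    raise ConfigError(f"select.method: unknown method {method!r}")


def run_pipeline(config, outdir=None, seed: Optional[int] = None) -> dict:
    """Execute the configured workflow and write all artifacts to ``outdir``.

    Returns the manifest (also written as ``manifest.json``): seeds,
    package version, per-file SHA-256 hashes and the headline validation
    accuracies.
    """
    config = load_config(config)
    # run id is a digest of the config, so identical runs are identical end to end
    run_id = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:8]
    logging.basicConfig(level=logging.INFO)
    logger.info("[run %s] starting pipeline", run_id)

    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    outdir = Path(outdir if outdir is not None else config.get("outdir", "scposition_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    matrices, annotations = _load_datasets(config, seed)
    train_names = list(_require(config, "train_datasets"))
    validate_names = list(config.get("validate_datasets", []))
    for name in train_names + validate_names:
        if name not in matrices:
            raise ConfigError(f"unknown dataset name {name!r}")

    # optional restriction to one cell type (e.g. resident macrophages):
    # positional fingerprints are cell-type specific, so selection and
    # training operate on the declared subset only
    cell_type = config.get("cell_type")
    if cell_type:
        column = cell_type.get("column", "cell_type")
        value = cell_type.get("value")
        if value is None:
            raise ConfigError("cell_type.value: missing")
        for name in list(matrices):
            ann = annotations[name]
            if column not in ann.covariates:
                raise ConfigError(f"cell_type.column: {column!r} not in dataset {name!r}")
            keep_ids = ann.cell_ids[ann.covariates[column] == value]
            matrices[name] = matrices[name].subset_cells(list(keep_ids))
            annotations[name] = ann.aligned_to(keep_ids)

    qc_cfg = config.get("qc", {}) or {}
    lognorm: Dict[str, ExpressionMatrix] = {}
    for name, m in matrices.items():
        filtered, report = qc_filter(
            m,
            min_genes=int(qc_cfg.get("min_genes", 200)),
            max_genes=int(qc_cfg.get("max_genes", 4000)),
            max_mito_frac=float(qc_cfg.get("max_mito_frac", 0.20)),
        )
        report.to_csv(outdir / f"qc_removed_{name}.tsv", sep="\t", index=False)
        lognorm[name] = log_normalize(filtered)

    geneset = _select_features(config, train_names, lognorm, annotations, seed)
    write_gmt([geneset], outdir / "geneset.gmt")

    train_m = concatenate_cells([lognorm[n] for n in train_names])
    train_ann = concatenate_annotations(
        [annotations[n].aligned_to(lognorm[n].cell_ids) for n in train_names]
    )
    train_cfg_kwargs = dict(config.get("train", {}) or {})
    train_cfg_kwargs.setdefault("seed", seed)
    try:
        cfg = TrainingConfig(**train_cfg_kwargs)
    except TypeError as exc:
        raise ConfigError(f"train: {exc}") from exc
    model = train_position_model(train_m, train_ann, geneset, cfg)
    save_model(model, outdir / "model.scpos")

    homology = None
    if config.get("homology_table"):
        homology = read_homology_table(config["homology_table"])

    reports: Dict[str, dict] = {}
    for name in validate_names:
        m = lognorm[name]
        if homology is not None:
            m = harmonize_matrix(m, model, homology)
        pred = predict(model, m)
        rep = evaluate(pred, annotations[name].aligned_to(m.cell_ids))
        reports[name] = rep.to_dict()
        rep.confusion.to_csv(outdir / f"confusion_{name}.tsv", sep="\t")
        pred.to_frame().to_csv(outdir / f"predictions_{name}.tsv", sep="\t")
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)

    apply_cfg = config.get("apply", {}) or {}
    group_by = apply_cfg.get("group_by", ["dataset"])
    for name in validate_names:
        ann = assign_positions(
            model, lognorm[name], annotations[name].aligned_to(lognorm[name].cell_ids)
        )
        write_annotations(ann, outdir / f"assigned_{name}.tsv")
        frac = compartment_fractions(ann, group_by)
        frac.to_csv(outdir / f"compartment_fractions_{name}.tsv", sep="\t")
        if apply_cfg.get("genesets_gmt"):
            for gs in read_gmt(apply_cfg["genesets_gmt"]):
                scores = module_score(lognorm[name], gs)
                scores.to_csv(outdir / f"module_score_{name}_{gs.name}.tsv", sep="\t")

    manifest = {
        "run_id": run_id,
        "version": __version__,
        "seed": seed,
        "geneset_size": len(geneset),
        "validation_accuracy": {
            n: reports[n]["overall_accuracy"] for n in validate_names
        },
        "files": {},
    }
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["files"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("[run %s] pipeline complete: %s", run_id, outdir)
    return manifest
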
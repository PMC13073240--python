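"""Reference evaluation protocols (simulated study designs).

Each function runs one complete study design on simulated data — the same
designs the real pipeline mirrors: train on one dataset, validate
externally on an independently batch-shifted dataset; swap the learned
gene set for a random one; erase or ramp the positional signal; carry the
signature across a synthetic species boundary.  They are used by the test
suite and the reproduction script, and serve as worked examples of how the
package's pieces compose.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .classify import (
    EvaluationReport,
    TrainingConfig,
    evaluate,
    predict,
    train_baselines,
    train_position_model,
)
from .containers import CellAnnotation, ExpressionMatrix, GeneSet, HomologyTable
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
from .preprocess import log_normalize, qc_filter
from .simulate import SimConfig, simulate, simulate_timecourse


def _prepared_pair(
    cfg: SimConfig,
) -> Tuple[ExpressionMatrix, CellAnnotation, ExpressionMatrix, CellAnnotation, Dict[str, GeneSet]]:
    """Simulate two datasets, QC-filter and log-normalize both."""
    datasets, truth = simulate(cfg)
    (mA, annA), (mB, annB) = datasets[:2]
    lA = log_normalize(qc_filter(mA)[0])
    lB = log_normalize(qc_filter(mB)[0])
    return lA, annA.aligned_to(lA.cell_ids), lB, annB.aligned_to(lB.cell_ids), truth


def _select(
    method: str,
    lA: ExpressionMatrix,
    annA: CellAnnotation,
    n_top: int,
    seed: int,
) -> GeneSet:
    if method == "hvg":
        return hvg_rank(lA, n_top=n_top)[0]
    if method == "random":
        return random_set(detected_universe(lA), n_top, seed)
    if method == "fam":
        return de_markers(lA, annA, top_per_class=max(1, n_top // len(annA.label_set)))
    base = hvg_rank(lA, n_top=min(2 * n_top, lA.n_genes))[0]
    if method == "rfe":
        return rfe_select(lA, annA, base, target_size=n_top, seed=seed)
    if method == "mir":
        return mi_rank(lA, annA, base, target_size=n_top)
    raise ValueError(f"unknown selector {method!r}")


def cross_batch_transfer(
    seed: int,
    method: str = "hvg",
    n_top: int = 100,
    motility_attenuation: float = 0.0,
    cfg: Optional[SimConfig] = None,
) -> EvaluationReport:
    """Train on simulated dataset A, validate externally on dataset B.

    Dataset B carries independent per-gene batch offsets, so this is a
    genuine transfer test.  ``method`` picks the feature selector run on
    dataset A alone; ``motility_attenuation`` scales the positional signal
    of both datasets (1 erases it).
    """
    cfg = cfg or SimConfig(seed=seed, motility_attenuation=motility_attenuation)
    lA, annA, lB, annB, _ = _prepared_pair(cfg)
    geneset = _select(method, lA, annA, n_top, seed)
    model = train_position_model(lA, annA, geneset, TrainingConfig(seed=seed))
    return evaluate(predict(model, lB), annB)


def signature_recovery(seed: int, n_top: int = 100) -> float:
    """Fraction of the planted signature genes found in one dataset's HVG top list."""
    cfg = SimConfig(seed=seed, n_datasets=1)
    datasets, truth = simulate(cfg)
    m, _ = datasets[0]
    lognorm = log_normalize(qc_filter(m)[0])
    top, _ = hvg_rank(lognorm, n_top=n_top)
    planted = {g for gs in truth.values() for g in gs.genes}
    return len(set(top.genes) & planted) / len(planted)


def residence_timecourse(
    seed: int,
    ramp: Optional[Dict[str, float]] = None,
    cells_per_timepoint: int = 200,
) -> Dict[str, float]:
    """Accuracy per timepoint for cells with ramped signal attenuation.

    A model is trained on a fully-resident dataset; prediction targets are
    timecourse cells sharing the same planted truth but independent batch
    noise, attenuated per timepoint (1 = just infiltrated, 0 = resident).
    """
    ramp = ramp or {"t0": 1.0, "t1": 0.5, "t2": 0.0}
    datasets, _ = simulate(SimConfig(seed=seed, n_datasets=1))
    mA, annA = datasets[0]
    lA = log_normalize(qc_filter(mA)[0])
    annA = annA.aligned_to(lA.cell_ids)
    geneset = hvg_rank(lA, n_top=100)[0]
    model = train_position_model(lA, annA, geneset, TrainingConfig(seed=seed))

    tc, _ = simulate_timecourse(
        SimConfig(
            seed=seed,
            n_datasets=1,
            cells_per_compartment=cells_per_timepoint,
            residence_ramp=ramp,
        )
    )
    mT, annT = tc[0]
    lT = log_normalize(qc_filter(mT)[0])
    annT = annT.aligned_to(lT.cell_ids)
    pred = predict(model, lT)
    out = {}
    for t in sorted(ramp):
        mask = annT.covariates["timepoint"] == t
        out[t] = float((pred.labels[mask] == annT.compartment[mask]).mean())
    return out


def toy_homology_table(
    model_genes, signature_genes, n_unmapped: int = 41, prefix: str = "HS_"
) -> HomologyTable:
    """Source→target table renaming a model's genes into a synthetic second
    species, leaving ``n_unmapped`` non-signature genes without a homolog.

    Source symbols are the second species' (prefixed); targets are the
    model's own symbols, so the table plugs directly into
    :func:`scposition.homology.harmonize_matrix`.
    """
    signature_genes = set(signature_genes)
    non_sig = [g for g in model_genes if g not in signature_genes]
    if n_unmapped > len(non_sig):
        raise ValueError("not enough non-signature genes to leave unmapped")
    unmapped = set(non_sig[:n_unmapped])
    pairs = [(prefix + g, g) for g in model_genes if g not in unmapped]
    return HomologyTable(pairs)


def cross_species_transfer(
    seed: int, n_unmapped: int = 41, n_top: int = 150
) -> Dict[str, float]:
    """Same-species vs homology-mapped cross-species validation accuracy.

    The gene universe is the union of per-dataset HVG lists from both the
    training and the validation dataset (the widest signature universe the
    study design produces).  Dataset B is relabeled with synthetic
    second-species symbols; a toy homology table maps all model genes back
    except ``n_unmapped`` non-signature genes, which are dropped
    (zero-filled) — emulating signature harmonization across species where
    some genes lack homologs.
    """
    cfg = SimConfig(seed=seed)
    lA, annA, lB, annB, truth = _prepared_pair(cfg)
    geneset = merge_union(
        [hvg_rank(lA, n_top=n_top)[0], hvg_rank(lB, n_top=n_top)[0]],
        name="hvg_union",
    )
    model = train_position_model(lA, annA, geneset, TrainingConfig(seed=seed))

    acc_same = evaluate(predict(model, lB), annB).overall_accuracy

    planted = {g for gs in truth.values() for g in gs.genes}
    table = toy_homology_table(model.gene_order, planted, n_unmapped=n_unmapped)
    lB_other = ExpressionMatrix(
        lB.cell_ids.copy(),
        ["HS_" + g for g in lB.gene_ids],
        lB.values,
        lB.layer,
    )
    harmonized = harmonize_matrix(lB_other, model, table)
    acc_cross = evaluate(predict(model, harmonized), annB).overall_accuracy
    return {"same_species": acc_same, "cross_species": acc_cross}


def selector_comparison(
    seed: int, methods=("hvg", "fam", "rfe", "mir"), n_top: int = 100
) -> Dict[str, float]:
    """External-validation accuracy of each feature selector on one simulation."""
    cfg = SimConfig(seed=seed)
    lA, annA, lB, annB, _ = _prepared_pair(cfg)
    out = {}
    for method in methods:
        geneset = _select(method, lA, annA, n_top, seed)
        model = train_position_model(lA, annA, geneset, TrainingConfig(seed=seed))
        out[method] = evaluate(predict(model, lB), annB).overall_accuracy
    return out


def baseline_comparison(seed: int, n_top: int = 100) -> Dict[str, float]:
    """Cross-batch accuracy of the seven classical baselines plus the gated MLP."""
    cfg = SimConfig(seed=seed)
    lA, annA, lB, annB, _ = _prepared_pair(cfg)
    geneset = hvg_rank(lA, n_top=n_top)[0]
    reports = train_baselines(lA, annA, geneset, seed=seed, test_m=lB, test_ann=annB)
    out = {name: rep.overall_accuracy for name, rep in reports.items()}
    model = train_position_model(lA, annA, geneset, TrainingConfig(seed=seed))
    out["gated_mlp"] = evaluate(predict(model, lB), annB).overall_accuracy
    return out
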
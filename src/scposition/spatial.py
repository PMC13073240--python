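"""Compartment-resolved downstream readouts for unlabeled datasets.

Once a trained model has assigned compartments to the cells of a new
dataset, this module produces the analyses built on those assignments:
normalized cell-count kinetics per compartment, per-cell gene-set module
scores (mean of member genes' z-scored log-normalized expression),
compartment-wise differential expression, and grouped score summaries.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import CellAnnotation, ExpressionMatrix, GeneSet
from .classify import PositionModel, predict
from .stats import bh_adjust, rank_sum_test


def assign_positions(
    model: PositionModel, m: ExpressionMatrix, ann: CellAnnotation
) -> CellAnnotation:
    """Predict each cell's compartment and attach it as a covariate.

    Adds ``predicted_compartment`` plus one probability column per class
    (``prob_<label>``); existing annotation columns are preserved, so true
    and predicted labels can coexist for evaluation.
    """
    if m.n_cells == 0:
        raise ValueError("empty matrix")
    ann = ann.aligned_to(m.cell_ids)
    pred = predict(model, m)
    out = ann.with_covariate("predicted_compartment", pred.labels)
    for j, c in enumerate(pred.class_order):
        out = out.with_covariate(f"prob_{c}", pred.probabilities[:, j])
    return out


def compartment_fractions(
    ann: CellAnnotation,
    group_by: Union[str, Sequence[str]],
    normalize: str = "fraction",
    baseline: Optional[str] = None,
    compartment_key: str = "predicted_compartment",
) -> pd.DataFrame:
    """Per-group compartment composition (group × compartment table).

    ``fraction`` mode divides compartment counts by the group total (rows
    sum to 1); ``relative_to_baseline`` divides each compartment's count by
    its count in the declared baseline group, so the baseline row is all
    ones.  Compartments with zero cells in a group report 0 in fraction
    mode; a zero in the baseline group is an error.
    """
    df = ann.to_frame()
    if compartment_key == "compartment":
        comp = df["compartment"]
    elif compartment_key in ann.covariates:
        comp = df[compartment_key]
    elif "compartment" in df.columns:
        comp = df["compartment"]
    else:
        raise KeyError(f"no {compartment_key!r} column available")
    keys = [group_by] if isinstance(group_by, str) else list(group_by)
    for k in keys:
        if k not in df.columns:
            raise KeyError(f"unknown covariate {k!r}")
    counts = (
        pd.crosstab([df[k] for k in keys], comp)
        .reindex(columns=sorted(comp.unique()), fill_value=0)
    )
    if normalize == "fraction":
        return counts.div(counts.sum(axis=1), axis=0)
    if normalize == "relative_to_baseline":
        if baseline is None:
            raise ValueError("relative_to_baseline needs a declared baseline group")
        if baseline not in counts.index:
            raise ValueError(f"baseline group {baseline!r} absent")
        base = counts.loc[baseline]
        zero = base[base == 0]
        if len(zero):
            raise ValueError(
                f"baseline group has zero cells in compartment {zero.index.tolist()}"
            )
        return counts.div(base, axis=1).astype(float)
    raise ValueError(f"unknown normalize mode {normalize!r}")


def module_score(m: ExpressionMatrix, gs: GeneSet) -> pd.Series:
    """Per-cell gene-set score: mean of member genes' z-scored lognorm expression.

    Genes absent from the matrix are ignored (the intersection is logged
    via the returned series' name); an empty intersection is an error.
    """
    if m.layer != "lognorm":
        raise ValueError(f"module_score expects a lognorm layer, got {m.layer!r}")
    present = [g for g in gs.genes if g in set(m.gene_ids)]
    if not present:
        raise ValueError(f"no genes of {gs.name!r} present in the matrix")
    sub = m.reindex_genes(present)
    mean = sub.values.mean(axis=0)
    sd = sub.values.std(axis=0, ddof=1) if m.n_cells > 1 else np.ones(len(present))
    safe = np.where(sd > 0, sd, 1.0)
    z = (sub.values - mean) / safe
    z[:, sd <= 0] = 0.0
    return pd.Series(z.mean(axis=1), index=m.cell_ids, name=gs.name)


def compartment_de(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    target: str,
    compartment_key: str = "predicted_compartment",
) -> pd.DataFrame:
    """Target-compartment vs rest differential expression.

    Two-sided rank-sum test per gene on lognorm values, BH adjustment
    across genes, natural-log fold change as difference of mean lognorm.
    Output is sorted by (adjusted p, −|logfc|, gene) — deterministic.
    """
    if m.layer != "lognorm":
        raise ValueError(f"compartment_de expects a lognorm layer, got {m.layer!r}")
    ann = ann.aligned_to(m.cell_ids)
    df = ann.to_frame()
    labels = df[compartment_key] if compartment_key in df.columns else df["compartment"]
    in_target = (labels == target).to_numpy()
    if not in_target.any():
        raise ValueError(f"target label {target!r} absent")
    x, y = m.values[in_target], m.values[~in_target]
    constant = np.array([
        np.all(m.values[:, j] == m.values[0, j]) for j in range(m.n_genes)
    ])
    p = rank_sum_test(x, y, axis=0)
    p[constant] = 1.0
    logfc = x.mean(axis=0) - y.mean(axis=0)
    logfc[constant] = 0.0
    table = pd.DataFrame(
        {"gene": m.gene_ids, "logfc": logfc, "p": p, "padj": bh_adjust(p)}
    )
    table["_neg_abs"] = -table["logfc"].abs()
    table = (
        table.sort_values(["padj", "_neg_abs", "gene"], kind="mergesort")
        .drop(columns="_neg_abs")
        .reset_index(drop=True)
    )
    return table


def score_summary(
    scores: pd.Series,
    ann: CellAnnotation,
    keys: Union[str, Sequence[str]],
    min_group_size: int = 10,
) -> pd.DataFrame:
    """Group means of a per-cell score with group sizes.

    Groups smaller than ``min_group_size`` are flagged ``low_confidence``.
    """
    keys = [keys] if isinstance(keys, str) else list(keys)
    df = ann.to_frame().loc[scores.index]
    df["_score"] = scores.to_numpy()
    grouped = df.groupby(keys, observed=True)["_score"].agg(["mean", "count"])
    grouped.columns = ["mean_score", "n"]
    grouped["low_confidence"] = grouped["n"] < min_group_size
    return grouped
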
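"""Candidate positional-signature gene selectors.

The primary selector ranks highly variable genes (HVG) by dispersion
standardized within equal-frequency mean bins, computed per dataset and
merged across datasets by order-preserving union.  Comparison selectors:
one-vs-rest differential-expression markers (rank-sum + BH), recursive
feature elimination over a linear multinomial model, mutual-information
ranking on quantile-binned expression, and a seeded random control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .containers import CellAnnotation, ExpressionMatrix, GeneSet
from .preprocess import standardize
from .stats import bh_adjust, rank_sum_test

logger = logging.getLogger(__name__)


def hvg_rank(
    m: ExpressionMatrix,
    n_top: int = 100,
    n_bins: int = 20,
    name: str = "hvg",
) -> Tuple[GeneSet, pd.DataFrame]:
    """Rank genes by within-mean-bin standardized dispersion.

    Genes with positive mean log-normalized expression are ordered by mean
    and split into ``n_bins`` equal-frequency bins; the dispersion
    (variance/mean) of each gene is z-scored within its bin and the
    ``n_top`` genes with the highest z are returned in descending order
    (ties broken lexicographically).  Also returns the full dispersion
    table (gene, mean, dispersion, dispersion_z, bin_index).
    """
    if m.layer != "lognorm":
        raise ValueError(f"hvg_rank expects a lognorm layer, got {m.layer!r}")
    if n_bins < 1:
        raise ValueError("n_bins must be ≥ 1")
    mean = m.values.mean(axis=0)
    var = m.values.var(axis=0, ddof=1) if m.n_cells > 1 else np.zeros(m.n_genes)
    eligible = mean > 0
    n_eligible = int(eligible.sum())
    if n_eligible < n_top:
        raise ValueError(f"only {n_eligible} genes with nonzero mean, need ≥ {n_top}")

    genes = m.gene_ids[eligible]
    gmean = mean[eligible]
    dispersion = var[eligible] / gmean

    # equal-frequency bins on mean; mean ties ordered by symbol for determinism
    order = np.lexsort((genes.astype(str), gmean))
    bin_index = np.empty(n_eligible, dtype=int)
    bin_index[order] = np.minimum(
        (np.arange(n_eligible) * n_bins) // n_eligible, n_bins - 1
    )

    dispersion_z = np.zeros(n_eligible)
    for b in np.unique(bin_index):
        in_bin = bin_index == b
        if in_bin.sum() < 2:
            continue
        d = dispersion[in_bin]
        sd = d.std(ddof=1)
        if sd > 0:
            dispersion_z[in_bin] = (d - d.mean()) / sd

    table = pd.DataFrame(
        {
            "gene": genes,
            "mean": gmean,
            "dispersion": dispersion,
            "dispersion_z": dispersion_z,
            "bin_index": bin_index,
        }
    ).set_index("gene")
    # ranking key rounded to 10 decimals so that exact ties (which float
    # summation order would otherwise perturb) break lexicographically
    top_order = np.lexsort((genes.astype(str), -np.round(dispersion_z, 10)))[:n_top]
    return GeneSet(name, genes[top_order].tolist(), "hvg"), table


def merge_union(sets: Sequence[GeneSet], name: Optional[str] = None) -> GeneSet:
    """Order-preserving union of gene sets (first appearance wins)."""
    if not sets:
        raise ValueError("merge_union needs at least one input set")
    genes: List[str] = []
    seen = set()
    for gs in sets:
        for g in gs.genes:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    provenance = "hvg" if all(gs.provenance == "hvg" for gs in sets) else "custom"
    if name is None:
        name = "+".join(gs.name for gs in sets)
    return GeneSet(name, genes, provenance)


def de_markers(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    min_logfc: float = 0.25,
    max_fdr: float = 0.05,
    top_per_class: Optional[int] = None,
    name: str = "fam",
) -> GeneSet:
    """One-vs-rest differential-expression marker selection.

    For every compartment, each gene is tested with a two-sided rank-sum
    test against all other compartments pooled; BH adjustment is applied
    across genes within the compartment.  Genes with adjusted p ≤
    ``max_fdr`` and natural-log fold change (difference of mean lognorm
    expression) ≥ ``min_logfc`` are kept, optionally truncated per class,
    and merged across compartments.
    """
    if m.layer != "lognorm":
        raise ValueError(f"de_markers expects a lognorm layer, got {m.layer!r}")
    ann = ann.aligned_to(m.cell_ids)
    labels = list(ann.label_set)
    if len(labels) < 2:
        raise ValueError("de_markers needs ≥ 2 compartments")
    per_class_sets = []
    for label in labels:
        in_class = ann.compartment == label
        if in_class.sum() < 3:
            raise ValueError(f"compartment {label!r} has fewer than 3 cells")
        table = _de_table(m, in_class)
        hits = table[(table["padj"] <= max_fdr) & (table["logfc"] >= min_logfc)]
        if top_per_class is not None:
            hits = hits.head(top_per_class)
        if len(hits):
            per_class_sets.append(GeneSet(f"{name}_{label}", hits.index.tolist(), "fam"))
    if not per_class_sets:
        raise ValueError("no genes passed the marker thresholds")
    merged = merge_union(per_class_sets, name=name)
    return GeneSet(name, merged.genes, "fam")


def _de_table(m: ExpressionMatrix, in_class: np.ndarray) -> pd.DataFrame:
    """Per-gene rank-sum p, BH-adjusted p and logfc for one class vs rest,
    sorted by (padj, −|logfc|, gene)."""
    x = m.values[in_class]
    y = m.values[~in_class]
    p = rank_sum_test(x, y, axis=0)
    logfc = x.mean(axis=0) - y.mean(axis=0)
    table = pd.DataFrame(
        {"logfc": logfc, "p": p, "padj": bh_adjust(p)},
        index=pd.Index(m.gene_ids, name="gene"),
    )
    table["_neg_abs_logfc"] = -table["logfc"].abs()
    table = table.sort_values(
        ["padj", "_neg_abs_logfc"], kind="mergesort"
    ).drop(columns="_neg_abs_logfc")
    return table


def rfe_select(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    geneset: GeneSet,
    target_size: int,
    step_frac: float = 0.1,
    seed: int = 0,
) -> GeneSet:
    """Recursive feature elimination over an L2 linear multinomial model.

    At each round the ⌈step_frac·current⌉ genes with the smallest aggregate
    |coefficient| (summed over classes, on standardized features) are
    dropped until ``target_size`` genes remain.  Ties are broken
    lexicographically, so the procedure is deterministic.
    """
    if target_size >= len(geneset):
        return GeneSet(f"{geneset.name}_rfe", list(geneset.genes), "rfe")
    z, labels = _design(m, ann, geneset)
    current = [g for g in geneset.genes]
    gene_pos = {g: i for i, g in enumerate(geneset.genes)}
    while len(current) > target_size:
        n_remove = min(
            math.ceil(step_frac * len(current)), len(current) - target_size
        )
        cols = [gene_pos[g] for g in current]
        # default L2 penalty, C=1
        clf = LogisticRegression(solver="lbfgs", max_iter=500, random_state=seed)
        try:
            clf.fit(z[:, cols], labels)
            score = np.abs(clf.coef_).sum(axis=0)
        except Exception:  # degenerate fit: drop lexicographically, logged
            logger.warning("RFE fit failed at %d genes; removing lexicographic ties", len(current))
            score = np.zeros(len(current))
        drop_order = sorted(range(len(current)), key=lambda i: (score[i], current[i]))
        dropped = {current[i] for i in drop_order[:n_remove]}
        current = [g for g in current if g not in dropped]
    return GeneSet(f"{geneset.name}_rfe", current, "rfe")


def mi_rank(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    geneset: GeneSet,
    target_size: int,
    n_quantile_bins: int = 8,
) -> GeneSet:
    """Mutual-information ranking on quantile-discretized expression.

    Each gene's lognorm expression is cut into up to ``n_quantile_bins``
    equal-frequency bins; MI with the compartment label (natural log, from
    the empirical joint) ranks the genes.  Ties break lexicographically.
    """
    if target_size > len(geneset):
        raise ValueError("target_size exceeds the candidate set")
    z, labels = _design(m, ann, geneset, standardized=False)
    label_codes = pd.Categorical(labels).codes
    mis = np.array(
        [_quantile_mi(z[:, i], label_codes, n_quantile_bins) for i in range(z.shape[1])]
    )
    genes = np.asarray(geneset.genes, dtype=object)
    order = np.lexsort((genes.astype(str), -mis))[:target_size]
    return GeneSet(f"{geneset.name}_mir", genes[order].tolist(), "mir")


def _quantile_mi(x: np.ndarray, labels: np.ndarray, n_bins: int) -> float:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.searchsorted(edges, x, side="right")
    joint = pd.crosstab(bins, labels).to_numpy(dtype=float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())


def random_set(universe: Sequence[str], n: int, seed: int) -> GeneSet:
    """Uniform sample of ``n`` symbols without replacement, reproducible by seed."""
    universe = list(universe)
    if n > len(universe):
        raise ValueError("cannot sample more genes than the universe holds")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(universe), size=n, replace=False)
    return GeneSet(f"random{n}_seed{seed}", [universe[i] for i in picked], "random")


def detected_universe(m: ExpressionMatrix, min_cell_frac: float = 0.01) -> List[str]:
    """Genes detected in at least ``min_cell_frac`` of cells — the default
    sampling universe for the random control."""
    frac = (m.values > 0).mean(axis=0)
    return m.gene_ids[frac >= min_cell_frac].tolist()


@dataclass(frozen=True)
class OverlapReport:
    n_shared: int
    n_only_a: int
    n_only_b: int
    frac_of_a: float
    frac_of_b: float


def overlap_report(a: GeneSet, b: GeneSet) -> OverlapReport:
    """Exact set overlap accounting between two gene sets."""
    sa, sb = set(a.genes), set(b.genes)
    shared = len(sa & sb)
    return OverlapReport(
        n_shared=shared,
        n_only_a=len(sa - sb),
        n_only_b=len(sb - sa),
        frac_of_a=shared / len(sa),
        frac_of_b=shared / len(sb),
    )


def _design(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    geneset: GeneSet,
    standardized: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """Subset a lognorm matrix to a gene set (matrix order = set order)."""
    if m.layer != "lognorm":
        raise ValueError("selector expects a lognorm layer")
    ann = ann.aligned_to(m.cell_ids)
    sub = m.reindex_genes(list(geneset.genes))
    if standardized:
        sub, _ = standardize(sub)
    return sub.values, ann.compartment
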
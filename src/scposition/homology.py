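"""Cross-species harmonization of gene signatures and matrices.

A trained signature is carried between species (e.g. mouse → human) through
an explicit curated homology table; genes without an entry are dropped and
reported, never guessed by casing.  Many-to-one homologies collapse to the
first source in set order, with a warning.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import numpy as np

from .containers import ExpressionMatrix, GeneSet, HomologyTable

logger = logging.getLogger(__name__)


def map_genes(gs: GeneSet, table: HomologyTable) -> Tuple[Optional[GeneSet], List[str]]:
    """Translate a gene set through a source → target homology table.

    Returns the mapped set (target symbols, set order preserved) and the
    list of source symbols with no entry.  When two sources map to the
    same target, the first in set order wins and a warning is logged.
    If nothing maps, the mapped set is ``None`` (warned, not an error).
    """
    mapped: List[str] = []
    seen_targets = set()
    unmapped: List[str] = []
    n_collapsed = 0
    for g in gs.genes:
        tgt = table.mapping.get(g)
        if tgt is None:
            unmapped.append(g)
        elif tgt in seen_targets:
            n_collapsed += 1
        else:
            seen_targets.add(tgt)
            mapped.append(tgt)
    if n_collapsed:
        logger.warning(
            "%d source symbols collapsed onto already-mapped targets", n_collapsed
        )
    if not mapped:
        logger.warning("no genes of %r could be mapped", gs.name)
        return None, unmapped
    return GeneSet(f"{gs.name}_mapped", mapped, gs.provenance), unmapped


def translate_matrix(m: ExpressionMatrix, table: HomologyTable) -> ExpressionMatrix:
    """Rename a matrix's gene symbols through the table; unmapped genes are dropped.

    When several source genes map to one target, the first column in matrix
    order is kept.
    """
    keep_idx: List[int] = []
    new_names: List[str] = []
    seen = set()
    for j, g in enumerate(m.gene_ids):
        tgt = table.mapping.get(str(g))
        if tgt is not None and tgt not in seen:
            seen.add(tgt)
            keep_idx.append(j)
            new_names.append(tgt)
    if not keep_idx:
        raise ValueError("homology table maps none of the matrix genes")
    return ExpressionMatrix(
        m.cell_ids.copy(), new_names, m.values[:, keep_idx], m.layer
    )


def harmonize_matrix(
    m: ExpressionMatrix,
    model,
    table: Optional[HomologyTable] = None,
) -> ExpressionMatrix:
    """Align a matrix to a model's gene order, optionally via homology.

    If ``table`` is given (source = the matrix's species symbols, target =
    the model's), the matrix genes are translated first; unmapped genes are
    dropped.  Columns are then re-indexed to ``model.gene_order`` with
    zero-fill.  Post-mapping coverage below 50% of the model genes is an
    error.
    """
    if table is not None:
        m = translate_matrix(m, table)
    coverage = len(set(m.gene_ids) & set(model.gene_order)) / len(model.gene_order)
    logger.info("harmonized coverage: %.1f%% of model genes", 100 * coverage)
    if coverage < 0.5:
        raise ValueError(
            f"post-mapping coverage {coverage:.0%} of model genes (need ≥ 50%)"
        )
    return m.reindex_genes(model.gene_order)
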
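"""Quality filtering and normalization.

Cells are kept when their detected-gene count (number of genes with at
least one UMI) lies in [min_genes, max_genes] and their mitochondrial count
fraction does not exceed ``max_mito_frac``; mitochondrial genes are found
by case-insensitive symbol prefix ("mt-"/"MT-").  Counts are then
library-size normalized and natural-log transformed,
``ln(1 + count / cell_total * scale)``, and optionally z-scored per gene
with clipping, reusing stored training statistics at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix


@dataclass
class GeneStats:
    """Per-gene standardization statistics, aligned to a gene order."""

    gene_ids: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if not (self.gene_ids.size == self.mean.size == self.sd.size):
            raise ValueError("gene ids, means and sds must have equal length")


def qc_filter(
    m: ExpressionMatrix,
    min_genes: int = 200,
    max_genes: int = 4000,
    max_mito_frac: float = 0.20,
    mito_prefix: str = "mt-",
) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove low-quality cells from a counts matrix.

    Returns the filtered matrix and a report listing each removed cell with
    the first rule it violated (``low_genes``, ``high_genes``,
    ``high_mito``).  Cells at exactly ``max_mito_frac`` are kept (≤ rule).
    """
    if m.layer != "counts":
        raise ValueError(f"qc_filter expects a counts layer, got {m.layer!r}")
    detected = (m.values > 0).sum(axis=1)
    totals = m.values.sum(axis=1)
    is_mito = np.array(
        [str(g).lower().startswith(mito_prefix.lower()) for g in m.gene_ids]
    )
    mito_counts = m.values[:, is_mito].sum(axis=1) if is_mito.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    reasons = np.full(m.n_cells, "", dtype=object)
    reasons[mito_frac > max_mito_frac] = "high_mito"
    reasons[detected > max_genes] = "high_genes"
    reasons[detected < min_genes] = "low_genes"
    keep = reasons == ""
    if not keep.any():
        raise ValueError("qc_filter removed every cell")
    report = pd.DataFrame(
        {
            "cell_id": m.cell_ids[~keep],
            "reason": reasons[~keep],
            "detected_genes": detected[~keep],
            "mito_frac": mito_frac[~keep],
        }
    )
    return m.subset_cells(keep), report


def log_normalize(m: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize and log-transform: ``ln(1 + count/total × scale)``."""
    if m.layer != "counts":
        raise ValueError(f"log_normalize expects a counts layer, got {m.layer!r}")
    totals = m.values.sum(axis=1)
    if (totals == 0).any():
        bad = m.cell_ids[totals == 0][:5].tolist()
        raise ValueError(f"cells with zero total counts (run qc_filter first): {bad}")
    values = np.log1p(m.values / totals[:, None] * scale)
    return ExpressionMatrix(m.cell_ids, m.gene_ids, values, layer="lognorm")


def standardize(
    m: ExpressionMatrix,
    stats: Optional[GeneStats] = None,
    clip: float = 10.0,
) -> Tuple[ExpressionMatrix, GeneStats]:
    """Per-gene z-scoring with clipping to ``[-clip, +clip]``.

    When ``stats`` is omitted the sample (n−1) mean/sd are computed from
    ``m`` and returned so prediction can reuse the training statistics.
    Genes with zero sd map to 0.
    """
    if m.layer != "lognorm":
        raise ValueError(f"standardize expects a lognorm layer, got {m.layer!r}")
    if stats is None:
        mean = m.values.mean(axis=0)
        sd = m.values.std(axis=0, ddof=1) if m.n_cells > 1 else np.zeros(m.n_genes)
        stats = GeneStats(m.gene_ids.copy(), mean, sd)
    else:
        pos = pd.Index(stats.gene_ids).get_indexer(m.gene_ids.tolist())
        if (pos < 0).any():
            missing = m.gene_ids[pos < 0][:5].tolist()
            raise ValueError(f"standardization stats lack genes: {missing}")
        stats = GeneStats(m.gene_ids.copy(), stats.mean[pos], stats.sd[pos])
    safe_sd = np.where(stats.sd > 0, stats.sd, 1.0)
    z = (m.values - stats.mean) / safe_sd
    z[:, stats.sd <= 0] = 0.0
    z = np.clip(z, -clip, clip)
    return ExpressionMatrix(m.cell_ids, m.gene_ids, z, layer="zscore"), stats
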
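"""Training and evaluation of the positional classifier and baselines.

The primary model is a gated-attention MLP (see :mod:`scposition.nn`)
trained on the z-scored log-normalized expression of a candidate gene set;
the trained bundle stores the gene order, class order and the per-gene
standardization statistics so prediction on any matrix aligns by symbol
and reuses the training statistics.  A seven-model scikit-learn baseline
suite runs under the identical preprocessing and split protocol.
Evaluation reports overall accuracy, per-compartment one-vs-rest ROC AUC,
the confusion matrix and, for repeated internal validation, the repeat
distribution (median, SEM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from . import nn
from .containers import CellAnnotation, ExpressionMatrix, GeneSet
from .preprocess import GeneStats, log_normalize, standardize
from .stats import bh_adjust, ovr_auc, student_t_test

logger = logging.getLogger(__name__)

BASELINE_NAMES = (
    "logistic_regression",
    "knn",
    "naive_bayes",
    "decision_tree",
    "random_forest",
    "gradient_boosting",
    "linear_svm",
)


@dataclass
class TrainingConfig:
    """Hyperparameters of the gated-attention MLP."""

    hidden_sizes: List[int] = field(default_factory=lambda: [128, 64])
    dropout: float = 0.2
    learning_rate: float = 1e-3
    max_epochs: int = 200
    early_stop_patience: int = 10
    batch_size: int = 64
    seed: int = 0
    attention: bool = True
    class_weighting: str = "none"
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError("class_weighting must be 'none' or 'balanced'")

    def to_dict(self) -> dict:
        return {
            "hidden_sizes": list(self.hidden_sizes),
            "dropout": self.dropout,
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs,
            "early_stop_patience": self.early_stop_patience,
            "batch_size": self.batch_size,
            "seed": self.seed,
            "attention": self.attention,
            "class_weighting": self.class_weighting,
            "val_fraction": self.val_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        return cls(**d)

    def with_seed(self, seed: int) -> "TrainingConfig":
        d = self.to_dict()
        d["seed"] = seed
        return TrainingConfig.from_dict(d)


@dataclass
class PositionModel:
    """Frozen classifier bundle: gene/class order, scaling stats, weights."""

    gene_order: List[str]
    class_order: List[str]
    mean: np.ndarray
    sd: np.ndarray
    weights: Dict[str, np.ndarray]
    config: TrainingConfig
    training_fingerprint: dict

    def stats(self) -> GeneStats:
        return GeneStats(np.asarray(self.gene_order, dtype=object), self.mean, self.sd)


@dataclass
class PredictionResult:
    cell_ids: np.ndarray
    class_order: List[str]
    probabilities: np.ndarray
    labels: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, index=self.cell_ids, columns=self.class_order)
        df["predicted_compartment"] = self.labels
        return df


@dataclass
class EvaluationReport:
    overall_accuracy: float
    per_class_auc: Dict[str, float]
    confusion: pd.DataFrame  # rows = true class, columns = predicted
    n_cells: int
    repeats: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "overall_accuracy": self.overall_accuracy,
            "per_class_auc": self.per_class_auc,
            "confusion": self.confusion.to_dict(),
            "n_cells": self.n_cells,
        }
        if self.repeats is not None:
            out["repeats"] = self.repeats
        return out


def _prepare_training(
    m: ExpressionMatrix, geneset: GeneSet
) -> Tuple[np.ndarray, GeneStats]:
    """Subset to the gene set, log-normalize if needed, standardize."""
    if m.layer == "counts":
        m = log_normalize(m)
    if m.layer != "lognorm":
        raise ValueError("training expects a counts or lognorm matrix")
    coverage = len(set(m.gene_ids) & set(geneset.genes)) / len(geneset)
    if coverage < 0.5:
        raise ValueError(
            f"matrix covers only {coverage:.0%} of the gene set (need ≥ 50%)"
        )
    missing = [g for g in geneset.genes if g not in set(m.gene_ids)]
    if missing:
        logger.info("zero-filling %d gene-set genes absent from the matrix", len(missing))
    sub = m.reindex_genes(list(geneset.genes))
    z, stats = standardize(sub)
    return z.values, stats


def train_position_model(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    geneset: GeneSet,
    cfg: Optional[TrainingConfig] = None,
) -> PositionModel:
    """Train the gated-attention MLP position classifier.

    Deterministic given (data, config): all randomness flows from
    ``cfg.seed`` through a single generator.
    """
    cfg = cfg or TrainingConfig()
    ann = ann.aligned_to(m.cell_ids)
    class_order = sorted(set(ann.compartment.tolist()))
    if len(class_order) < 2:
        raise ValueError("training needs at least 2 compartment labels")
    counts = pd.Series(ann.compartment).value_counts()
    small = counts[counts < 10]
    if len(small):
        raise ValueError(f"compartments with < 10 cells: {small.index.tolist()}")

    x, stats = _prepare_training(m, geneset)
    label_idx = np.array([class_order.index(c) for c in ann.compartment])
    y_onehot = np.eye(len(class_order))[label_idx]
    class_weight = None
    if cfg.class_weighting == "balanced":
        freq = np.bincount(label_idx, minlength=len(class_order))
        class_weight = freq.sum() / (len(class_order) * freq)

    rng = np.random.default_rng(cfg.seed)
    weights, n_epochs = nn.train(
        x,
        y_onehot,
        hidden_sizes=cfg.hidden_sizes,
        attention=cfg.attention,
        dropout=cfg.dropout,
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        batch_size=cfg.batch_size,
        early_stop_patience=cfg.early_stop_patience,
        val_fraction=cfg.val_fraction,
        rng=rng,
        class_weight=class_weight,
    )
    fingerprint = {
        "n_cells": int(m.n_cells),
        "label_histogram": {c: int(counts[c]) for c in class_order},
        "seed": cfg.seed,
        "epochs_run": n_epochs,
    }
    return PositionModel(
        gene_order=list(geneset.genes),
        class_order=class_order,
        mean=stats.mean,
        sd=stats.sd,
        weights=weights,
        config=cfg,
        training_fingerprint=fingerprint,
    )


def predict(model: PositionModel, m: ExpressionMatrix) -> PredictionResult:
    """Predict compartment probabilities for every cell of ``m``.

    The matrix is aligned to the model's gene order by symbol (missing
    genes zero-filled) and standardized with the training statistics.
    Coverage below 50% of the model genes is an error; 50–80% warns.
    """
    coverage = len(set(m.gene_ids) & set(model.gene_order)) / len(model.gene_order)
    if coverage < 0.5:
        raise ValueError(f"matrix covers only {coverage:.0%} of model genes (need ≥ 50%)")
    if coverage < 0.8:
        logger.warning("matrix covers only %.0f%% of model genes", 100 * coverage)
    if m.layer == "counts":
        m = log_normalize(m)
    if m.layer != "lognorm":
        raise ValueError("predict expects a counts or lognorm matrix")
    sub = m.reindex_genes(model.gene_order)
    z, _ = standardize(sub, stats=model.stats())
    probs, _ = nn.forward(model.weights, z.values)
    labels = np.asarray(
        [model.class_order[i] for i in probs.argmax(axis=1)], dtype=object
    )
    return PredictionResult(m.cell_ids.copy(), list(model.class_order), probs, labels)


def _report(
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    scores: np.ndarray,
    class_order: List[str],
) -> EvaluationReport:
    extra = set(true_labels.tolist()) - set(class_order)
    if extra:
        raise ValueError(f"true labels outside model class order: {sorted(extra)}")
    accuracy = float((true_labels == pred_labels).mean())
    confusion = pd.DataFrame(
        0, index=class_order, columns=class_order, dtype=int
    )
    for t, p in zip(true_labels, pred_labels):
        confusion.loc[t, p] += 1
    aucs = {}
    for j, c in enumerate(class_order):
        pos = true_labels == c
        if pos.any() and (~pos).any():
            aucs[c] = ovr_auc(scores[:, j], pos)
        else:
            aucs[c] = float("nan")
    return EvaluationReport(accuracy, aucs, confusion, len(true_labels))


def evaluate(pred: PredictionResult, ann: CellAnnotation) -> EvaluationReport:
    """Score predictions against true compartment labels."""
    ann = ann.aligned_to(pred.cell_ids)
    return _report(ann.compartment, pred.labels, pred.probabilities, pred.class_order)


def stratified_split(
    labels: np.ndarray, train_frac: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-class random split preserving class proportions."""
    train_idx: List[int] = []
    test_idx: List[int] = []
    for c in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == c)
        members = members[rng.permutation(members.size)]
        n_train = int(round(train_frac * members.size))
        if n_train == 0 or n_train == members.size:
            raise ValueError(f"class {c!r} too small to stratify at {train_frac}")
        train_idx.extend(members[:n_train].tolist())
        test_idx.extend(members[n_train:].tolist())
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def repeated_holdout(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    geneset: GeneSet,
    cfg: Optional[TrainingConfig] = None,
    n_repeats: int = 100,
    train_frac: float = 0.8,
) -> EvaluationReport:
    """Repeated stratified-holdout internal validation.

    Repeat ``i`` uses the derived seed ``cfg.seed + i`` for both the split
    and the training.  The report's headline numbers are the pooled
    accuracy/confusion plus the repeat distribution (accuracies, median,
    SEM = sd/√n).
    """
    cfg = cfg or TrainingConfig()
    ann = ann.aligned_to(m.cell_ids)
    accuracies: List[float] = []
    confusion_sum = None
    auc_lists: Dict[str, List[float]] = {}
    for i in range(n_repeats):
        seed_i = cfg.seed + i
        rng = np.random.default_rng(seed_i)
        train_idx, test_idx = stratified_split(ann.compartment, train_frac, rng)
        m_train = m.subset_cells(np.isin(np.arange(m.n_cells), train_idx))
        m_test = m.subset_cells(np.isin(np.arange(m.n_cells), test_idx))
        model = train_position_model(
            m_train, ann.aligned_to(m_train.cell_ids), geneset, cfg.with_seed(seed_i)
        )
        rep = evaluate(predict(model, m_test), ann.aligned_to(m_test.cell_ids))
        accuracies.append(rep.overall_accuracy)
        confusion_sum = rep.confusion if confusion_sum is None else confusion_sum + rep.confusion
        for c, a in rep.per_class_auc.items():
            auc_lists.setdefault(c, []).append(a)
    acc_arr = np.asarray(accuracies)
    sem = float(acc_arr.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0
    total = int(confusion_sum.to_numpy().sum())
    pooled_accuracy = float(np.trace(confusion_sum.to_numpy()) / total)
    return EvaluationReport(
        overall_accuracy=pooled_accuracy,
        per_class_auc={c: float(np.nanmean(v)) for c, v in auc_lists.items()},
        confusion=confusion_sum,
        n_cells=total,
        repeats={
            "accuracies": accuracies,
            "median": float(np.median(acc_arr)),
            "sem": sem,
        },
    )


def _make_baselines(seed: int) -> Dict[str, object]:
    return {
        "logistic_regression": LogisticRegression(max_iter=1000, random_state=seed),
        "knn": KNeighborsClassifier(),
        "naive_bayes": GaussianNB(),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
        "gradient_boosting": HistGradientBoostingClassifier(random_state=seed),
        "linear_svm": LinearSVC(random_state=seed),
    }


def train_baselines(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    geneset: GeneSet,
    seed: int = 0,
    test_m: Optional[ExpressionMatrix] = None,
    test_ann: Optional[CellAnnotation] = None,
    train_frac: float = 0.8,
) -> Dict[str, EvaluationReport]:
    """Train and evaluate the seven-model baseline suite.

    With an external test set the models train on all of ``m``; otherwise
    a single stratified holdout (``train_frac``) is split off with
    ``seed``.  Preprocessing (log-normalize, z-score with training stats)
    matches the MLP protocol.  The linear SVM's AUC uses decision-function
    scores.
    """
    ann = ann.aligned_to(m.cell_ids)
    if test_m is None:
        rng = np.random.default_rng(seed)
        train_idx, test_idx = stratified_split(ann.compartment, train_frac, rng)
        test_m = m.subset_cells(np.isin(np.arange(m.n_cells), test_idx))
        test_ann = ann.aligned_to(test_m.cell_ids)
        m = m.subset_cells(np.isin(np.arange(m.n_cells), train_idx))
        ann = ann.aligned_to(m.cell_ids)
    if test_ann is None:
        raise ValueError("test_ann required when test_m is given")
    test_ann = test_ann.aligned_to(test_m.cell_ids)

    x_train, stats = _prepare_training(m, geneset)
    mt = log_normalize(test_m) if test_m.layer == "counts" else test_m
    z_test, _ = standardize(mt.reindex_genes(list(geneset.genes)), stats=stats)
    x_test = z_test.values
    class_order = sorted(set(ann.compartment.tolist()))

    out: Dict[str, EvaluationReport] = {}
    for bname, clf in _make_baselines(seed).items():
        clf.fit(x_train, ann.compartment.astype(str))
        pred_labels = clf.predict(x_test).astype(object)
        if hasattr(clf, "predict_proba"):
            scores = clf.predict_proba(x_test)
        else:
            scores = clf.decision_function(x_test)
        order = [list(clf.classes_).index(c) for c in class_order]
        out[bname] = _report(
            test_ann.compartment, pred_labels, np.asarray(scores)[:, order], class_order
        )
    return out


def compare_accuracies(
    pairs: Sequence[Tuple[Sequence[float], Sequence[float]]]
) -> pd.DataFrame:
    """Batch of two-sided Student's t-tests with BH adjustment across the batch.

    Each element of ``pairs`` is (group A accuracies, group B accuracies).
    Returns a DataFrame with columns ``t``, ``p``, ``p_adj``.
    """
    rows = [student_t_test(a, b) for a, b in pairs]
    t = [r[0] for r in rows]
    p = [r[1] for r in rows]
    return pd.DataFrame({"t": t, "p": p, "p_adj": bh_adjust(p)})
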
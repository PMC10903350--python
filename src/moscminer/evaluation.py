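"""Cross-validation, multiclass metrics, grid search and ablation protocols.

Metrics follow the evaluation used for the classifier: accuracy, weighted
F1, the Gorodkin multiclass MCC, and macro-averaged one-vs-rest AUC, all
computed through scikit-learn. Folds are stratified by subtype because
several subtypes in real datasets have only a dozen cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import attention_net
from .attention_net import AttentionConfig, AttentionModelParams
from .preprocess import MINMAX_KINDS, MinMaxStats, PreprocessConfig, minmax_normalize
from .types import ACCESSIBILITY, EXPRESSION, METHYLATION, MultiOmicsDataset

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "f1_weighted", "mcc", "auc")

#: Short tags used to name omics-combination ablation runs.
OMICS_TAGS = {EXPRESSION: "gene", METHYLATION: "methyl", ACCESSIBILITY: "acc"}


@dataclass
class CVResult:
    """Per-fold and aggregated cross-validation metrics."""

    fold_metrics: list[dict[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]
    per_subtype: pd.DataFrame
    fold_assignment: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "folds": self.fold_metrics,
        }


def kfold_split(
    cells: Sequence[str], labels: dict[str, str], k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Stratified k-fold assignment of labeled cells.

    Within each subtype the fold sizes differ by at most one. A subtype with
    fewer than k members triggers a warning (scikit-learn pools it best
    effort).
    """
    cells = list(cells)
    y = np.array([labels[c] for c in cells])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_tr, te) in enumerate(skf.split(np.zeros(len(cells)), y)):
        for i in te:
            assignment[cells[i]] = fold
    return assignment


def _ovr_macro_auc(y_true: np.ndarray, y_prob: np.ndarray, n_classes: int) -> float:
    """Macro OvR AUC; classes absent from y_true are excluded with a log line."""
    aucs = []
    for c in range(n_classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            logger.info("class %d absent from y_true (or only class); OvR AUC skipped", c)
            continue
        aucs.append(roc_auc_score(pos, y_prob[:, c]))
    if not aucs:
        return float("nan")
    return float(np.mean(aucs))


def compute_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    y_prob: Optional[np.ndarray],
    class_inventory: Sequence[str],
) -> dict[str, float]:
    """Accuracy, weighted F1, multiclass (Gorodkin) MCC and macro OvR AUC.

    Labels may be subtype strings or integer indices into class_inventory.
    """
    inv = {c: i for i, c in enumerate(class_inventory)}
    yt = np.array([inv.get(v, v) for v in y_true], dtype=int)
    yp = np.array([inv.get(v, v) for v in y_pred], dtype=int)
    all_cls = list(range(len(class_inventory)))
    out = {
        "accuracy": float(accuracy_score(yt, yp)),
        "f1_weighted": float(f1_score(yt, yp, labels=all_cls, average="weighted", zero_division=0)),
        "mcc": float(matthews_corrcoef(yt, yp)),
    }
    out["auc"] = _ovr_macro_auc(yt, y_prob, len(class_inventory)) if y_prob is not None else float("nan")
    return out


def per_subtype_table(
    y_true: Sequence, y_pred: Sequence, class_inventory: Sequence[str]
) -> pd.DataFrame:
    inv = {c: i for i, c in enumerate(class_inventory)}
    yt = np.array([inv.get(v, v) for v in y_true], dtype=int)
    yp = np.array([inv.get(v, v) for v in y_pred], dtype=int)
    prec, rec, f1, support = precision_recall_fscore_support(
        yt, yp, labels=list(range(len(class_inventory))), zero_division=0
    )
    return pd.DataFrame(
        {"subtype": list(class_inventory), "precision": prec, "recall": rec,
         "f1": f1, "support": support}
    )


def run_cv(
    dataset: MultiOmicsDataset,
    config: Optional[AttentionConfig] = None,
    k: int = 5,
    seed: int = 0,
    preprocess_config: Optional[PreprocessConfig] = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the attention classifier.

    With ``minmax_fit='train_only'`` (default) the min-max statistics for
    expression/accessibility are fitted inside each training fold; the
    ``'all'`` mode fits them once on the whole dataset before splitting.
    """
    config = config or AttentionConfig()
    pp = preprocess_config or PreprocessConfig()
    if dataset.labels is None:
        raise ValueError("cross-validation requires labels")
    assignment = kfold_split(dataset.cells, dataset.labels, k=k, seed=seed)
    classes = dataset.class_inventory()

    global_stats: Optional[dict[str, MinMaxStats]] = None
    if pp.minmax_fit == "all":
        global_stats = {}
        for m in dataset.omics:
            if m.omics_kind in MINMAX_KINDS:
                _, st = minmax_normalize(m)
                global_stats[m.omics_kind] = st

    fold_metrics = []
    all_true: list[str] = []
    all_pred: list[str] = []
    cells = dataset.cells
    for fold in range(k):
        te_idx = np.array([i for i, c in enumerate(cells) if assignment[c] == fold])
        tr_idx = np.array([i for i, c in enumerate(cells) if assignment[c] != fold])
        train_ds = dataset.subset_cells(tr_idx)
        test_ds = dataset.subset_cells(te_idx)
        try:
            model = attention_net.train(train_ds, config, minmax_stats=global_stats)
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {fold}: {exc}") from exc
        pred, prob = attention_net.predict(model, test_ds)
        y_true = [dataset.labels[c] for c in test_ds.cells]
        fold_metrics.append(compute_metrics(y_true, pred, prob, classes))
        all_true.extend(y_true)
        all_pred.extend(pred)

    mean = {m: float(np.mean([f[m] for f in fold_metrics])) for m in METRIC_NAMES}
    sd = {m: float(np.std([f[m] for f in fold_metrics], ddof=1)) for m in METRIC_NAMES}
    return CVResult(
        fold_metrics=fold_metrics,
        mean=mean,
        sd=sd,
        per_subtype=per_subtype_table(all_true, all_pred, classes),
        fold_assignment=assignment,
    )


def run_omics_ablation(
    dataset: MultiOmicsDataset,
    config: Optional[AttentionConfig] = None,
    combos: Optional[list[list[str]]] = None,
    k: int = 5,
    seed: int = 0,
    preprocess_config: Optional[PreprocessConfig] = None,
) -> dict[str, CVResult]:
    """Cross-validate every requested omics subset (default: all 2^n - 1)."""
    kinds = dataset.omics_kinds
    if combos is None:
        combos = [list(c) for r in range(1, len(kinds) + 1) for c in combinations(kinds, r)]
    results: dict[str, CVResult] = {}
    for combo in combos:
        name = "+".join(OMICS_TAGS.get(kind, kind) for kind in combo)
        sub = dataset.select_omics(list(combo))
        results[name] = run_cv(sub, config, k=k, seed=seed, preprocess_config=preprocess_config)
        logger.info("ablation %s: accuracy %.4f", name, results[name].mean["accuracy"])
    return results


def grid_search(
    dataset: MultiOmicsDataset,
    grid: list[AttentionConfig],
    split_ratio: float = 0.8,
    seed: int = 0,
    preprocess_config: Optional[PreprocessConfig] = None,
) -> tuple[AttentionConfig, pd.DataFrame]:
    """Pick the config with the best test accuracy on one stratified 80/20 split.

    Ties resolve to the earliest grid entry.
    """
    if not grid:
        raise ValueError("empty grid")
    y = [dataset.labels[c] for c in dataset.cells]
    idx = np.arange(dataset.n_cells)
    tr_idx, te_idx = train_test_split(
        idx, train_size=split_ratio, stratify=y, random_state=seed
    )
    train_ds = dataset.subset_cells(np.sort(tr_idx))
    test_ds = dataset.subset_cells(np.sort(te_idx))
    rows = []
    best_i, best_acc = 0, -1.0
    for i, cfg in enumerate(grid):
        if cfg.epochs > 0:
            model = attention_net.train(train_ds, cfg)
            pred, prob = attention_net.predict(model, test_ds)
        else:
            pred = [train_ds.class_inventory()[0]] * test_ds.n_cells
            prob = None
        y_true = [dataset.labels[c] for c in test_ds.cells]
        met = compute_metrics(y_true, pred, prob, dataset.class_inventory())
        rows.append({"grid_index": i, **_config_row(cfg), **met})
        if met["accuracy"] > best_acc:
            best_i, best_acc = i, met["accuracy"]
    return grid[best_i], pd.DataFrame(rows)


def _config_row(cfg: AttentionConfig) -> dict:
    return {
        "embed_dim": cfg.embed_dim, "encoded_dim": cfg.encoded_dim,
        "hidden_nodes": cfg.hidden_nodes, "dropout_rate": cfg.dropout_rate,
        "learning_rate": cfg.learning_rate, "epochs": cfg.epochs,
        "batch_size": cfg.batch_size,
    }


# ---------------------------------------------------------------------------
# Baseline hooks (off-the-shelf classifiers on the same feature matrices)


def baseline_classifier(name: str, seed: int = 0):
    """Thin adapter returning an off-the-shelf scikit-learn classifier.

    Supported names: rf, svm, lr, nb.
    """
    name = name.lower()
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed)
    if name == "svm":
        from sklearn.svm import SVC

        return SVC(probability=True, random_state=seed)
    if name == "lr":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "nb":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB()
    raise ValueError(f"unknown baseline {name!r}")


def concat_features(dataset: MultiOmicsDataset) -> np.ndarray:
    """Min-max scaled, concatenated feature matrix for baseline classifiers."""
    blocks = []
    for m in dataset.omics:
        if m.omics_kind in MINMAX_KINDS:
            m, _ = minmax_normalize(m)
        blocks.append(m.values)
    return np.concatenate(blocks, axis=1)
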
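"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-implement the model equations and the
evaluation metrics with plain loops / first-principles formulas so the
vectorized package code is checked against an independent route.
"""

from __future__ import annotations

import numpy as np
import pytest

import moscminer as mm
from moscminer import attention_net as an
from moscminer.types import (
    ACCESSIBILITY,
    EXPRESSION,
    METHYLATION,
    MultiOmicsDataset,
    OmicsMatrix,
)


@pytest.fixture(scope="session")
def easy():
    """The canonical planted-marker fixture (600 cells, 120 genes, 4 subtypes)."""
    ds, truth = mm.easy_fixture(seed=1)
    return ds, truth


@pytest.fixture(scope="session")
def trained_model(easy):
    ds, _ = easy
    return mm.train(ds, mm.AttentionConfig.synthetic_scale(seed=1))


def make_gene_dataset(seed=0, n=60, k=6, n_classes=3, effect=4.0, kinds=None):
    """Tiny labeled gene-level dataset with a planted mean shift per class."""
    kinds = kinds or [EXPRESSION, METHYLATION, ACCESSIBILITY]
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, n)
    cells = [f"c{i:03d}" for i in range(n)]
    mats = []
    for kind in kinds:
        X = rng.normal(0.0, 1.0, (n, k))
        for cls in range(n_classes):
            X[y == cls, cls % k] += effect
        if kind == METHYLATION:  # betas must stay in [0, 1]
            X = 1.0 / (1.0 + np.exp(-X))
        genes = [f"g{j}" for j in range(k)]
        mats.append(
            OmicsMatrix(cells=cells, feature_ids=genes, anchor_genes=genes,
                        values=X, omics_kind=kind)
        )
    labels = {c: f"s{y[i]}" for i, c in enumerate(cells)}
    return MultiOmicsDataset(omics=mats, labels=labels)


@pytest.fixture
def tiny_dataset():
    return make_gene_dataset(seed=3)


def random_tiny_model(rng, kinds=None, k=3, m=4, d=3, da=3, hidden=5, C=2):
    """A randomly initialized model over tiny dimensions, for oracle checks."""
    kinds = kinds or [EXPRESSION, METHYLATION]
    cfg = mm.AttentionConfig(
        embed_dim=m, encoded_dim=d, attn_dim=da, hidden_nodes=hidden,
        dropout_rate=0.0, epochs=1, batch_size=8, seed=int(rng.integers(2**31)),
    )
    counts = {kd: k for kd in kinds}
    fids = {kd: [f"{kd[:3]}{j}" for j in range(k)] for kd in kinds}
    model = an._init_model(cfg, list(kinds), counts, fids, fids,
                           [f"cls{i}" for i in range(C)], rng)
    # non-degenerate weights everywhere (init leaves biases and W3 small)
    for p in model.per_omics.values():
        p.b1 = rng.normal(0, 0.5, p.b1.shape).astype(np.float32)
        p.b2 = rng.normal(0, 0.5, p.b2.shape).astype(np.float32)
        p.W3 = rng.normal(0, 1.0, p.W3.shape).astype(np.float32)
    model.fc1_b = rng.normal(0, 0.5, model.fc1_b.shape).astype(np.float32)
    model.fc2_b = rng.normal(0, 0.5, model.fc2_b.shape).astype(np.float32)
    model.minmax_stats = {kd: None for kd in kinds}
    return model


def oracle_forward(model, x_per_omics):
    """Loop-based forward pass: embed, encode, score, softmax, pool, FC head."""
    contexts = []
    alphas = {}
    for kind in model.omics_kinds:
        p = model.per_omics[kind]
        x = np.asarray(x_per_omics[kind], dtype=float)
        k = len(x)
        x_hat = [np.asarray(p.E[j], dtype=float) * x[j] for j in range(k)]
        x_bar = [np.tanh(np.asarray(p.W1, float) @ xh + np.asarray(p.b1, float)) for xh in x_hat]
        s = np.array(
            [np.asarray(p.W3, float) @ np.tanh(np.asarray(p.W2, float) @ xh + np.asarray(p.b2, float))
             for xh in x_hat]
        )
        e = np.exp(s - s.max())
        alpha = e / e.sum()
        alphas[kind] = alpha
        c = np.zeros(len(x_bar[0]))
        for j in range(k):
            c = c + alpha[j] * x_bar[j]
        contexts.append(c)
    h = np.concatenate(contexts)
    a1 = np.asarray(model.fc1_W, float) @ h + np.asarray(model.fc1_b, float)
    r = np.maximum(a1, 0.0) if model.config.hidden_activation == "relu" else np.tanh(a1)
    a2 = np.asarray(model.fc2_W, float) @ r + np.asarray(model.fc2_b, float)
    e = np.exp(a2 - a2.max())
    return e / e.sum(), alphas


def oracle_metrics(y_true, y_pred, y_prob, n_classes):
    """First-principles accuracy, weighted F1, Gorodkin MCC, macro OvR AUC."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    n = len(y_true)
    conf = np.zeros((n_classes, n_classes))
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    acc = np.trace(conf) / n

    f1s, supports = [], []
    for c in range(n_classes):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        supports.append(conf[c, :].sum())
    f1_weighted = float(np.average(f1s, weights=supports))

    t_k = conf.sum(axis=1)  # true counts
    p_k = conf.sum(axis=0)  # predicted counts
    s = n
    cov = np.trace(conf) * s - t_k @ p_k
    denom = np.sqrt(s**2 - p_k @ p_k) * np.sqrt(s**2 - t_k @ t_k)
    mcc = float(cov / denom) if denom else 0.0

    aucs = []
    for c in range(n_classes):
        pos = y_true == c
        n_pos, n_neg = pos.sum(), (~pos).sum()
        if n_pos == 0 or n_neg == 0:
            continue
        from scipy.stats import rankdata

        ranks = rankdata(y_prob[:, c])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
    auc = float(np.mean(aucs)) if aucs else float("nan")
    return {"accuracy": float(acc), "f1_weighted": f1_weighted, "mcc": mcc, "auc": auc}
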
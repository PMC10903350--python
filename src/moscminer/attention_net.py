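"""The omics-level self-attention classifier.

Each omics layer gets its own attention block. A feature value x^(j) is
embedded by scaling a learned m-vector e_j,

    x_hat^(j) = e_j * x^(j),

encoded as x_bar^(j) = tanh(W1 x_hat^(j) + b1), and scored with

    s^(j) = W3 . tanh(W2 x_hat^(j) + b2).

Scores are softmax-normalized over the omics' features into attention
weights alpha^(j), and the omics collapses to one context vector per cell,
c = sum_j alpha^(j) x_bar^(j). Context vectors from all omics layers are
concatenated and passed through two fully connected layers ending in a
softmax over cell subtypes; training minimizes cross-entropy with Adam.

Implementation notes: because the embedding is bilinear, W1 @ (x * e_j)
equals x * (W1 @ e_j), so the per-feature projections E @ W1.T and E @ W2.T
are formed once per optimization step and the heavy tensors reduce to cheap
broadcasts. All math is NumPy float32 with hand-derived gradients; results
are bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .preprocess import MINMAX_KINDS, MinMaxStats, minmax_normalize
from .types import MultiOmicsDataset, OmicsMatrix, sort_omics

logger = logging.getLogger(__name__)

_EPS_LOG = 1e-12


@dataclass
class AttentionConfig:
    """Architecture and optimization hyperparameters.

    Defaults are the grid-search optimum reported for the real datasets:
    embedding size 128, encoded size 64, 100 hidden nodes, dropout 0.2,
    Adam with learning rate 1e-3, 300 epochs, batch size 128. ``attn_dim``
    is the width of the scoring layer (W2/b2) and defaults to the encoded
    size. ``synthetic_scale`` returns a lighter preset sized for the
    synthetic fixtures.
    """

    embed_dim: int = 128
    encoded_dim: int = 64
    attn_dim: int = 64
    hidden_nodes: int = 100
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 128
    seed: int = 0
    use_attention: bool = True
    train_embeddings: bool = True
    hidden_activation: str = "relu"  # or "tanh"

    def __post_init__(self) -> None:
        for name in ("embed_dim", "encoded_dim", "attn_dim", "hidden_nodes", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.hidden_activation not in ("relu", "tanh"):
            raise ValueError(f"bad hidden_activation {self.hidden_activation!r}")

    @classmethod
    def synthetic_scale(cls, seed: int = 0, **overrides) -> "AttentionConfig":
        """Reduced dimensions and epochs for the planted-signal fixtures."""
        kw = dict(
            embed_dim=64, encoded_dim=16, attn_dim=16, hidden_nodes=64,
            epochs=80, batch_size=128, seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class OmicsAttentionParams:
    """Attention-block weights for one omics layer (k features)."""

    E: np.ndarray  # (k, m) embedding vectors e_j
    W1: np.ndarray  # (encoded_dim, m)
    b1: np.ndarray  # (encoded_dim,)
    W2: np.ndarray  # (attn_dim, m)
    b2: np.ndarray  # (attn_dim,)
    W3: np.ndarray  # (attn_dim,)


@dataclass
class AttentionModelParams:
    """All trained parameters plus the bookkeeping needed to apply them."""

    config: AttentionConfig
    omics_kinds: list[str]
    feature_ids: dict[str, list[str]]
    anchor_genes: dict[str, list[str]]
    per_omics: dict[str, OmicsAttentionParams]
    fc1_W: np.ndarray
    fc1_b: np.ndarray
    fc2_W: np.ndarray
    fc2_b: np.ndarray
    class_inventory: list[str]
    minmax_stats: dict[str, Optional[MinMaxStats]]
    loss_trace: list[float] = field(default_factory=list)


@dataclass
class AttentionReport:
    """Per-sample and mean attention weights for each omics layer."""

    cells: list[str]
    omics_kinds: list[str]
    feature_ids: dict[str, list[str]]
    anchor_genes: dict[str, list[str]]
    alpha: dict[str, np.ndarray]  # kind -> (n_cells, k)
    mean_alpha: dict[str, np.ndarray]  # kind -> (k,)


# ---------------------------------------------------------------------------
# Elementary operations (the literal per-feature equations)


def embed_feature(x_value: float, e_j: np.ndarray) -> np.ndarray:
    """x_hat = e_j * x."""
    return np.asarray(e_j) * x_value


def encode_feature(x_hat: np.ndarray, W1: np.ndarray, b1: np.ndarray) -> np.ndarray:
    """x_bar = tanh(W1 x_hat + b1)."""
    return np.tanh(W1 @ x_hat + b1)


def score_feature(x_hat: np.ndarray, W2: np.ndarray, b2: np.ndarray, W3: np.ndarray) -> float:
    """s = W3 . tanh(W2 x_hat + b2)."""
    return float(np.asarray(W3) @ np.tanh(W2 @ x_hat + b2))


def normalize_attention(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Stable softmax over feature scores; rows sum to 1."""
    s = np.asarray(s)
    if s.shape[axis] == 0:
        raise ValueError("cannot normalize an empty score vector")
    z = s - s.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def context_vector(alpha: np.ndarray, x_bar: np.ndarray) -> np.ndarray:
    """Attention-pooled encoding: c = sum_j alpha_j x_bar_j."""
    return np.asarray(alpha) @ np.asarray(x_bar)


def cross_entropy(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """-sum_i y_i log(y_hat_i), with probabilities floored at 1e-12."""
    y_hat = np.maximum(np.asarray(y_hat, dtype=float), _EPS_LOG)
    return float(-(np.asarray(y_true, dtype=float) * np.log(y_hat)).sum())


# ---------------------------------------------------------------------------
# Vectorized forward / backward


def _act(a: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(a, 0.0) if kind == "relu" else np.tanh(a)


def _act_grad(a: np.ndarray, r: np.ndarray, kind: str) -> np.ndarray:
    return (a > 0).astype(a.dtype) if kind == "relu" else 1.0 - r * r


def _forward_batch(
    model: AttentionModelParams,
    X: dict[str, np.ndarray],
    train_mode: bool = False,
    dropout_rng: Optional[np.random.Generator] = None,
    want_cache: bool = False,
):
    """Run Eqs. (1)-(5) plus the FC head on a batch; returns (probs, alphas, cache)."""
    cfg = model.config
    contexts = []
    alphas: dict[str, np.ndarray] = {}
    cache: dict = {"per_omics": {}}
    for kind in model.omics_kinds:
        x = X[kind]
        if cfg.use_attention:
            p = model.per_omics[kind]
            P1 = (p.E @ p.W1.T).astype(np.float32)  # (k, d)
            P2 = (p.E @ p.W2.T).astype(np.float32)  # (k, da)
            Xb = np.tanh(x[:, :, None] * P1[None, :, :] + p.b1)  # (n, k, d)
            T2 = np.tanh(x[:, :, None] * P2[None, :, :] + p.b2)  # (n, k, da)
            s = T2 @ p.W3  # (n, k)
            alpha = normalize_attention(s, axis=1)
            c = np.einsum("nk,nkd->nd", alpha, Xb)
            alphas[kind] = alpha
            if want_cache:
                cache["per_omics"][kind] = dict(x=x, Xb=Xb, T2=T2, alpha=alpha)
            contexts.append(c)
        else:
            contexts.append(x)
    H = np.concatenate(contexts, axis=1)
    A1 = H @ model.fc1_W.T + model.fc1_b
    R = _act(A1, cfg.hidden_activation)
    if train_mode and cfg.dropout_rate > 0:
        keep = 1.0 - cfg.dropout_rate
        mask = (dropout_rng.random(R.shape) < keep).astype(R.dtype) / keep
        Rd = R * mask
    else:
        mask = None
        Rd = R
    A2 = Rd @ model.fc2_W.T + model.fc2_b
    probs = normalize_attention(A2, axis=1)  # same stable softmax
    if want_cache:
        cache.update(H=H, A1=A1, R=R, mask=mask, Rd=Rd, probs=probs)
    return probs, alphas, cache


def _backward_batch(model: AttentionModelParams, cache: dict, Y: np.ndarray) -> dict:
    """Gradients of mean cross-entropy over the batch w.r.t. all parameters."""
    cfg = model.config
    n = Y.shape[0]
    grads: dict = {}
    dA2 = (cache["probs"] - Y) / n
    grads["fc2_W"] = dA2.T @ cache["Rd"]
    grads["fc2_b"] = dA2.sum(axis=0)
    dRd = dA2 @ model.fc2_W
    dR = dRd * cache["mask"] if cache["mask"] is not None else dRd
    dA1 = dR * _act_grad(cache["A1"], cache["R"], cfg.hidden_activation)
    grads["fc1_W"] = dA1.T @ cache["H"]
    grads["fc1_b"] = dA1.sum(axis=0)
    dH = dA1 @ model.fc1_W
    if not cfg.use_attention:
        return grads
    offset = 0
    d = cfg.encoded_dim
    for kind in model.omics_kinds:
        p = model.per_omics[kind]
        co = cache["per_omics"][kind]
        x, Xb, T2, alpha = co["x"], co["Xb"], co["T2"], co["alpha"]
        dc = dH[:, offset : offset + d]
        offset += d
        dalpha = np.einsum("nd,nkd->nk", dc, Xb)
        dXb = alpha[:, :, None] * dc[:, None, :]
        ds = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
        dT2 = ds[:, :, None] * p.W3[None, None, :]
        dZ2 = dT2 * (1.0 - T2 * T2)
        dZ1 = dXb * (1.0 - Xb * Xb)
        dP1 = np.einsum("nk,nkd->kd", x, dZ1)
        dP2 = np.einsum("nk,nka->ka", x, dZ2)
        g = {
            "W1": dP1.T @ p.E,
            "b1": dZ1.sum(axis=(0, 1)),
            "W2": dP2.T @ p.E,
            "b2": dZ2.sum(axis=(0, 1)),
            "W3": np.einsum("nk,nka->a", ds, T2),
        }
        if cfg.train_embeddings:
            g["E"] = dP1 @ p.W1 + dP2 @ p.W2
        grads[kind] = g
    return grads


# ---------------------------------------------------------------------------
# Model assembly, training, prediction


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[-1]
    fan_out = shape[0]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(np.float32)


def _init_model(
    config: AttentionConfig,
    omics_kinds: list[str],
    feature_counts: dict[str, int],
    feature_ids: dict[str, list[str]],
    anchor_genes: dict[str, list[str]],
    class_inventory: list[str],
    rng: np.random.Generator,
) -> AttentionModelParams:
    per_omics: dict[str, OmicsAttentionParams] = {}
    if config.use_attention:
        for kind in omics_kinds:
            k = feature_counts[kind]
            per_omics[kind] = OmicsAttentionParams(
                E=rng.standard_normal((k, config.embed_dim)).astype(np.float32),
                W1=_glorot(rng, (config.encoded_dim, config.embed_dim)),
                b1=np.zeros(config.encoded_dim, dtype=np.float32),
                W2=_glorot(rng, (config.attn_dim, config.embed_dim)),
                b2=np.zeros(config.attn_dim, dtype=np.float32),
                # small scoring head: attention starts near-uniform so its
                # growth is driven by gradient usefulness, not init noise
                W3=0.1 * _glorot(rng, (1, config.attn_dim))[0],
            )
        fc1_in = config.encoded_dim * len(omics_kinds)
    else:
        fc1_in = sum(feature_counts.values())
    C = len(class_inventory)
    return AttentionModelParams(
        config=config,
        omics_kinds=list(omics_kinds),
        feature_ids=feature_ids,
        anchor_genes=anchor_genes,
        per_omics=per_omics,
        fc1_W=_glorot(rng, (config.hidden_nodes, fc1_in)),
        fc1_b=np.zeros(config.hidden_nodes, dtype=np.float32),
        fc2_W=_glorot(rng, (C, config.hidden_nodes)),
        fc2_b=np.zeros(C, dtype=np.float32),
        class_inventory=list(class_inventory),
        minmax_stats={},
    )


def _param_items(model: AttentionModelParams):
    """Yield (setter-key, array) pairs for every trainable parameter."""
    items = [("fc1_W", model.fc1_W), ("fc1_b", model.fc1_b),
             ("fc2_W", model.fc2_W), ("fc2_b", model.fc2_b)]
    for kind in model.omics_kinds:
        if kind not in model.per_omics:
            continue
        p = model.per_omics[kind]
        names = ["W1", "b1", "W2", "b2", "W3"]
        if model.config.train_embeddings:
            names.append("E")
        for nm in names:
            items.append(((kind, nm), getattr(p, nm)))
    return items


def _grad_for(grads: dict, key) -> Optional[np.ndarray]:
    if isinstance(key, tuple):
        return grads.get(key[0], {}).get(key[1])
    return grads.get(key)


def _normalized_views(
    model_or_stats, dataset: MultiOmicsDataset, fit: bool
) -> tuple[dict[str, np.ndarray], dict[str, Optional[MinMaxStats]]]:
    """Min-max scale expression/accessibility; methylation passes through."""
    X: dict[str, np.ndarray] = {}
    stats: dict[str, Optional[MinMaxStats]] = {}
    for m in dataset.omics:
        if m.omics_kind in MINMAX_KINDS:
            prior = None if fit else model_or_stats.get(m.omics_kind)
            scaled, st = minmax_normalize(m, fit_stats=prior)
            X[m.omics_kind] = scaled.values.astype(np.float32)
            stats[m.omics_kind] = st
        else:
            X[m.omics_kind] = m.values.astype(np.float32)
            stats[m.omics_kind] = None
    return X, stats


def train(
    dataset: MultiOmicsDataset,
    config: Optional[AttentionConfig] = None,
    minmax_stats: Optional[dict[str, MinMaxStats]] = None,
) -> AttentionModelParams:
    """Train the attention classifier with Adam on mini-batch cross-entropy.

    Min-max statistics for expression/accessibility are fitted on ``dataset``
    unless supplied, and are stored on the model so prediction applies the
    same scaling (with clipping). Initialization, batch shuffling and dropout
    all derive from ``config.seed``; identical seeds give identical models.
    """
    config = config or AttentionConfig()
    if dataset.labels is None:
        raise ValueError("training requires a labeled dataset")
    mats = sort_omics(dataset.omics)
    dataset = MultiOmicsDataset(omics=mats, labels=dataset.labels)
    kinds = [m.omics_kind for m in mats]

    if minmax_stats is None:
        X, stats = _normalized_views({}, dataset, fit=True)
    else:
        X, stats = _normalized_views(minmax_stats, dataset, fit=False)

    classes = dataset.class_inventory()
    y = dataset.label_array()
    Y = np.eye(len(classes), dtype=np.float32)[y]

    rng = np.random.default_rng(config.seed)
    model = _init_model(
        config, kinds,
        {m.omics_kind: m.n_features for m in mats},
        {m.omics_kind: list(m.feature_ids) for m in mats},
        {m.omics_kind: list(m.anchor_genes) for m in mats},
        classes, rng,
    )
    model.minmax_stats = stats

    items = _param_items(model)
    adam_m = [np.zeros_like(a) for _, a in items]
    adam_v = [np.zeros_like(a) for _, a in items]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = len(dataset.cells)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb = {k: v[idx] for k, v in X.items()}
            Yb = Y[idx]
            probs, _, cache = _forward_batch(
                model, Xb, train_mode=True, dropout_rng=rng, want_cache=True
            )
            p_true = np.maximum(probs[np.arange(len(idx)), y[idx]], _EPS_LOG)
            loss = float(-np.log(p_true).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(f"divergence: non-finite loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            grads = _backward_batch(model, cache, Yb)
            t += 1
            bc1 = 1.0 - beta1**t
            bc2 = 1.0 - beta2**t
            for i, (key, arr) in enumerate(items):
                g = _grad_for(grads, key)
                if g is None:
                    continue
                g = g.astype(arr.dtype)
                adam_m[i] = beta1 * adam_m[i] + (1 - beta1) * g
                adam_v[i] = beta2 * adam_v[i] + (1 - beta2) * (g * g)
                arr -= (config.learning_rate * (adam_m[i] / bc1)
                        / (np.sqrt(adam_v[i] / bc2) + eps)).astype(arr.dtype)
        model.loss_trace.append(epoch_loss / n)
    return model


def build_no_attention_variant(config: Optional[AttentionConfig] = None) -> AttentionConfig:
    """Config for the ablation that feeds raw normalized features to the FC head."""
    config = config or AttentionConfig()
    kw = asdict(config)
    kw["use_attention"] = False
    return AttentionConfig(**kw)


def _validated_views(model: AttentionModelParams, dataset: MultiOmicsDataset) -> dict[str, np.ndarray]:
    for kind in model.omics_kinds:
        m = dataset.matrix(kind)
        expected = len(model.feature_ids[kind])
        if m.n_features != expected:
            raise ValueError(
                f"{kind}: model expects {expected} features, dataset has {m.n_features}"
            )
    X, _ = _normalized_views(model.minmax_stats, dataset, fit=False)
    return X


def forward(
    model: AttentionModelParams,
    sample: dict[str, np.ndarray],
    train_mode: bool = False,
    dropout_rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Class probabilities and attention rows for pre-normalized feature vectors.

    ``sample`` maps omics kind to a (k,) vector or (n, k) matrix of values
    already on the model's input scale.
    """
    squeeze = False
    X = {}
    for kind in model.omics_kinds:
        v = np.asarray(sample[kind], dtype=np.float32)
        if v.ndim == 1:
            v = v[None, :]
            squeeze = True
        expected = len(model.feature_ids[kind])
        if v.shape[1] != expected:
            raise ValueError(f"{kind}: expected {expected} features, got {v.shape[1]}")
        X[kind] = v
    if train_mode and dropout_rng is None:
        dropout_rng = np.random.default_rng(model.config.seed)
    probs, alphas, _ = _forward_batch(model, X, train_mode=train_mode, dropout_rng=dropout_rng)
    if squeeze:
        probs = probs[0]
        alphas = {k: a[0] for k, a in alphas.items()}
    return probs, alphas


def predict(model: AttentionModelParams, dataset: MultiOmicsDataset) -> tuple[list[str], np.ndarray]:
    """Deterministic argmax prediction; ties resolve to the lowest class index."""
    X = _validated_views(model, dataset)
    probs, _, _ = _forward_batch(model, X, train_mode=False)
    labels = [model.class_inventory[i] for i in probs.argmax(axis=1)]
    return labels, probs


def extract_attention(model: AttentionModelParams, dataset: MultiOmicsDataset) -> AttentionReport:
    """Per-sample attention weights (dropout off) and their per-feature means."""
    if not model.config.use_attention:
        raise ValueError("model was trained without the attention blocks")
    X = _validated_views(model, dataset)
    _, alphas, _ = _forward_batch(model, X, train_mode=False)
    return AttentionReport(
        cells=list(dataset.cells),
        omics_kinds=list(model.omics_kinds),
        feature_ids={k: list(v) for k, v in model.feature_ids.items()},
        anchor_genes={k: list(v) for k, v in model.anchor_genes.items()},
        alpha=alphas,
        mean_alpha={k: a.mean(axis=0) for k, a in alphas.items()},
    )


# ---------------------------------------------------------------------------
# Serialization: one .npz archive holding config JSON + parameter arrays


def save_model(model: AttentionModelParams, path: Union[str, Path]) -> None:
    meta = {
        "config": asdict(model.config),
        "omics_kinds": model.omics_kinds,
        "feature_ids": model.feature_ids,
        "anchor_genes": model.anchor_genes,
        "class_inventory": model.class_inventory,
        "loss_trace": model.loss_trace,
        "scaled_kinds": [k for k, v in model.minmax_stats.items() if v is not None],
    }
    arrays = {
        "fc1_W": model.fc1_W, "fc1_b": model.fc1_b,
        "fc2_W": model.fc2_W, "fc2_b": model.fc2_b,
    }
    for kind, p in model.per_omics.items():
        for nm in ("E", "W1", "b1", "W2", "b2", "W3"):
            arrays[f"attn.{kind}.{nm}"] = getattr(p, nm)
    for kind, st in model.minmax_stats.items():
        if st is not None:
            arrays[f"minmax.{kind}.min"] = st.feature_min
            arrays[f"minmax.{kind}.max"] = st.feature_max
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: Union[str, Path]) -> AttentionModelParams:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = AttentionConfig(**meta["config"])
        per_omics = {}
        for kind in meta["omics_kinds"]:
            if f"attn.{kind}.E" in z:
                per_omics[kind] = OmicsAttentionParams(
                    *[z[f"attn.{kind}.{nm}"] for nm in ("E", "W1", "b1", "W2", "b2", "W3")]
                )
        stats: dict[str, Optional[MinMaxStats]] = {}
        for kind in meta["omics_kinds"]:
            if kind in meta["scaled_kinds"]:
                stats[kind] = MinMaxStats(z[f"minmax.{kind}.min"], z[f"minmax.{kind}.max"])
            else:
                stats[kind] = None
        return AttentionModelParams(
            config=cfg,
            omics_kinds=meta["omics_kinds"],
            feature_ids=meta["feature_ids"],
            anchor_genes=meta["anchor_genes"],
            per_omics=per_omics,
            fc1_W=z["fc1_W"], fc1_b=z["fc1_b"],
            fc2_W=z["fc2_W"], fc2_b=z["fc2_b"],
            class_inventory=meta["class_inventory"],
            minmax_stats=stats,
            loss_trace=list(meta["loss_trace"]),
        )
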
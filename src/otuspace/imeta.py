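"""IMETA: interpretable attribute classification on embedded taxa.

A sample is represented by its log-scaled OTU abundance vector x (length
k).  Taxo-Embedding scales each OTU's fixed, pre-trained embedding row
by that OTU's abundance, giving a k x d matrix; a 1-D convolution layer
with three kernels (each a length-k weight vector over OTUs) turns the
matrix into three d-dimensional vectors — each kernel output is exactly
an abundance-weighted sum of embedded OTU vectors.  The three vectors
are flattened (n_kernels * d components), optionally concatenated with
the sample's own embedding vector, and a dense sigmoid head outputs the
binary class probability.  Because each kernel weight multiplies one
OTU, the averaged kernel parameters read out directly as per-OTU
importance scores.

The end-to-end twin shares the architecture but trains the embedding
matrix from random initialisation, for ablating the value of
pre-trained OTU vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ImetaConfig", "ImetaModel", "log_scale_abundance", "taxo_embed",
           "forward", "forward_batch", "loss_and_grads", "train_imeta",
           "train_end_to_end",
           "importance_scores", "save_model", "load_model", "upsample_minority"]


@dataclass
class ImetaConfig:
    k: int
    d: int = 128
    n_kernels: int = 3
    use_sample_vector: bool = False
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int | None = 64
    seed: int = 0
    upsample: bool = True
    optimizer: str = "adam"  # or "gd" (full-batch gradient descent)
    early_stopping: bool = True
    patience: int = 10
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_kernels < 1:
            raise ValueError("need at least one kernel")

    @property
    def dense_in(self) -> int:
        return self.n_kernels * self.d + (self.d if self.use_sample_vector else 0)


@dataclass
class ImetaModel:
    """Embedding matrix E (k x d), kernels A (k x n_kernels), dense head."""

    E: np.ndarray
    A: np.ndarray
    w: np.ndarray
    b: float
    config: ImetaConfig
    trainable_embedding: bool = False
    history: dict = field(default_factory=dict)

    def n_trainable(self) -> int:
        n = self.A.size + self.w.size + 1
        if self.trainable_embedding:
            n += self.E.size
        return n


def log_scale_abundance(
    rel_row: np.ndarray, r_floor: float = 1e-5, mode: str = "shifted"
) -> np.ndarray:
    """Base-10 log scaling of a relative-abundance vector.

    ``shifted`` (default): absent OTUs map to 0 and present OTUs to
    log10(r) - log10(r_floor) > 0, where ``r_floor`` is the smallest
    detectable abundance (1 / max sequencing depth).  With this
    convention an absent OTU contributes nothing to the weighted sum of
    embedded vectors.  ``raw`` keeps plain log10(r) with absent -> 0.
    """
    rel_row = np.asarray(rel_row, dtype=np.float64)
    if (rel_row < 0).any():
        raise ValueError("negative abundance")
    x = np.zeros_like(rel_row)
    nz = rel_row > 0
    if mode == "shifted":
        x[nz] = np.log10(rel_row[nz]) - np.log10(r_floor)
    elif mode == "raw":
        x[nz] = np.log10(rel_row[nz])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return x


def taxo_embed(x: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Scale each OTU's embedding row by its log-scaled abundance."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != E.shape[0]:
        raise ValueError(f"abundance length {x.shape[0]} != embedding rows {E.shape[0]}")
    return x[:, None] * E


def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                    np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))


def _logits(model: ImetaModel, X: np.ndarray, S: np.ndarray | None) -> np.ndarray:
    cfg = model.config
    d = model.E.shape[1]
    # kernel c output: (X * A[:, c]) @ E, an abundance-weighted sum of rows of E
    flat = np.concatenate(
        [(X * model.A[:, c]) @ model.E for c in range(cfg.n_kernels)], axis=1
    )
    if cfg.use_sample_vector:
        if S is None:
            raise ValueError("sample vectors required when use_sample_vector is on")
        flat = np.concatenate([flat, S], axis=1)
    return flat @ model.w + model.b


def forward(model: ImetaModel, x: np.ndarray, s: np.ndarray | None = None) -> float:
    """Class probability for one sample."""
    X = np.asarray(x, dtype=np.float64)[None, :]
    S = None if s is None else np.asarray(s, dtype=np.float64)[None, :]
    return float(_sigmoid(_logits(model, X, S))[0])


def forward_batch(model: ImetaModel, X: np.ndarray, S: np.ndarray | None = None) -> np.ndarray:
    return _sigmoid(_logits(model, np.asarray(X, dtype=np.float64), S))


def upsample_minority(
    y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices balancing the two classes by resampling the minority."""
    y = np.asarray(y)
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("both classes must be present")
    if idx0.size < idx1.size:
        extra = rng.choice(idx0, size=idx1.size - idx0.size, replace=True)
    elif idx1.size < idx0.size:
        extra = rng.choice(idx1, size=idx0.size - idx1.size, replace=True)
    else:
        extra = np.empty(0, dtype=np.int64)
    idx = np.concatenate([idx0, idx1, extra])
    rng.shuffle(idx)
    return idx


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def loss_and_grads(
    model: ImetaModel,
    X: np.ndarray,
    S: np.ndarray | None,
    y: np.ndarray,
    trainable_embedding: bool = False,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean binary cross-entropy and its analytic gradients.

    Gradients cover the kernels A, the dense weights w, the bias b, and
    (when ``trainable_embedding``) the embedding matrix E.
    """
    cfg = model.config
    d = model.E.shape[1]
    z = _logits(model, X, S)
    p = _sigmoid(z)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    dz = (p - y) / len(y)
    flat = np.concatenate(
        [(X * model.A[:, c]) @ model.E for c in range(cfg.n_kernels)], axis=1
    )
    if cfg.use_sample_vector:
        flat = np.concatenate([flat, S], axis=1)
    grads = {"w": flat.T @ dz, "b": np.array([dz.sum()])}
    Xtdz = X.T @ dz
    Wmat = model.w[: cfg.n_kernels * d].reshape(cfg.n_kernels, d)
    grads["A"] = Xtdz[:, None] * (model.E @ Wmat.T)
    if trainable_embedding:
        grads["E"] = Xtdz[:, None] * (model.A @ Wmat)
    return loss, grads


def _train(
    X: np.ndarray,
    S: np.ndarray | None,
    y: np.ndarray,
    E: np.ndarray,
    config: ImetaConfig,
    trainable_embedding: bool,
) -> ImetaModel:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0} or len(np.unique(y)) < 2:
        raise ValueError("y must contain both binary classes 0 and 1")
    rng = np.random.default_rng(config.seed)
    k, d = config.k, config.d
    if E.shape != (k, d):
        raise ValueError(f"embedding matrix must be {k} x {d}, got {E.shape}")
    E = E.astype(np.float64).copy() if trainable_embedding else np.asarray(E, np.float64)

    # held-out validation split for early stopping
    Xv = Sv = yv = None
    if config.early_stopping and config.val_fraction > 0:
        n_val = int(round(config.val_fraction * len(y)))
        order = rng.permutation(len(y))
        val, tr = order[:n_val], order[n_val:]
        if n_val >= 2 and len(set(y[val])) == 2 and len(set(y[tr])) == 2:
            Xv, yv = X[val], y[val]
            Sv = S[val] if S is not None else None
            X, y = X[tr], y[tr]
            S = S[tr] if S is not None else None

    if config.upsample:
        idx = upsample_minority(y, rng)
        X, y = X[idx], y[idx]
        S = S[idx] if S is not None else None

    A = rng.normal(0.0, 0.01, size=(k, config.n_kernels))
    w = rng.normal(0.0, 0.01, size=config.dense_in)
    b = 0.0
    model = ImetaModel(E, A, w, b, config, trainable_embedding)

    params = {"A": A, "w": w, "b": np.array([b])}
    if trainable_embedding:
        params["E"] = E
    m = {p: np.zeros_like(v) for p, v in params.items()}
    v2 = {p: np.zeros_like(v) for p, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = {"loss": [], "val_f1": []}
    best_val, best_state, patience_left = -np.inf, None, config.patience

    n = len(y)
    batch = n if config.batch_size is None else min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = np.arange(n) if config.optimizer == "gd" else rng.permutation(n)
        losses = []
        for lo in range(0, n, batch):
            sel = order[lo : lo + batch]
            Xb, yb = X[sel], y[sel]
            Sb = S[sel] if S is not None else None
            loss, grads = loss_and_grads(model, Xb, Sb, yb, trainable_embedding)
            losses.append(loss)
            t += 1
            for pname, g in grads.items():
                if config.optimizer == "adam":
                    m[pname] = beta1 * m[pname] + (1 - beta1) * g
                    v2[pname] = beta2 * v2[pname] + (1 - beta2) * g * g
                    mhat = m[pname] / (1 - beta1**t)
                    vhat = v2[pname] / (1 - beta2**t)
                    step = config.lr * mhat / (np.sqrt(vhat) + eps)
                else:
                    step = config.lr * g
                params[pname] -= step
            model.b = float(params["b"][0])
        history["loss"].append(float(np.mean(losses)))
        if Xv is not None:
            pv = forward_batch(model, Xv, Sv)
            val_f1 = _f1(yv, (pv >= 0.5).astype(int))
            history["val_f1"].append(val_f1)
            if val_f1 > best_val:
                best_val = val_f1
                best_state = (model.A.copy(), model.w.copy(), model.b,
                              model.E.copy() if trainable_embedding else None)
                patience_left = config.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_state is not None:
        model.A[:], model.w[:], model.b = best_state[0], best_state[1], best_state[2]
        if trainable_embedding and best_state[3] is not None:
            model.E[:] = best_state[3]
    model.history = history
    return model


def train_imeta(
    X: np.ndarray,
    S: np.ndarray | None,
    y: np.ndarray,
    E: np.ndarray,
    config: ImetaConfig,
) -> ImetaModel:
    """Train with the pre-trained OTU embedding matrix E held frozen."""
    return _train(X, S, y, E, config, trainable_embedding=False)


def train_end_to_end(
    X: np.ndarray,
    S: np.ndarray | None,
    y: np.ndarray,
    config: ImetaConfig,
    E_init: np.ndarray | None = None,
) -> ImetaModel:
    """Same architecture with a randomly initialised, trainable embedding."""
    rng = np.random.default_rng(config.seed + 1)
    E = (rng.normal(0.0, 0.1, size=(config.k, config.d))
         if E_init is None else np.array(E_init, dtype=np.float64))
    return _train(X, S, y, E, config, trainable_embedding=True)


def importance_scores(
    model: ImetaModel,
    threshold: float = 0.3,
    otu_ids: list[str] | None = None,
    mode: str = "mean_abs",
) -> pd.DataFrame:
    """Per-OTU importance from the convolution kernels.

    The sign of each kernel column is a gauge freedom (negating A[:, c]
    together with its dense block leaves the model unchanged), so the
    identifiable importance is the mean of the absolute kernel
    parameters per OTU — the default.  ``mode="signed_mean"`` instead
    averages the raw parameters and takes the absolute value of that
    mean; it is interpretable only when the trained kernels happen to
    share signs.  Rank 1 is the most important OTU; ``flagged`` marks
    importance > threshold.
    """
    signed = model.A.mean(axis=1)
    importance = np.abs(model.A).mean(axis=1) if mode == "mean_abs" else np.abs(signed)
    order = np.argsort(-importance, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    idx = otu_ids if otu_ids is not None else list(range(model.A.shape[0]))
    return pd.DataFrame(
        {"signed_mean": signed, "importance": importance, "rank": rank,
         "flagged": importance > threshold},
        index=pd.Index(idx, name="otu_id"),
    )


def save_model(model: ImetaModel, path: str | Path) -> None:
    """Single-archive checkpoint: config JSON + weight arrays."""
    np.savez(
        path,
        config=json.dumps(asdict(model.config)),
        trainable_embedding=model.trainable_embedding,
        E=model.E, A=model.A, w=model.w, b=model.b,
    )


def load_model(path: str | Path) -> ImetaModel:
    with np.load(path, allow_pickle=False) as z:
        config = ImetaConfig(**json.loads(str(z["config"])))
        return ImetaModel(z["E"], z["A"], z["w"], float(z["b"]), config,
                          bool(z["trainable_embedding"]))
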
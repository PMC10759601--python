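"""Graph-level neural classification of brain graphs.

Two architectures, implemented directly in numpy with hand-derived
reverse-mode gradients and an Adam optimizer:

* **GCN** — stacked symmetric-normalized graph convolutions
  ``H' = relu(D^{-1/2}(A+I)D^{-1/2} H W)`` with mean node readout and a
  dense softmax head;
* **DGCNN** — tanh graph convolutions whose channel-concatenated outputs
  pass through SortPooling (nodes sorted by the last channel, truncated or
  zero-padded to k rows), a 1-D convolution along the node axis, max
  pooling, and a dense softmax head.  SortPooling gives a canonical node
  order, so isomorphic graphs map to identical representations.

Training uses full-batch cross-entropy with early stopping on a held-out
validation split.  Both forward passes also expose gradients with respect
to the (normalized) adjacency and the node features, which the explainer
module reuses for mask optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .connectome import binarize
from .datamodel import BinaryGraph, Cohort, ConnectomlError
from .features import compute_local
from .ml import METRIC_NAMES, MetricSummary, confusion_counts, metrics_from_confusion


@dataclass(frozen=True)
class GnnConfig:
    gcn_channels: tuple[int, ...] = (64, 64, 64)
    dgcnn_channels: tuple[int, ...] = (32, 32, 32, 1)
    sortpool_k: int = 30
    conv1d_filters: int = 16
    learning_rate: float = 0.01
    patience: int = 10
    max_epochs: int = 150
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1 or self.max_epochs < 1:
            raise ConnectomlError("patience and max_epochs must be >= 1")
        if self.dgcnn_channels[-1] != 1:
            raise ConnectomlError("last DGCNN conv layer must have 1 channel "
                                  "(the SortPooling key)")


@dataclass
class GraphSample:
    """One training instance: normalized adjacency, node features, label."""

    A_norm: np.ndarray
    X: np.ndarray
    y: int


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric renormalization with self-loops: D̂^{-1/2}(A+I)D̂^{-1/2}."""
    A = np.asarray(A, dtype=float)
    At = A + np.eye(A.shape[0])
    d = At.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return dinv[:, None] * At * dinv[None, :]


def gcn_layer(A_norm: np.ndarray, H: np.ndarray, Wt: np.ndarray,
              act: str = "relu") -> np.ndarray:
    """One graph-convolution layer: act(Â H W)."""
    pre = A_norm @ (H @ Wt)
    if act == "relu":
        return np.maximum(pre, 0.0)
    if act == "tanh":
        return np.tanh(pre)
    raise ConnectomlError(f"unknown activation {act!r}")


def sort_pooling(H: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Canonical node ordering and truncation/padding to k rows.

    Rows sort descending by the last channel; ties break by the preceding
    channels right-to-left, and remaining ties by original node order
    (stable).  Returns (k x C matrix, kept row indices, number kept).
    """
    if k <= 0:
        raise ConnectomlError("sortpool k must be positive")
    n, C = H.shape
    order = np.lexsort([-H[:, c] for c in range(C)])
    keep = order[: min(n, k)]
    pooled = np.zeros((k, C))
    pooled[: len(keep)] = H[keep]
    return pooled, keep, len(keep)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


# ---------------------------------------------------------------------------
# GCN


class GcnModel:
    """Graph convolutional network with mean readout."""

    kind = "gcn"

    def __init__(self, n_features: int, config: GnnConfig = GnnConfig()):
        self.n_features = n_features
        self.config = config

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        sizes = [self.n_features, *self.config.gcn_channels]
        params = {
            f"W{i}": _glorot(rng, sizes[i], sizes[i + 1])
            for i in range(len(sizes) - 1)
        }
        params["Wd"] = _glorot(rng, sizes[-1], 2)
        params["bd"] = np.zeros(2)
        return params

    def forward(self, A_norm: np.ndarray, X: np.ndarray,
                params: dict) -> tuple[np.ndarray, dict]:
        Hs = [X]
        n_conv = len(self.config.gcn_channels)
        for i in range(n_conv):
            Hs.append(gcn_layer(A_norm, Hs[-1], params[f"W{i}"], act="relu"))
        z = Hs[-1].mean(axis=0)
        logits = z @ params["Wd"] + params["bd"]
        probs = softmax(logits)
        return probs, {"A": A_norm, "Hs": Hs, "z": z, "probs": probs}

    def backward(self, cache: dict, params: dict,
                 dlogits: np.ndarray) -> tuple[dict, np.ndarray, np.ndarray]:
        """Gradients of the loss w.r.t. params, A_norm and X."""
        A, Hs = cache["A"], cache["Hs"]
        n = Hs[0].shape[0]
        grads = {
            "Wd": np.outer(cache["z"], dlogits),
            "bd": dlogits.copy(),
        }
        dH = np.tile((dlogits @ params["Wd"].T) / n, (n, 1))
        dA = np.zeros_like(A)
        n_conv = len(self.config.gcn_channels)
        for i in reversed(range(n_conv)):
            H_out, H_in = Hs[i + 1], Hs[i]
            dpre = dH * (H_out > 0)
            HW = H_in @ params[f"W{i}"]
            grads[f"W{i}"] = (A @ H_in).T @ dpre
            dA += dpre @ HW.T
            dH = A.T @ dpre @ params[f"W{i}"].T
        return grads, dA, dH


# ---------------------------------------------------------------------------
# DGCNN


class DgcnnModel:
    """Deep graph convolutional network with SortPooling."""

    kind = "dgcnn"

    def __init__(self, n_features: int, config: GnnConfig = GnnConfig()):
        self.n_features = n_features
        self.config = config
        self.concat_channels = sum(config.dgcnn_channels)
        if self.config.sortpool_k % 2:
            raise ConnectomlError("sortpool_k must be even (max-pool of size 2)")

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        sizes = [self.n_features, *cfg.dgcnn_channels]
        params = {
            f"W{i}": _glorot(rng, sizes[i], sizes[i + 1])
            for i in range(len(sizes) - 1)
        }
        C = self.concat_channels
        params["Wc"] = _glorot(rng, C, cfg.conv1d_filters)
        params["bc"] = np.zeros(cfg.conv1d_filters)
        dense_in = (cfg.sortpool_k // 2) * cfg.conv1d_filters
        params["Wd"] = _glorot(rng, dense_in, 2)
        params["bd"] = np.zeros(2)
        return params

    def forward(self, A_norm: np.ndarray, X: np.ndarray,
                params: dict) -> tuple[np.ndarray, dict]:
        cfg = self.config
        Hs = [X]
        for i in range(len(cfg.dgcnn_channels)):
            Hs.append(gcn_layer(A_norm, Hs[-1], params[f"W{i}"], act="tanh"))
        Hc = np.concatenate(Hs[1:], axis=1)
        P, keep, n_keep = sort_pooling(Hc, cfg.sortpool_k)
        # 1-D conv with kernel = channel width and stride = channel width
        # over the row-major flattened representation == per-row linear map
        Z = np.maximum(P @ params["Wc"] + params["bc"], 0.0)
        half = cfg.sortpool_k // 2
        Zp = Z.reshape(half, 2, cfg.conv1d_filters)
        arg = Zp.argmax(axis=1)
        M = Zp.max(axis=1)
        flat = M.ravel()
        logits = flat @ params["Wd"] + params["bd"]
        probs = softmax(logits)
        return probs, {
            "A": A_norm, "Hs": Hs, "Hc": Hc, "P": P, "keep": keep,
            "n_keep": n_keep, "Z": Z, "arg": arg, "flat": flat, "probs": probs,
        }

    def backward(self, cache: dict, params: dict,
                 dlogits: np.ndarray) -> tuple[dict, np.ndarray, np.ndarray]:
        cfg = self.config
        A, Hs = cache["A"], cache["Hs"]
        grads = {
            "Wd": np.outer(cache["flat"], dlogits),
            "bd": dlogits.copy(),
        }
        half = cfg.sortpool_k // 2
        dM = (dlogits @ params["Wd"].T).reshape(half, cfg.conv1d_filters)
        dZ = np.zeros_like(cache["Z"]).reshape(half, 2, cfg.conv1d_filters)
        rows = np.arange(half)[:, None]
        cols = np.arange(cfg.conv1d_filters)[None, :]
        dZ[rows, cache["arg"], cols] = dM
        dZ = dZ.reshape(cfg.sortpool_k, cfg.conv1d_filters)
        dZ = dZ * (cache["Z"] > 0)
        grads["Wc"] = cache["P"].T @ dZ
        grads["bc"] = dZ.sum(axis=0)
        dP = dZ @ params["Wc"].T
        dHc = np.zeros_like(cache["Hc"])
        dHc[cache["keep"]] = dP[: cache["n_keep"]]
        # split concat gradient back per conv layer
        dH_layers = np.split(dHc, np.cumsum(cfg.dgcnn_channels)[:-1], axis=1)
        dA = np.zeros_like(A)
        dH_next = np.zeros_like(Hs[-1])
        for i in reversed(range(len(cfg.dgcnn_channels))):
            H_out, H_in = Hs[i + 1], Hs[i]
            dH_total = dH_layers[i] + dH_next
            dpre = dH_total * (1.0 - H_out**2)
            HW = H_in @ params[f"W{i}"]
            grads[f"W{i}"] = (A @ H_in).T @ dpre
            dA += dpre @ HW.T
            dH_next = A.T @ dpre @ params[f"W{i}"].T
        return grads, dA, dH_next


def make_gnn(kind: str, n_features: int, config: GnnConfig):
    if kind == "gcn":
        return GcnModel(n_features, config)
    if kind == "dgcnn":
        return DgcnnModel(n_features, config)
    raise ConnectomlError(f"unknown GNN kind {kind!r}")


# ---------------------------------------------------------------------------
# training


class Adam:
    def __init__(self, params: dict, lr: float, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _loss_and_grads(model, params: dict, batch: list[GraphSample],
                    compute_grads: bool = True) -> tuple[float, dict | None, float]:
    total_loss = 0.0
    correct = 0
    grads = {k: np.zeros_like(v) for k, v in params.items()} if compute_grads else None
    for s in batch:
        probs, cache = model.forward(s.A_norm, s.X, params)
        p = max(probs[s.y], 1e-12)
        total_loss += -np.log(p)
        correct += int(probs.argmax() == s.y)
        if compute_grads:
            dlogits = probs.copy()
            dlogits[s.y] -= 1.0
            g, _, _ = model.backward(cache, params, dlogits)
            for k in grads:
                grads[k] += g[k]
    nb = len(batch)
    if compute_grads:
        for k in grads:
            grads[k] /= nb
        if np.any([not np.isfinite(v).all() for v in grads.values()]):
            raise ConnectomlError("GNN training diverged: non-finite gradient")
    return total_loss / nb, grads, correct / nb


def train(model, train_set: list[GraphSample], val_set: list[GraphSample],
          config: GnnConfig) -> tuple[dict, dict]:
    """Adam + early stopping; returns (best-validation params, history)."""
    if not train_set or not val_set:
        raise ConnectomlError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    params = model.init_params(rng)
    opt = Adam(params, lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    stale = 0
    for epoch in range(config.max_epochs):
        loss, grads, acc = _loss_and_grads(model, params, train_set)
        if not np.isfinite(loss):
            raise ConnectomlError(f"GNN training diverged at epoch {epoch}")
        opt.step(params, grads)
        val_loss, _, val_acc = _loss_and_grads(model, params, val_set,
                                               compute_grads=False)
        history["train_loss"].append(loss)
        history["val_loss"].append(val_loss)
        history["train_acc"].append(acc)
        history["val_acc"].append(val_acc)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return best_params, history


def predict(model, params: dict, samples: list[GraphSample]) -> np.ndarray:
    return np.array([
        int(model.forward(s.A_norm, s.X, params)[0].argmax()) for s in samples
    ])


# ---------------------------------------------------------------------------
# cohort-level evaluation


def cohort_samples(cohort: Cohort, tau: float,
                   local_features: np.ndarray | None = None) -> list[GraphSample]:
    """Build GraphSamples: binary graph at tau + 26 local nodal measures.

    ``local_features`` (n_subjects x N x 26) can be precomputed to avoid
    recomputing the feature engine across folds or models.
    """
    samples = []
    for idx, s in enumerate(cohort):
        gb = binarize(s.matrix, tau)
        if local_features is not None:
            X = local_features[idx]
        else:
            X = compute_local(gb, s.matrix).to_numpy()
        samples.append(GraphSample(A_norm=normalize_adjacency(gb.A),
                                   X=np.asarray(X, dtype=float), y=s.label))
    return samples


def _standardize(train: list[GraphSample], others: list[list[GraphSample]]):
    stack = np.concatenate([s.X for s in train], axis=0)
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0)
    sd[sd == 0] = 1.0
    sets = [train, *others]
    return [
        [GraphSample(s.A_norm, (s.X - mu) / sd, s.y) for s in part]
        for part in sets
    ]


def crossval_gnn(cohort: Cohort, kind: str, folds: int = 10,
                 config: GnnConfig = GnnConfig(), tau: float = 0.20,
                 local_features: np.ndarray | None = None) -> MetricSummary:
    """Stratified k-fold evaluation; augmented subjects train-only.

    Node features are NaN-free only for connected graphs; NaN columns are
    zero-imputed after standardization so isolated disconnections do not
    poison training.
    """
    samples = cohort_samples(cohort, tau, local_features)
    y = cohort.labels
    original = np.array([s.provenance == "original" for s in cohort])
    orig_idx = np.flatnonzero(original)
    aug_idx = np.flatnonzero(~original)
    counts = np.bincount(y[orig_idx], minlength=2)
    if counts.min() < folds:
        raise ConnectomlError(
            f"need at least {folds} original subjects per class, got {counts.tolist()}"
        )
    for s in samples:
        s.X = np.nan_to_num(s.X, nan=0.0, posinf=0.0, neginf=0.0)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    per_fold = []
    for fold, (tr, te) in enumerate(cv.split(np.zeros(len(orig_idx)), y[orig_idx])):
        train_idx = np.concatenate([orig_idx[tr], aug_idx]).astype(int)
        test_idx = orig_idx[te]
        tr_in, val_in = train_test_split(
            train_idx, test_size=config.val_fraction, stratify=y[train_idx],
            random_state=config.seed + fold)
        train_set = [samples[i] for i in tr_in]
        val_set = [samples[i] for i in val_in]
        test_set = [samples[i] for i in test_idx]
        train_set, val_set, test_set = _standardize(train_set, [val_set, test_set])
        model = make_gnn(kind, samples[0].X.shape[1],
                         replace(config, seed=config.seed + fold))
        params, _ = train(model, train_set, val_set,
                          replace(config, seed=config.seed + fold))
        pred = predict(model, params, test_set)
        per_fold.append(metrics_from_confusion(
            *confusion_counts(y[test_idx], pred)))
    mean = {m: float(np.mean([f[m] for f in per_fold])) for m in METRIC_NAMES}
    std = {m: float(np.std([f[m] for f in per_fold])) for m in METRIC_NAMES}
    return MetricSummary(model=kind, mean=mean, std=std, per_fold=per_fold)
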
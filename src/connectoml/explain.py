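"""Model interpretability: Shapley attributions and GNN edge/feature masks.

Tree-ensemble attributions use the polynomial-time path-dependent Shapley
algorithm for decision trees (conditional expectations follow training-set
cover down unsplit branches), summed over ensemble members; a
permutation-sampling approximation is available for arbitrary models.
Local attributions are additive: base value + sum of attributions equals
the model's predicted probability of the patient class.

GNN explanations learn continuous masks over edges and node-feature
channels by gradient descent on the frozen model's cross-entropy toward
its own prediction, with an L1 size penalty and an elementwise entropy
penalty pushing masks toward binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .datamodel import ConnectomlError
from .gnn import GraphSample

EXACT_DEPTH_LIMIT = 10


# ---------------------------------------------------------------------------
# exact Shapley values for decision trees (path-dependent conditioning)


class _Path:
    __slots__ = ("feature", "zero", "one", "pweight")

    def __init__(self, feature: int, zero: float, one: float, pweight: float):
        self.feature = feature
        self.zero = zero
        self.one = one
        self.pweight = pweight


def _extend(path: list[_Path], zero: float, one: float, feature: int) -> None:
    depth = len(path)
    path.append(_Path(feature, zero, one, 1.0 if depth == 0 else 0.0))
    for i in range(depth - 1, -1, -1):
        path[i + 1].pweight += one * path[i].pweight * (i + 1) / (depth + 1)
        path[i].pweight = zero * path[i].pweight * (depth - i) / (depth + 1)


def _unwind(path: list[_Path], index: int) -> None:
    depth = len(path) - 1
    one = path[index].one
    zero = path[index].zero
    carry = path[depth].pweight
    for i in range(depth - 1, -1, -1):
        if one != 0:
            tmp = path[i].pweight
            path[i].pweight = carry * (depth + 1) / ((i + 1) * one)
            carry = tmp - path[i].pweight * zero * (depth - i) / (depth + 1)
        else:
            path[i].pweight = path[i].pweight * (depth + 1) / (zero * (depth - i))
    for i in range(index, depth):
        path[i].feature = path[i + 1].feature
        path[i].zero = path[i + 1].zero
        path[i].one = path[i + 1].one
    path.pop()


def _unwound_sum(path: list[_Path], index: int) -> float:
    depth = len(path) - 1
    one = path[index].one
    zero = path[index].zero
    carry = path[depth].pweight
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one != 0:
            tmp = carry * (depth + 1) / ((i + 1) * one)
            total += tmp
            carry = path[i].pweight - tmp * zero * (depth - i) / (depth + 1)
        else:
            total += path[i].pweight / (zero * (depth - i) / (depth + 1))
    return total


def _shap_single_tree(tree, x: np.ndarray, phi: np.ndarray) -> None:
    """Accumulate Shapley values of one sklearn tree's P(class 1) output."""
    left, right = tree.children_left, tree.children_right
    feature, threshold = tree.feature, tree.threshold
    cover = tree.weighted_n_node_samples
    value = tree.value  # (nodes, 1, n_classes) class fractions
    probs = value[:, 0, :]
    probs = probs / probs.sum(axis=1, keepdims=True)
    out = probs[:, 1] if probs.shape[1] > 1 else probs[:, 0]

    def recurse(node: int, path: list[_Path], zero: float, one: float,
                pfeat: int) -> None:
        path = [_Path(p.feature, p.zero, p.one, p.pweight) for p in path]
        _extend(path, zero, one, pfeat)
        if left[node] < 0:  # leaf
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                el = path[i]
                phi[el.feature] += w * (el.one - el.zero) * out[node]
            return
        f = feature[node]
        hot, cold = (left[node], right[node]) if x[f] <= threshold[node] \
            else (right[node], left[node])
        hot_zero = cover[hot] / cover[node]
        cold_zero = cover[cold] / cover[node]
        incoming_one = 1.0
        # if this feature already appears on the path, unwind it first
        k = next((i for i in range(1, len(path)) if path[i].feature == f), None)
        if k is not None:
            incoming_one = path[k].one
            hot_zero *= path[k].zero
            cold_zero *= path[k].zero
            _unwind(path, k)
        recurse(hot, path, hot_zero, incoming_one, f)
        recurse(cold, path, cold_zero, 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


def _ensemble_trees(model) -> list:
    if isinstance(model, DecisionTreeClassifier):
        return [model.tree_]
    if isinstance(model, (RandomForestClassifier, ExtraTreesClassifier)):
        return [e.tree_ for e in model.estimators_]
    raise ConnectomlError(
        f"exact tree attribution supports decision trees and forests, "
        f"got {type(model).__name__}; use mode='sampling'"
    )


@dataclass
class Attribution:
    """Per-sample additive attributions toward P(label = 1)."""

    phi: np.ndarray          # (n_samples, n_features)
    base_value: float
    feature_names: list[str] | None = None

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.phi).mean(axis=0)

    def mean_abs_series(self) -> pd.Series:
        names = self.feature_names or [f"f{i}" for i in range(self.phi.shape[1])]
        return pd.Series(self.mean_abs, index=names)


def feature_attribution(model, X: np.ndarray, mode: str = "exact",
                        n_permutations: int = 64, seed: int = 0,
                        background: np.ndarray | None = None,
                        feature_names: list[str] | None = None) -> Attribution:
    """Shapley attributions of P(class 1) for each row of X.

    ``exact`` walks the ensemble's trees (depth <= 10 enforced, since cost
    grows with path length); ``sampling`` averages marginal contributions
    over random feature permutations against a background sample.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ConnectomlError("features must be finite")
    if mode == "exact":
        trees = _ensemble_trees(model)
        if max(t.max_depth for t in trees) > EXACT_DEPTH_LIMIT:
            raise ConnectomlError(
                f"tree depth exceeds {EXACT_DEPTH_LIMIT}; use mode='sampling'")
        phi = np.zeros_like(X)
        base = 0.0
        for t in trees:
            probs = t.value[0, 0, :]
            probs = probs / probs.sum()
            base += probs[1] if len(probs) > 1 else probs[0]
            for i in range(X.shape[0]):
                _shap_single_tree(t, X[i], phi[i])
        phi /= len(trees)
        base /= len(trees)
        return Attribution(phi=phi, base_value=float(base),
                           feature_names=feature_names)
    if mode == "sampling":
        return _sampling_attribution(model, X, n_permutations, seed,
                                     background, feature_names)
    raise ConnectomlError(f"unknown attribution mode {mode!r}")


def _predict_prob1(model, X: np.ndarray) -> np.ndarray:
    p = model.predict_proba(X)
    return p[:, 1] if p.shape[1] > 1 else p[:, 0]


def _sampling_attribution(model, X, n_permutations, seed, background,
                          feature_names) -> Attribution:
    rng = np.random.default_rng(seed)
    bg = X if background is None else np.asarray(background, dtype=float)
    n, d = X.shape
    phi = np.zeros((n, d))
    base = float(_predict_prob1(model, bg).mean())
    for i in range(n):
        for _ in range(n_permutations):
            perm = rng.permutation(d)
            z = bg[rng.integers(len(bg))].copy()
            prev = float(_predict_prob1(model, z[None, :])[0])
            for f in perm:
                z[f] = X[i, f]
                cur = float(_predict_prob1(model, z[None, :])[0])
                phi[i, f] += cur - prev
                prev = cur
    phi /= n_permutations
    return Attribution(phi=phi, base_value=base, feature_names=feature_names)


def importance_percentages(attributions: pd.Series | dict | np.ndarray) -> pd.Series:
    """Normalize nonnegative aggregated attributions to percent of total."""
    s = pd.Series(attributions, dtype=float)
    if (s < 0).any():
        raise ConnectomlError("aggregated attributions must be nonnegative")
    total = s.sum()
    if total == 0:
        raise ConnectomlError("all-zero attributions cannot be normalized")
    return 100.0 * s / total


def rank_explained_features(scores: pd.Series | dict) -> pd.DataFrame:
    """Descending ranked table of measure scores; ties lexicographic."""
    s = pd.Series(scores, dtype=float)
    df = s.rename("score").rename_axis("measure").reset_index()
    df = df.sort_values(["score", "measure"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df


# ---------------------------------------------------------------------------
# GNN mask explanations


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GnnExplanation:
    edge_mask: np.ndarray      # (N, N) symmetric, in [0, 1]; 0 off-edges
    feature_mask: np.ndarray   # (C,) in [0, 1]
    target_class: int
    losses: list[float]


def gnn_explain(model, params: dict, sample: GraphSample,
                lambda_size: float = 0.005, lambda_entropy: float = 1.0,
                steps: int = 100, lr: float = 0.05,
                seed: int = 0) -> GnnExplanation:
    """Learn edge and feature masks explaining the model's own prediction.

    Masks multiply the normalized adjacency (off-diagonal support only;
    self-loops stay) and the node-feature channels.  The model parameters
    are never updated.
    """
    A = sample.A_norm
    X = sample.X
    n, C = X.shape
    probs0, _ = model.forward(A, X, params)
    target = int(probs0.argmax())
    edge_sup = (A > 0) & ~np.eye(n, dtype=bool)
    iu, ju = np.nonzero(np.triu(edge_sup, k=1))
    rng = np.random.default_rng(seed)
    em = rng.normal(1.0, 0.1, size=len(iu))   # start near-open (sigmoid ~ 0.73)
    fm = rng.normal(1.0, 0.1, size=C)
    m_e = np.zeros_like(em)
    v_e = np.zeros_like(em)
    m_f = np.zeros_like(fm)
    v_f = np.zeros_like(fm)
    b1, b2, eps = 0.9, 0.999, 1e-8
    losses = []
    n_edges = max(len(iu), 1)
    for t in range(1, steps + 1):
        se = _sigmoid(em)
        sf = _sigmoid(fm)
        S = np.ones((n, n))
        S[iu, ju] = se
        S[ju, iu] = se
        Am = A * S
        Xm = X * sf[None, :]
        probs, cache = model.forward(Am, Xm, params)
        p = max(probs[target], 1e-12)
        ent_e = -(se * np.log(se + 1e-12) + (1 - se) * np.log(1 - se + 1e-12))
        ent_f = -(sf * np.log(sf + 1e-12) + (1 - sf) * np.log(1 - sf + 1e-12))
        loss = (-np.log(p)
                + lambda_size * (se.sum() / n_edges + sf.mean())
                + lambda_entropy * (ent_e.mean() if len(se) else 0.0)
                + lambda_entropy * ent_f.mean())
        losses.append(float(loss))
        if not np.isfinite(loss):
            raise ConnectomlError(f"mask optimization diverged at step {t}")
        dlogits = probs.copy()
        dlogits[target] -= 1.0
        _, dAm, dXm = model.backward(cache, params, dlogits)
        ds_e = se * (1 - se)
        ds_f = sf * (1 - sf)
        g_e = (dAm[iu, ju] * A[iu, ju] + dAm[ju, iu] * A[ju, iu]) * ds_e
        g_f = (dXm * X).sum(axis=0) * ds_f
        g_e += lambda_size * ds_e / n_edges
        g_f += lambda_size * ds_f / C
        g_e += lambda_entropy * ds_e * np.log((se + 1e-12) / (1 - se + 1e-12)) * (-1.0) / n_edges
        g_f += lambda_entropy * ds_f * np.log((sf + 1e-12) / (1 - sf + 1e-12)) * (-1.0) / C
        for g, mm, vv, x in ((g_e, m_e, v_e, em), (g_f, m_f, v_f, fm)):
            mm *= b1
            mm += (1 - b1) * g
            vv *= b2
            vv += (1 - b2) * g**2
            x -= lr * (mm / (1 - b1**t)) / (np.sqrt(vv / (1 - b2**t)) + eps)
    se = _sigmoid(em)
    edge_mask = np.zeros((n, n))
    edge_mask[iu, ju] = se
    edge_mask[ju, iu] = se
    return GnnExplanation(edge_mask=edge_mask, feature_mask=_sigmoid(fm),
                          target_class=target, losses=losses)


def gnn_explain_cohort(model, params: dict, samples: list[GraphSample],
                       labels: np.ndarray | None = None,
                       **kwargs) -> tuple[np.ndarray, list[GnnExplanation]]:
    """Average feature mask over correctly classified samples only.

    When labels are omitted every sample contributes.
    """
    explanations = []
    masks = []
    base_seed = kwargs.pop("seed", 0)
    for idx, s in enumerate(samples):
        probs, _ = model.forward(s.A_norm, s.X, params)
        if labels is not None and int(probs.argmax()) != int(labels[idx]):
            continue
        ex = gnn_explain(model, params, s, seed=base_seed + idx, **kwargs)
        explanations.append(ex)
        masks.append(ex.feature_mask)
    if not masks:
        raise ConnectomlError("no correctly classified samples to explain")
    return np.mean(masks, axis=0), explanations
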
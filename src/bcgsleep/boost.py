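"""Fast-ABC Boost: adaptive-base-class LogitBoost with restricted search.

Multi-class LogitBoost keeps a sum-to-zero score matrix F (samples x
classes) and class probabilities p = softmax(F).  At each iteration a base
class b is fixed and, for every other class k, a J-leaf regression tree is
fit to the second-order statistics

    g_i = (r_ib - p_ib) - (r_ik - p_ik)
    h_i = p_ib (1 - p_ib) + p_ik (1 - p_ik) + 2 p_ib p_ik

(r the one-hot true-class indicator) with Newton leaf values
-sum(g)/(sum(h)+eps) scaled by nu (K-1)/K; the base-class column absorbs
the negated sum so F stays sum-to-zero.

Classic adaptive-base-class boosting tries every class as base and keeps
the one with the lowest training loss.  The fast variant ranks classes by
per-true-class mean log-loss, searches only the s worst ("s-worst"
strategy), starts searching after w warm-up iterations (which use the
running worst class), and re-searches only once every g+1 iterations,
reusing the previous base in between.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeRegressor

EPS_LEAF = 1e-12


@dataclass
class FastAbcParams:
    n_iter: int = 645
    learning_rate: float = 0.4546
    s: int = 3
    gap: int = 19
    warmup: int = 34
    max_leaves: int = 20
    min_leaf: int = 5
    seed: int = 0
    early_stop_tol: float = 1e-10

    def validate(self, n_classes: int) -> None:
        if not 1 <= self.s <= n_classes:
            raise ValueError("s must satisfy 1 <= s <= K")
        if self.gap < 0 or self.warmup < 0:
            raise ValueError("gap and warm-up must be >= 0")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning rate must lie in (0, 1]")


@dataclass
class _Tree:
    """Plain-array regression tree (serializable)."""

    feature: list[int]
    threshold: list[float]
    left: list[int]
    right: list[int]
    value: list[float]

    def predict(self, X: np.ndarray) -> np.ndarray:
        feature = np.asarray(self.feature)
        threshold = np.asarray(self.threshold)
        left = np.asarray(self.left)
        right = np.asarray(self.right)
        value = np.asarray(self.value)
        node = np.zeros(len(X), dtype=int)
        while True:
            leaf = feature[node] < 0
            if leaf.all():
                break
            go_left = X[np.arange(len(X)), np.maximum(feature[node], 0)] <= threshold[node]
            nxt = np.where(go_left, left[node], right[node])
            node = np.where(leaf, node, nxt)
        return value[node]


def softmax_rows(F: np.ndarray) -> np.ndarray:
    z = F - F.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def multiclass_logloss(p: np.ndarray, y_idx: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(p[np.arange(len(y_idx)), y_idx], 1e-15, None))))


def derivatives(p: np.ndarray, r: np.ndarray, base: int, k: int):
    """Per-sample first/second derivatives of the loss in direction F_k
    with the sum-to-zero constraint absorbed by base class ``base``."""
    if k == base:
        raise ValueError("k must differ from the base class")
    g = (r[:, base] - p[:, base]) - (r[:, k] - p[:, k])
    h = p[:, base] * (1 - p[:, base]) + p[:, k] * (1 - p[:, k]) + 2 * p[:, base] * p[:, k]
    return g, h


def _fit_newton_tree(
    X: np.ndarray, g: np.ndarray, h: np.ndarray, params: FastAbcParams, rs: int
) -> _Tree:
    """Second-order-gain tree: split search on the Newton ratio -g/h with
    hessian sample weights (weighted-MSE gain equals the second-order gain
    up to constants); exact leaf values recomputed as -sum g/(sum h + eps)."""
    target = -g / np.maximum(h, 1e-12)
    reg = DecisionTreeRegressor(
        max_leaf_nodes=params.max_leaves,
        min_samples_leaf=params.min_leaf,
        random_state=rs,
    )
    reg.fit(X, target, sample_weight=h)
    t = reg.tree_
    leaf_ids = reg.apply(X)
    value = np.zeros(t.node_count)
    scale = params.learning_rate * 1.0
    for node in np.unique(leaf_ids):
        sel = leaf_ids == node
        value[node] = -g[sel].sum() / (h[sel].sum() + EPS_LEAF)
    return _Tree(
        feature=t.feature.tolist(),
        threshold=t.threshold.tolist(),
        left=t.children_left.tolist(),
        right=t.children_right.tolist(),
        value=(scale * value).tolist(),
    )


@dataclass
class BoostModel:
    classes: list
    params: FastAbcParams
    trees: list[dict] = field(default_factory=list)  # per iter: {class k: _Tree}
    base_trace: list[int] = field(default_factory=list)
    loss_trace: list[float] = field(default_factory=list)

    # ---------------------------------------------------------- prediction
    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        K = len(self.classes)
        F = np.zeros((len(X), K))
        nu_scale = (K - 1) / K
        for it, (trees_k, b) in enumerate(zip(self.trees, self.base_trace)):
            upd = np.zeros((len(X), K))
            for k, tree in trees_k.items():
                upd[:, int(k)] = nu_scale * tree.predict(X)
            upd[:, b] = -upd.sum(axis=1)
            F += upd
        return F

    def predict_proba(self, X) -> np.ndarray:
        return softmax_rows(self.decision_function(np.asarray(X, dtype=float)))

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        return np.asarray(self.classes)[p.argmax(axis=1)]

    # ------------------------------------------------------- serialization
    def save(self, path: str | Path) -> None:
        payload = {
            "classes": np.asarray(self.classes).tolist(),
            "params": asdict(self.params),
            "base_trace": self.base_trace,
            "loss_trace": self.loss_trace,
            "trees": [
                {str(k): asdict(t) for k, t in trees_k.items()}
                for trees_k in self.trees
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "BoostModel":
        payload = json.loads(Path(path).read_text())
        model = cls(
            classes=payload["classes"],
            params=FastAbcParams(**payload["params"]),
            base_trace=payload["base_trace"],
            loss_trace=payload["loss_trace"],
        )
        model.trees = [
            {int(k): _Tree(**t) for k, t in trees_k.items()}
            for trees_k in payload["trees"]
        ]
        return model


def _one_iteration(
    X: np.ndarray,
    r: np.ndarray,
    F: np.ndarray,
    p: np.ndarray,
    base: int,
    params: FastAbcParams,
    rs_base: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One boosting round with a fixed base class; returns (F', p', trees)."""
    K = r.shape[1]
    nu_scale = (K - 1) / K
    upd = np.zeros_like(F)
    trees: dict[int, _Tree] = {}
    for k in range(K):
        if k == base:
            continue
        g, h = derivatives(p, r, base, k)
        tree = _fit_newton_tree(X, g, h, params, rs=rs_base + k)
        trees[k] = tree
        upd[:, k] = nu_scale * tree.predict(X)
    upd[:, base] = -upd.sum(axis=1)
    F_new = F + upd
    return F_new, softmax_rows(F_new), trees


def _classwise_loss(p: np.ndarray, y_idx: np.ndarray, K: int) -> np.ndarray:
    """Per-true-class mean negative log-probability ("performance" ranking)."""
    ll = -np.log(np.clip(p[np.arange(len(y_idx)), y_idx], 1e-15, None))
    out = np.zeros(K)
    for k in range(K):
        sel = y_idx == k
        out[k] = ll[sel].mean() if sel.any() else 0.0
    return out


def select_base(
    X: np.ndarray,
    r: np.ndarray,
    y_idx: np.ndarray,
    F: np.ndarray,
    p: np.ndarray,
    s: int,
    params: FastAbcParams,
    rs_base: int,
) -> int:
    """Best base among the s worst-performing classes (by tentative round)."""
    K = r.shape[1]
    if not 1 <= s <= K:
        raise ValueError("1 <= s <= K required")
    ranking = np.argsort(-_classwise_loss(p, y_idx, K), kind="stable")
    candidates = ranking[:s]
    if s == 1:
        return int(candidates[0])
    best_b, best_loss = None, np.inf
    for b in candidates:
        _, p_try, _ = _one_iteration(X, r, F, p, int(b), params, rs_base)
        loss = multiclass_logloss(p_try, y_idx)
        if loss < best_loss - 1e-15:
            best_loss, best_b = loss, int(b)
    return best_b


def fit(X, y, params: FastAbcParams | None = None) -> BoostModel:
    """Train a Fast-ABC Boost ensemble.

    Iterations 1..w (warm-up) use the running worst class without search;
    afterwards the s-worst search runs at iterations w+1, w+1+(g+1), ...,
    and the last chosen base is reused in between.  Training stops early
    when the loss improvement falls below ``early_stop_tol``.
    """
    params = params or FastAbcParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    K = len(classes)
    if K < 2:
        raise ValueError("need at least 2 classes")
    params.validate(K)
    y_idx = np.searchsorted(classes, y)
    r = np.eye(K)[y_idx]
    n = len(y)
    F = np.zeros((n, K))
    p = softmax_rows(F)
    model = BoostModel(classes=list(classes), params=params)
    prev_loss = multiclass_logloss(p, y_idx)
    base = None
    for it in range(params.n_iter):
        rs_base = (params.seed * 1_000_003 + it * 131) % (2**31 - 1)
        if it < params.warmup:
            base = int(np.argsort(-_classwise_loss(p, y_idx, K), kind="stable")[0])
        elif (it - params.warmup) % (params.gap + 1) == 0 or base is None:
            base = select_base(X, r, y_idx, F, p, params.s, params, rs_base)
        F, p, trees = _one_iteration(X, r, F, p, base, params, rs_base)
        loss = multiclass_logloss(p, y_idx)
        model.trees.append(trees)
        model.base_trace.append(base)
        model.loss_trace.append(loss)
        if prev_loss - loss < params.early_stop_tol:
            break
        prev_loss = loss
    return model
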
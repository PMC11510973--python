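"""Whole-graph classifier: graph convolutions, TopK pooling, CV evaluation.

The model follows a two-branch fusion design.  For a fused 20-node
sample (14 EEG + 6 fNIRS nodes) the pass is

    branch convs (13 -> 30, one weight per modality, block adjacency)
    fusion conv  (30 -> 60, bimodal adjacency incl. bridges)
    TopK pool    (20 -> 10 nodes)
    conv         (60 -> 90, pooled-subgraph adjacency)
    TopK pool    (10 -> 1 node)
    linear       (90 -> 2 logits)

Unimodal baselines reuse the same stack with a single branch and pool
sizes n -> ceil(n/2) -> 1 (14 -> 7 -> 1 for EEG, 6 -> 3 -> 1 for fNIRS).

Convolutions are symmetric-normalized with self-loops,
X' = ReLU(D^-1/2 (A + I) D^-1/2 X W); TopK pooling scores nodes with a
learnable projection, keeps the k best (ties to the lower index, kept
nodes stay in original order) and gates their features by tanh(score).
Training is Adam on softmax cross-entropy with L2 regularization; the
full backward pass is implemented analytically, so gradients can be
verified against finite differences.  Evaluation is stratified k-fold
cross-validation reporting accuracy, binary F1 (positive class = motion
sickness), recall and precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold

from .graphs import GraphSample, N_FEATURES

#: feature widths after the branch, fusion and post-pool convolutions
WIDTHS: tuple[int, int, int] = (30, 60, 90)

N_CLASSES = 2

WEIGHT_KEYS = ("W1", "W2", "W3", "W4", "p1", "p2", "Wout")


class ModelError(ValueError):
    """Raised on invalid model configuration or data."""


@dataclass(frozen=True)
class GCNConfig:
    """Training hyperparameters (exposed for grid search)."""

    lr: float = 1e-3
    weight_decay: float = 5e-4
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0


@dataclass(frozen=True)
class ModelReport:
    """Cross-validated performance: per-fold metrics and their summary."""

    accuracy: tuple[float, ...]
    f1: tuple[float, ...]
    recall: tuple[float, ...]
    precision: tuple[float, ...]
    config: GCNConfig
    folds: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recall))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precision))

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": self.mean_accuracy,
            "f1": self.mean_f1,
            "recall": self.mean_recall,
            "precision": self.mean_precision,
            "accuracy_sd": float(np.std(self.accuracy)),
            "f1_sd": float(np.std(self.f1)),
        }


# ---------------------------------------------------------------------------
# primitives

def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^-1/2 (A + I) D^-1/2."""
    a = np.asarray(a, dtype=float)
    at = a + np.eye(a.shape[-1])
    inv_sqrt = 1.0 / np.sqrt(at.sum(axis=-1))
    return at * inv_sqrt[..., :, None] * inv_sqrt[..., None, :]


def graph_conv(x: np.ndarray, a: np.ndarray, w: np.ndarray) -> np.ndarray:
    """One convolution step: ReLU(D^-1/2 (A+I) D^-1/2 X W)."""
    return np.maximum(normalize_adjacency(a) @ x @ w, 0.0)


def topk_pool(x: np.ndarray, a: np.ndarray, k: int, p: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """TopK pooling: keep the k highest-scoring nodes, gate by tanh(score).

    Scores are s = X p / ||p||; ties break to the lower node index and
    kept nodes retain their original order.  Returns the gated features,
    the induced sub-adjacency and the kept indices.
    """
    if k > x.shape[0]:
        raise ModelError(f"k={k} exceeds node count {x.shape[0]}")
    s = x @ (p / np.linalg.norm(p))
    idx = np.sort(np.argsort(-s, kind="stable")[:k])
    gated = x[idx] * np.tanh(s[idx])[:, None]
    return gated, a[np.ix_(idx, idx)], idx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# batched data

@dataclass
class Batch:
    """Dense arrays for a set of same-shape graph samples."""

    x: np.ndarray        # (B, n, d0)
    a: np.ndarray        # (B, n, n) raw binary adjacency
    ahat_branch: np.ndarray  # (B, n, n) block-normalized (branch layers)
    ahat_full: np.ndarray    # (B, n, n) normalized full adjacency
    y: np.ndarray        # (B,)

    def subset(self, idx: np.ndarray) -> "Batch":
        return Batch(self.x[idx], self.a[idx], self.ahat_branch[idx],
                     self.ahat_full[idx], self.y[idx])

    def __len__(self) -> int:
        return len(self.y)


def _infer_split(sample: GraphSample) -> int | None:
    """EEG-block size of a fused sample (None for unimodal samples)."""
    if not sample.modality.startswith("fused"):
        return None
    for i, name in enumerate(sample.node_names):
        if name.startswith("Ch"):
            return i
    raise ModelError("fused sample has no fNIRS block")


def prepare_batch(samples: Sequence[GraphSample],
                  split: int | None) -> Batch:
    x = np.stack([s.node_features for s in samples]).astype(float)
    a = np.stack([s.adjacency for s in samples]).astype(float)
    ahat_full = normalize_adjacency(a)
    if split is None:
        ahat_branch = ahat_full
    else:
        blocks = np.zeros_like(a)
        blocks[:, :split, :split] = a[:, :split, :split]
        blocks[:, split:, split:] = a[:, split:, split:]
        ahat_branch = normalize_adjacency(blocks)
    y = np.array([s.y for s in samples], dtype=int)
    return Batch(x, a, ahat_branch, ahat_full, y)


def _gather_sub_adj(a: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Induced sub-adjacency per batch element: a[b][idx[b]][:, idx[b]]."""
    rows = np.take_along_axis(a, idx[:, :, None], axis=1)
    return np.take_along_axis(rows, idx[:, None, :], axis=2)


# ---------------------------------------------------------------------------
# the classifier

class GCNClassifier:
    """Fused or unimodal whole-graph classifier with analytic gradients."""

    def __init__(self, n_nodes: int, split: int | None = None,
                 pool_sizes: tuple[int, int] | None = None,
                 d0: int = N_FEATURES, seed: int = 0):
        if pool_sizes is None:
            pool_sizes = (10, 1) if split is not None \
                else (math.ceil(n_nodes / 2), 1)
        k1, k2 = pool_sizes
        if not (n_nodes >= k1 > k2 >= 1):
            raise ModelError(f"pool sizes {pool_sizes} must strictly decrease "
                             f"below n_nodes={n_nodes}")
        if k2 != 1:
            raise ModelError("final pooling must reduce to a single node")
        self.n_nodes = n_nodes
        self.split = split
        self.k1 = k1
        self.d0 = d0
        self.seed = seed
        self._scalers: list[tuple[np.ndarray, np.ndarray]] = []
        self.params = self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        # He (fan-in) init for the ReLU convolution stack: Glorot-scaled
        # weights can leave the whole network dead at initialization
        # (loss pinned at ln 2), which He scaling avoids
        def he(shape):
            return rng.standard_normal(shape) * math.sqrt(2.0 / shape[0])

        def glorot(shape):
            lim = math.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        w1, w2, w3 = WIDTHS
        params = {
            "W1": he((self.d0, w1)),
            "W3": he((w1, w2)),
            "W4": he((w2, w3)),
            "p1": rng.standard_normal(w2) / math.sqrt(w2),
            "p2": rng.standard_normal(w3) / math.sqrt(w3),
            "Wout": glorot((w3, N_CLASSES)),
            "b": np.zeros(N_CLASSES),
        }
        if self.split is not None:
            params["W2"] = he((self.d0, w1))
        return params

    # -- forward -----------------------------------------------------------

    def forward(self, batch: Batch, params: Mapping[str, np.ndarray] | None = None,
                trace: list | None = None) -> tuple[np.ndarray, dict]:
        """Batched forward pass; returns logits (B, 2) and the cache.

        ``trace``, if given, collects (n_nodes, width) after each stage.
        """
        p = self.params if params is None else params
        split = self.split
        cache: dict = {}

        m1 = batch.ahat_branch @ batch.x
        z1 = np.empty((*batch.x.shape[:2], WIDTHS[0]))
        if split is None:
            z1 = m1 @ p["W1"]
        else:
            z1[:, :split] = m1[:, :split] @ p["W1"]
            z1[:, split:] = m1[:, split:] @ p["W2"]
        h1 = np.maximum(z1, 0.0)
        if trace is not None:
            trace.append((h1.shape[1], h1.shape[2]))

        m2 = batch.ahat_full @ h1
        z2 = m2 @ p["W3"]
        h2 = np.maximum(z2, 0.0)
        if trace is not None:
            trace.append((h2.shape[1], h2.shape[2]))

        # pool 1: n -> k1
        p1h = p["p1"] / np.linalg.norm(p["p1"])
        s1 = h2 @ p1h                                   # (B, n)
        idx1 = np.sort(np.argsort(-s1, axis=1, kind="stable")[:, :self.k1],
                       axis=1)
        h2_sel = np.take_along_axis(h2, idx1[:, :, None], axis=1)
        t1 = np.tanh(np.take_along_axis(s1, idx1, axis=1))
        xp = h2_sel * t1[:, :, None]                    # (B, k1, 60)
        ahat3 = normalize_adjacency(_gather_sub_adj(batch.a, idx1))
        if trace is not None:
            trace.append((xp.shape[1], xp.shape[2]))

        m3 = ahat3 @ xp
        z3 = m3 @ p["W4"]
        h3 = np.maximum(z3, 0.0)                        # (B, k1, 90)
        if trace is not None:
            trace.append((h3.shape[1], h3.shape[2]))

        # pool 2: k1 -> 1
        p2h = p["p2"] / np.linalg.norm(p["p2"])
        s2 = h3 @ p2h                                   # (B, k1)
        idx2 = np.argsort(-s2, axis=1, kind="stable")[:, 0]
        h3_sel = np.take_along_axis(h3, idx2[:, None, None], axis=1)[:, 0]
        t2 = np.tanh(np.take_along_axis(s2, idx2[:, None], axis=1)[:, 0])
        g = h3_sel * t2[:, None]                        # (B, 90)
        if trace is not None:
            trace.append((1, g.shape[1]))

        logits = g @ p["Wout"] + p["b"]
        if trace is not None:
            trace.append((1, logits.shape[1]))

        cache.update(m1=m1, z1=z1, h1=h1, m2=m2, z2=z2, h2=h2,
                     s1=s1, idx1=idx1, h2_sel=h2_sel, t1=t1, xp=xp,
                     ahat3=ahat3, m3=m3, z3=z3, h3=h3,
                     idx2=idx2, h3_sel=h3_sel, t2=t2, g=g,
                     p1h=p1h, p2h=p2h)
        return logits, cache

    # -- loss and analytic gradients --------------------------------------

    def loss_and_grads(self, batch: Batch, weight_decay: float = 0.0,
                       params: Mapping[str, np.ndarray] | None = None
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy + L2 penalty, with gradients for every parameter."""
        p = self.params if params is None else params
        logits, c = self.forward(batch, params=p)
        b_size = len(batch)
        probs = _softmax(logits)
        onehot = np.eye(N_CLASSES)[batch.y]
        loss = float(-np.mean(np.log(probs[np.arange(b_size), batch.y] + 1e-300)))

        dlogits = (probs - onehot) / b_size             # (B, 2)
        grads: dict[str, np.ndarray] = {}
        grads["Wout"] = c["g"].T @ dlogits
        grads["b"] = dlogits.sum(axis=0)
        dg = dlogits @ p["Wout"].T                      # (B, 90)

        # pool 2 backward
        ds2 = (dg * c["h3_sel"]).sum(axis=1) * (1.0 - c["t2"] ** 2)  # (B,)
        dh3_sel = dg * c["t2"][:, None] + ds2[:, None] * c["p2h"][None, :]
        dh3 = np.zeros_like(c["h3"])
        np.put_along_axis(dh3, c["idx2"][:, None, None],
                          dh3_sel[:, None, :], axis=1)
        dp2h = ds2 @ c["h3_sel"]                        # (90,)
        p2 = p["p2"]
        p2n = np.linalg.norm(p2)
        grads["p2"] = (dp2h - c["p2h"] * (c["p2h"] @ dp2h)) / p2n

        # conv 4 backward
        dz3 = dh3 * (c["z3"] > 0)
        grads["W4"] = np.einsum("bkf,bkg->fg", c["m3"], dz3)
        dm3 = dz3 @ p["W4"].T
        dxp = c["ahat3"] @ dm3                          # ahat3 symmetric

        # pool 1 backward
        ds1 = (dxp * c["h2_sel"]).sum(axis=2) * (1.0 - c["t1"] ** 2)  # (B,k1)
        dh2_sel = dxp * c["t1"][:, :, None] \
            + ds1[:, :, None] * c["p1h"][None, None, :]
        dh2 = np.zeros_like(c["h2"])
        np.put_along_axis(dh2, c["idx1"][:, :, None], dh2_sel, axis=1)
        dp1h = np.einsum("bk,bkf->f", ds1, c["h2_sel"])
        p1 = p["p1"]
        p1n = np.linalg.norm(p1)
        grads["p1"] = (dp1h - c["p1h"] * (c["p1h"] @ dp1h)) / p1n

        # conv 3 (fusion) backward
        dz2 = dh2 * (c["z2"] > 0)
        grads["W3"] = np.einsum("bnf,bng->fg", c["m2"], dz2)
        dm2 = dz2 @ p["W3"].T
        dh1 = batch.ahat_full @ dm2                     # symmetric

        # branch convs backward
        dz1 = dh1 * (c["z1"] > 0)
        if self.split is None:
            grads["W1"] = np.einsum("bnf,bng->fg", c["m1"], dz1)
        else:
            s = self.split
            grads["W1"] = np.einsum("bnf,bng->fg", c["m1"][:, :s], dz1[:, :s])
            grads["W2"] = np.einsum("bnf,bng->fg", c["m1"][:, s:], dz1[:, s:])

        if weight_decay:
            for key in WEIGHT_KEYS:
                if key in p:
                    loss += 0.5 * weight_decay * float(np.sum(p[key] ** 2))
                    grads[key] = grads[key] + weight_decay * p[key]
        return loss, grads

    # -- training ----------------------------------------------------------

    def _node_blocks(self) -> list[slice]:
        if self.split is None:
            return [slice(None)]
        return [slice(0, self.split), slice(self.split, None)]

    def _standardize(self, x: np.ndarray, fit: bool) -> np.ndarray:
        """Z-score each feature across the training samples.

        Fused graphs are standardized per modality block: EEG and fNIRS
        node features live on different physical scales, and a joint
        scaler would let the larger-amplitude modality dominate.
        """
        blocks = self._node_blocks()
        if fit:
            self._scalers = []
            for sl in blocks:
                flat = x[:, sl, :].reshape(-1, x.shape[-1])
                mean = flat.mean(axis=0)
                sd = flat.std(axis=0)
                sd[sd == 0] = 1.0
                self._scalers.append((mean, sd))
        if not getattr(self, "_scalers", None):
            return x
        out = x.copy()
        for sl, (mean, sd) in zip(blocks, self._scalers):
            out[:, sl, :] = (x[:, sl, :] - mean) / sd
        return out

    def fit(self, samples: Sequence[GraphSample], cfg: GCNConfig
            ) -> list[float]:
        """Train on the given samples; returns the per-epoch mean loss history.

        Features are z-scored per feature across the training samples
        (the scaler is stored and reapplied at prediction time).
        """
        labels = {s.y for s in samples}
        if labels != {0, 1}:
            raise ModelError("training needs samples from both classes")
        batch = prepare_batch(samples, self.split)
        batch.x = self._standardize(batch.x, fit=True)
        rng = np.random.default_rng(cfg.seed)
        opt = Adam(self.params, lr=cfg.lr)
        history = []
        n = len(batch)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, grads = self.loss_and_grads(batch.subset(idx),
                                                  weight_decay=cfg.weight_decay)
                opt.step(grads)
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history

    def predict_proba(self, samples: Sequence[GraphSample]) -> np.ndarray:
        batch = prepare_batch(samples, self.split)
        batch.x = self._standardize(batch.x, fit=False)
        logits, _ = self.forward(batch)
        return _softmax(logits)

    def predict(self, samples: Sequence[GraphSample]) -> np.ndarray:
        return self.predict_proba(samples).argmax(axis=1)


class Adam:
    """Adam optimizer over a parameter dict (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# model construction and evaluation

def make_model(samples: Sequence[GraphSample], seed: int = 0) -> GCNClassifier:
    """Build a classifier matching the samples' shape (fused or unimodal)."""
    if not samples:
        raise ModelError("empty dataset")
    n = samples[0].n_nodes
    split = _infer_split(samples[0])
    if any(s.n_nodes != n or _infer_split(s) != split for s in samples):
        raise ModelError("all samples must share node count and modality kind")
    return GCNClassifier(n_nodes=n, split=split, seed=seed,
                         d0=samples[0].node_features.shape[1])


def train(samples: Sequence[GraphSample], cfg: GCNConfig
          ) -> tuple[GCNClassifier, list[float]]:
    """Train a fresh model on the full sample list; returns (model, history)."""
    model = make_model(samples, seed=cfg.seed)
    history = model.fit(samples, cfg)
    return model, history


def evaluate_cv(samples: Sequence[GraphSample], cfg: GCNConfig,
                folds: int = 10) -> ModelReport:
    """Stratified k-fold cross-validation of the classifier."""
    y = np.array([s.y for s in samples])
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ModelError(
            f"each class needs >= {folds} samples (have {counts.tolist()})")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    accs, f1s, recs, precs = [], [], [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = make_model([samples[i] for i in tr],
                           seed=cfg.seed * 1000 + fold)
        model.fit([samples[i] for i in tr],
                  replace(cfg, seed=cfg.seed * 1000 + fold))
        pred = model.predict([samples[i] for i in te])
        truth = y[te]
        accs.append(accuracy_score(truth, pred))
        f1s.append(f1_score(truth, pred, pos_label=1, zero_division=0))
        recs.append(recall_score(truth, pred, pos_label=1, zero_division=0))
        precs.append(precision_score(truth, pred, pos_label=1, zero_division=0))
    return ModelReport(tuple(accs), tuple(f1s), tuple(recs), tuple(precs),
                       cfg, folds)


def grid_search(samples: Sequence[GraphSample],
                grid: Mapping[str, Sequence] | Sequence[GCNConfig],
                base: GCNConfig = GCNConfig(), folds: int = 10
                ) -> tuple[GCNConfig, list[tuple[GCNConfig, ModelReport]]]:
    """Exhaustive grid search by cross-validated mean F1.

    ``grid`` is either a mapping of config-field name to candidate values
    (expanded as a product) or an explicit list of configs.  Ties break
    by higher mean accuracy, then smaller weight decay.  Returns the best
    config and the full (config, report) table.
    """
    if isinstance(grid, Mapping):
        keys = list(grid)
        configs = [replace(base, **dict(zip(keys, combo)))
                   for combo in itertools.product(*(grid[k] for k in keys))]
    else:
        configs = list(grid)
    if not configs:
        raise ModelError("empty hyperparameter grid")
    table = [(cfg, evaluate_cv(samples, cfg, folds=folds)) for cfg in configs]
    best_cfg, _ = max(
        table, key=lambda t: (t[1].mean_f1, t[1].mean_accuracy,
                              -t[0].weight_decay))
    return best_cfg, table
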
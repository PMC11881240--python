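"""Two-layer SAGE-aggregation GCN with an MLP edge regressor, in numpy.

The network embeds the three node types of the heterogeneous graph into a
shared hidden space and updates each node by concatenating its own vector
with the mean of its neighbors' vectors, per relation, under a learned linear
map and ReLU:

    h_v^(l+1) = ReLU( sum_r  W_r^(l) . CONCAT(h_v^(l), mean_{u in N_r(v)} h_u^(l)) )

with one weight pair per (relation, layer) and outputs summed over the
relations entering each node type. A pair of herbs is scored by concatenating
their final-layer embeddings and passing them through a one-hidden-layer MLP
whose output goes through softplus, so predicted strengths are nonnegative
and the downstream log2(y+1) transform is always defined. Because
concatenation is order-sensitive while compatibility is symmetric, the
reported score for an unordered pair is the average over both orders.

Training minimizes mean squared error against the corpus compatibility
scores, augmented each epoch with uniformly re-sampled zero-label negative
pairs (herb pairs that never co-occur), using Adam. Gradients are computed by
reverse-mode differentiation written out explicitly; the model is small
enough that full-batch numpy updates are fast on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

from .corpus import PairLabel
from .errors import DivergenceError, HerbnetError
from .graph import HeteroGraph

# (name, destination type, source type): every relation is one direction of
# message passing; all three biological relations are symmetrized.
RELATIONS = (
    ("hh", "herb", "herb"),
    ("mh", "herb", "molecule"),
    ("hm", "molecule", "herb"),
    ("tm", "molecule", "target"),
    ("mt", "target", "molecule"),
)

TYPES = ("herb", "molecule", "target")

#: Sentinel for an undefined coefficient of determination (diverged fit or
#: zero-variance held-out labels).
R2_UNDEFINED = None


@dataclass
class ModelConfig:
    """Hyperparameters for the edge-regression GNN.

    hidden_channels is the shared embedding/hidden width; the grid-search
    axes are hidden_channels {64, 128, 256, 512} and learning_rate
    {1e-4, 1e-3, 1e-2}. Training runs a fixed 60 epochs by default (the
    convergence horizon used for the reference fit). negative_pair_ratio is
    the number of zero-label pairs sampled per labeled pair each epoch.
    """

    hidden_channels: int = 64
    learning_rate: float = 1e-3
    n_layers: int = 2
    epochs: int = 60
    seed: int = 0
    negative_pair_ratio: float = 1.0
    mlp_hidden: int | None = None

    def __post_init__(self):
        if self.hidden_channels <= 0 or self.epochs <= 0 or self.n_layers <= 0:
            raise ValueError("hidden_channels, epochs and n_layers must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.negative_pair_ratio < 0:
            raise ValueError("negative_pair_ratio must be nonnegative")
        if self.mlp_hidden is None:
            self.mlp_hidden = self.hidden_channels


@dataclass
class TrainedModel:
    """Opaque parameter bundle with a deterministic pair-scoring contract."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    herb_ids: list[str]
    training_log: list[float] = field(default_factory=list)
    final_train_r2: float | None = None

    def predict_pairs(self, g: HeteroGraph, pairs: np.ndarray) -> np.ndarray:
        """Symmetrized scores for an array of (i, j) herb-index pairs."""
        h = node_embeddings(self.params, g, self.config.n_layers)["herb"]
        return _score_pairs_symmetric(self.params, h, np.asarray(pairs))


# ---------------------------------------------------------------------------
# Primitive ops
# ---------------------------------------------------------------------------


def sage_layer(node_feats: np.ndarray, neighbor_sets, weights: np.ndarray,
               bias: np.ndarray | None = None) -> np.ndarray:
    """One homogeneous SAGE update: ReLU(W . concat(h_v, mean of neighbors)).

    ``neighbor_sets`` is either a row-normalized sparse/dense matrix or a
    sequence of per-node neighbor index iterables. A node with no neighbors
    aggregates the zero vector. ``weights`` has shape (d_out, 2 * d_in).
    """
    x = np.asarray(node_feats, dtype=float)
    n, d = x.shape
    if weights.shape[1] != 2 * d:
        raise ValueError(
            f"weights expect input dim {weights.shape[1] // 2}, features have {d}"
        )
    if sp.issparse(neighbor_sets) or isinstance(neighbor_sets, np.ndarray):
        agg = np.asarray(neighbor_sets @ x)
    else:
        agg = np.zeros_like(x)
        for v, nbrs in enumerate(neighbor_sets):
            nbrs = list(nbrs)
            if nbrs:
                agg[v] = x[nbrs].mean(axis=0)
    z = np.concatenate([x, agg], axis=1) @ weights.T
    if bias is not None:
        z = z + bias
    return np.maximum(z, 0.0)


def mse_loss(y, y_hat) -> float:
    """Mean squared error (1/M) sum (y - y_hat)^2; errors on empty input."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("mse_loss requires at least one observation")
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.mean((y - y_hat) ** 2))


def r_squared(y, y_hat):
    """Coefficient of determination 1 - SS_res/SS_tot.

    Returns :data:`R2_UNDEFINED` when the observations have zero variance
    (SS_tot = 0) or either vector is non-finite.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("r_squared requires at least two observations")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(y_hat))):
        return R2_UNDEFINED
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return R2_UNDEFINED
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def _softplus(s: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, s)


# ---------------------------------------------------------------------------
# Parameter handling and forward pass
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_params(g: HeteroGraph, cfg: ModelConfig,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    d = cfg.hidden_channels
    nh, nm, nt = len(g.herb_ids), len(g.mol_ids), len(g.target_ids)
    p: dict[str, np.ndarray] = {
        "emb_herb": rng.normal(0.0, 0.1, (nh, d)),
        "emb_molecule": rng.normal(0.0, 0.1, (nm, d)),
        "emb_target": rng.normal(0.0, 0.1, (nt, d)),
        "proj_fp": _glorot(rng, (d, g.fingerprints.shape[1])),
        "proj_term": _glorot(rng, (d, max(g.term_matrix.shape[1], 1))),
    }
    for l in range(cfg.n_layers):
        for r, _, _ in RELATIONS:
            p[f"W_self_{l}_{r}"] = _glorot(rng, (d, d))
            p[f"W_nbr_{l}_{r}"] = _glorot(rng, (d, d))
        for t in TYPES:
            p[f"b_{l}_{t}"] = np.zeros(d)
    mh = cfg.mlp_hidden
    p["mlp_W1"] = _glorot(rng, (mh, 2 * d))
    p["mlp_b1"] = np.zeros(mh)
    p["mlp_W2"] = _glorot(rng, (1, mh))
    p["mlp_b2"] = np.zeros(1)
    return p


def _base_features(p: dict[str, np.ndarray], g: HeteroGraph) -> dict[str, np.ndarray]:
    # Herbs have no intrinsic features; molecule/target intrinsic features are
    # linearly projected to the hidden width and added to learned embeddings.
    x = {"herb": p["emb_herb"],
         "molecule": p["emb_molecule"] + g.fingerprints @ p["proj_fp"].T}
    tm = g.term_matrix
    if tm.shape[1] == 0:
        x["target"] = p["emb_target"]
    else:
        x["target"] = p["emb_target"] + tm @ p["proj_term"].T
    return x


def _forward_layers(p, g: HeteroGraph, n_layers: int, adjs=None):
    """Run the GCN stack; returns final per-type embeddings and a tape."""
    if adjs is None:
        adjs = {r: g.adjacency(r) for r, _, _ in RELATIONS}
    h = _base_features(p, g)
    tape = []
    for l in range(n_layers):
        aggs = {r: np.asarray(adjs[r] @ h[src]) for r, _, src in RELATIONS}
        z = {t: np.broadcast_to(p[f"b_{l}_{t}"], h[t].shape).copy() for t in TYPES}
        for r, dst, _src in RELATIONS:
            z[dst] += h[dst] @ p[f"W_self_{l}_{r}"].T + aggs[r] @ p[f"W_nbr_{l}_{r}"].T
        h_new = {t: np.maximum(z[t], 0.0) for t in TYPES}
        tape.append({"h_in": h, "aggs": aggs, "z": z})
        h = h_new
    return h, tape, adjs


def node_embeddings(p, g: HeteroGraph, n_layers: int) -> dict[str, np.ndarray]:
    """Final-layer embeddings for every node, by type."""
    h, _, _ = _forward_layers(p, g, n_layers)
    return h


def _mlp(p, u: np.ndarray):
    a1 = np.maximum(u @ p["mlp_W1"].T + p["mlp_b1"], 0.0)
    s = (a1 @ p["mlp_W2"].T + p["mlp_b2"]).ravel()
    return _softplus(s), a1, s


def _score_pairs_symmetric(p, h_herb: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    i, j = pairs[:, 0], pairs[:, 1]
    u_ij = np.concatenate([h_herb[i], h_herb[j]], axis=1)
    u_ji = np.concatenate([h_herb[j], h_herb[i]], axis=1)
    y_ij, _, _ = _mlp(p, u_ij)
    y_ji, _, _ = _mlp(p, u_ji)
    return 0.5 * (y_ij + y_ji)


def forward(model: TrainedModel, g: HeteroGraph, pair: tuple[str, str]) -> float:
    """Symmetrized predicted strength for one unordered herb pair (>= 0)."""
    i, j = g.herb_index(pair[0]), g.herb_index(pair[1])
    return float(model.predict_pairs(g, np.array([[i, j]]))[0])


# ---------------------------------------------------------------------------
# Backward pass
# ---------------------------------------------------------------------------


def _n_layers_of(p) -> int:
    layers = {int(k.split("_")[2]) for k in p if k.startswith("W_self_")}
    return max(layers) + 1


def loss_and_grads(p, g: HeteroGraph, pairs: np.ndarray, y: np.ndarray,
                   adjs=None, n_layers: int | None = None):
    """Compute MSE loss over symmetrized pair predictions and its gradient
    with respect to every parameter (reverse-mode, full batch)."""
    if n_layers is None:
        n_layers = _n_layers_of(p)
    h, tape, adjs = _forward_layers(p, g, n_layers, adjs)
    hh = h["herb"]
    i, j = pairs[:, 0], pairs[:, 1]
    m = len(y)

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    d_hh = np.zeros_like(hh)
    y_acc = np.zeros(m)

    # forward both orders, keep per-order caches
    caches = []
    for a, b in ((i, j), (j, i)):
        u = np.concatenate([hh[a], hh[b]], axis=1)
        y_o, a1, s = _mlp(p, u)
        caches.append((a, b, u, a1, s, y_o))
        y_acc += 0.5 * y_o
    loss = float(np.mean((y - y_acc) ** 2))

    d_yhat = 2.0 * (y_acc - y) / m
    d = hh.shape[1]
    for a, b, u, a1, s, _y_o in caches:
        d_s = (0.5 * d_yhat) * expit(s)          # softplus' = sigmoid
        d_a1 = np.outer(d_s, p["mlp_W2"].ravel()) * (a1 > 0)
        grads["mlp_W2"] += (d_s @ a1).reshape(1, -1)
        grads["mlp_b2"] += np.array([d_s.sum()])
        grads["mlp_W1"] += d_a1.T @ u
        grads["mlp_b1"] += d_a1.sum(axis=0)
        d_u = d_a1 @ p["mlp_W1"]
        np.add.at(d_hh, a, d_u[:, :d])
        np.add.at(d_hh, b, d_u[:, d:])

    d_h = {"herb": d_hh,
           "molecule": np.zeros_like(h["molecule"]),
           "target": np.zeros_like(h["target"])}
    for l in reversed(range(n_layers)):
        rec = tape[l]
        d_z = {t: d_h[t] * (rec["z"][t] > 0) for t in TYPES}
        d_prev = {t: np.zeros_like(rec["h_in"][t]) for t in TYPES}
        for t in TYPES:
            grads[f"b_{l}_{t}"] += d_z[t].sum(axis=0)
        for r, dst, src in RELATIONS:
            grads[f"W_self_{l}_{r}"] += d_z[dst].T @ rec["h_in"][dst]
            grads[f"W_nbr_{l}_{r}"] += d_z[dst].T @ rec["aggs"][r]
            d_prev[dst] += d_z[dst] @ p[f"W_self_{l}_{r}"]
            d_prev[src] += np.asarray(adjs[r].T @ (d_z[dst] @ p[f"W_nbr_{l}_{r}"]))
        d_h = d_prev

    grads["emb_herb"] += d_h["herb"]
    grads["emb_molecule"] += d_h["molecule"]
    grads["emb_target"] += d_h["target"]
    grads["proj_fp"] += d_h["molecule"].T @ g.fingerprints
    if g.term_matrix.shape[1] > 0:
        grads["proj_term"] += d_h["target"].T @ g.term_matrix
    return loss, grads, y_acc


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k in params:
            gk = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _negative_candidates(g: HeteroGraph, labeled: set[tuple[int, int]]) -> np.ndarray:
    nh = len(g.herb_ids)
    cands = [(a, b) for a, b in combinations(range(nh), 2) if (a, b) not in labeled]
    return np.array(cands, dtype=np.int64).reshape(-1, 2)


def _pairs_to_indices(g: HeteroGraph, labels: list[PairLabel]) -> tuple[np.ndarray, np.ndarray]:
    pairs = np.array(
        [sorted((g.herb_index(l.pair[0]), g.herb_index(l.pair[1]))) for l in labels],
        dtype=np.int64,
    ).reshape(-1, 2)
    y = np.array([l.c_ij for l in labels], dtype=float)
    return pairs, y


def train(g: HeteroGraph, labels: list[PairLabel], config: ModelConfig,
          negative_exclude: list[PairLabel] | None = None) -> TrainedModel:
    """Fit the GNN regressor to pair compatibility labels.

    Each epoch takes one full-batch Adam step on the labeled pairs plus
    ``negative_pair_ratio`` times as many zero-label pairs drawn uniformly
    (without replacement) from never-co-occurring herb pairs; the negative
    sample is reseeded deterministically per epoch, so identical seeds give
    identical training logs. ``negative_exclude`` lists additional pairs that
    must never be sampled as negatives (e.g. held-out labeled pairs during
    cross-validation, which have nonzero labels the trainer must not see).
    Raises :class:`DivergenceError` if the loss goes non-finite.
    """
    if len(labels) < 10:
        raise HerbnetError("training requires at least 10 labeled pairs")
    pairs, y = _pairs_to_indices(g, labels)
    rng = np.random.default_rng(config.seed)
    p = init_params(g, config, rng)
    adjs = {r: g.adjacency(r) for r, _, _ in RELATIONS}
    labeled = {tuple(pr) for pr in pairs.tolist()}
    if negative_exclude:
        ex_pairs, _ = _pairs_to_indices(g, negative_exclude)
        labeled |= {tuple(pr) for pr in ex_pairs.tolist()}
    negs = _negative_candidates(g, labeled)
    n_neg = int(round(config.negative_pair_ratio * len(pairs)))
    opt = _Adam(p, config.learning_rate)

    log: list[float] = []
    for epoch in range(config.epochs):
        if n_neg > 0 and len(negs) > 0:
            ep_rng = np.random.default_rng([config.seed, epoch])
            take = ep_rng.choice(len(negs), size=min(n_neg, len(negs)), replace=False)
            batch_pairs = np.vstack([pairs, negs[take]])
            batch_y = np.concatenate([y, np.zeros(len(take))])
        else:
            batch_pairs, batch_y = pairs, y
        loss, grads, _ = loss_and_grads(p, g, batch_pairs, batch_y, adjs,
                                        config.n_layers)
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        log.append(loss)
        opt.step(p, grads)

    model = TrainedModel(params=p, config=config, herb_ids=list(g.herb_ids),
                         training_log=log)
    y_hat = model.predict_pairs(g, pairs)
    model.final_train_r2 = r_squared(y, y_hat) if len(y) >= 2 else None
    return model


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Mean held-out metrics for one hyperparameter configuration.

    ``r2`` is :data:`R2_UNDEFINED` (None) when the fit diverged or the
    held-out labels were degenerate, mirroring an undefined table cell.
    """

    config: ModelConfig
    mse: float
    r2: float | None
    fold_mse: list[float] = field(default_factory=list)
    fold_r2: list = field(default_factory=list)
    diverged: bool = False


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by label quantile: pairs are ordered by
    label and folds rotated within consecutive groups of k."""
    order = np.argsort(y, kind="stable")
    fold = np.empty(len(y), dtype=int)
    for start in range(0, len(y), k):
        block = order[start:start + k]
        fold[block] = rng.permutation(k)[: len(block)]
    return fold


def cross_validate(g: HeteroGraph, labels: list[PairLabel],
                   grid: list[ModelConfig], k: int = 5,
                   seed: int = 0) -> list[CVResult]:
    """Grid search with k-fold cross-validation over labeled herb pairs.

    Splits are edge-level: held-out pairs are removed from both supervision
    and herb-herb message passing in their fold, so the evaluation measures
    generalization to unseen pairs. Fold assignment is stratified by label
    quantile and seeded. A configuration whose training diverges on any fold
    reports the undefined R² sentinel.
    """
    if k < 2:
        raise ValueError("cross-validation requires k >= 2 folds")
    if len(labels) < k:
        raise HerbnetError(f"need at least {k} labeled pairs for {k} folds")
    pairs, y = _pairs_to_indices(g, labels)
    folds = _stratified_folds(y, k, np.random.default_rng(seed))

    # map label row -> index in g.hh_edges so held-out edges can be masked
    edge_pos = {tuple(e): idx for idx, e in enumerate(g.hh_edges.tolist())}

    results: list[CVResult] = []
    for cfg in grid:
        fold_mse, fold_r2 = [], []
        diverged = False
        for f in range(k):
            test = folds == f
            train_lbls = [l for l, t in zip(labels, test) if not t]
            keep = np.ones(len(g.hh_edges), dtype=bool)
            for pr, t in zip(pairs.tolist(), test):
                if t and tuple(pr) in edge_pos:
                    keep[edge_pos[tuple(pr)]] = False
            g_f = g.with_hh_edges(keep)
            cfg_f = ModelConfig(**{**asdict(cfg), "seed": cfg.seed + f})
            try:
                m = train(g_f, train_lbls, cfg_f, negative_exclude=labels)
            except DivergenceError:
                diverged = True
                fold_mse.append(float("nan"))
                fold_r2.append(R2_UNDEFINED)
                continue
            y_hat = m.predict_pairs(g_f, pairs[test])
            fold_mse.append(mse_loss(y[test], y_hat))
            fold_r2.append(r_squared(y[test], y_hat))
        finite = [v for v in fold_mse if np.isfinite(v)]
        mean_mse = float(np.mean(finite)) if finite else float("nan")
        defined = [v for v in fold_r2 if v is not None]
        r2 = R2_UNDEFINED if (diverged or not defined) else float(np.mean(defined))
        results.append(CVResult(config=cfg, mse=mean_mse, r2=r2,
                                fold_mse=fold_mse, fold_r2=fold_r2,
                                diverged=diverged))
    return results


def cv_results_frame(results: list[CVResult]):
    """Results as a table shaped (hidden_channels, lr, mse, r2); undefined R²
    renders as the marker '/'."""
    import pandas as pd

    return pd.DataFrame(
        [{"hidden_channels": r.config.hidden_channels,
          "lr": r.config.learning_rate,
          "mse": r.mse,
          "r2": "/" if r.r2 is None else r.r2}
         for r in results]
    )


def default_grid(epochs: int = 60, seed: int = 0, **kw) -> list[ModelConfig]:
    """The 12-configuration grid: hidden {64,128,256,512} x lr {1e-4,1e-3,1e-2}."""
    return [
        ModelConfig(hidden_channels=h, learning_rate=lr, epochs=epochs, seed=seed, **kw)
        for h in (64, 128, 256, 512)
        for lr in (1e-4, 1e-3, 1e-2)
    ]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize to .npz: parameter arrays plus a JSON header with the config,
    herb vocabulary and training log."""
    header = {
        "config": asdict(model.config),
        "herb_ids": model.herb_ids,
        "training_log": model.training_log,
        "final_train_r2": model.final_train_r2,
    }
    np.savez(
        path,
        __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        **model.params,
    )


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as z:
        header = json.loads(z["__header__"].tobytes().decode())
        params = {k: z[k] for k in z.files if k != "__header__"}
    return TrainedModel(
        params=params,
        config=ModelConfig(**header["config"]),
        herb_ids=list(header["herb_ids"]),
        training_log=list(header["training_log"]),
        final_train_r2=header.get("final_train_r2"),
    )
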
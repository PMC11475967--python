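"""Message-passing regression on a sample-similarity graph.

Nodes are patient samples, connected to their k nearest training samples
in transformed-feature space with Gaussian edge weights
z_e = exp(-d^2 / (2 * bandwidth^2)). One message-passing layer updates,
in this order, every edge and then every node:

    edge:  b_e = [g_e^(l-1), agg of endpoint states]   -> g_e^l = ReLU(W_E b_e + c_E)
    node:  a_v = [h_v^(l-1), agg of neighbour states]  -> h_v^l = ReLU(W_V a_v + c_V)

after L layers a per-node readout maps [h_v^L, agg of incident edge
states] affinely to a scalar severity score. All layer-l updates complete
before layer l+1 begins. Aggregation is a mean (or sum) over the
neighbourhood multiset, so the network is invariant to node relabelling
and to neighbour enumeration order.

Evaluation is inductive: test nodes receive messages from training nodes
but never send any, so fitted parameters and training-node predictions
are unchanged by the presence or absence of test samples.

Training minimizes mean absolute error over training nodes with
adaptive-moment gradient descent; everything is seeded and
single-threaded, so loss histories are bitwise reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.neighbors import NearestNeighbors

from . import _autograd as ag
from ._autograd import Var

__all__ = ["SampleGraph", "TrainConfig", "GNNModel", "MLPModel",
           "build_sample_graph", "gnn_forward", "train_gnn", "predict",
           "mlp_baseline", "train_mlp", "mlp_forward"]


@dataclass
class SampleGraph:
    node_features: np.ndarray      # (n, d) rows = samples
    edges: np.ndarray              # (E, 2) directed (src, dst); no self-loops
    edge_features: np.ndarray      # (E, 1) Gaussian similarity of endpoints
    train_mask: np.ndarray         # (n,) bool

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(self.train_mask)

    @property
    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.train_mask)


@dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    hidden_width: int = 32
    n_layers: int = 2
    k_neighbors: int = 10
    kernel_bandwidth: float | None = None   # None -> median pairwise train distance
    seed: int = 0
    early_stop_patience: int | None = 20
    aggregator: str = "mean"                # "mean" | "sum"

    def __post_init__(self):
        if self.epochs <= 0 or self.learning_rate <= 0 or self.hidden_width <= 0:
            raise ValueError("epochs, learning_rate and hidden_width must be positive")
        if self.n_layers < 0 or self.k_neighbors < 1:
            raise ValueError("n_layers must be >= 0 and k_neighbors >= 1")
        if self.aggregator not in ("mean", "sum"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")


def build_sample_graph(X_train: np.ndarray, X_test: np.ndarray | None = None,
                       k: int = 10, bandwidth: float | None = None,
                       ) -> SampleGraph:
    """k-nearest-training-neighbour graph over samples.

    Training nodes link to their k nearest other training nodes in both
    directions; test nodes only receive edges from their k nearest
    training nodes (inductive orientation). Edge features are Gaussian
    similarities of the endpoint distance.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = (np.empty((0, X_train.shape[1]))
              if X_test is None else np.asarray(X_test, dtype=np.float64))
    n_train, n_test = X_train.shape[0], X_test.shape[0]
    if n_train < 2:
        raise ValueError("need at least 2 training samples")
    if k >= n_train:
        warnings.warn(f"k={k} >= n_train={n_train}; clamping to {n_train - 1}")
        k = n_train - 1
    if bandwidth is None:
        bandwidth = float(np.median(pdist(X_train)))
        if bandwidth == 0:
            bandwidth = 1.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    nodes = np.vstack([X_train, X_test])
    nn = NearestNeighbors(n_neighbors=min(k + 1, n_train)).fit(X_train)
    dist, ind = nn.kneighbors(nodes)

    src, dst, w = [], [], []
    for v in range(n_train + n_test):
        is_train = v < n_train
        picked = 0
        for d, u in zip(dist[v], ind[v]):
            if is_train and u == v:
                continue
            if picked >= k:
                break
            picked += 1
            z = float(np.exp(-d * d / (2.0 * bandwidth * bandwidth)))
            # train neighbour -> v always carries a message
            src.append(u); dst.append(v); w.append(z)
            if is_train:
                # reverse direction only between training nodes
                src.append(v); dst.append(u); w.append(z)
    edges = np.column_stack([src, dst]).astype(int)
    weights = np.asarray(w, dtype=np.float64)[:, None]
    edges, keep = np.unique(edges, axis=0, return_index=True)
    weights = weights[keep]
    mask = np.zeros(n_train + n_test, dtype=bool)
    mask[:n_train] = True
    return SampleGraph(node_features=nodes, edges=edges,
                       edge_features=weights, train_mask=mask)


def _init_affine(rng: np.random.Generator, fan_in: int, fan_out: int,
                 ) -> tuple[Var, Var]:
    W = Var(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
    c = Var(np.zeros((fan_out,)))
    return W, c


@dataclass
class GNNModel:
    layers: list[dict]             # per layer: {"W_E","c_E","W_V","c_V"} Vars
    readout_W: Var | None
    readout_c: Var | None
    aggregator: str = "mean"
    readout_kind: str = "affine"   # "affine" | "identity" (diagnostic use)
    seed: int = 0

    @classmethod
    def init(cls, in_dim: int, edge_dim: int = 1, hidden: int = 32,
             n_layers: int = 2, seed: int = 0, aggregator: str = "mean",
             ) -> "GNNModel":
        rng = np.random.default_rng(seed)
        layers = []
        h_dim, g_dim = in_dim, edge_dim
        for _ in range(n_layers):
            W_E, c_E = _init_affine(rng, g_dim + h_dim, hidden)
            W_V, c_V = _init_affine(rng, 2 * h_dim, hidden)
            layers.append({"W_E": W_E, "c_E": c_E, "W_V": W_V, "c_V": c_V})
            h_dim = g_dim = hidden
        W_R, c_R = _init_affine(rng, h_dim + g_dim, 1)
        return cls(layers=layers, readout_W=W_R, readout_c=c_R,
                   aggregator=aggregator, seed=seed)

    def parameters(self) -> list[Var]:
        out = []
        for layer in self.layers:
            out.extend(layer.values())
        if self.readout_kind == "affine":
            out.extend([self.readout_W, self.readout_c])
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays):
            p.data = a.copy()


def _aggregate(values: Var, seg: np.ndarray, n: int, how: str) -> Var:
    if how == "sum":
        return ag.segment_sum(values, seg, n)
    return ag.segment_mean(values, seg, n)


def gnn_forward(model: GNNModel, graph: SampleGraph) -> Var:
    """Run the message-passing layers and per-node readout; returns (n, 1)."""
    n = graph.n_nodes
    src = graph.edges[:, 0] if len(graph.edges) else np.empty(0, dtype=int)
    dst = graph.edges[:, 1] if len(graph.edges) else np.empty(0, dtype=int)
    h = Var(graph.node_features)
    g = Var(graph.edge_features)
    for li, layer in enumerate(model.layers, start=1):
        # edges first: aggregate endpoint states with the edge's own state
        endpoints = ag.add(ag.gather(h, src), ag.gather(h, dst))
        if model.aggregator == "mean":
            endpoints = ag.scale(endpoints, 0.5)
        b_e = ag.concat([g, endpoints], axis=1)
        g = ag.relu(ag.add(ag.matmul(b_e, layer["W_E"]), layer["c_E"]))
        # then nodes: aggregate incoming neighbour states with the node's own
        messages = _aggregate(ag.gather(h, src), dst, n, model.aggregator)
        a_v = ag.concat([h, messages], axis=1)
        h = ag.relu(ag.add(ag.matmul(a_v, layer["W_V"]), layer["c_V"]))
        if not (np.all(np.isfinite(h.data)) and np.all(np.isfinite(g.data))):
            raise FloatingPointError(f"non-finite activation at layer {li}")
    incident = _aggregate(g, dst, n, model.aggregator)
    r = ag.concat([h, incident], axis=1)
    if model.readout_kind == "identity":
        return r
    return ag.add(ag.matmul(r, model.readout_W), model.readout_c)


def predict(model: GNNModel, graph: SampleGraph) -> np.ndarray:
    return gnn_forward(model, graph).data[:, 0].copy()


def _fit(forward, model, y: np.ndarray, fit_idx: np.ndarray,
         config: TrainConfig, idx_to_y: np.ndarray,
         ) -> tuple[list[float], int]:
    """Shared MAE training loop with optional early stopping.

    ``idx_to_y`` maps node/sample index -> position in y. Early stopping
    holds out ~15% of the fitted samples when there are at least 20;
    the best-validation parameters are restored afterwards.
    """
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(config.seed + 1)
    use_val = (config.early_stop_patience is not None and len(fit_idx) >= 20)
    if use_val:
        perm = rng.permutation(len(fit_idx))
        n_val = max(2, int(round(0.15 * len(fit_idx))))
        val_idx = fit_idx[perm[:n_val]]
        opt_idx = fit_idx[perm[n_val:]]
    else:
        val_idx = np.empty(0, dtype=int)
        opt_idx = fit_idx

    params = model.parameters()
    optim = ag.Adam(params, lr=config.learning_rate)
    y_opt = Var(y[idx_to_y[opt_idx]][:, None])
    history: list[float] = []
    best_val = np.inf
    best_state = None
    best_epoch = -1
    stall = 0
    for epoch in range(config.epochs):
        optim.zero_grad()
        pred = forward()
        loss = ag.mean_abs(ag.sub(ag.gather(pred, opt_idx), y_opt))
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} "
                f"(learning_rate={config.learning_rate})")
        history.append(float(loss.data))
        loss.backward()
        optim.step()
        if use_val:
            val_pred = forward().data[val_idx, 0]
            val_mae = float(np.mean(np.abs(val_pred - y[idx_to_y[val_idx]])))
            if val_mae < best_val - 1e-12:
                best_val = val_mae
                best_state = model.state_arrays()
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
                if stall >= config.early_stop_patience:
                    break
    if best_state is not None:
        model.load_arrays(best_state)
    return history, best_epoch


def train_gnn(graph: SampleGraph, y_train: np.ndarray,
              config: TrainConfig | None = None,
              ) -> tuple[GNNModel, list[float]]:
    """Fit the message-passing model on the graph's training nodes.

    ``y_train`` is aligned with ``graph.train_indices`` (typically
    standardized scores). Returns the fitted model and the per-epoch
    training-loss history.
    """
    config = config or TrainConfig()
    train_idx = graph.train_indices
    if len(train_idx) < 2:
        raise ValueError("need at least 2 training nodes")
    if len(y_train) != len(train_idx):
        raise ValueError("y_train length must match number of training nodes")
    model = GNNModel.init(in_dim=graph.node_features.shape[1],
                          hidden=config.hidden_width,
                          n_layers=config.n_layers, seed=config.seed,
                          aggregator=config.aggregator)
    idx_to_y = np.full(graph.n_nodes, -1, dtype=int)
    idx_to_y[train_idx] = np.arange(len(train_idx))
    history, _ = _fit(lambda: gnn_forward(model, graph), model,
                      np.asarray(y_train, dtype=np.float64),
                      train_idx, config, idx_to_y)
    return model, history


@dataclass
class MLPModel:
    """Feed-forward ReLU network (the graph-free ablation arm)."""

    weights: list[Var] = field(default_factory=list)
    biases: list[Var] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def init(cls, in_dim: int, hidden: int = 32, n_hidden_layers: int = 2,
             seed: int = 0) -> "MLPModel":
        rng = np.random.default_rng(seed)
        dims = [in_dim] + [hidden] * n_hidden_layers + [1]
        weights, biases = [], []
        for fi, fo in zip(dims[:-1], dims[1:]):
            W, c = _init_affine(rng, fi, fo)
            weights.append(W)
            biases.append(c)
        return cls(weights=weights, biases=biases, seed=seed)

    def parameters(self) -> list[Var]:
        return [*self.weights, *self.biases]

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays):
            p.data = a.copy()


def mlp_forward(model: MLPModel, X: np.ndarray | Var) -> Var:
    h = X if isinstance(X, Var) else Var(np.asarray(X, dtype=np.float64))
    last = len(model.weights) - 1
    for i, (W, c) in enumerate(zip(model.weights, model.biases)):
        h = ag.add(ag.matmul(h, W), c)
        if i != last:
            h = ag.relu(h)
        if not np.all(np.isfinite(h.data)):
            raise FloatingPointError(f"non-finite activation at layer {i + 1}")
    return h


def train_mlp(X_train: np.ndarray, y_train: np.ndarray,
              config: TrainConfig | None = None,
              ) -> tuple[MLPModel, list[float]]:
    config = config or TrainConfig()
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    model = MLPModel.init(in_dim=X_train.shape[1], hidden=config.hidden_width,
                          n_hidden_layers=config.n_layers, seed=config.seed)
    idx = np.arange(X_train.shape[0])
    history, _ = _fit(lambda: mlp_forward(model, X_train), model,
                      np.asarray(y_train, dtype=np.float64),
                      idx, config, idx)
    return model, history


def mlp_baseline(X_train: np.ndarray, y_train: np.ndarray,
                 X_test: np.ndarray, config: TrainConfig | None = None,
                 ) -> np.ndarray:
    """Train the feed-forward baseline and predict the test rows."""
    model, _ = train_mlp(X_train, y_train, config)
    return mlp_forward(model, np.asarray(X_test, dtype=np.float64)).data[:, 0]
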
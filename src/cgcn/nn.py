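"""The connectivity-based graph convolutional network (cGCN).

Every fMRI frame is a graph signal: node i carries the BOLD value of ROI i,
and convolution aggregates over the k-NN connectivity neighborhood using the
asymmetric EdgeConv edge function

    x_i' = max_{j : (i,j) in E}  h_Theta( x_i || x_j - x_i )

where h_Theta is an MLP with ReLU activations and the max is feature-wise
over the k neighbors.  The architecture stacks several such layers on one
shared graph (same graph for all subjects and all frames), concatenates the
earlier layers' outputs into the last one (skip connections), pools node
features to a per-frame embedding, combines frames with a temporal head
(average pooling, or a recurrent layer), and classifies with softmax.

Following the EdgeConv lineage (dynamic graph CNNs), each edge-MLP linear
map is paired with batch normalization before the ReLU; without it, deep
ReLU/max stacks collapse onto a large shared offset and optimization
stalls.  Batch statistics are used during training and tracked running
moments at evaluation, so trained models are deterministic functions.

Implemented directly on numpy with hand-derived gradients; parameters live
in a flat name -> array dict so optimizers and checkpoints stay trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp

from .fc_graph import KnnGraph

__all__ = [
    "EdgeMlp",
    "CgcnConfig",
    "CgcnModel",
    "edgeconv_forward",
    "receptive_field",
    "softmax",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9
DTYPE = np.float32  # default parameter/activation dtype; float64 available via initialize()


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class EdgeMlp:
    """The trainable edge function h_Theta: a ReLU MLP on [x_i, x_j - x_i].

    ``weights[m]`` has shape (width_{m+1}, width_m); the first width is
    2 * F_in (central features concatenated with the neighbor difference).
    The optional batch-norm lists hold, per sublayer, the trainable
    gamma/beta and the running mean/variance buffers (updated in place
    during training).  With ``gammas is None`` the MLP is a plain
    linear+ReLU chain, which is the form used for hand-set edge functions.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray] | None = None
    gammas: list[np.ndarray] | None = None
    betas: list[np.ndarray] | None = None
    run_means: list[np.ndarray] | None = None
    run_vars: list[np.ndarray] | None = None

    @property
    def layer_widths(self) -> list[int]:
        return [self.weights[0].shape[1]] + [w.shape[0] for w in self.weights]

    @property
    def has_bn(self) -> bool:
        return self.gammas is not None


def _bn_forward(pre: np.ndarray, mlp: EdgeMlp, m: int, train: bool):
    if train:
        mu = pre.mean(axis=0)
        var = pre.var(axis=0)
        mlp.run_means[m] *= _BN_MOMENTUM
        mlp.run_means[m] += (1 - _BN_MOMENTUM) * mu
        mlp.run_vars[m] *= _BN_MOMENTUM
        mlp.run_vars[m] += (1 - _BN_MOMENTUM) * var
    else:
        mu, var = mlp.run_means[m], mlp.run_vars[m]
    s = np.sqrt(var + _BN_EPS)
    xhat = (pre - mu) / s
    return mlp.gammas[m] * xhat + mlp.betas[m], xhat, s


def _bn_backward(d_h: np.ndarray, xhat: np.ndarray, s: np.ndarray,
                 gamma: np.ndarray):
    d_gamma = np.sum(d_h * xhat, axis=0)
    d_beta = np.sum(d_h, axis=0)
    d_xhat = d_h * gamma
    d_pre = (d_xhat - d_xhat.mean(axis=0)
             - xhat * (d_xhat * xhat).mean(axis=0)) / s
    return d_pre, d_gamma, d_beta


def _edgeconv_batch(x: np.ndarray, graph: KnnGraph, mlp: EdgeMlp,
                    need_cache: bool, train: bool = False):
    """EdgeConv on a stack of frames: (B, N, F_in) -> (B, N, F_out).

    The first linear map is applied as W_c @ x_i + W_d @ (x_j - x_i) with
    the central term computed once per node (not per edge slot); under
    batch normalization the linear biases are skipped, since BN's mean
    subtraction cancels them exactly.
    """
    nbr = graph.neighbors
    b_, n, f = x.shape
    k = graph.k
    w0 = mlp.weights[0]
    wc, wd = w0[:, :f], w0[:, f:]
    x2 = x.reshape(b_ * n, f)
    diff = x[:, nbr, :] - x[:, :, None, :]          # (B, N, k, F)
    diff2 = diff.reshape(b_ * n * k, f)
    pre = diff2 @ wd.T
    pre4 = pre.reshape(b_, n, k, -1)
    pre4 += (x2 @ wc.T).reshape(b_, n, 1, -1)
    if not mlp.has_bn and mlp.biases is not None:
        pre += mlp.biases[0]
    caches = []
    a = pre
    for m in range(len(mlp.weights)):
        if m > 0:
            a_in = a
            pre = a @ mlp.weights[m].T
            if not mlp.has_bn and mlp.biases is not None:
                pre += mlp.biases[m]
        else:
            a_in = None  # layer-0 inputs cached as (x2, diff2)
        if mlp.has_bn:
            h, xhat, s = _bn_forward(pre, mlp, m, train)
        else:
            h, xhat, s = pre, None, None
        a = relu(h)
        if need_cache:
            caches.append((a_in, h > 0, xhat, s))
    f_out = a.shape[1]
    a4 = a.reshape(b_, n, k, f_out)
    out = a4.max(axis=2)
    if not need_cache:
        return out, None
    arg = a4.argmax(axis=2)
    return out, (caches, arg, f, x2, diff2)


def _scatter_matrix(graph: KnnGraph) -> sp.csr_matrix:
    """(N, N*k) matrix that sums edge-slot gradients back onto neighbor nodes."""
    n, k = graph.n_nodes, graph.k
    cols = np.arange(n * k)
    rows = graph.neighbors.ravel()
    data = np.ones(n * k, dtype=np.float32)  # exact in either precision
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n * k))


def _edgeconv_backward(d_out: np.ndarray, cache, graph: KnnGraph, mlp: EdgeMlp,
                       scatter: sp.csr_matrix):
    """Gradients of one EdgeConv layer given d(loss)/d(output)."""
    caches, arg, f_in, x2, diff2 = cache
    b_, n, f_out = d_out.shape
    k = graph.k
    d_a4 = np.zeros((b_, n, k, f_out), dtype=d_out.dtype)
    np.put_along_axis(d_a4, arg[:, :, None, :], d_out[:, :, None, :], axis=2)
    d_a = d_a4.reshape(-1, f_out)

    d_ws, d_bs, d_gs, d_betas = [], [], [], []
    d_x = None
    for m in range(len(mlp.weights) - 1, -1, -1):
        a_in, mask, xhat, s = caches[m]
        d_h = d_a * mask
        if mlp.has_bn:
            d_pre, d_gamma, d_beta = _bn_backward(d_h, xhat, s, mlp.gammas[m])
            d_gs.append(d_gamma)
            d_betas.append(d_beta)
        else:
            d_pre = d_h
            d_bs.append(d_pre.sum(axis=0))
        if m > 0:
            d_ws.append(d_pre.T @ a_in)
            d_a = d_pre @ mlp.weights[m]
        else:
            # split map: x_i enters via W_c once per node, x_j - x_i via W_d
            w0 = mlp.weights[0]
            wc, wd = w0[:, :f_in], w0[:, f_in:]
            d_pre_c = d_pre.reshape(b_, n, k, -1).sum(axis=2).reshape(b_ * n, -1)
            d_ws.append(np.concatenate([d_pre_c.T @ x2, d_pre.T @ diff2], axis=1))
            d_diff4 = (d_pre @ wd).reshape(b_, n, k, f_in)
            d_x = (d_pre_c @ wc).reshape(b_, n, f_in) - d_diff4.sum(axis=2)
            flat = d_diff4.transpose(1, 2, 0, 3).reshape(n * k, b_ * f_in)
            d_x += (scatter @ flat).reshape(n, b_, f_in).transpose(1, 0, 2)
    return d_x, d_ws[::-1], d_bs[::-1], d_gs[::-1], d_betas[::-1]


@dataclass
class CgcnConfig:
    """Architecture hyperparameters.

    ``features_per_layer`` must have one entry per convolutional layer; the
    default five-layer stack mirrors the published architecture at desk
    scale (the original work fixes the depth at 5 but not the widths).
    """

    n_classes: int
    n_conv_layers: int = 5
    features_per_layer: tuple[int, ...] = (8, 8, 16, 16, 32)
    temporal_head: str = "average_pool"  # or "recurrent"
    recurrent_hidden: int = 32
    l2_lambda: float = 0.0
    skip_connections: bool = True
    node_pool: str = "flatten"  # or "max" / "mean"
    mlp_depth: int = 1
    batch_norm: bool = True

    def __post_init__(self) -> None:
        self.features_per_layer = tuple(int(f) for f in self.features_per_layer)
        if len(self.features_per_layer) != self.n_conv_layers:
            raise ValueError("features_per_layer length must equal n_conv_layers")
        if self.temporal_head not in ("average_pool", "recurrent"):
            raise ValueError(f"unknown temporal head {self.temporal_head!r}")
        if self.node_pool not in ("flatten", "max", "mean"):
            raise ValueError(f"unknown node pooling {self.node_pool!r}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "CgcnConfig":
        d = json.loads(text)
        d["features_per_layer"] = tuple(d["features_per_layer"])
        return cls(**d)


def _conv_input_widths(cfg: CgcnConfig) -> list[int]:
    """Feature width entering each conv layer (input signal is 1 feature)."""
    widths = []
    for layer in range(cfg.n_conv_layers):
        if layer == 0:
            widths.append(1)
        elif cfg.skip_connections and layer == cfg.n_conv_layers - 1:
            widths.append(sum(cfg.features_per_layer[:-1]))
        else:
            widths.append(cfg.features_per_layer[layer - 1])
    return widths


def edgeconv_forward(x: np.ndarray, graph: KnnGraph, mlp: EdgeMlp) -> np.ndarray:
    """Single-frame EdgeConv: (N, F_in) node features -> (N, F_out).

    For each node the k candidate vectors h_Theta(x_i || x_j - x_i) are
    formed over its out-neighbors j and reduced by a feature-wise maximum.
    Evaluation mode: batch-norm layers, if present, use running moments.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be (n_nodes, n_features)")
    if x.shape[0] != graph.n_nodes:
        raise ValueError(f"x has {x.shape[0]} rows, graph has {graph.n_nodes} nodes")
    if mlp.weights[0].shape[1] != 2 * x.shape[1]:
        raise ValueError(
            f"edge MLP expects input width {mlp.weights[0].shape[1]}, "
            f"got 2*{x.shape[1]} features"
        )
    out, _ = _edgeconv_batch(x[None], graph, mlp, need_cache=False, train=False)
    return out[0]


def receptive_field(graph: KnnGraph, n_layers: int) -> list[set[int]]:
    """Nodes reachable from each node within ``n_layers`` directed hops.

    Stacking L conv layers lets node i aggregate information from exactly
    this set, so it bounds which input perturbations can affect i's output.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    fields = []
    for start in range(graph.n_nodes):
        seen = {start}
        frontier = {start}
        for _ in range(n_layers):
            nxt = set()
            for node in frontier:
                for j in graph.neighbors[node]:
                    j = int(j)
                    if j not in seen:
                        seen.add(j)
                        nxt.add(j)
            frontier = nxt
            if not frontier:
                break
        fields.append(seen)
    return fields


class CgcnModel:
    """A cGCN bound to one fixed k-NN graph.

    ``params`` are trainable arrays; ``buffers`` hold batch-norm running
    moments (state, but not optimized).  The graph never changes during the
    model's lifetime; rebuilding the graph means building a new model.
    """

    def __init__(self, config: CgcnConfig, graph: KnnGraph,
                 params: dict[str, np.ndarray],
                 buffers: dict[str, np.ndarray] | None = None):
        self.config = config
        self.graph = graph
        self.params = params
        self.buffers = buffers if buffers is not None else {}
        self._scatter = _scatter_matrix(graph)

    # -- construction ------------------------------------------------------

    @classmethod
    def initialize(cls, config: CgcnConfig, graph: KnnGraph, seed: int,
                   dtype=DTYPE) -> "CgcnModel":
        """Fan-in-scaled (He) random initialization, reproducible from seed."""
        rng = np.random.default_rng(seed)
        params: dict[str, np.ndarray] = {}
        buffers: dict[str, np.ndarray] = {}
        in_widths = _conv_input_widths(config)
        for layer in range(config.n_conv_layers):
            widths = [2 * in_widths[layer]]
            widths += [config.features_per_layer[layer]] * config.mlp_depth
            for m in range(config.mlp_depth):
                fan_in = widths[m]
                name = f"conv{layer}.mlp{m}"
                params[f"{name}.W"] = (rng.standard_normal(
                    (widths[m + 1], fan_in)) * np.sqrt(2.0 / fan_in)).astype(dtype)
                if not config.batch_norm:
                    params[f"{name}.b"] = np.zeros(widths[m + 1], dtype=dtype)
                if config.batch_norm:
                    params[f"{name}.gamma"] = np.ones(widths[m + 1], dtype=dtype)
                    params[f"{name}.beta"] = np.zeros(widths[m + 1], dtype=dtype)
                    buffers[f"{name}.rmean"] = np.zeros(widths[m + 1], dtype=dtype)
                    buffers[f"{name}.rvar"] = np.ones(widths[m + 1], dtype=dtype)
        emb = config.features_per_layer[-1]
        if config.node_pool == "flatten":
            emb *= graph.n_nodes
        if config.temporal_head == "recurrent":
            h = config.recurrent_hidden
            params["head.Wx"] = (rng.standard_normal((h, emb))
                                 * np.sqrt(1.0 / emb)).astype(dtype)
            params["head.Wh"] = (rng.standard_normal((h, h))
                                 * np.sqrt(1.0 / h)).astype(dtype)
            params["head.b"] = np.zeros(h, dtype=dtype)
            clf_in = h
        else:
            clf_in = emb
        params["clf.W"] = (rng.standard_normal(
            (config.n_classes, clf_in)) * np.sqrt(1.0 / clf_in)).astype(dtype)
        params["clf.b"] = np.zeros(config.n_classes, dtype=dtype)
        return cls(config, graph, params, buffers)

    @property
    def dtype(self):
        return self.params["clf.W"].dtype

    def copy(self) -> "CgcnModel":
        return CgcnModel(self.config, self.graph,
                         {k: v.copy() for k, v in self.params.items()},
                         {k: v.copy() for k, v in self.buffers.items()})

    def _mlp(self, layer: int) -> EdgeMlp:
        ws, bs = [], []
        gs, betas, rms, rvs = [], [], [], []
        for m in range(self.config.mlp_depth):
            name = f"conv{layer}.mlp{m}"
            ws.append(self.params[f"{name}.W"])
            if self.config.batch_norm:
                gs.append(self.params[f"{name}.gamma"])
                betas.append(self.params[f"{name}.beta"])
                rms.append(self.buffers[f"{name}.rmean"])
                rvs.append(self.buffers[f"{name}.rvar"])
            else:
                bs.append(self.params[f"{name}.b"])
        if self.config.batch_norm:
            return EdgeMlp(ws, None, gs, betas, rms, rvs)
        return EdgeMlp(ws, bs)

    # -- forward -----------------------------------------------------------

    def forward_batch(self, clips: np.ndarray, need_cache: bool = False,
                      train: bool = False):
        """Class probabilities for a batch of equal-length clips (B, T, N).

        ``train=True`` makes batch-norm layers use (and update) batch
        statistics; evaluation uses the frozen running moments.
        """
        cfg = self.config
        b_, t, n = clips.shape
        if n != self.graph.n_nodes:
            raise ValueError(f"clips have {n} ROIs, graph has {self.graph.n_nodes} nodes")
        if t < 1:
            raise ValueError("clips must contain at least one frame")
        x = clips.reshape(b_ * t, n, 1).astype(self.dtype)

        outs, caches = [], []
        h = x
        last = cfg.n_conv_layers - 1
        for layer in range(cfg.n_conv_layers):
            if layer == last and cfg.skip_connections and last > 0:
                h = np.concatenate(outs, axis=-1)
            h, cache = _edgeconv_batch(h, self.graph, self._mlp(layer),
                                       need_cache, train)
            outs.append(h)
            caches.append(cache)

        if cfg.node_pool == "flatten":
            node_arg = None
            emb = h.reshape(b_ * t, -1)
        elif cfg.node_pool == "max":
            node_arg = h.argmax(axis=1)
            emb = np.take_along_axis(h, node_arg[:, None, :], axis=1)[:, 0, :]
        else:
            node_arg = None
            emb = h.mean(axis=1)
        emb = emb.reshape(b_, t, -1)

        rnn_cache = None
        if cfg.temporal_head == "recurrent":
            wx, wh, bias = self.params["head.Wx"], self.params["head.Wh"], self.params["head.b"]
            hidden = np.zeros((b_, wx.shape[0]))
            states = [hidden]
            for step in range(t):
                hidden = np.tanh(emb[:, step] @ wx.T + hidden @ wh.T + bias)
                states.append(hidden)
            pooled = hidden
            rnn_cache = states
        else:
            pooled = emb.mean(axis=1)

        logits = pooled @ self.params["clf.W"].T + self.params["clf.b"]
        probs = softmax(logits)
        if not need_cache:
            return probs, None
        return probs, {
            "shape": (b_, t, n),
            "conv_caches": caches,
            "node_arg": node_arg,
            "emb": emb,
            "rnn_states": rnn_cache,
            "pooled": pooled,
        }

    def forward(self, clip: np.ndarray) -> np.ndarray:
        """Probability vector for one T x N clip (sums to 1); evaluation mode."""
        clip = np.asarray(clip, dtype=float)
        if clip.ndim != 2:
            raise ValueError("clip must be a T x N matrix")
        probs, _ = self.forward_batch(clip[None])
        return probs[0]

    def predict_proba(self, clips: list[np.ndarray], batch_size: int = 16) -> np.ndarray:
        """Probabilities for a list of clips; clips may differ in length."""
        by_len: dict[int, list[int]] = {}
        for i, c in enumerate(clips):
            by_len.setdefault(c.shape[0], []).append(i)
        out = np.empty((len(clips), self.config.n_classes))
        for t, idxs in by_len.items():
            for start in range(0, len(idxs), batch_size):
                chunk = idxs[start:start + batch_size]
                batch = np.stack([clips[i] for i in chunk])
                probs, _ = self.forward_batch(batch)
                out[chunk] = probs
        return out

    # -- backward ----------------------------------------------------------

    def backward_batch(self, cache: dict, d_logits: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients given d(loss)/d(logits) for the cached batch."""
        cfg = self.config
        b_, t, n = cache["shape"]
        d_logits = np.asarray(d_logits, dtype=self.dtype)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        pooled = cache["pooled"]
        grads["clf.W"] += d_logits.T @ pooled
        grads["clf.b"] += d_logits.sum(axis=0)
        d_pooled = d_logits @ self.params["clf.W"]

        emb = cache["emb"]
        if cfg.temporal_head == "recurrent":
            wx, wh = self.params["head.Wx"], self.params["head.Wh"]
            states = cache["rnn_states"]
            d_h = d_pooled
            d_emb = np.empty_like(emb)
            for step in range(t - 1, -1, -1):
                d_pre = d_h * (1.0 - states[step + 1] ** 2)
                grads["head.Wx"] += d_pre.T @ emb[:, step]
                grads["head.Wh"] += d_pre.T @ states[step]
                grads["head.b"] += d_pre.sum(axis=0)
                d_emb[:, step] = d_pre @ wx
                d_h = d_pre @ wh
        else:
            d_emb = np.repeat(d_pooled[:, None, :] / t, t, axis=1)

        f_last = cfg.features_per_layer[-1]
        d_emb_flat = d_emb.reshape(b_ * t, -1)
        if cfg.node_pool == "flatten":
            d_nodes = d_emb_flat.reshape(b_ * t, n, f_last)
        elif cfg.node_pool == "max":
            d_nodes = np.zeros((b_ * t, n, f_last), dtype=d_emb_flat.dtype)
            np.put_along_axis(d_nodes, cache["node_arg"][:, None, :],
                              d_emb_flat[:, None, :], axis=1)
        else:
            d_nodes = np.broadcast_to(d_emb_flat[:, None, :] / n,
                                      (b_ * t, n, f_last)).copy()

        # Output of layer l feeds layer l+1 sequentially and, with skips,
        # also the concatenated input of the last layer; both gradient
        # routes are summed while walking the stack in reverse.
        last = cfg.n_conv_layers - 1
        d_out = d_nodes
        chunks: list[np.ndarray] = []
        for layer in range(last, -1, -1):
            d_in, d_ws, d_bs, d_gs, d_betas = _edgeconv_backward(
                d_out, cache["conv_caches"][layer], self.graph,
                self._mlp(layer), self._scatter)
            for m in range(cfg.mlp_depth):
                name = f"conv{layer}.mlp{m}"
                grads[f"{name}.W"] += d_ws[m]
                if cfg.batch_norm:
                    grads[f"{name}.gamma"] += d_gs[m]
                    grads[f"{name}.beta"] += d_betas[m]
                else:
                    grads[f"{name}.b"] += d_bs[m]
            if layer == 0:
                break
            if layer == last and cfg.skip_connections and last > 0:
                splits = np.cumsum(cfg.features_per_layer[:-1])[:-1]
                chunks = list(np.split(d_in, splits, axis=-1))
                d_out = chunks.pop()
            else:
                d_out = d_in + chunks.pop() if chunks else d_in
        return grads
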
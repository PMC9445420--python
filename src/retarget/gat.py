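"""Graph attention network for binary node classification.

Two attention layers in the canonical multi-head formulation: per head a
shared linear map W, attention logits

    e_ij = LeakyReLU(a_src . W h_i_src + a_dst . W h_i_dst) + b_ij

over j in N(i) union {i}, softmax-normalised per destination node, with
an optional additive log-edge-weight bias b_ij so that heavier
interactions receive more initial attention. Hidden-layer heads are
concatenated and passed through ELU; the output layer is a single
attention head producing one logit per node, read through a sigmoid.

Message passing is edge-wise (gather/scatter on the edge list), so cost
scales with the number of edges, not nodes squared. The dense-masked
formulation exists only as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad


@dataclass
class GATConfig:
    """Architecture and optimisation settings for the gene classifier."""

    n_layers: int = 2
    heads: int = 8
    hidden_dim: int = 16
    leaky_relu_slope: float = 0.2
    dropout: float = 0.3
    learning_rate: float = 1e-2
    weight_decay: float = 5e-4
    max_epochs: int = 400
    patience: int = 60
    seed: int = 0
    edge_weight_mode: str = "bias"  # "bias" | "ignore"

    def validate(self):
        if self.n_layers != 2:
            raise ValueError("only the 2-layer architecture is implemented")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        for name in ("heads", "hidden_dim", "max_epochs", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")
        if self.edge_weight_mode not in ("bias", "ignore"):
            raise ValueError("edge_weight_mode must be 'bias' or 'ignore'")


@dataclass
class EdgeIndex:
    """Directed edge arrays (both directions plus self-loops) for one graph."""

    src: np.ndarray
    dst: np.ndarray
    bias: np.ndarray  # additive attention-logit bias, log(edge weight)
    n_nodes: int


def build_edge_index(n_nodes: int, edges, weights=None,
                     edge_weight_mode: str = "bias") -> EdgeIndex:
    """Expand an undirected edge list into directed arrays with self-loops.

    ``edges`` is an iterable of (u, v) integer pairs; ``weights`` aligned
    positive reals (ignored when mode is "ignore"). Self-loops get bias 0.
    """
    src, dst, bias = [], [], []
    if weights is None:
        weights = [1.0] * len(edges)
    for (u, v), w in zip(edges, weights):
        if w is None or edge_weight_mode == "ignore":
            b = 0.0
        else:
            if w <= 0:
                raise ValueError("edge weights must be positive")
            b = float(np.log(w))
        src.extend((u, v))
        dst.extend((v, u))
        bias.extend((b, b))
    loops = np.arange(n_nodes)
    src = np.concatenate([np.asarray(src, dtype=np.intp), loops])
    dst = np.concatenate([np.asarray(dst, dtype=np.intp), loops])
    bias = np.concatenate([np.asarray(bias, dtype=np.float64),
                           np.zeros(n_nodes)])
    return EdgeIndex(src=src, dst=dst, bias=bias, n_nodes=n_nodes)


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


def init_params(in_dim: int, config: GATConfig,
                rng: np.random.Generator) -> dict[str, ad.Tensor]:
    """Glorot-initialised parameter set for the 2-layer network."""
    params: dict[str, ad.Tensor] = {}
    h, k = config.hidden_dim, config.heads
    for head in range(k):
        params[f"W1_{head}"] = ad.Tensor(_glorot(rng, (in_dim, h)),
                                         requires_grad=True)
        params[f"a1s_{head}"] = ad.Tensor(_glorot(rng, (h, 1)),
                                          requires_grad=True)
        params[f"a1d_{head}"] = ad.Tensor(_glorot(rng, (h, 1)),
                                          requires_grad=True)
    params["W2"] = ad.Tensor(_glorot(rng, (h * k, 1)), requires_grad=True)
    params["a2s"] = ad.Tensor(_glorot(rng, (1, 1)), requires_grad=True)
    params["a2d"] = ad.Tensor(_glorot(rng, (1, 1)), requires_grad=True)
    return params


def _attention_head(H: ad.Tensor, a_src: ad.Tensor, a_dst: ad.Tensor,
                    ei: EdgeIndex, slope: float, dropout: float,
                    rng, training: bool,
                    collect_alpha: list | None = None) -> ad.Tensor:
    """One attention head: softmax-normalised neighbour aggregation."""
    s_src = ad.matmul(H, a_src)          # n x 1
    s_dst = ad.matmul(H, a_dst)
    e = ad.leaky_relu(ad.add(ad.gather(s_src, ei.src),
                             ad.gather(s_dst, ei.dst)), slope)
    e = ad.add(e, ad.constant(ei.bias[:, None]))
    # segment softmax over incoming edges of each destination node;
    # the max shift is piecewise constant, so no gradient flows through it
    shift = ad.segment_max(e.data, ei.dst, ei.n_nodes)
    z = ad.exp(ad.add(e, ad.constant(-shift[ei.dst])))
    denom = ad.scatter_sum(z, ei.dst, ei.n_nodes)
    alpha = ad.div(z, ad.gather(denom, ei.dst))
    if collect_alpha is not None:
        collect_alpha.append(alpha.data[:, 0].copy())
    if training and dropout > 0:
        mask = (rng.random(alpha.data.shape) >= dropout) / (1.0 - dropout)
        alpha = ad.mul(alpha, ad.constant(mask))
    msg = ad.mul(alpha, ad.gather(H, ei.src))
    return ad.scatter_sum(msg, ei.dst, ei.n_nodes)


def forward(params: dict, X: np.ndarray, ei: EdgeIndex, config: GATConfig,
            rng: np.random.Generator | None = None, training: bool = False,
            collect_alpha: list | None = None):
    """Full forward pass; returns (hidden Tensor, logits Tensor).

    ``hidden`` is the concatenated multi-head first-layer output after
    ELU — the node embedding used for clustering.
    """
    Xt = ad.constant(X)
    if training and config.dropout > 0:
        mask = (rng.random(X.shape) >= config.dropout) / (1.0 - config.dropout)
        Xt = ad.mul(Xt, ad.constant(mask))
    heads_out = []
    for head in range(config.heads):
        H = ad.matmul(Xt, params[f"W1_{head}"])
        heads_out.append(_attention_head(
            H, params[f"a1s_{head}"], params[f"a1d_{head}"], ei,
            config.leaky_relu_slope, config.dropout, rng, training,
            collect_alpha))
    hidden = ad.elu(ad.concat(heads_out, axis=1))
    h_in = hidden
    if training and config.dropout > 0:
        mask = (rng.random(hidden.data.shape) >= config.dropout) / (1.0 - config.dropout)
        h_in = ad.mul(hidden, ad.constant(mask))
    H2 = ad.matmul(h_in, params["W2"])
    logits = _attention_head(H2, params["a2s"], params["a2d"], ei,
                             config.leaky_relu_slope, config.dropout, rng,
                             training, collect_alpha)
    return hidden, logits


def bce_with_logits(logits: ad.Tensor, idx: np.ndarray, y: np.ndarray,
                    sample_weight: np.ndarray) -> ad.Tensor:
    """Weighted binary cross-entropy on a node subset, numerically stable."""
    z = ad.gather(logits, idx)
    y = np.asarray(y, dtype=np.float64)[:, None]
    w = np.asarray(sample_weight, dtype=np.float64)[:, None]
    w = w / w.sum()
    # BCE(z, y) = softplus(z) - y*z
    per = ad.sub(ad.softplus(z), ad.mul(ad.constant(y), z))
    return ad.tsum(ad.mul(ad.constant(w), per))


def predict_proba(params: dict, X: np.ndarray, ei: EdgeIndex,
                  config: GATConfig) -> np.ndarray:
    """Deterministic (dropout-off) probability per node."""
    _, logits = forward(params, X, ei, config, training=False)
    return 1.0 / (1.0 + np.exp(-logits.data[:, 0]))


def node_embeddings(params: dict, X: np.ndarray, ei: EdgeIndex,
                    config: GATConfig) -> np.ndarray:
    hidden, _ = forward(params, X, ei, config, training=False)
    return hidden.data.copy()


@dataclass
class TrainResult:
    params: dict
    best_epoch: int
    history: list = field(default_factory=list)


def class_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights per sample to counter class imbalance."""
    y = np.asarray(y)
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int(len(y) - y.sum()), 1)
    w = np.where(y == 1, len(y) / (2.0 * n_pos), len(y) / (2.0 * n_neg))
    return w


def train_gat(X: np.ndarray, ei: EdgeIndex, config: GATConfig,
              train_idx: np.ndarray, y_train: np.ndarray,
              val_idx: np.ndarray | None = None,
              y_val: np.ndarray | None = None,
              score_fn=None) -> TrainResult:
    """Full-batch training with Adam and early stopping.

    Early stopping monitors ``score_fn`` (default AUROC) on the
    validation nodes; the parameters from the best epoch are restored.
    Without a validation set the model trains for ``max_epochs``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = init_params(X.shape[1], config, rng)
    opt = ad.Adam(params.values(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    w = class_weights(y_train)
    if score_fn is None:
        from sklearn.metrics import roc_auc_score

        def score_fn(y_true, y_score):
            if len(np.unique(y_true)) < 2:
                return 0.5
            return roc_auc_score(y_true, y_score)

    best_score, best_params, best_epoch = -np.inf, None, 0
    history = []
    bad = 0
    for epoch in range(config.max_epochs):
        _, logits = forward(params, X, ei, config, rng=rng, training=True)
        loss = bce_with_logits(logits, train_idx, y_train, w)
        opt.zero_grad()
        ad.backward(loss)
        opt.step()
        rec = {"epoch": epoch, "loss": float(loss.data)}
        if val_idx is not None and len(val_idx):
            proba = predict_proba(params, X, ei, config)
            s = score_fn(y_val, proba[val_idx])
            rec["val_score"] = s
            if s > best_score + 1e-9:
                best_score, best_epoch, bad = s, epoch, 0
                best_params = {k: v.data.copy() for k, v in params.items()}
            else:
                bad += 1
            if bad >= config.patience:
                history.append(rec)
                break
        history.append(rec)
    if best_params is not None:
        for k, v in params.items():
            v.data = best_params[k]
    return TrainResult(params=params, best_epoch=best_epoch, history=history)
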
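"""Equivariant message-passing scorer for protein–ligand complex graphs.

Each block stacks three submodules:

* an information-aware attention step — neighbourhood-masked multi-head
  self-attention whose logits carry an additive bias projected from the edge
  features;
* an equivariant node/coordinate update,

  .. math::

     m_{ij} &= \\phi_e(h_i, h_j, \\lVert x_i - x_j \\rVert, a_{ij}) \\\\
     x_i'   &= x_i + \\textstyle\\sum_{j \\ne i} (x_i - x_j)\\, \\phi_x(m_{ij}) \\\\
     m_i    &= \\textstyle\\sum_{j \\in N(i)} m_{ij} \\\\
     h_i'   &= \\phi_h(h_i, m_i)

  where :math:`\\phi_e, \\phi_x, \\phi_h` are small MLPs (residual on the node
  update, scalar output for :math:`\\phi_x`);
* an edge update that projects the per-edge attention values back into the
  edge-feature space through two linear modules and adds them residually.

Because coordinates enter only through interatomic distances and the coordinate
update is a weighted sum of difference vectors, the invariant embeddings, the
pooled complex representation and the scalar score are E(3)-invariant while the
coordinate stream is E(3)-equivariant.  The pooled representation taken before
the prediction head (the "penultimate feature") is what downstream efficacy
models consume.

The network is intentionally desk-scale and runs on the package's own autodiff
core; no pretrained weights are shipped — the trunk is pretrained on a
synthetic docking-score regression task and then frozen for feature extraction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat
from .complex_graph import ComplexGraph, ELEMENTS, INTERACTION_TYPES

# ---------------------------------------------------------------------------
# featurization: integer-coded graph attrs -> dense one-hot vectors
# ---------------------------------------------------------------------------

_MAX_DEGREE = 6
_N_DIST_BINS = 16   # 8 Å cutoff at 0.5 Å bins is the widest default grid
_N_KIND_PAIRS = 6

NODE_FEATURE_DIM = len(ELEMENTS) + (_MAX_DEGREE + 1) + 2 + 3 + 6 + 3
EDGE_FEATURE_DIM = 2 + _N_DIST_BINS + _N_KIND_PAIRS + len(INTERACTION_TYPES)

_KINDS = ("protein", "ligand_atom", "aromatic_virtual")


def encode_graph(graph: ComplexGraph):
    """Dense arrays for the scorer: node features, coords, edge index/features."""
    n = len(graph.nodes)
    node_feat = np.zeros((n, NODE_FEATURE_DIM))
    for i, node in enumerate(graph.nodes):
        elem, degree, aromatic, charge, rescls = node.feature
        off = 0
        node_feat[i, off + elem] = 1.0
        off += len(ELEMENTS)
        node_feat[i, off + min(degree, _MAX_DEGREE)] = 1.0
        off += _MAX_DEGREE + 1
        node_feat[i, off + int(bool(aromatic))] = 1.0
        off += 2
        node_feat[i, off + min(max(charge, 0), 2)] = 1.0
        off += 3
        node_feat[i, off + min(rescls, 5)] = 1.0
        off += 6
        node_feat[i, off + _KINDS.index(node.kind)] = 1.0

    m = len(graph.edges)
    src = np.empty(m, dtype=int)
    dst = np.empty(m, dtype=int)
    edge_feat = np.zeros((m, EDGE_FEATURE_DIM))
    for e, edge in enumerate(graph.edges):
        src[e], dst[e] = edge.src, edge.dst
        if edge.channel == "geometric":
            edge_feat[e, 0] = 1.0
            dbin, pair = edge.attr
            edge_feat[e, 2 + min(dbin, _N_DIST_BINS - 1)] = 1.0
            edge_feat[e, 2 + _N_DIST_BINS + pair] = 1.0
        else:
            edge_feat[e, 1] = 1.0
            edge_feat[e, 2 + _N_DIST_BINS + _N_KIND_PAIRS + edge.attr[0]] = 1.0
    return node_feat, graph.coords, src, dst, edge_feat


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

class MLP:
    """Dense ReLU network; linear final layer, optional small-scale output init."""

    def __init__(self, dims: list[int], rng: np.random.Generator, out_scale: float = 1.0):
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for k, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            scale = np.sqrt(2.0 / a)
            if k == len(dims) - 2:
                scale *= out_scale
            self.weights.append(Tensor(rng.normal(0, scale, (a, b)), requires_grad=True))
            self.biases.append(Tensor(np.zeros(b), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ W + b
            if k < len(self.weights) - 1:
                x = x.relu()
        return x

    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases


@dataclass
class ScorerConfig:
    hidden_dim: int = 64       # D: invariant embedding width (= penultimate dim)
    edge_dim: int = 16         # E: learned edge-feature width
    n_layers: int = 3          # T: stacked blocks
    n_heads: int = 4
    seed: int = 0


class ScorerParams:
    """All learnable weights of the scorer, with JSON (text) persistence."""

    def __init__(self, config: ScorerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, E, H = config.hidden_dim, config.edge_dim, config.n_heads
        if D % H:
            raise ValueError("hidden_dim must be divisible by n_heads")
        self.node_embed = MLP([NODE_FEATURE_DIM, D], rng)
        self.edge_embed = MLP([EDGE_FEATURE_DIM, E], rng)
        self.layers: list[dict] = []
        for _ in range(config.n_layers):
            layer = {
                "Wq": Tensor(rng.normal(0, 1 / np.sqrt(D), (D, D)), requires_grad=True),
                "Wk": Tensor(rng.normal(0, 1 / np.sqrt(D), (D, D)), requires_grad=True),
                "Wv": Tensor(rng.normal(0, 1 / np.sqrt(D), (D, D)), requires_grad=True),
                "Wo": Tensor(rng.normal(0, 1 / np.sqrt(D), (D, D)) * 0.1, requires_grad=True),
                "Wbias": Tensor(rng.normal(0, 0.1, (E, H)), requires_grad=True),
                "phi_e": MLP([2 * D + 1 + E, D, D], rng),
                "phi_x": MLP([D, D // 2, 1], rng, out_scale=0.01),
                "phi_h": MLP([2 * D, D, D], rng, out_scale=0.1),
                "edge_proj1": Tensor(rng.normal(0, 0.1, (H, E)), requires_grad=True),
                "edge_proj2": Tensor(rng.normal(0, 0.1, (E, E)), requires_grad=True),
            }
            self.layers.append(layer)
        self.head = MLP([D, 32, 1], rng)

    def parameters(self) -> list[Tensor]:
        out = self.node_embed.parameters() + self.edge_embed.parameters()
        for layer in self.layers:
            for v in layer.values():
                out += v.parameters() if isinstance(v, MLP) else [v]
        return out + self.head.parameters()

    def trunk_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p not in self.head.parameters()]

    # -- persistence (text only) -------------------------------------------
    def save(self, path) -> None:
        blob = {
            "manifest": {"hidden_dim": self.config.hidden_dim,
                         "edge_dim": self.config.edge_dim,
                         "n_layers": self.config.n_layers,
                         "n_heads": self.config.n_heads,
                         "seed": self.config.seed},
            "weights": [p.data.tolist() for p in self.parameters()],
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "ScorerParams":
        with open(path) as fh:
            blob = json.load(fh)
        params = cls(ScorerConfig(**blob["manifest"]))
        for p, w in zip(params.parameters(), blob["weights"], strict=True):
            p.data = np.asarray(w, dtype=np.float64).reshape(p.data.shape)
        return params


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def edge_message(phi_e: MLP, h_dst: Tensor, h_src: Tensor, dist: Tensor, a: Tensor) -> Tensor:
    """m_ij = φ_e(h_i, h_j, ‖x_i − x_j‖, a_ij) — coordinates enter only via the distance."""
    return phi_e(concat([h_dst, h_src, dist, a], axis=1))


def coord_update(phi_x: MLP, x: Tensor, messages: Tensor, src: np.ndarray, dst: np.ndarray) -> Tensor:
    """x_i' = x_i + Σ_j (x_i − x_j) φ_x(m_ij), summed over incoming edges."""
    scale = phi_x(messages)                      # (m, 1)
    diff = x[dst] - x[src]                       # (m, 3)
    delta = (diff * scale).index_add(x.shape[0], dst)
    return x + delta


def aggregate(messages: Tensor, dst: np.ndarray, n_nodes: int) -> Tensor:
    """m_i = Σ_{j∈N(i)} m_ij — permutation-invariant elementwise sum."""
    return messages.index_add(n_nodes, dst)


def node_update(phi_h: MLP, h: Tensor, m: Tensor) -> Tensor:
    """h_i' = φ_h(h_i, m_i) with a residual connection."""
    return h + phi_h(concat([h, m], axis=1))


def _segment_softmax(logits: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Softmax of `logits` (m, H) within segments given by `seg` (per-row ids)."""
    # subtract the per-segment max (constant shift: softmax-invariant, stable)
    seg_max = np.full((n_seg, logits.shape[1]), -np.inf)
    np.maximum.at(seg_max, seg, logits.data)
    e = (logits - Tensor(seg_max[seg])).exp()
    denom = e.index_add(n_seg, seg)
    return e / denom[seg]


def attention_block(layer: dict, h: Tensor, edge_feat: Tensor,
                    src: np.ndarray, dst: np.ndarray, n_heads: int
                    ) -> tuple[Tensor, Tensor]:
    """Neighbourhood-masked multi-head attention with additive edge bias.

    Every node attends to its graph neighbours and itself (so an isolated node
    reduces to identity mixing).  Returns the updated embeddings and the
    attention weights of the *real* edges (m, H) for the edge-update step.
    """
    n, D = h.shape
    H = n_heads
    dh = D // H
    q = (h @ layer["Wq"]).reshape(n, H, dh)
    k = (h @ layer["Wk"]).reshape(n, H, dh)
    v = (h @ layer["Wv"]).reshape(n, H, dh)

    m = len(src)
    self_idx = np.arange(n)
    a_src = np.concatenate([src, self_idx])
    a_dst = np.concatenate([dst, self_idx])
    logits = (q[a_dst] * k[a_src]).sum(axis=2) / np.sqrt(dh)   # (m+n, H)
    bias = edge_feat @ layer["Wbias"]                          # (m, H); self-loops bias 0
    logits = concat([logits[np.arange(m)] + bias, logits[np.arange(m, m + n)]], axis=0)
    w = _segment_softmax(logits, a_dst, n)                     # rows per dst sum to 1
    mixed = (v[a_src] * w.reshape(m + n, H, 1)).index_add(n, a_dst)  # (n, H, dh)
    h_new = h + mixed.reshape(n, D) @ layer["Wo"]
    return h_new, w[np.arange(m)]


def edge_update(layer: dict, edge_feat: Tensor, attn_weights: Tensor) -> Tensor:
    """Project per-edge attention values into edge-feature space; residual add."""
    return edge_feat + (attn_weights @ layer["edge_proj1"]).relu() @ layer["edge_proj2"]


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------

def forward(graph: ComplexGraph, params: ScorerParams):
    """Score one complex.

    Returns ``(score, penultimate, coords_out)``: the scalar head output, the
    pooled pre-head complex representation (mean over ligand + virtual nodes)
    and the final coordinate stream.
    """
    if not graph.ligand_node_ids:
        raise ValueError("graph has no ligand nodes")
    node_feat, coords, src, dst, edge_raw = encode_graph(graph)
    h = params.node_embed(Tensor(node_feat))
    a = params.edge_embed(Tensor(edge_raw))
    x = Tensor(coords)
    n = h.shape[0]
    for layer in params.layers:
        h, attn = attention_block(layer, h, a, src, dst, params.config.n_heads)
        if len(src):
            dvec = x[dst] - x[src]
            dist = ((dvec * dvec).sum(axis=1, keepdims=True) + 1e-12).sqrt()
            msgs = edge_message(layer["phi_e"], h[dst], h[src], dist, a)
            x = coord_update(layer["phi_x"], x, msgs, src, dst)
            m_i = aggregate(msgs, dst, n)
        else:
            m_i = Tensor(np.zeros((n, params.config.hidden_dim)))
        h = node_update(layer["phi_h"], h, m_i)
        if len(src):
            a = edge_update(layer, a, attn)
    pooled = h[np.asarray(graph.ligand_node_ids, dtype=int)].mean(axis=0, keepdims=True)
    score = params.head(pooled)
    return score.reshape(()), pooled.reshape(-1), x


def score_complex(graph: ComplexGraph, params: ScorerParams) -> tuple[float, np.ndarray]:
    """Convenience wrapper returning plain floats/arrays (no gradient tape)."""
    s, pen, _ = forward(graph, params)
    return float(s.data), pen.data.copy()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _bce_with_logits(z: Tensor, y: float) -> Tensor:
    """Numerically stable binary cross-entropy on a raw logit."""
    az = z.relu() + (-z).relu()
    return z.relu() - z * y + (1.0 + (-az).exp()).log()


def train_scorer(graphs: list[ComplexGraph], labels, config: ScorerConfig | None = None,
                 task: str = "classification", epochs: int = 100, lr: float = 1e-3,
                 params: ScorerParams | None = None, trainable: str = "all",
                 ) -> tuple[ScorerParams, list[float]]:
    """Fit the scorer by full-batch Adam; returns params and the loss trajectory.

    `task` selects binary cross-entropy on the logit ("classification") or mean
    squared error ("regression", e.g. pretraining against docking scores).
    `trainable` may be "all" or "head" (frozen-trunk fine-tuning).
    """
    labels = np.asarray(labels, dtype=float)
    if task == "classification" and len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes present")
    if params is None:
        params = ScorerParams(config or ScorerConfig())
    pool = params.parameters() if trainable == "all" else params.head.parameters()
    opt = Adam(pool, lr=lr)
    losses = []
    for _ in range(epochs):
        opt.zero_grad()
        total = None
        for graph, y in zip(graphs, labels):
            z, _, _ = forward(graph, params)
            term = _bce_with_logits(z, y) if task == "classification" else (z - y) ** 2
            total = term if total is None else total + term
        loss = total / len(graphs)
        loss.backward()
        if lr > 0:
            opt.step()
        losses.append(float(loss.data))
    return params, losses
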
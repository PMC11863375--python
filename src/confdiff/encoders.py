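"""The three graph encoders feeding the score model.

* :class:`EdgeEncoder` — per-edge features from (length, type): a linear
  length expansion concatenated with a type embedding, a GeLU MLP,
  element-wise recombination with the type embedding, and a second MLP.
* :class:`GlobalEncoder` — an attention-enhanced continuous-filter
  convolution network: an atom-type embedding followed by interaction
  blocks, each holding two parallel CFConv pathways (128 and 64 filters),
  a learnable shifted-softplus, a sigmoid attention gate, a projection
  back to the 128-wide stream and a residual add; an adaptive
  feature-scaling module (channel scales from mean-pooled context) runs
  in the main loop after every block. Geometry enters only through
  interatomic distances, so node features are rotation/translation
  invariant.
* :class:`LocalEncoder` — a GIN-style message-passing stack over local
  (covalent + 2/3-hop) edges with batch normalization and ReLU after
  every layer but the last, residual recombination and a final two-layer
  MLP.

Distance weighting (used inside CFConv) combines a fixed Gaussian
envelope exp(-d^2 / (2 sigma^2)) with sigma = d_cutoff — hard-zeroed for
d > d_cutoff — with the output of a small learnable network of the
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import (
    BatchNorm, Embedding, Linear, MLP, Module, Parameter, Tensor, concat,
    segment_sum,
)
from .molgraph import EDGE_TYPE_NAMES, EdgeSet

__all__ = [
    "EncoderConfig", "EdgeEncoder", "GlobalEncoder", "LocalEncoder",
    "distance_weight", "LearnedDistanceWeight", "CFConv",
    "InteractionBlock", "AdaptiveScale",
]

N_EDGE_TYPES = len(EDGE_TYPE_NAMES)
MAX_Z = 54  # atomic-number vocabulary (H..Xe); plenty for organic molecules


@dataclass
class EncoderConfig:
    """Widths and depths; defaults are the repo's standard configuration."""

    hidden: int = 128
    n_filters: int = 128          # main CFConv pathway
    n_filters_reduced: int = 64   # reduced CFConv pathway
    n_blocks: int = 6             # interaction blocks in the global encoder
    gin_depth: int = 4            # GIN layers in the local encoder
    cutoff: float = 10.0          # Angstrom; spatial cutoff and envelope sigma
    norm_eval_stats: str = "batch"  # normalization statistics at inference
    length_expansion: str = "linear"  # or "rbf": Gaussian radial basis
    n_rbf: int = 32               # basis size for the rbf option


def distance_weight(d: np.ndarray, d_cutoff: float,
                    learned: np.ndarray | None = None) -> np.ndarray:
    """Gaussian envelope with sigma = d_cutoff, hard zero past the cutoff.

    `learned` (same leading shape as `d`, or None for unit factor) is the
    learnable network's output, combined by element-wise multiplication.
    """
    d = np.asarray(d, dtype=np.float64)
    env = np.exp(-d ** 2 / (2.0 * d_cutoff ** 2)) * (d <= d_cutoff)
    if learned is None:
        return env
    return env * np.asarray(learned, dtype=np.float64)


class LearnedDistanceWeight(Module):
    """Per-filter learnable distance weighting combined with the envelope."""

    def __init__(self, n_filters: int, cutoff: float, rng: np.random.Generator):
        super().__init__()
        self.cutoff = cutoff
        # sigmoid output, zero-init last layer -> starts at 1/2 per channel
        self.net = MLP([1, 16, n_filters], rng, activation="relu",
                       final_activation="sigmoid")

    def __call__(self, lengths: np.ndarray) -> Tensor:
        env = distance_weight(lengths, self.cutoff)  # (E,)
        learned = self.net(Tensor(lengths.reshape(-1, 1)))  # (E, F)
        return learned * env.reshape(-1, 1)


class EdgeEncoder(Module):
    """Encode (length, type) per directed edge into a `hidden`-wide vector.

    The length expansion is a plain linear map by default; the "rbf"
    option featurizes the length with a Gaussian radial basis spanning
    [0, cutoff] before the linear map, giving the network much finer
    distance resolution.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        h = cfg.hidden
        self.type_emb = Embedding(N_EDGE_TYPES, h, rng)
        if cfg.length_expansion == "rbf":
            self.rbf_centers = np.linspace(0.0, cfg.cutoff, cfg.n_rbf)
            self.rbf_width = self.rbf_centers[1] - self.rbf_centers[0]
            self.expand = Linear(cfg.n_rbf, h, rng)
        elif cfg.length_expansion == "linear":
            self.rbf_centers = None
            self.expand = Linear(1, h, rng)
        else:
            raise ValueError(f"unknown length_expansion "
                             f"{cfg.length_expansion!r}")
        self.mlp1 = MLP([2 * h, h, h], rng, activation="gelu")
        self.mlp2 = MLP([h, h], rng)

    def __call__(self, lengths: np.ndarray, types: np.ndarray) -> Tensor:
        types = np.asarray(types)
        if types.size and (types.min() < 0 or types.max() >= N_EDGE_TYPES):
            raise ValueError("edge type outside the fixed vocabulary")
        lengths = np.asarray(lengths, dtype=np.float64).reshape(-1, 1)
        if self.rbf_centers is not None:
            lengths = np.exp(-(lengths - self.rbf_centers) ** 2
                             / (2.0 * self.rbf_width ** 2))
        t_emb = self.type_emb(types)
        x = concat([self.expand(Tensor(lengths)), t_emb], axis=1)
        x = self.mlp1(x)
        x = x * t_emb  # recombination with the chemical type
        return self.mlp2(x)


class CFConv(Module):
    """Continuous-filter convolution with batch-norm and LeakyReLU.

    Node features are projected to the filter width and LeakyReLU-activated
    before message passing; per-edge messages are the sender features gated
    element-wise by the filter network's output and the distance weight,
    sum-aggregated per receiver. Batch normalization stabilizes the
    aggregated feature maps before the atom-wise output layer. (Placing the
    normalization after aggregation keeps the message path alive for
    single-element molecules, whose pre-aggregation node rows are
    identical.)
    """

    def __init__(self, cfg: EncoderConfig, n_filters: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_proj = Linear(cfg.hidden, n_filters, rng)
        self.bn = BatchNorm(n_filters, eval_stats=cfg.norm_eval_stats)
        self.filter_net = MLP([cfg.hidden, n_filters, n_filters], rng,
                              activation="relu")
        self.dist_weight = LearnedDistanceWeight(n_filters, cfg.cutoff, rng)
        self.out_proj = Linear(n_filters, n_filters, rng)

    def __call__(self, h: Tensor, edges: EdgeSet, edge_emb: Tensor,
                 lengths: np.ndarray) -> Tensor:
        x = self.in_proj(h).leaky_relu()
        if len(edges) == 0:
            agg = Tensor(np.zeros((h.shape[0], x.shape[1])))
        else:
            w = self.filter_net(edge_emb) * self.dist_weight(lengths)
            msgs = x.gather(edges.pairs[:, 1]) * w  # sender j -> receiver i
            agg = segment_sum(msgs, edges.pairs[:, 0], h.shape[0])
        return self.out_proj(self.bn(agg))


class ShiftedSoftplus(Module):
    """softplus(x - s) * c with per-channel learnable shift s and scale c."""

    def __init__(self, n_features: int):
        super().__init__()
        self.shift = Parameter(np.zeros(n_features))
        self.scale = Parameter(np.ones(n_features))

    def __call__(self, x: Tensor) -> Tensor:
        return (x - self.shift).softplus() * self.scale


class AttentionGate(Module):
    """Two-layer gate: half-width ReLU layer, then sigmoid weights."""

    def __init__(self, n_features: int, rng: np.random.Generator):
        super().__init__()
        self.lin1 = Linear(n_features, n_features // 2, rng)
        self.lin2 = Linear(n_features // 2, n_features, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu()).sigmoid()


class InteractionBlock(Module):
    """Dual-pathway CFConv block with attention and a residual connection."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cf_main = CFConv(cfg, cfg.n_filters, rng)
        self.cf_reduced = CFConv(cfg, cfg.n_filters_reduced, rng)
        width = cfg.n_filters + cfg.n_filters_reduced
        self.ssp = ShiftedSoftplus(width)
        self.attention = AttentionGate(width, rng)
        self.proj = Linear(width, cfg.hidden, rng)

    def __call__(self, h: Tensor, edges: EdgeSet, edge_emb: Tensor,
                 lengths: np.ndarray) -> Tensor:
        a = self.cf_main(h, edges, edge_emb, lengths)
        b = self.cf_reduced(h, edges, edge_emb, lengths)
        x = concat([a, b], axis=1)
        x = self.ssp(x)
        x = x * self.attention(x)
        return h + self.proj(x)


class AdaptiveScale(Module):
    """Channel-wise scaling from mean-pooled global context.

    The scale is 2*sigmoid(net(context)) per channel; the final layer is
    initialized near zero so scaling starts close to the identity.
    """

    def __init__(self, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.net = MLP([hidden, hidden // 2, hidden], rng, activation="relu")
        self.net.layers[-1].weight.data *= 1e-2

    def __call__(self, h: Tensor) -> Tensor:
        context = h.mean(axis=0, keepdims=True)
        scale = self.net(context).sigmoid() * 2.0
        return h * scale


class GlobalEncoder(Module):
    """Attention-enhanced CFConv stack over all (local + spatial) edges."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.atom_emb = Embedding(MAX_Z + 1, cfg.hidden, rng)
        self.blocks = [InteractionBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.scales = [AdaptiveScale(cfg.hidden, rng) for _ in range(cfg.n_blocks)]

    def __call__(self, atom_numbers: np.ndarray, edges: EdgeSet,
                 edge_emb: Tensor, lengths: np.ndarray,
                 h_extra: Tensor | None = None) -> Tensor:
        h = self.atom_emb(atom_numbers)
        if h_extra is not None:
            h = h + h_extra
        for block, ascale in zip(self.blocks, self.scales):
            h = block(h, edges, edge_emb, lengths)
            h = ascale(h)
        return h


class GINLayer(Module):
    """GIN convolution with edge features: MLP((1+eps)h_i + sum_j relu(h_j + e_ij))."""

    def __init__(self, hidden: int, rng: np.random.Generator,
                 final_bias: bool = True):
        super().__init__()
        # layers feeding a batch-norm drop the final bias (absorbed by it)
        self.mlp = MLP([hidden, hidden, hidden], rng, activation="relu",
                       final_bias=final_bias)
        self.eps = Parameter(np.zeros(1))

    def __call__(self, h: Tensor, edges: EdgeSet, edge_emb: Tensor) -> Tensor:
        if len(edges) == 0:
            agg = Tensor(np.zeros(h.shape))
        else:
            msgs = (h.gather(edges.pairs[:, 1]) + edge_emb).relu()
            agg = segment_sum(msgs, edges.pairs[:, 0], h.shape[0])
        return self.mlp(h * (1.0 + self.eps) + agg)


class LocalEncoder(Module):
    """GIN stack over local edges; coordinate-free except through edge lengths."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.atom_emb = Embedding(MAX_Z + 1, cfg.hidden, rng)
        self.layers = [GINLayer(cfg.hidden, rng,
                                final_bias=(k == cfg.gin_depth - 1))
                       for k in range(cfg.gin_depth)]
        self.norms = [BatchNorm(cfg.hidden, eval_stats=cfg.norm_eval_stats)
                      for _ in range(cfg.gin_depth - 1)]
        self.head = MLP([cfg.hidden, cfg.hidden, cfg.hidden], rng,
                        activation="relu")

    def __call__(self, atom_numbers: np.ndarray, edges: EdgeSet,
                 edge_emb: Tensor, h_extra: Tensor | None = None) -> Tensor:
        h = self.atom_emb(atom_numbers)
        if h_extra is not None:
            h = h + h_extra
        for k, layer in enumerate(self.layers):
            out = layer(h, edges, edge_emb)
            if k < len(self.layers) - 1:
                out = self.norms[k](out).relu()
            h = h + out  # residual recombination
        return self.head(h)
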
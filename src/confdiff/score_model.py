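"""Edge scores and equivariant noise prediction.

Two encoder streams — global (all edges) and local (covalent/hop edges)
— produce node features that a per-stream MLP turns into one scalar
score per directed edge. The symmetric endpoint combination (h_i + h_j,
concatenated with the edge features) guarantees score(i,j) = score(j,i).
Scores become per-atom 3-vectors by pushing/pulling along interatomic
displacement unit vectors:

    g_i = sum_j s_ij * (x_i - x_j) / ||x_i - x_j||,

centered to zero mean. Built this way, the prediction rotates with the
coordinates (SE(3) equivariance with translations removed by centering).

Training computes a separate denoising loss per stream,
L = L_global + lambda * L_local; inference mixes the two gradient fields
as w_g * eps_g + w_l * eps_l. Default mixing weights are 0.5 each so the
mixed prediction matches the per-stream training target's scale.

Time conditioning: a sinusoidal embedding of the step t passed through a
small MLP and added to the node embeddings of both streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autograd import MLP, Module, Tensor, concat, no_grad, segment_sum
from .diffusion import (DivergenceError, NoiseSchedule, forward_sample,
                        zero_center)
from .encoders import EdgeEncoder, EncoderConfig, GlobalEncoder, LocalEncoder
from .molgraph import (EdgeSet, MoleculeGraph, build_local_edges,
                       build_spatial_edges, edge_lengths, merge_edges)

__all__ = ["ScoreModelConfig", "ScoreModel", "scores_to_gradients",
           "save_checkpoint", "load_checkpoint"]

_COINCIDENT_GUARD = 1e-8
_DIVERGENCE_LIMIT = 1e3
CHECKPOINT_VERSION = 1


@dataclass
class ScoreModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    w_global: float = 0.5
    w_local: float = 0.5
    lambda_local: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["encoder"] = dict(self.encoder.__dict__)
        return d

    @staticmethod
    def from_dict(d: dict) -> "ScoreModelConfig":
        d = dict(d)
        d["encoder"] = EncoderConfig(**d["encoder"])
        return ScoreModelConfig(**d)


def scores_to_gradients(scores, coords: np.ndarray, edges: EdgeSet):
    """Convert per-edge scalar scores into centered per-atom 3-vectors.

    Edges with coincident endpoints (length < 1e-8) contribute zero.
    Accepts scores as a Tensor (differentiable path) or plain array.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    is_tensor = isinstance(scores, Tensor)
    if len(edges) == 0:
        zero = np.zeros((n, 3))
        return Tensor(zero) if is_tensor else zero
    i, j = edges.pairs[:, 0], edges.pairs[:, 1]
    disp = coords[i] - coords[j]
    norm = np.linalg.norm(disp, axis=1, keepdims=True)
    safe = norm >= _COINCIDENT_GUARD
    unit = np.where(safe, disp / np.where(safe, norm, 1.0), 0.0)
    if is_tensor:
        contrib = scores.reshape(-1, 1) * unit
        g = segment_sum(contrib, i, n)
        return g - g.mean(axis=0, keepdims=True)
    s = np.asarray(scores, dtype=np.float64).reshape(-1, 1)
    g = np.zeros((n, 3))
    np.add.at(g, i, s * unit)
    return g - g.mean(axis=0, keepdims=True)


def _sinusoidal(t: float, dim: int) -> np.ndarray:
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)]).reshape(1, dim)


class _ScoreHead(Module):
    """MLP over [h_i + h_j, edge features] -> scalar score per directed edge."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.mlp = MLP([2 * hidden, hidden, 1], rng, activation="relu")

    def __call__(self, h: Tensor, edges: EdgeSet, edge_emb: Tensor) -> Tensor:
        hi = h.gather(edges.pairs[:, 0])
        hj = h.gather(edges.pairs[:, 1])
        return self.mlp(concat([hi + hj, edge_emb], axis=1))


class ScoreModel(Module):
    """Full noise-prediction network: encoders, score heads, mixing."""

    def __init__(self, config: ScoreModelConfig | None = None):
        super().__init__()
        self.config = config or ScoreModelConfig()
        cfg = self.config.encoder
        rng = np.random.default_rng(self.config.seed)
        self.edge_encoder = EdgeEncoder(cfg, rng)
        self.global_encoder = GlobalEncoder(cfg, rng)
        self.local_encoder = LocalEncoder(cfg, rng)
        self.score_global = _ScoreHead(cfg.hidden, rng)
        self.score_local = _ScoreHead(cfg.hidden, rng)
        self.time_mlp = MLP([cfg.hidden, cfg.hidden, cfg.hidden], rng,
                            activation="gelu")
        self._local_cache: dict[int, EdgeSet] = {}

    # ------------------------------------------------------------------
    def local_edges(self, graph: MoleculeGraph) -> EdgeSet:
        key = id(graph)
        if key not in self._local_cache:
            if len(self._local_cache) > 256:
                self._local_cache.clear()
            self._local_cache[key] = build_local_edges(graph)
        return self._local_cache[key]

    def _streams(self, graph: MoleculeGraph, xt: np.ndarray, t: int,
                 sched: NoiseSchedule):
        """Both gradient fields (Tensors) for coordinates `xt` at step `t`."""
        sched.check_t(t)
        xt = np.asarray(xt, dtype=np.float64)
        if not np.all(np.isfinite(xt)) or (xt.size and np.abs(xt).max() > _DIVERGENCE_LIMIT):
            raise DivergenceError("coordinates diverged beyond 1e3 A")
        local = self.local_edges(graph)
        spatial = build_spatial_edges(xt, self.config.encoder.cutoff,
                                      exclude=local)
        all_edges = edge_lengths(xt, merge_edges(local, spatial))
        n_local = len(local)
        local_edges = EdgeSet(all_edges.pairs[:n_local],
                              all_edges.types[:n_local],
                              all_edges.is_local[:n_local],
                              all_edges.lengths[:n_local])
        edge_emb = self.edge_encoder(all_edges.lengths, all_edges.types)
        edge_emb_local = edge_emb.gather(np.arange(n_local))
        t_emb = self.time_mlp(
            Tensor(_sinusoidal(float(t), self.config.encoder.hidden)))
        h_g = self.global_encoder(graph.atom_numbers, all_edges, edge_emb,
                                  all_edges.lengths, h_extra=t_emb)
        h_l = self.local_encoder(graph.atom_numbers, local_edges,
                                 edge_emb_local, h_extra=t_emb)
        s_g = self.score_global(h_g, all_edges, edge_emb)
        s_l = self.score_local(h_l, local_edges, edge_emb_local)
        eps_g = scores_to_gradients(s_g, xt, all_edges)
        eps_l = scores_to_gradients(s_l, xt, local_edges)
        return eps_g, eps_l

    def predict_eps(self, graph: MoleculeGraph, xt: np.ndarray, t: int,
                    sched: NoiseSchedule) -> np.ndarray:
        """Mixed noise prediction w_g * eps_g + w_l * eps_l (inference)."""
        with no_grad():
            eps_g, eps_l = self._streams(graph, xt, t, sched)
        return (self.config.w_global * eps_g.data
                + self.config.w_local * eps_l.data)

    def training_loss(self, graph: MoleculeGraph, x0: np.ndarray, t: int,
                      eps: np.ndarray, sched: NoiseSchedule,
                      cfg_gamma: float = 1.0):
        """L = L_global + lambda * L_local (each a denoising MSE Tensor)."""
        xt = forward_sample(x0, t, eps, sched)
        target = zero_center(eps)
        eps_g, eps_l = self._streams(graph, xt, t, sched)
        l_g = ((eps_g - target) ** 2).mean() * cfg_gamma
        l_l = ((eps_l - target) ** 2).mean() * cfg_gamma
        loss = l_g + l_l * self.config.lambda_local
        return loss, float(l_g.data), float(l_l.data)

    def predictor(self, graph: MoleculeGraph, sched: NoiseSchedule):
        """Bound (xt, t) -> eps_hat callable for the sampler."""
        def predict(xt, t):
            return self.predict_eps(graph, xt, t, sched)
        return predict


# ---------------------------------------------------------------------------
# Checkpointing (shared by encoders / score model / trainer)


def save_checkpoint(path: str, model: ScoreModel,
                    extra: dict | None = None) -> None:
    """Single-archive checkpoint with a versioned header."""
    state = model.state_dict()
    header = {
        "version": CHECKPOINT_VERSION,
        "config": model.config.to_dict(),
        "extra": extra or {},
    }
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str) -> tuple[ScoreModel, dict]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version in {path!r}")
        state = {k: data[k] for k in data.files if k != "__header__"}
    model = ScoreModel(ScoreModelConfig.from_dict(header["config"]))
    model.load_state_dict(state)
    model.eval()
    return model, header.get("extra", {})
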
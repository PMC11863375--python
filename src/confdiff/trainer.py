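"""Training loop for the score model.

Each iteration draws a batch of molecules, samples a uniform step t and
Gaussian noise per molecule, accumulates the two-stream denoising loss,
clips the global gradient norm and takes an Adam step (moment
coefficients 0.95/0.999, no weight decay). The validation objective is
evaluated on a fixed noise seed every `val_interval` iterations; a
plateau scheduler multiplies the learning rate by 0.6 after 10
consecutive non-improving validations (min-lr floor 1e-6, strict
improvement comparison).

Presets: batch 64 / clip 10,000 (small molecules) and batch 32 /
clip 30,000 (drug-like molecules).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .diffusion import DiffusionConfig, NoiseSchedule, make_schedule
from .molgraph import MoleculeGraph
from .score_model import ScoreModel, save_checkpoint

__all__ = ["TrainConfig", "TrainState", "Adam", "clip_gradients",
           "PlateauScheduler", "train", "validate"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.95
    beta2: float = 0.999
    weight_decay: float = 0.0
    plateau_factor: float = 0.6
    plateau_patience: int = 10
    min_lr: float = 1e-6
    batch_size: int = 64
    clip_norm: float = 10_000.0
    val_interval: int = 5_000
    val_draws: int = 1
    max_iterations: int = 10_000
    seed: int = 0
    checkpoint_dir: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must be in (0, 1)")
        for name in ("learning_rate", "batch_size", "clip_norm",
                     "val_interval", "max_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def preset(cls, which: str, **overrides) -> "TrainConfig":
        base = {"small": dict(batch_size=64, clip_norm=10_000.0),
                "drug": dict(batch_size=32, clip_norm=30_000.0)}[which]
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainState:
    iteration: int = 0
    lr: float = 1e-3
    best_val: float = np.inf
    plateau_count: int = 0
    history: list[dict] = field(default_factory=list)


class Adam:
    """Adam over the autodiff parameter list; state round-trips exactly."""

    def __init__(self, params, lr: float, beta1: float = 0.95,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.step_count = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.step_count += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.step_count
        bc2 = 1.0 - b2 ** self.step_count
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {"step": self.step_count, "lr": self.lr,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.step_count = int(state["step"])
        self.lr = float(state["lr"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src


def clip_gradients(params, max_norm: float) -> float:
    """Scale all gradients so the global norm is at most `max_norm`.

    Returns the pre-clip global norm.
    """
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class PlateauScheduler:
    """Reduce-on-plateau with strict improvement and a min-lr floor."""

    def __init__(self, optimizer: Adam, factor: float, patience: int,
                 min_lr: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.count = 0

    def step(self, metric: float) -> bool:
        """Record one validation; returns True if the lr was reduced."""
        if metric < self.best:
            self.best = metric
            self.count = 0
            return False
        self.count += 1
        if self.count >= self.patience:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.count = 0
            return True
        return False

    def state_dict(self) -> dict:
        return {"best": self.best, "count": self.count}

    def load_state_dict(self, state: dict) -> None:
        self.best = float(state["best"])
        self.count = int(state["count"])


def validate(model: ScoreModel, dataset: list[MoleculeGraph],
             sched: NoiseSchedule, n_draws: int, seed: int) -> float:
    """Mean training objective with fixed noise seeds (comparable across calls)."""
    if not dataset:
        raise ValueError("validation set is empty")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    was_training = model.training
    model.eval()
    losses = []
    for mi, mol in enumerate(dataset):
        for draw in range(n_draws):
            rng = np.random.default_rng([seed, mi, draw])
            t = int(rng.integers(1, sched.T + 1))
            eps = rng.standard_normal(mol.coords.shape)
            loss, _, _ = model.training_loss(mol, mol.coords, t, eps, sched)
            losses.append(float(loss.data))
    if was_training:
        model.train()
    return float(np.mean(losses))


def _training_step(model: ScoreModel, batch: list[MoleculeGraph],
                   sched: NoiseSchedule, rng: np.random.Generator) -> float:
    model.zero_grad()
    total = 0.0
    scale = 1.0 / len(batch)
    for mol in batch:
        t = int(rng.integers(1, sched.T + 1))
        eps = rng.standard_normal(mol.coords.shape)
        loss, _, _ = model.training_loss(mol, mol.coords, t, eps, sched)
        loss.backward(np.full_like(loss.data, scale))
        total += float(loss.data) * scale
    return total


def train(config: TrainConfig, dataset: list[MoleculeGraph],
          model: ScoreModel,
          diffusion: DiffusionConfig | NoiseSchedule | None = None,
          val_dataset: list[MoleculeGraph] | None = None,
          resume_state: dict | None = None) -> TrainState:
    """Run the training loop; returns the final TrainState.

    `resume_state` (from a previous run's checkpoint extra) restores the
    optimizer, scheduler, RNG and iteration counter bit-exactly.
    """
    if not dataset:
        raise ValueError("training set is empty")
    for mol in dataset:
        if mol.coords is None:
            raise ValueError(f"molecule {mol.name!r} has no coordinates")
    if isinstance(diffusion, NoiseSchedule):
        sched = diffusion
    else:
        sched = make_schedule(diffusion or DiffusionConfig())
    val_dataset = val_dataset or dataset

    opt = Adam(model.parameters(), config.learning_rate, config.beta1,
               config.beta2, weight_decay=config.weight_decay)
    plateau = PlateauScheduler(opt, config.plateau_factor,
                               config.plateau_patience, config.min_lr)
    rng = np.random.default_rng(config.seed)
    state = TrainState(lr=config.learning_rate)

    if resume_state is not None:
        opt.load_state_dict(resume_state["optimizer"])
        plateau.load_state_dict(resume_state["plateau"])
        rng.bit_generator.state = json.loads(resume_state["rng"])
        state.iteration = int(resume_state["iteration"])
        state.best_val = float(resume_state["best_val"])
        state.lr = opt.lr

    model.train()
    log_rows = []
    while state.iteration < config.max_iterations:
        idx = rng.integers(0, len(dataset), size=config.batch_size)
        batch = [dataset[i] for i in idx]
        loss = _training_step(model, batch, sched, rng)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at iteration {state.iteration}")
        grad_norm = clip_gradients(opt.params, config.clip_norm)
        opt.step()
        state.iteration += 1
        state.lr = opt.lr
        log_rows.append({"iteration": state.iteration, "loss": loss,
                         "lr": opt.lr, "grad_norm": grad_norm})

        if state.iteration % config.val_interval == 0:
            val = validate(model, val_dataset, sched, config.val_draws,
                           seed=config.seed + 1)
            plateau.step(val)
            state.lr = opt.lr
            state.best_val = min(state.best_val, val)
            log_rows[-1]["val_loss"] = val
            if config.checkpoint_dir:
                _save(config, model, opt, plateau, rng, state)
    state.history = log_rows
    if config.checkpoint_dir:
        _save(config, model, opt, plateau, rng, state, tag="final")
    if config.log_path:
        import pandas as pd

        pd.DataFrame(log_rows).to_csv(config.log_path, index=False)
    return state


def _save(config: TrainConfig, model: ScoreModel, opt: Adam,
          plateau: PlateauScheduler, rng: np.random.Generator,
          state: TrainState, tag: str | None = None) -> None:
    os.makedirs(config.checkpoint_dir, exist_ok=True)
    name = tag or f"iter{state.iteration:08d}"
    path = os.path.join(config.checkpoint_dir, f"checkpoint_{name}.npz")
    extra = resume_payload(opt, plateau, rng, state)
    # optimizer moments are arrays; store them alongside the model state
    arrays = {}
    for k, m in enumerate(extra["optimizer"].pop("m")):
        arrays[f"opt_m_{k}"] = m
    for k, v in enumerate(extra["optimizer"].pop("v")):
        arrays[f"opt_v_{k}"] = v
    payload = model.state_dict()
    payload.update(arrays)
    hdr_extra = {"train": json.dumps(extra)}
    try:
        np.savez(path, __header__=np.frombuffer(json.dumps({
            "version": 1, "config": model.config.to_dict(),
            "extra": hdr_extra}).encode(), dtype=np.uint8), **payload)
    except OSError as exc:
        raise OSError(f"failed to write checkpoint {path!r}: {exc}") from exc


def resume_payload(opt: Adam, plateau: PlateauScheduler,
                   rng: np.random.Generator, state: TrainState) -> dict:
    return {
        "optimizer": opt.state_dict(),
        "plateau": plateau.state_dict(),
        "rng": json.dumps(rng.bit_generator.state),
        "iteration": state.iteration,
        "best_val": state.best_val,
    }


def load_training_checkpoint(path: str) -> tuple[ScoreModel, dict]:
    """Restore a model plus the resume payload written by `train`."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        state = {k: data[k] for k in data.files if k != "__header__"}
    from .score_model import ScoreModelConfig

    model = ScoreModel(ScoreModelConfig.from_dict(header["config"]))
    opt_m = sorted((k for k in state if k.startswith("opt_m_")),
                   key=lambda s: int(s.split("_")[-1]))
    opt_v = sorted((k for k in state if k.startswith("opt_v_")),
                   key=lambda s: int(s.split("_")[-1]))
    moments = {"m": [state.pop(k) for k in opt_m],
               "v": [state.pop(k) for k in opt_v]}
    model.load_state_dict(state)
    resume = json.loads(header["extra"]["train"])
    resume["optimizer"].update(moments)
    return model, resume
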
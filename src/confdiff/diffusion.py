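"""Denoising-diffusion machinery over atomic coordinates.

The forward process perturbs coordinates with Gaussian noise under a
sigmoidal variance schedule: T values s_t linearly spaced on [-6, 6] give

    beta_t = beta_min + logistic(s_t) * (beta_max - beta_min),

with alpha_t = 1 - beta_t and alpha_bar_t the running product. The closed
form of the t-step marginal is

    X_t = sqrt(alpha_bar_t) * X_0 + sqrt(1 - alpha_bar_t) * eps.

The reverse (denoising) step uses the standard DDPM posterior mean with
predicted noise eps_hat and fixed posterior variance
sigma_t^2 = beta_t * (1 - alpha_bar_{t-1}) / (1 - alpha_bar_t).

Coordinates and injected noise are centroid-subtracted at every step:
removing the unconstrained translational mode keeps the process (and
equivariance checks) well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "DiffusionConfig", "NoiseSchedule", "make_schedule", "zero_center",
    "forward_sample", "reverse_step", "loss_eps", "sample",
    "ScheduleError", "StepError", "DivergenceError",
]


class ScheduleError(ValueError):
    """Invalid schedule configuration."""


class StepError(ValueError):
    """Diffusion step index out of range."""


class DivergenceError(RuntimeError):
    """Non-finite coordinates encountered during sampling."""


@dataclass
class DiffusionConfig:
    """Schedule and objective settings.

    Defaults follow the reference setup: 5000 steps with beta sigmoidal
    between 1e-7 and 2e-3 over s in [-6, 6]; simple objective (gamma = 1);
    posterior variance rule for sigma_t.
    """

    T: int = 5000
    beta_min: float = 1e-7
    beta_max: float = 2e-3
    sigmoid_span: tuple[float, float] = (-6.0, 6.0)
    gamma: float = 1.0  # loss weight; 1 -> simple DDPM objective

    def __post_init__(self):
        if self.T < 1:
            raise ScheduleError("T must be >= 1")
        if not self.beta_min < self.beta_max:
            raise ScheduleError("beta_min must be < beta_max")


@dataclass
class NoiseSchedule:
    """Precomputed per-step arrays, all indexed by t = 1..T via [t-1]."""

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    sigma: np.ndarray = field(init=False)

    def __post_init__(self):
        # posterior variance beta_t * (1 - abar_{t-1}) / (1 - abar_t);
        # abar_0 = 1 makes sigma_1 = 0, matching the noise-free final step.
        abar_prev = np.concatenate(([1.0], self.alpha_bar[:-1]))
        var = self.beta * (1.0 - abar_prev) / (1.0 - self.alpha_bar)
        self.sigma = np.sqrt(var)

    def check_t(self, t: int) -> int:
        t = int(t)
        if not 1 <= t <= self.T:
            raise StepError(f"step t={t} outside [1, {self.T}]")
        return t

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": np.arange(1, self.T + 1), "beta": self.beta,
            "alpha_bar": self.alpha_bar, "sigma": self.sigma,
        })

    def save_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def load_csv(path: str) -> "NoiseSchedule":
        import pandas as pd

        df = pd.read_csv(path)
        beta = df["beta"].to_numpy()
        return NoiseSchedule(len(beta), beta, 1.0 - beta,
                             df["alpha_bar"].to_numpy())


def make_schedule(cfg: DiffusionConfig) -> NoiseSchedule:
    """Build the sigmoidal beta schedule and derived arrays.

    A degenerate T=1 linspace takes the left endpoint of the span.
    """
    lo, hi = cfg.sigmoid_span
    s = np.linspace(lo, hi, cfg.T) if cfg.T > 1 else np.array([lo])
    beta = cfg.beta_min + expit(s) * (cfg.beta_max - cfg.beta_min)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    return NoiseSchedule(cfg.T, beta, alpha, alpha_bar)


def zero_center(x: np.ndarray) -> np.ndarray:
    """Subtract the centroid (zero center-of-mass convention)."""
    x = np.asarray(x, dtype=np.float64)
    return x - x.mean(axis=0, keepdims=True)


def forward_sample(x0: np.ndarray, t: int, eps: np.ndarray,
                   sched: NoiseSchedule) -> np.ndarray:
    """Draw X_t | X_0 from the closed-form marginal (zero-centered)."""
    t = sched.check_t(t)
    x0 = zero_center(x0)
    eps = zero_center(eps)
    if eps.shape != x0.shape:
        raise ValueError("eps must be shaped like x0")
    abar = sched.alpha_bar[t - 1]
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps


def reverse_step(xt: np.ndarray, eps_hat: np.ndarray, t: int,
                 z: np.ndarray | None, sched: NoiseSchedule) -> np.ndarray:
    """One denoising update X_t -> X_{t-1}; the noise term is dropped at t=1."""
    t = sched.check_t(t)
    xt = np.asarray(xt, dtype=np.float64)
    beta = sched.beta[t - 1]
    alpha = sched.alpha[t - 1]
    abar = sched.alpha_bar[t - 1]
    mean = (xt - (beta / np.sqrt(1.0 - abar)) * np.asarray(eps_hat)) / np.sqrt(alpha)
    if t > 1 and z is not None:
        mean = mean + sched.sigma[t - 1] * zero_center(np.asarray(z))
    return zero_center(mean)


def loss_eps(eps_hat: np.ndarray, eps: np.ndarray, t: int | None = None,
             cfg: DiffusionConfig | None = None) -> float:
    """Simple denoising objective: gamma_t * mean squared error on the noise."""
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if eps_hat.shape != eps.shape:
        raise ValueError(
            f"shape mismatch: {eps_hat.shape} vs {eps.shape}")
    gamma = cfg.gamma if cfg is not None else 1.0
    return float(gamma * np.mean((eps - eps_hat) ** 2))


def sample(predict, n_atoms: int, sched: NoiseSchedule,
           rng: np.random.Generator, save_every: int | None = None,
           divergence_limit: float = 1e3):
    """Run the full reverse process from a standard-normal prior.

    Parameters
    ----------
    predict : callable (xt, t) -> eps_hat
        The noise predictor (typically a bound score model).
    save_every : int or None
        If given, every k-th intermediate frame is kept; the returned
        trajectory then has the initial frame, the saved frames, and the
        final frame.

    Returns
    -------
    (final_coords, trajectory) where trajectory is a list of frames
    (empty unless save_every is set; save_every=1 keeps all T+1 frames).
    """
    x = zero_center(rng.standard_normal((n_atoms, 3)))
    traj: list[np.ndarray] = []
    if save_every:
        traj.append(x.copy())
    for t in range(sched.T, 0, -1):
        eps_hat = predict(x, t)
        z = rng.standard_normal(x.shape) if t > 1 else None
        x = reverse_step(x, eps_hat, t, z, sched)
        if not np.all(np.isfinite(x)) or np.abs(x).max() > divergence_limit:
            raise DivergenceError(f"sampling diverged at step t={t}")
        if save_every and ((sched.T - t + 1) % save_every == 0 or t == 1):
            traj.append(x.copy())
    return x, traj
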
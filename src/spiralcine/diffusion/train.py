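"""Denoising score matching training.

The training objective is the sigma^2-weighted DSM loss: draw a discrete
noise level sigma(t_i) uniformly over the schedule, perturb a clean image
x(t) = x0 + sigma*z with standard Gaussian z, and minimize

    E || sigma * s_theta(x(t), sigma) + z ||^2 .

Optimization uses Adam with a linear learning-rate warm-up and an exponential
moving average (EMA) of the parameters; the EMA weights are returned as the
trained score function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .net import ScoreNet
from .schedule import DiffusionSchedule


@dataclass
class TrainConfig:
    """Training hyper-parameters (defaults follow the reference protocol:
    lr 2e-4 reached after a 5000-step linear warm-up, Adam betas 0.9/0.999,
    EMA rate 0.999, batch size 1)."""

    learning_rate: float = 2e-4
    warmup_steps: int = 5000
    beta1: float = 0.9
    beta2: float = 0.999
    ema_rate: float = 0.999
    batch_size: int = 1
    n_steps: int = 2000
    channels: int = 32
    n_hidden: int = 3
    seed: int = 0


def dsm_loss(
    score,
    x0: np.ndarray,
    schedule: DiffusionSchedule,
    rng: np.random.Generator,
    return_parts: bool = False,
):
    """Monte-Carlo DSM loss for a batch of clean 2-channel images.

    x0: (B, 2, H, W). Per sample the loss is the squared norm summed over all
    entries, averaged over the batch; with a zero score its expectation is
    the dimensionality of z.
    """
    x0 = np.asarray(x0, dtype=float)
    b = x0.shape[0]
    i = rng.integers(1, schedule.n_steps + 1, size=b)
    sigma = schedule.sigmas[i]
    z = rng.standard_normal(x0.shape)
    xt = x0 + sigma[:, None, None, None] * z
    if isinstance(score, ScoreNet):
        s = score.forward(xt, sigma)
    else:
        s = np.stack([score(xt[j], sigma[j]) for j in range(b)])
    resid = sigma[:, None, None, None] * s + z
    loss = float((resid**2).sum() / b)
    if return_parts:
        return loss, (xt, sigma, z, resid)
    return loss


class _Adam:
    def __init__(self, params: dict, cfg: TrainConfig) -> None:
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.cfg = cfg

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        c = self.cfg
        lr = c.learning_rate * min(1.0, self.t / max(c.warmup_steps, 1))
        for k in params:
            g = grads[k]
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / (1 - c.beta1**self.t)
            vhat = self.v[k] / (1 - c.beta2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)


@dataclass
class TrainingResult:
    score: ScoreNet  # EMA-averaged network
    loss_history: np.ndarray
    config: TrainConfig
    schedule: DiffusionSchedule


def train_score(
    dataset: np.ndarray,
    schedule: DiffusionSchedule,
    config: TrainConfig,
) -> TrainingResult:
    """Train the score network on a stack of normalized complex frames.

    ``dataset``: (n_frames, H, W) complex or (n_frames, 2, H, W) real
    channels, already normalized so that max |image| is ~1 per frame.
    Deterministic given ``config.seed``.
    """
    data = np.asarray(dataset)
    if np.iscomplexobj(data):
        data = np.stack([data.real, data.imag], axis=1)
    if data.ndim != 4 or data.shape[1] != 2:
        raise ValueError("dataset must be (n, H, W) complex or (n, 2, H, W)")

    rng = np.random.default_rng(config.seed)
    sigma_data = float(np.sqrt((data**2).mean() * 2.0))
    net = ScoreNet(
        channels=config.channels,
        n_hidden=config.n_hidden,
        sigma_data=max(sigma_data, 1e-3),
        seed=config.seed,
    )
    opt = _Adam(net.params, config)
    ema = net.copy_params()
    losses = np.empty(config.n_steps)

    n = data.shape[0]
    for step in range(config.n_steps):
        idx = rng.integers(0, n, size=config.batch_size)
        x0 = data[idx]
        i = rng.integers(1, schedule.n_steps + 1, size=config.batch_size)
        sigma = schedule.sigmas[i]
        z = rng.standard_normal(x0.shape)
        xt = x0 + sigma[:, None, None, None] * z
        s, cache = net.forward(xt, sigma, want_cache=True)
        resid = sigma[:, None, None, None] * s + z
        loss = float((resid**2).sum() / config.batch_size)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged: non-finite loss at step {step} "
                f"(sigma={sigma}, |x0|max={np.abs(x0).max():.3g})"
            )
        losses[step] = loss
        # dL/ds = 2 * sigma * resid / B
        dscore = 2.0 * sigma[:, None, None, None] * resid / config.batch_size
        grads, _ = net.backward(cache, dscore, want_param_grads=True)
        opt.step(net.params, grads)
        r = config.ema_rate
        for k in ema:
            ema[k] = r * ema[k] + (1 - r) * net.params[k]

    net.set_params(ema)
    return TrainingResult(
        score=net, loss_history=losses, config=config, schedule=schedule
    )
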
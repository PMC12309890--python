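"""Variance-exploding noise schedule.

The forward SDE has drift f = 0 and diffusion g(t) = sqrt(d sigma^2/dt) with
the geometric noise scale sigma(t) = sigma_min * (sigma_max/sigma_min)^t on
t in [0, 1]. Discretized at t_i = (i-1)/(N-1), i = 1..N, with the convention
sigma_0 = 0 for the final reverse step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiffusionSchedule:
    sigma_min: float = 0.01
    sigma_max: float = 378.0
    n_steps: int = 2000

    def __post_init__(self) -> None:
        if not (0 < self.sigma_min < self.sigma_max):
            raise ValueError("need 0 < sigma_min < sigma_max")
        if self.n_steps < 2:
            raise ValueError("need at least 2 steps")

    def sigma(self, t) -> np.ndarray:
        """Continuous noise scale sigma(t), t in [0, 1]."""
        return self.sigma_min * (self.sigma_max / self.sigma_min) ** np.asarray(t)

    @property
    def sigmas(self) -> np.ndarray:
        """Discrete scales, index 0..N with sigma_0 = 0 and sigma_i = sigma(t_i)."""
        i = np.arange(1, self.n_steps + 1)
        s = self.sigma((i - 1) / (self.n_steps - 1))
        return np.concatenate([[0.0], s])

    def with_steps(self, n_steps: int) -> "DiffusionSchedule":
        """Same sigma range on a different discretization (e.g. inference)."""
        return DiffusionSchedule(self.sigma_min, self.sigma_max, n_steps)
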
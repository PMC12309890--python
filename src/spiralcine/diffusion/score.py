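"""Score-function interface and the analytic Gaussian oracle.

Complex images travel through the score path as two real channels
(real, imaginary); the conversion is lossless. A score function maps a
2-channel image and a noise scale sigma to the score
``grad_x log p_sigma(x)`` of the noise-perturbed density, and exposes a
vector-Jacobian product so reconstruction can differentiate the data-fidelity
term through the Tweedie denoiser.
"""

from __future__ import annotations

import numpy as np


def complex_to_channels(x: np.ndarray) -> np.ndarray:
    """(H, W) complex -> (2, H, W) real."""
    return np.stack([x.real, x.imag])


def channels_to_complex(x: np.ndarray) -> np.ndarray:
    """(2, H, W) real -> (H, W) complex."""
    return x[0] + 1j * x[1]


class AnalyticGaussianScore:
    """Exact score of a Gaussian prior N(mu, cov).

    For x ~ N(mu, cov) perturbed with noise of scale sigma, the marginal is
    N(mu, cov + sigma^2 I) and the score is -(cov + sigma^2 I)^-1 (x - mu).
    ``cov`` may be a scalar variance (isotropic) or a full (n, n) matrix over
    the flattened 2-channel image.
    """

    kind = "analytic_gaussian"

    def __init__(self, mean: np.ndarray, cov) -> None:
        self.mean = np.asarray(mean, dtype=float)
        self.cov = cov
        self._full = isinstance(cov, np.ndarray) and np.ndim(cov) == 2
        if self._full and cov.shape[0] != self.mean.size:
            raise ValueError("covariance size must match flattened mean")

    def __call__(self, x: np.ndarray, sigma: float) -> np.ndarray:
        d = x - self.mean
        if not self._full:
            return -d / (self.cov + sigma**2)
        n = self.mean.size
        sol = np.linalg.solve(self.cov + sigma**2 * np.eye(n), d.reshape(n))
        return -sol.reshape(x.shape)

    def vjp(self, x: np.ndarray, sigma: float, cotangent: np.ndarray) -> np.ndarray:
        """(ds/dx)^T v; the score is linear so this is -(cov+sigma^2 I)^-1 v."""
        if not self._full:
            return -cotangent / (self.cov + sigma**2)
        n = self.mean.size
        sol = np.linalg.solve(
            (self.cov + sigma**2 * np.eye(n)).T, cotangent.reshape(n)
        )
        return -sol.reshape(x.shape)

    def posterior_mean(self, sigma: float, x: np.ndarray) -> np.ndarray:
        """Closed-form E[x0 | x] for the isotropic case (conjugate Gaussian)."""
        if self._full:
            raise NotImplementedError
        s2, v = sigma**2, self.cov
        return (v * x + s2 * self.mean) / (v + s2)
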
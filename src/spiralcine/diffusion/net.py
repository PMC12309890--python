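"""A compact time-conditioned convolutional score network in pure numpy.

The network estimates the score of noise-perturbed 2-channel (real/imaginary)
images. It uses the standard denoiser parameterization: an inner CNN F is
wrapped with noise-dependent scalings,

    D(x, sigma) = c_skip * x + c_out * F(c_in * x, emb(log sigma)),
    score(x, sigma) = (D(x, sigma) - x) / sigma^2,

with c_in = 1/sqrt(sigma^2 + sd^2), c_skip = sd^2/(sigma^2 + sd^2) and
c_out = sigma*sd/sqrt(sigma^2 + sd^2) (sd = typical data scale). This keeps
activations O(1) over the full geometric sigma range. The sigma conditioning
enters each convolution as a per-channel bias projected from Fourier features
of log sigma. Forward and backward passes are written out explicitly, which
also provides the exact vector-Jacobian product through the score that the
posterior-sampling reconstruction needs.
"""

from __future__ import annotations

import numpy as np


def silu(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return x * s


def silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H, W, C*k*k) patches with zero 'same' padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((b, c, k * k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(b, c * k * k, h, w).transpose(0, 2, 3, 1)


def _col2im(dcols: np.ndarray, c: int, k: int) -> np.ndarray:
    """Adjoint of _im2col: (B, H, W, C*k*k) -> (B, C, H, W)."""
    b, h, w, _ = dcols.shape
    p = k // 2
    d = dcols.transpose(0, 3, 1, 2).reshape(b, c, k * k, h, w)
    out = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + h, j : j + w] += d[:, :, i * k + j]
    return out[:, :, p : p + h, p : p + w]


def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple:
    """w: (C_out, C_in*k*k); returns (y, cols) with y (B, C_out, H, W)."""
    k = int(round(np.sqrt(w.shape[1] // (x.shape[1]))))
    cols = _im2col(x, k)
    y = cols @ w.T + b
    return y.transpose(0, 3, 1, 2), cols


def _conv_backward(
    dy: np.ndarray, cols: np.ndarray, w: np.ndarray, c_in: int
) -> tuple:
    """Returns (dx, dw, db)."""
    k = int(round(np.sqrt(w.shape[1] // c_in)))
    dyf = dy.transpose(0, 2, 3, 1)  # (B, H, W, C_out)
    dw = np.einsum("bhwo,bhwi->oi", dyf, cols)
    db = dyf.sum(axis=(0, 1, 2))
    dcols = dyf @ w
    dx = _col2im(dcols, c_in, k)
    return dx, dw, db


class ScoreNet:
    """Time-conditioned CNN denoiser with explicit backprop."""

    kind = "trained_network"

    def __init__(
        self,
        channels: int = 32,
        n_hidden: int = 3,
        kernel: int = 3,
        emb_features: int = 16,
        emb_dim: int = 32,
        sigma_data: float = 0.5,
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.kernel = kernel
        self.sigma_data = sigma_data
        self.channel_sizes = [2] + [channels] * n_hidden + [2]
        self.freqs = rng.standard_normal(emb_features)  # Fourier features of log sigma
        p: dict[str, np.ndarray] = {}
        p["emb_w"] = rng.standard_normal((emb_dim, 2 * emb_features)) / np.sqrt(
            2 * emb_features
        )
        p["emb_b"] = np.zeros(emb_dim)
        for l in range(len(self.channel_sizes) - 1):
            cin, cout = self.channel_sizes[l], self.channel_sizes[l + 1]
            fan = cin * kernel * kernel
            scale = 0.0 if l == len(self.channel_sizes) - 2 else np.sqrt(2.0 / fan)
            p[f"w{l}"] = scale * rng.standard_normal((cout, fan))
            p[f"b{l}"] = np.zeros(cout)
            p[f"p{l}"] = rng.standard_normal((cout, emb_dim)) / np.sqrt(emb_dim) * 0.1
        self.params = p

    # -- preconditioning coefficients ------------------------------------
    def _coeffs(self, sigma: np.ndarray) -> tuple:
        sd2 = self.sigma_data**2
        s2 = sigma**2
        c_in = 1.0 / np.sqrt(s2 + sd2)
        c_skip = sd2 / (s2 + sd2)
        c_out = sigma * self.sigma_data / np.sqrt(s2 + sd2)
        return c_in, c_skip, c_out

    # -- forward ----------------------------------------------------------
    def forward(self, x: np.ndarray, sigma: np.ndarray, want_cache: bool = False):
        """Score of a batch. x: (B, 2, H, W); sigma: scalar or (B,)."""
        p = self.params
        b = x.shape[0]
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (b,))
        c_in, c_skip, c_out = self._coeffs(sigma)
        u = np.log(sigma)
        feats = np.concatenate(
            [np.cos(np.outer(u, self.freqs)), np.sin(np.outer(u, self.freqs))],
            axis=1,
        )
        emb_pre = feats @ p["emb_w"].T + p["emb_b"]
        emb = silu(emb_pre)

        h = x * c_in[:, None, None, None]
        cache = {"x": x, "sigma": sigma, "h0": h, "feats": feats, "emb_pre": emb_pre,
                 "emb": emb, "c": (c_in, c_skip, c_out), "pre": [], "cols": []}
        n_layers = len(self.channel_sizes) - 1
        for l in range(n_layers):
            y, cols = _conv(h, p[f"w{l}"], p[f"b{l}"])
            y = y + (emb @ p[f"p{l}"].T)[:, :, None, None]
            cache["cols"].append(cols if want_cache else None)
            cache["pre"].append(y if want_cache else None)
            h = silu(y) if l < n_layers - 1 else y
        f_out = h
        d = c_skip[:, None, None, None] * x + c_out[:, None, None, None] * f_out
        score = (d - x) / (sigma**2)[:, None, None, None]
        if want_cache:
            cache["f_out"] = f_out
            return score, cache
        return score

    def __call__(self, x: np.ndarray, sigma: float) -> np.ndarray:
        """Single-image score: x (2, H, W) -> (2, H, W)."""
        return self.forward(x[None], np.asarray([sigma]))[0]

    # -- backward ---------------------------------------------------------
    def backward(
        self,
        cache: dict,
        dscore: np.ndarray,
        want_param_grads: bool = True,
        want_input_grad: bool = False,
    ):
        """Backpropagate a cotangent on the score output.

        Returns (param_grads or None, input_grad or None). The input gradient
        treats sigma as constant (the VJP used by posterior sampling).
        """
        p = self.params
        sigma = cache["sigma"]
        c_in, c_skip, c_out = cache["c"]
        # score = (c_skip*x + c_out*F(c_in*x, emb) - x) / sigma^2
        dd = dscore / (sigma**2)[:, None, None, None]
        dh = c_out[:, None, None, None] * dd  # cotangent on F output
        grads = {k: np.zeros_like(v) for k, v in p.items()} if want_param_grads else None
        demb = 0.0
        n_layers = len(self.channel_sizes) - 1
        for l in range(n_layers - 1, -1, -1):
            if l < n_layers - 1:
                dh = dh * silu_grad(cache["pre"][l])
            if want_param_grads:
                grads[f"p{l}"] += dh.sum(axis=(2, 3)).T @ cache["emb"]
            demb = demb + dh.sum(axis=(2, 3)) @ p[f"p{l}"]
            cin_l = self.channel_sizes[l]
            dh, dw, db = _conv_backward(dh, cache["cols"][l], p[f"w{l}"], cin_l)
            if want_param_grads:
                grads[f"w{l}"] += dw
                grads[f"b{l}"] += db
        if want_param_grads:
            demb_pre = demb * silu_grad(cache["emb_pre"])
            grads["emb_w"] += demb_pre.T @ cache["feats"]
            grads["emb_b"] += demb_pre.sum(axis=0)
        input_grad = None
        if want_input_grad:
            input_grad = (
                dh * c_in[:, None, None, None]
                + dd * (c_skip - 1.0)[:, None, None, None]
            )
        return grads, input_grad

    def vjp(self, x: np.ndarray, sigma: float, cotangent: np.ndarray) -> np.ndarray:
        """(d score/d x)^T v for a single image."""
        _, cache = self.forward(x[None], np.asarray([sigma]), want_cache=True)
        _, g = self.backward(
            cache, cotangent[None], want_param_grads=False, want_input_grad=True
        )
        return g[0]

    # -- parameter utilities ----------------------------------------------
    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    def save(self, path) -> None:
        meta = dict(
            kernel=self.kernel,
            sigma_data=self.sigma_data,
            channel_sizes=np.asarray(self.channel_sizes),
            freqs=self.freqs,
        )
        np.savez(path, **{f"param_{k}": v for k, v in self.params.items()}, **meta)

    @classmethod
    def load(cls, path) -> "ScoreNet":
        d = np.load(path, allow_pickle=False)
        sizes = d["channel_sizes"]
        net = cls(
            channels=int(sizes[1]),
            n_hidden=len(sizes) - 2,
            kernel=int(d["kernel"]),
            sigma_data=float(d["sigma_data"]),
        )
        net.freqs = d["freqs"]
        net.params = {
            k[len("param_") :]: d[k] for k in d.files if k.startswith("param_")
        }
        return net
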
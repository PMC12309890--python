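"""Comparison reconstructions: naive adjoint, l1-TV (ADMM), l1-wavelet
(FISTA), and low-rank plus sparse.

All solvers minimize ``||A x - y||^2 + lambda * psi(x)`` (no 1/2 on the data
term) with the unitary encoding operator A = MFS, matching the convention
that ||A|| <= 1. TV and wavelet reconstructions operate frame by frame (2D);
the low-rank plus sparse model operates on the whole series via the Casorati
matrix (pixels x frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .encoding import EncodingModel


@dataclass
class RegularizedProblem:
    model: EncodingModel
    y: np.ndarray  # gridded multi-coil k-space (nc, N, N)
    lam: float = 0.03
    iterations: int = 40
    normalization_scale: float | None = None  # default: max |naive recon|

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


class SolverDivergence(RuntimeError):
    pass


def recon_naive(y: np.ndarray, model: EncodingModel) -> np.ndarray:
    """Adjoint of A followed by coil combination (A^H already combines)."""
    return model.adjoint(y)


# ---------------------------------------------------------------------------
# total variation via ADMM
# ---------------------------------------------------------------------------

def _grad2d(x: np.ndarray) -> np.ndarray:
    """Forward differences with Neumann boundary (last difference 0)."""
    g = np.zeros((2, *x.shape), dtype=x.dtype)
    g[0, :-1] = x[1:] - x[:-1]
    g[1, :, :-1] = x[:, 1:] - x[:, :-1]
    return g


def _div2d(g: np.ndarray) -> np.ndarray:
    """Negative adjoint of _grad2d (discrete divergence)."""
    d = np.zeros(g.shape[1:], dtype=g.dtype)
    d[0] -= g[0, 0]
    d[1:-1] += g[0, :-2] - g[0, 1:-1]
    d[-1] += g[0, -2]
    d[:, 0] -= g[1, :, 0]
    d[:, 1:-1] += g[1, :, :-2] - g[1, :, 1:-1]
    d[:, -1] += g[1, :, -2]
    return -d


def tv_objective(x: np.ndarray, y: np.ndarray, model: EncodingModel, lam: float) -> float:
    g = _grad2d(x)
    tv = np.sqrt((np.abs(g) ** 2).sum(axis=0)).sum()
    return float(np.linalg.norm(model.forward(x) - y) ** 2 + lam * tv)


def recon_tv(problem: RegularizedProblem, rho: float = 1.0, cg_iters: int = 10) -> np.ndarray:
    """Isotropic 2D total-variation reconstruction by ADMM.

    Splitting z = Dx with augmented-Lagrangian penalty rho; the quadratic
    x-subproblem is solved with a few conjugate-gradient steps. The objective
    is monitored and a >10% increase raises ``SolverDivergence``.
    """
    model, lam = problem.model, problem.lam
    scale = problem.normalization_scale
    if scale is None:
        scale = float(np.abs(recon_naive(problem.y, model)).max()) or 1.0
    y = problem.y / scale

    n = model.grid_matrix
    x = model.adjoint(y)
    z = _grad2d(x)
    u = np.zeros_like(z)

    def normal_op(v: np.ndarray) -> np.ndarray:
        return model.normal(v) - (rho / 2.0) * _div2d(_grad2d(v))

    obj_prev = tv_objective(x, y, model, lam)
    best = x
    for _ in range(problem.iterations):
        # x-step: (A^H A + rho/2 D^H D) x = A^H y + rho/2 D^H (z - u)
        rhs = model.adjoint(y) - (rho / 2.0) * _div2d(z - u)
        x = _cg(normal_op, rhs, x, cg_iters)
        # z-step: grouped soft threshold with threshold lam/rho
        dx = _grad2d(x)
        w = dx + u
        mag = np.sqrt((np.abs(w) ** 2).sum(axis=0, keepdims=True))
        shrink = np.maximum(1.0 - (lam / rho) / np.maximum(mag, 1e-30), 0.0)
        z = shrink * w
        u = u + dx - z
        obj = tv_objective(x, y, model, lam)
        if obj > 1.10 * obj_prev + 1e-8:
            raise SolverDivergence(
                f"TV-ADMM objective increased by more than 10% "
                f"({obj_prev:.4g} -> {obj:.4g})"
            )
        if obj <= obj_prev:
            best = x
        obj_prev = min(obj_prev, obj)
    return best * scale


def _cg(op, b: np.ndarray, x0: np.ndarray, iters: int) -> np.ndarray:
    x = x0.copy()
    r = b - op(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    for _ in range(iters):
        if rs < 1e-30:
            break
        ap = op(p)
        alpha = rs / np.vdot(p, ap).real
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = np.vdot(r, r).real
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


# ---------------------------------------------------------------------------
# wavelet l1 via FISTA
# ---------------------------------------------------------------------------

_WAVELET = "db4"
_WV_LEVELS = 3
_WV_MODE = "periodization"


def _wv_forward(x: np.ndarray) -> tuple:
    level = min(_WV_LEVELS, pywt.dwt_max_level(min(x.shape), _WAVELET))
    coeffs = pywt.wavedec2(x, _WAVELET, level=max(level, 1), mode=_WV_MODE)
    arr, slices = pywt.coeffs_to_array(coeffs)
    return arr, slices


def _wv_inverse(arr: np.ndarray, slices) -> np.ndarray:
    coeffs = pywt.array_to_coeffs(arr, slices, output_format="wavedec2")
    return pywt.waverec2(coeffs, _WAVELET, mode=_WV_MODE)


def soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    """Complex (magnitude) soft threshold, the prox of t*||.||_1."""
    mag = np.abs(v)
    return v * np.maximum(1.0 - t / np.maximum(mag, 1e-30), 0.0)


def _wv_shrink(arr: np.ndarray, slices, t: float) -> np.ndarray:
    """Soft-threshold the detail bands; the coarsest approximation is not
    penalized (so the large-lambda limit keeps the coarse approximation)."""
    out = soft_threshold(arr, t)
    out[slices[0]] = arr[slices[0]]
    return out


def wavelet_objective(
    x: np.ndarray, y: np.ndarray, model: EncodingModel, lam: float
) -> float:
    arr, slices = _wv_forward(x)
    detail = np.abs(arr).sum() - np.abs(arr[slices[0]]).sum()
    return float(np.linalg.norm(model.forward(x) - y) ** 2 + lam * detail)


def recon_wavelet(problem: RegularizedProblem) -> np.ndarray:
    """Orthogonal-wavelet l1 reconstruction by FISTA with monotone restart.

    Gradient of the data term is 2 A^H (A x - y) with Lipschitz constant 2
    (unitary A), so the proximal step soft-thresholds the coefficients at
    lambda/2. Default Daubechies-4, 3 levels, periodized boundary.
    """
    model, lam = problem.model, problem.lam
    scale = problem.normalization_scale
    if scale is None:
        scale = float(np.abs(recon_naive(problem.y, model)).max()) or 1.0
    y = problem.y / scale

    x = model.adjoint(y)
    v = x.copy()
    t = 1.0
    obj_prev = wavelet_objective(x, y, model, lam)
    step = 0.5  # 1/L with L = 2
    for _ in range(problem.iterations):
        g = 2.0 * model.adjoint(model.forward(v) - y)
        arr, slices = _wv_forward(v - step * g)
        x_new = _wv_inverse(_wv_shrink(arr, slices, lam * step), slices)
        obj = wavelet_objective(x_new, y, model, lam)
        if obj > obj_prev:  # monotone restart
            v = x.copy()
            t = 1.0
            g = 2.0 * model.adjoint(model.forward(v) - y)
            arr, slices = _wv_forward(v - step * g)
            x_new = _wv_inverse(_wv_shrink(arr, slices, lam * step), slices)
            obj = wavelet_objective(x_new, y, model, lam)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t**2))
        v = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t, obj_prev = x_new, t_new, min(obj, obj_prev)
    return x * scale


# ---------------------------------------------------------------------------
# low rank plus sparse
# ---------------------------------------------------------------------------

@dataclass
class LowRankSparseSplit:
    low_rank: np.ndarray  # (n_frames, N, N)
    sparse: np.ndarray

    @property
    def series(self) -> np.ndarray:
        return self.low_rank + self.sparse


def svt(mat: np.ndarray, tau: float) -> np.ndarray:
    """Singular value soft-thresholding, the prox of the nuclear norm."""
    u, s, vh = np.linalg.svd(mat, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (u * s) @ vh


def recon_lrs(
    y_series: np.ndarray,
    models: list[EncodingModel],
    lam_l: float = 0.02,
    lam_s: float = 0.02,
    iterations: int = 60,
) -> LowRankSparseSplit:
    """Low-rank plus sparse reconstruction of a dynamic series.

    Alternates singular-value thresholding of the Casorati matrix (pixels x
    frames) of the background, soft-thresholding of the temporal frequencies
    of the residual, and a unit-step gradient data-consistency update.
    Thresholds are relative: lam_l scales the largest initial singular value,
    lam_s the largest initial temporal-frequency magnitude. The series is
    normalized by the maximum of the coil-combined magnitude series.
    """
    nf = y_series.shape[0]
    if nf < 2:
        raise ValueError("low rank + sparse needs at least 2 frames")
    if len(models) != nf:
        raise ValueError("one encoding model per frame required")
    n = models[0].grid_matrix

    m = np.stack([models[f].adjoint(y_series[f]) for f in range(nf)])
    scale = float(np.abs(m).max()) or 1.0
    m = m / scale
    y = y_series / scale

    def casorati(series: np.ndarray) -> np.ndarray:
        return series.reshape(nf, -1).T  # (pixels, frames)

    def uncasorati(mat: np.ndarray) -> np.ndarray:
        return mat.T.reshape(nf, n, n)

    s0 = np.linalg.svd(casorati(m), compute_uv=False)
    tau_l = lam_l * s0[0]
    ft0 = np.fft.fft(m, axis=0) / np.sqrt(nf)
    tau_s = lam_s * np.abs(ft0).max()

    low = m.copy()
    sparse = np.zeros_like(m)
    for _ in range(iterations):
        low = uncasorati(svt(casorati(m - sparse), tau_l))
        ft = np.fft.fft(m - low, axis=0) / np.sqrt(nf)
        sparse = np.fft.ifft(soft_threshold(ft, tau_s), axis=0) * np.sqrt(nf)
        # data consistency: gradient step (step 1, ||A|| = 1)
        ls = low + sparse
        resid = np.stack(
            [models[f].adjoint(models[f].forward(ls[f]) - y[f]) for f in range(nf)]
        )
        m = ls - resid
    return LowRankSparseSplit(low_rank=low * scale, sparse=sparse * scale)
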
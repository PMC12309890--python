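"""Cartesian encoding model A = M F S, GRAPPA operator gridding, and
coil-sensitivity estimation.

Conventions: unitary centered FFT (``fftshift(fft2(ifftshift(x))) / N``);
k-space coordinates in cycles/FOV map to grid index ``k*N + N//2`` (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import KSpaceData, SensitivityMaps


def fft2c(x: np.ndarray) -> np.ndarray:
    """Unitary centered 2D FFT over the last two axes."""
    n = x.shape[-1]
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    ) / n


def ifft2c(y: np.ndarray) -> np.ndarray:
    """Unitary centered 2D inverse FFT over the last two axes."""
    n = y.shape[-1]
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(y, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    ) * n


def coil_combine(coil_images: np.ndarray, maps: SensitivityMaps) -> np.ndarray:
    """Sensitivity-weighted combination sum_i conj(S_i) * x_i."""
    ci = np.asarray(coil_images)
    if ci.shape != maps.maps.shape:
        raise ValueError("coil image / map shape mismatch")
    return (np.conj(maps.maps) * ci).sum(axis=0)


@dataclass
class EncodingModel:
    """The linear MRI operator y = M F S x on a Cartesian grid."""

    maps: SensitivityMaps
    mask: np.ndarray  # (N, N) binary
    grid_matrix: int

    def __post_init__(self) -> None:
        n = self.grid_matrix
        if self.mask.shape != (n, n):
            raise ValueError("mask shape must equal grid_matrix^2")
        if self.maps.maps.shape[-2:] != (n, n):
            raise ValueError("map shape must equal grid_matrix^2")
        self.mask = self.mask.astype(bool)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x (N, N) -> masked multi-coil Cartesian k-space (nc, N, N)."""
        if x.shape != (self.grid_matrix, self.grid_matrix):
            raise ValueError("image shape mismatch")
        return self.mask[None] * fft2c(self.maps.maps * x[None])

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """Masked k-space (nc, N, N) -> coil-combined image (N, N)."""
        if y.shape != self.maps.maps.shape:
            raise ValueError("k-space shape mismatch")
        return coil_combine(ifft2c(self.mask[None] * y), self.maps)

    def normal(self, x: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(x))


class IdentityOperator:
    """A = I on complex images; useful for denoising-style posterior tests."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        return y


# ---------------------------------------------------------------------------
# GRAPPA operator gridding
# ---------------------------------------------------------------------------

class GrogCalibrationError(RuntimeError):
    pass


@dataclass
class GrogKernels:
    """Unit-shift coil-mixing operators along kx and ky and their eigen
    factorizations, used to form fractional-shift powers G^delta."""

    g_x: np.ndarray  # (nc, nc)
    g_y: np.ndarray
    calibration_residual: float
    _eig_x: tuple = None
    _eig_y: tuple = None

    def __post_init__(self) -> None:
        for name in ("x", "y"):
            g = getattr(self, f"g_{name}")
            w, v = np.linalg.eig(g)
            setattr(self, f"_eig_{name}", (np.log(w.astype(complex)), v, np.linalg.inv(v)))

    @property
    def n_coils(self) -> int:
        return self.g_x.shape[0]

    def apply_shift(self, values: np.ndarray, delta: np.ndarray) -> np.ndarray:
        """Apply G_x^dx G_y^dy to coil vectors.

        values: (nc, S); delta: (S, 2) fractional shifts in grid units.
        Vectorized over samples via the eigen decomposition
        G^d = V diag(exp(d*log(lambda))) V^-1.
        """
        out = values
        for axis, (logw, v, vinv) in ((0, self._eig_x), (1, self._eig_y)):
            t = vinv @ out  # (nc, S)
            t = t * np.exp(logw[:, None] * delta[:, axis][None, :])
            out = v @ t
        return out

    def power(self, delta_x: float, delta_y: float) -> np.ndarray:
        """Dense operator G_x^dx G_y^dy (nc, nc), for diagnostics/tests."""
        lx, vx, vix = self._eig_x
        ly, vy, viy = self._eig_y
        gx = vx @ np.diag(np.exp(delta_x * lx)) @ vix
        gy = vy @ np.diag(np.exp(delta_y * ly)) @ viy
        return gy @ gx


def grog_calibrate(calib_kspace: np.ndarray) -> GrogKernels:
    """Fit unit-shift operators from a fully sampled Cartesian block.

    ``calib_kspace``: (nc, ny, nx). Solves min ||G S - T|| where T are the
    one-step-shifted neighbors, separately per axis. Axis order follows the
    grid convention: axis -1 is kx, axis -2 is ky.
    """
    c = np.asarray(calib_kspace, dtype=complex)
    if c.ndim != 3:
        raise ValueError("calibration block must be (nc, ny, nx)")
    nc, ny, nx = c.shape
    if ny < 2 or nx < 2:
        raise GrogCalibrationError("calibration block too small")

    def fit(src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, float]:
        s = src.reshape(nc, -1)
        t = tgt.reshape(nc, -1)
        sh = s @ s.conj().T
        ridge = 1e-9 * np.trace(sh).real / nc
        try:
            g = t @ s.conj().T @ np.linalg.inv(sh + ridge * np.eye(nc))
        except np.linalg.LinAlgError as err:
            raise GrogCalibrationError(f"rank-deficient calibration: {err}")
        resid = np.linalg.norm(g @ s - t) / max(np.linalg.norm(t), 1e-30)
        return g, resid

    g_x, r_x = fit(c[:, :, :-1], c[:, :, 1:])
    g_y, r_y = fit(c[:, :-1, :], c[:, 1:, :])
    resid = max(r_x, r_y)
    if resid > 0.5:
        raise GrogCalibrationError(
            f"calibration failed: relative residual {resid:.3f}"
        )
    return GrogKernels(g_x=g_x, g_y=g_y, calibration_residual=resid)


def grog_self_calibrate(
    raw: KSpaceData,
    grid_matrix: int,
    max_step: float = 0.8,
    sv_cap: float = 1.5,
) -> GrogKernels:
    """Self-calibrating GROG: fit the shift-operator generators directly
    from consecutive raw samples along each spiral arm.

    Consecutive readout samples are related by a small known k-space shift
    delta, so ``y(k+delta) ~= expm(dx*Lx + dy*Ly) y(k)``; with the midpoint
    (Crank-Nicolson) form this is linear in the generators and second-order
    accurate. Frames that share a trajectory (repeated patterns within a
    block) are averaged first, which suppresses measurement noise without
    mixing inconsistent geometry. Unit-shift operators are obtained as
    expm(L); their singular values are capped at ``sv_cap`` to bound noise
    amplification by fractional powers.
    """
    from scipy.linalg import expm

    n = grid_matrix
    # group frames by identical trajectory (same pattern rotation)
    groups: dict[bytes, list[int]] = {}
    for f in range(raw.n_frames):
        sel = raw.frame_samples(f)
        key = np.round(raw.traj[sel[: min(50, sel.size)]], 9).tobytes()
        groups.setdefault(key, []).append(f)

    s_list, d_list, step_list = [], [], []
    for frames in groups.values():
        sels = [raw.frame_samples(f) for f in frames]
        ks = np.mean([raw.kspace[:, s] for s in sels], axis=0)
        traj = raw.traj[sels[0]]
        arm = raw.arm_index[sels[0]]
        u = traj * n
        j = np.flatnonzero(np.diff(arm) == 0)
        d = u[j + 1] - u[j]
        step = np.hypot(d[:, 0], d[:, 1])
        keep = (step <= max_step) & (step > 1e-6)
        j, d = j[keep], d[keep]
        s_list.append(0.5 * (ks[:, j] + ks[:, j + 1]))
        d_list.append(ks[:, j + 1] - ks[:, j])
        step_list.append(d)
    s = np.concatenate(s_list, axis=1)
    dif = np.concatenate(d_list, axis=1)
    d = np.concatenate(step_list, axis=0)
    if s.shape[1] < 4 * s.shape[0]:
        raise GrogCalibrationError("too few sample pairs for self-calibration")

    nc = s.shape[0]
    u_mat = np.concatenate([d[:, 0][None, :] * s, d[:, 1][None, :] * s], axis=0)
    gram = u_mat @ u_mat.conj().T
    ridge = 1e-9 * np.trace(gram).real / (2 * nc)
    w = dif @ u_mat.conj().T @ np.linalg.inv(gram + ridge * np.eye(2 * nc))
    resid = float(np.linalg.norm(w @ u_mat - dif) / np.linalg.norm(dif))

    def cap(g: np.ndarray) -> np.ndarray:
        uu, sv, vh = np.linalg.svd(g)
        return (uu * np.minimum(sv, sv_cap)) @ vh

    return GrogKernels(
        g_x=cap(expm(w[:, :nc])),
        g_y=cap(expm(w[:, nc:])),
        calibration_residual=resid,
    )


def grog_grid(
    raw: KSpaceData | tuple,
    kernels: GrogKernels,
    grid_matrix: int,
    sample_sel: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shift off-grid samples to their nearest Cartesian grid points.

    Returns (gridded k-space (nc, N, N), mask (N, N), hit counts (N, N)).
    Collisions are averaged arithmetically. ``sample_sel`` restricts gridding
    to a subset of samples (e.g. one frame).
    """
    if isinstance(raw, tuple):
        kspace, traj = raw
    else:
        kspace, traj = raw.kspace, raw.traj
    if sample_sel is not None:
        kspace = kspace[:, sample_sel]
        traj = traj[sample_sel]
    if kspace.shape[1] == 0:
        raise ValueError("no samples to grid")
    n = grid_matrix
    u = traj * n + n // 2  # continuous grid coordinates (x, y)
    g = np.rint(u)
    delta = g - u  # shift to apply, |delta| <= 0.5
    if np.abs(delta).max() > 0.5 + 1e-9:
        raise ValueError("shift exceeds half a grid unit")
    shifted = kernels.apply_shift(kspace, delta)

    gx = g[:, 0].astype(int)
    gy = g[:, 1].astype(int)
    ok = (gx >= 0) & (gx < n) & (gy >= 0) & (gy < n)
    gx, gy, shifted = gx[ok], gy[ok], shifted[:, ok]

    grid = np.zeros((kspace.shape[0], n, n), dtype=complex)
    counts = np.zeros((n, n))
    np.add.at(counts, (gy, gx), 1.0)
    for c in range(kspace.shape[0]):
        np.add.at(grid[c], (gy, gx), shifted[c])
    nz = counts > 0
    grid[:, nz] /= counts[nz]
    return grid, nz, counts


def grog_grid_frames(
    raw: KSpaceData, kernels: GrogKernels, grid_matrix: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame GROG gridding: returns (n_frames, nc, N, N) and masks."""
    nf = raw.n_frames
    grids = np.zeros((nf, raw.n_coils, grid_matrix, grid_matrix), dtype=complex)
    masks = np.zeros((nf, grid_matrix, grid_matrix), dtype=bool)
    for f in range(nf):
        sel = raw.frame_samples(f)
        grids[f], masks[f], _ = grog_grid(raw, kernels, grid_matrix, sample_sel=sel)
    return grids, masks


def convolution_grid_average(
    raw: KSpaceData,
    grid_matrix: int,
    width: int = 4,
    beta: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser-Bessel convolution gridding of all samples (temporal average).

    Each sample is spread onto its ``width x width`` grid neighborhood with
    Kaiser-Bessel weights and the accumulation is normalized by the summed
    weights (sampling-density compensation a la Jackson). Used to obtain a
    clean Cartesian calibration region for GROG kernel fitting; the GROG path
    itself never interpolates. Returns (gridded k-space, weight sums).
    """
    from scipy.special import i0

    n = grid_matrix
    if beta is None:
        beta = np.pi * width / 2.0  # standard choice for moderate oversampling
    u = raw.traj * n + n // 2  # continuous grid coordinates (x, y)
    half = width / 2.0
    offs = np.arange(-(width // 2) + 1, width // 2 + 1)

    def kb(d: np.ndarray) -> np.ndarray:
        arg = 1.0 - (d / half) ** 2
        out = np.where(arg > 0, i0(beta * np.sqrt(np.clip(arg, 0, None))), 0.0)
        return out / i0(beta)

    grid = np.zeros((raw.n_coils, n, n), dtype=complex)
    wsum = np.zeros((n, n))
    base = np.floor(u).astype(int)
    frac = u - base
    for oy in offs:
        wy = kb(oy - frac[:, 1])
        gy = base[:, 1] + oy
        for ox in offs:
            wx = kb(ox - frac[:, 0])
            gx = base[:, 0] + ox
            w = wx * wy
            ok = (gx >= 0) & (gx < n) & (gy >= 0) & (gy < n) & (w > 0)
            np.add.at(wsum, (gy[ok], gx[ok]), w[ok])
            for c in range(raw.n_coils):
                np.add.at(grid[c], (gy[ok], gx[ok]), w[ok] * raw.kspace[c, ok])
    nz = wsum > 1e-12
    grid[:, nz] /= wsum[nz]
    return grid, wsum


def naive_grid_average(
    raw: KSpaceData, grid_matrix: int
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-grid-point accumulation of all samples (temporal average),
    averaging by hit count. Used to bootstrap GROG calibration."""
    n = grid_matrix
    u = raw.traj * n + n // 2
    gx = np.rint(u[:, 0]).astype(int)
    gy = np.rint(u[:, 1]).astype(int)
    ok = (gx >= 0) & (gx < n) & (gy >= 0) & (gy < n)
    grid = np.zeros((raw.n_coils, n, n), dtype=complex)
    counts = np.zeros((n, n))
    np.add.at(counts, (gy[ok], gx[ok]), 1.0)
    for c in range(raw.n_coils):
        np.add.at(grid[c], (gy[ok], gx[ok]), raw.kspace[c, ok])
    nz = counts > 0
    grid[:, nz] /= counts[nz]
    return grid, counts


def calibration_block(
    avg_kspace: np.ndarray, counts: np.ndarray, size: int, fill: bool = True
) -> np.ndarray:
    """Central block of a temporal-average k-space for GROG calibration.

    Isolated uncovered points (nearest-neighbor accumulation leaves holes
    between spiral turns) are filled by iterative 3x3 neighbor averaging when
    ``fill`` is enabled; a block that cannot be filled raises."""
    n = avg_kspace.shape[-1]
    lo, hi = n // 2 - size // 2, n // 2 + (size + 1) // 2
    block = avg_kspace[:, lo:hi, lo:hi].copy()
    covered = counts[lo:hi, lo:hi] > 0
    if np.all(covered):
        return block
    if not fill:
        raise GrogCalibrationError(
            f"central {size}x{size} region is not fully covered"
        )
    for _ in range(size):
        if np.all(covered):
            break
        newly = np.zeros_like(covered)
        fillval = np.zeros_like(block)
        for gy in range(size):
            for gx in range(size):
                if covered[gy, gx]:
                    continue
                ys, xs = slice(max(gy - 1, 0), gy + 2), slice(max(gx - 1, 0), gx + 2)
                w = covered[ys, xs]
                if w.sum() >= 3:
                    fillval[:, gy, gx] = block[:, ys, xs][:, w].mean(axis=1)
                    newly[gy, gx] = True
        if not newly.any():
            raise GrogCalibrationError(
                f"central {size}x{size} region has unfillable holes"
            )
        block[:, newly] = fillval[:, newly]
        covered |= newly
    return block


def estimate_sensitivities(
    avg_kspace: np.ndarray,
    calib_size: int = 24,
    support_threshold: float = 0.05,
) -> SensitivityMaps:
    """Low-resolution sensitivity estimate from a temporal-average k-space.

    The central ``calib_size`` region is apodized (Hamming), transformed to
    image space, and divided by its root-sum-of-squares; the result is
    RSS-normalized on the support (RSS > 5% of max) and phase-referenced to
    the first coil. A deliberately simple stand-in for eigen-decomposition
    calibration: recovery tests only need smooth, consistent maps.
    """
    nc, n, _ = avg_kspace.shape
    w1 = np.hamming(calib_size)
    win = np.zeros((n, n))
    lo = n // 2 - calib_size // 2
    win[lo : lo + calib_size, lo : lo + calib_size] = np.outer(w1, w1)
    lowres = ifft2c(avg_kspace * win[None])
    rss = np.sqrt((np.abs(lowres) ** 2).sum(axis=0))
    support = rss > support_threshold * rss.max()
    maps = np.zeros_like(lowres)
    maps[:, support] = lowres[:, support] / rss[support]
    ref = maps[0]
    phase = np.ones_like(ref)
    nzref = np.abs(ref) > 1e-12
    phase[nzref] = np.conj(ref[nzref]) / np.abs(ref[nzref])
    maps = maps * phase[None]
    return SensitivityMaps(maps)
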
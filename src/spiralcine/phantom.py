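"""Synthetic dynamic cardiac phantom and spiral acquisition simulator.

The phantom is a short-axis left-ventricle stand-in: a bright blood pool
(bSSFP-like blood >> myocardium contrast) inside a myocardial annulus,
embedded in a torso ellipse. The endocardial radius follows a sinusoidal
contraction program between its diastolic and systolic values; the epicardial
border conserves the annulus area (near-incompressible myocardium). Optional
respiratory drift translates the whole scene in-plane.

The acquisition simulator evaluates the non-uniform Fourier transform of the
coil-weighted images by exact type-2 discrete summation, so it contains no
gridding approximation and can serve as an independent oracle for the
reconstruction chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import AcquisitionSchedule, SpiralArm


@dataclass
class CineSeries:
    """A complex image time series with geometry metadata."""

    frames: np.ndarray  # (n_frames, matrix, matrix) complex
    pixel_spacing_mm: float
    slice_thickness_mm: float
    frame_duration_ms: float
    normalization_scale: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must be (n_frames, matrix, matrix)")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.normalization_scale <= 0:
            raise ValueError("normalization_scale must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def matrix(self) -> int:
        return self.frames.shape[1]


@dataclass
class PhantomSpec:
    """Geometry, contrast and motion program of the synthetic phantom.

    Intensities are arbitrary units chosen to mimic bSSFP contrast
    (blood >> myocardium > background tissue > air).
    """

    matrix: int = 96
    fov_mm: float = 300.0
    heart_period_ms: float = 900.0
    endo_radius_diastole_mm: float = 24.0
    endo_radius_systole_mm: float = 15.2  # ~60% ejection fraction by area
    epi_radius_mm: float = 32.0  # at diastole; tracks area conservation
    blood_intensity: float = 1.0
    myocardium_intensity: float = 0.28
    background_intensity: float = 0.12
    slice_thickness_mm: float = 8.0
    respiratory_amplitude_mm: float = 0.0
    respiratory_period_ms: float = 3000.0
    noise_sigma: float = 0.0  # relative to max |signal|, used by the simulator
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.endo_radius_systole_mm
            < self.endo_radius_diastole_mm
            < self.epi_radius_mm
        ):
            raise ValueError("need endo_systole < endo_diastole < epi_radius")
        for v in (
            self.blood_intensity,
            self.myocardium_intensity,
            self.background_intensity,
        ):
            if v < 0:
                raise ValueError("intensities must be non-negative")

    @property
    def analytic_ef_percent(self) -> float:
        """Single-slice area ejection fraction of the radius program."""
        ratio = self.endo_radius_systole_mm / self.endo_radius_diastole_mm
        return 100.0 * (1.0 - ratio**2)


@dataclass
class SensitivityMaps:
    maps: np.ndarray  # (n_coils, matrix, matrix) complex

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.maps.ndim != 3:
            raise ValueError("maps must be (n_coils, matrix, matrix)")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))


@dataclass
class KSpaceData:
    """Raw multi-coil samples with trajectory coordinates and timestamps."""

    kspace: np.ndarray  # (n_coils, n_samples) complex
    traj: np.ndarray  # (n_samples, 2) cycles/FOV in [-0.5, 0.5)
    timestamps_ms: np.ndarray  # (n_samples,)
    arm_index: np.ndarray  # (n_samples,)
    frame_index: np.ndarray  # (n_samples,)
    frame_duration_ms: float
    maps: SensitivityMaps | None = None

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[0]

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.max()) + 1

    def frame_samples(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.frame_index == f)


def _coverage(dist: np.ndarray, radius: float, soft_px: float) -> np.ndarray:
    """Smooth indicator of dist <= radius with a soft edge of ~soft_px pixels."""
    if soft_px <= 0:
        return (dist <= radius).astype(float)
    return np.clip(0.5 + (radius - dist) / (2.0 * soft_px), 0.0, 1.0)


def _phantom_frame(
    spec: PhantomSpec, t_ms: float, soft_px: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """One frame (complex image) and the blood-pool coverage mask at time t."""
    n = spec.matrix
    dx = spec.fov_mm / n
    ii = (np.arange(n) - n // 2) * dx
    yy, xx = np.meshgrid(ii, ii, indexing="ij")

    # respiratory in-plane translation (exact, evaluated in the geometry)
    shift = spec.respiratory_amplitude_mm * np.sin(
        2.0 * np.pi * t_ms / spec.respiratory_period_ms
    )
    xs, ys = xx - shift, yy - 0.3 * shift

    phase_c = 2.0 * np.pi * t_ms / spec.heart_period_ms
    contraction = 0.5 * (1.0 - np.cos(phase_c))  # 0 at diastole, 1 at systole
    r_endo = (
        spec.endo_radius_diastole_mm
        - (spec.endo_radius_diastole_mm - spec.endo_radius_systole_mm) * contraction
    )
    # myocardium conserves annulus area
    ring_area = spec.epi_radius_mm**2 - spec.endo_radius_diastole_mm**2
    r_epi = np.sqrt(r_endo**2 + ring_area)

    r_lv = np.hypot(xs, ys)
    torso = _coverage(
        np.hypot(xs / (0.45 * spec.fov_mm), ys / (0.38 * spec.fov_mm)), 1.0, 0.01
    )
    epi = _coverage(r_lv, r_epi, soft_px * dx)
    endo = _coverage(r_lv, r_endo, soft_px * dx)
    # a static bright vessel (descending aorta stand-in) for texture
    r_ao = np.hypot(xs - 0.22 * spec.fov_mm, ys + 0.10 * spec.fov_mm)
    aorta = _coverage(r_ao, 0.04 * spec.fov_mm, soft_px * dx)

    img = (
        spec.background_intensity * torso
        + (spec.myocardium_intensity - spec.background_intensity) * epi
        + (spec.blood_intensity - spec.myocardium_intensity) * endo
        + (spec.blood_intensity - spec.background_intensity) * aorta * (1 - epi)
    )
    # smooth low-order phase makes the object genuinely complex
    ph = 0.4 * np.pi * (xs / spec.fov_mm) + 0.25 * np.pi * (ys / spec.fov_mm) ** 2
    frame = img * np.exp(1j * ph)

    # blood-pool coverage by exact subpixel counting (volumetry ground truth)
    ss = 8
    fine = ((np.arange(n * ss) + 0.5) / ss - 0.5 - n // 2) * dx
    fy, fx = np.meshgrid(fine, fine, indexing="ij")
    inside = (np.hypot(fx - shift, fy - 0.3 * shift) <= r_endo).astype(float)
    mask = inside.reshape(n, ss, n, ss).mean(axis=(1, 3))
    return frame, mask


def make_cine_phantom(
    spec: PhantomSpec,
    n_frames: int,
    frame_duration_ms: float = 48.0,
    timestamps_ms: np.ndarray | None = None,
) -> tuple[CineSeries, np.ndarray]:
    """Generate the beating phantom.

    Returns the complex cine series and per-frame blood-pool masks (float
    pixel-coverage fractions in [0, 1], suitable for sub-pixel volumetry).
    If ``timestamps_ms`` is given it overrides the uniform frame timing.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if timestamps_ms is None:
        timestamps_ms = np.arange(n_frames) * frame_duration_ms
    frames = np.empty((n_frames, spec.matrix, spec.matrix), dtype=complex)
    masks = np.empty((n_frames, spec.matrix, spec.matrix), dtype=float)
    for f, t in enumerate(np.asarray(timestamps_ms, dtype=float)):
        frames[f], masks[f] = _phantom_frame(spec, t)
    return (
        CineSeries(
            frames=frames,
            pixel_spacing_mm=spec.fov_mm / spec.matrix,
            slice_thickness_mm=spec.slice_thickness_mm,
            frame_duration_ms=frame_duration_ms,
        ),
        masks,
    )


def make_cine_for_schedule(
    spec: PhantomSpec, schedule: AcquisitionSchedule
) -> tuple[CineSeries, np.ndarray]:
    """Phantom frames evaluated at the schedule's frame timestamps."""
    ts = np.array([e.timestamp_ms for e in schedule.entries])
    return make_cine_phantom(
        spec, len(ts), schedule.frame_duration_ms, timestamps_ms=ts
    )


def make_coil_maps(
    n_coils: int,
    matrix: int,
    seed: int = 0,
    uniform_single: bool = False,
) -> SensitivityMaps:
    """Smooth complex coil sensitivities: Gaussian-profiled coils on a ring
    with linear + mildly random smooth phase. Deterministic given the seed."""
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if uniform_single:
        if n_coils != 1:
            raise ValueError("uniform_single requires n_coils == 1")
        return SensitivityMaps(np.ones((1, matrix, matrix), dtype=complex))
    rng = np.random.default_rng(seed)
    ii = (np.arange(matrix) - matrix // 2) / matrix
    yy, xx = np.meshgrid(ii, ii, indexing="ij")
    maps = np.empty((n_coils, matrix, matrix), dtype=complex)
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils + rng.normal(0, 0.05)
        cx, cy = 0.55 * np.cos(ang), 0.55 * np.sin(ang)
        width = 0.45 * (1.0 + 0.1 * rng.normal())
        mag = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * width**2))
        ph = (
            2.0 * np.pi * (rng.normal(0, 0.3) * xx + rng.normal(0, 0.3) * yy)
            + rng.uniform(0, 2 * np.pi)
        )
        maps[c] = mag * np.exp(1j * ph)
    return SensitivityMaps(maps)


def nudft2(
    image: np.ndarray, coords: np.ndarray, *, adjoint: bool = False
) -> np.ndarray:
    """Exact type-2 non-uniform DFT at normalized coordinates (cycles/FOV).

    Matches the unitary centered FFT convention on grid points: with
    ``coords = (grid_index - N//2) / N`` the output equals
    ``fftshift(fft2(ifftshift(x))) / N``.
    """
    n = image.shape[-1]
    idx = np.arange(n) - n // 2
    ex = np.exp(-2j * np.pi * coords[:, 0:1] * idx[None, :])  # (S, N)
    ey = np.exp(-2j * np.pi * coords[:, 1:2] * idx[None, :])
    if not adjoint:
        # y_s = (1/N) sum_{r,c} x[r,c] ey[s,r] ex[s,c]  (row=y, col=x)
        return np.einsum("sr,rc,sc->s", ey, image, ex) / n
    raise NotImplementedError("use the encoding module for adjoint gridding")


def simulate_acquisition(
    cine: CineSeries,
    maps: SensitivityMaps,
    schedule: AcquisitionSchedule,
    arms: list[SpiralArm],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> KSpaceData:
    """Simulate the noisy multi-coil spiral acquisition y = A x + n.

    For each scheduled frame the coil-weighted image is sampled by exact
    discrete Fourier summation at the rotated arm coordinates; complex
    Gaussian noise with sd ``noise_sigma * max|signal|`` is added.
    """
    if cine.n_frames != schedule.n_frames:
        raise ValueError(
            f"cine has {cine.n_frames} frames but schedule has {schedule.n_frames}"
        )
    base = arms[0]
    if np.abs(base.k_samples).max() >= 0.5:
        raise ValueError("arm coordinates must lie within [-0.5, 0.5)^2")
    n_arms = len(arms)
    n_samp_arm = base.n_readout
    n = cine.matrix
    nc = maps.n_coils
    samples_per_frame = n_arms * n_samp_arm
    total = schedule.n_frames * samples_per_frame

    kspace = np.empty((nc, total), dtype=complex)
    traj = np.empty((total, 2))
    timestamps = np.empty(total)
    arm_idx = np.empty(total, dtype=int)
    frame_idx = np.empty(total, dtype=int)

    # group frames by pattern rotation so the DFT matrix is built once per set
    by_rot: dict[float, list] = {}
    for e in schedule.entries:
        by_rot.setdefault(round(e.rotation, 12), []).append(e)

    idxg = np.arange(n) - n // 2
    smaps = maps.maps
    for rot, entries in by_rot.items():
        angles = entries[0].arm_angles
        coords = np.concatenate(
            [
                base.k_samples
                @ np.array(
                    [[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]]
                )
                for a in angles
            ]
        )  # row-vector rotation by +a
        ex = np.exp(-2j * np.pi * coords[:, 0:1] * idxg[None, :])
        ey = np.exp(-2j * np.pi * coords[:, 1:2] * idxg[None, :])
        for e in entries:
            x = cine.frames[e.frame_index]
            cx = smaps * x[None]  # (nc, N, N)
            tmp = np.einsum("sr,nrc->nsc", ey, cx)
            y = np.einsum("nsc,sc->ns", tmp, ex) / n
            lo = e.frame_index * samples_per_frame
            sl = slice(lo, lo + samples_per_frame)
            kspace[:, sl] = y
            traj[sl] = coords
            timestamps[sl] = e.timestamp_ms
            arm_idx[sl] = np.repeat(np.arange(n_arms), n_samp_arm)
            frame_idx[sl] = e.frame_index

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sigma * np.abs(kspace).max()
        kspace = kspace + sd * (
            rng.standard_normal(kspace.shape)
            + 1j * rng.standard_normal(kspace.shape)
        )

    return KSpaceData(
        kspace=kspace,
        traj=traj,
        timestamps_ms=timestamps,
        arm_index=arm_idx,
        frame_index=frame_idx,
        frame_duration_ms=schedule.frame_duration_ms,
        maps=maps,
    )
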
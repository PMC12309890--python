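"""Spiral trajectory design and acquisition scheduling.

A real-time frame is built from ``n_arms`` equidistant variable-density spiral
interleaves (default 13) read out within a short temporal footprint (~48 ms).
Consecutive frames repeat the identical pattern for one block; after each block
the whole pattern is rotated by an angle chosen to fill the largest gap among
all previously acquired arm orientations, so that the union of patterns over a
breath-hold converges to a dense, equidistant angular coverage suitable for
segmented (binned) reference reconstruction.

Units: k-space coordinates are stored in cycles/FOV normalized such that the
nominal resolution edge sits at 0.5 (i.e. ``k_norm = k_phys * fov / matrix``).
Gradients are in mT/m, slew in mT/m/ms, time in ms unless suffixed otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

GAMMA_HZ_PER_T = 42.577478518e6  # gyromagnetic ratio of 1H


class SpiralDesignError(RuntimeError):
    """Raised when gradient limits cannot realize the requested trajectory."""


class GatingError(RuntimeError):
    """Raised when no cardiac modulation can be detected in the DC signal."""


@dataclass(frozen=True)
class GradientLimits:
    """Hardware limits of the gradient system.

    Defaults correspond to a 1.5T clinical system (40 mT/m, 170 mT/m/ms).
    """

    amplitude_mt_m: float = 40.0
    slew_mt_m_ms: float = 170.0

    def __post_init__(self) -> None:
        if self.amplitude_mt_m <= 0 or self.slew_mt_m_ms <= 0:
            raise ValueError("gradient limits must be positive")


@dataclass(frozen=True)
class FovProfile:
    """Effective sampling FOV at the k-space center and edge, in meters.

    The sampling density of the variable-density spiral corresponds to an
    effective FOV that decreases linearly (in k-space radius) from
    ``center_m`` to ``edge_m``.
    """

    center_m: float = 0.09
    edge_m: float = 0.03

    def __post_init__(self) -> None:
        if self.center_m <= 0 or self.edge_m <= 0:
            raise ValueError("FOV profile values must be positive")


@dataclass
class SpiralArm:
    """One spiral interleave.

    ``k_samples`` are the readout samples (normalized cycles/FOV); they start
    at k=0 and |k| is non-decreasing. The rewinder (which nulls the zeroth
    gradient moment) is stored separately: its k excursion necessarily exceeds
    the sampled k-space box while the gradients ramp down, and no data is
    acquired during it.
    """

    k_samples: np.ndarray  # (n_readout, 2)
    base_angle: float  # radians
    duration_ms: float  # readout duration
    dt_us: float
    gradients: np.ndarray  # (n_readout - 1, 2) mT/m, between consecutive samples
    rewinder_gradients: np.ndarray  # (n_rew, 2) mT/m

    @property
    def n_readout(self) -> int:
        return self.k_samples.shape[0]

    def full_gradient_waveform(self) -> np.ndarray:
        """Readout + rewinder gradient waveform, (n, 2) in mT/m."""
        return np.concatenate([self.gradients, self.rewinder_gradients], axis=0)


@dataclass
class ScheduleEntry:
    block_index: int
    frame_index: int
    rotation: float  # pattern rotation phi, radians
    arm_angles: np.ndarray  # (n_arms,) radians in [0, 2pi)
    timestamp_ms: float
    transient: bool = False


@dataclass
class AcquisitionSchedule:
    entries: list[ScheduleEntry]
    mode: str  # "breath_hold" | "free_breathing"
    n_cine: int
    t_rr_ms: float
    n_heartbeats: int
    frame_duration_ms: float
    n_arms: int = 13

    @property
    def n_frames(self) -> int:
        return len(self.entries)

    @property
    def total_duration_ms(self) -> float:
        return self.n_heartbeats * self.n_cine * self.frame_duration_ms

    def to_json(self) -> str:
        blocks: dict[int, dict] = {}
        for e in self.entries:
            b = blocks.setdefault(
                e.block_index,
                {"rotation_rad": e.rotation, "transient": e.transient, "frames": []},
            )
            b["frames"].append(
                {
                    "timestamp_ms": e.timestamp_ms,
                    "arm_angles_rad": [float(a) for a in e.arm_angles],
                }
            )
        payload = {
            "mode": self.mode,
            "t_rr_ms": self.t_rr_ms,
            "frame_duration_ms": self.frame_duration_ms,
            "n_cine": self.n_cine,
            "n_heartbeats": self.n_heartbeats,
            "n_arms": self.n_arms,
            "blocks": [blocks[i] for i in sorted(blocks)],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AcquisitionSchedule":
        d = json.loads(text)
        entries = []
        frame = 0
        for bi, b in enumerate(d["blocks"]):
            for f in b["frames"]:
                entries.append(
                    ScheduleEntry(
                        block_index=bi,
                        frame_index=frame,
                        rotation=b["rotation_rad"],
                        arm_angles=np.asarray(f["arm_angles_rad"], dtype=float),
                        timestamp_ms=f["timestamp_ms"],
                        transient=b.get("transient", False),
                    )
                )
                frame += 1
        return cls(
            entries=entries,
            mode=d["mode"],
            n_cine=d["n_cine"],
            t_rr_ms=d["t_rr_ms"],
            n_heartbeats=d["n_heartbeats"],
            frame_duration_ms=d["frame_duration_ms"],
            n_arms=d.get("n_arms", 13),
        )


@dataclass
class GatingSignal:
    samples: np.ndarray  # real-valued DC series, one value per frame
    dt_ms: float
    triggers: np.ndarray  # timestamps (ms) of detected beats
    period_estimate_ms: float

    def __post_init__(self) -> None:
        t = np.asarray(self.triggers, dtype=float)
        if t.size >= 2:
            if not np.all(np.diff(t) > 0):
                raise ValueError("triggers must be strictly increasing")
            if self.period_estimate_ms <= 0:
                raise ValueError("period estimate must be positive")


# ---------------------------------------------------------------------------
# spiral design
# ---------------------------------------------------------------------------

def _spiral_geometry(
    n_arms: int,
    k_max: float,
    fov_profile: FovProfile,
) -> tuple:
    """Return callables r(phi) and dr/dphi for the variable-density spiral.

    The radial advance per full turn of one interleave is
    ``n_arms / FOV_eff(r)`` so the interleaved set satisfies Nyquist for the
    effective FOV, which falls linearly from the center to the edge value.
    """
    fc, fe = fov_profile.center_m, fov_profile.edge_m

    def fov_eff(r: np.ndarray) -> np.ndarray:
        frac = np.clip(r / k_max, 0.0, 1.0)
        return fc + (fe - fc) * frac

    def drdphi(r: np.ndarray) -> np.ndarray:
        return n_arms / (2.0 * np.pi * fov_eff(r))

    return fov_eff, drdphi


def design_spiral(
    n_arms: int = 13,
    matrix: int = 512,
    fov_profile: FovProfile | tuple = FovProfile(),
    gradient_limits: GradientLimits = GradientLimits(),
    *,
    fov_m: float = 0.592,
    dt_us: float = 10.0,
    max_duration_ms: float = 10.0,
    safety: float = 0.99,
) -> list[SpiralArm]:
    """Design ``n_arms`` variable-density spiral interleaves.

    The first arm starts along the +x axis; arm ``i`` is the same waveform
    rotated by ``2*pi*i/n_arms``. Integration is slew-limited near the center
    (high curvature) and amplitude-limited toward the edge, on a fixed raster
    of ``dt_us``. A triangular rewinder nulls the zeroth gradient moment.

    Raises
    ------
    SpiralDesignError
        If the k-space edge cannot be reached within ``max_duration_ms``.
    """
    if n_arms < 1:
        raise ValueError("n_arms must be >= 1")
    if matrix < 16:
        raise ValueError("matrix must be >= 16")
    if isinstance(fov_profile, tuple):
        fov_profile = FovProfile(*fov_profile)

    g_max = safety * gradient_limits.amplitude_mt_m * 1e-3  # T/m
    s_max = safety * gradient_limits.slew_mt_m_ms  # mT/m/ms == T/m/s numerically
    dt = dt_us * 1e-6  # s
    k_phys_max = 0.4995 * matrix / fov_m  # 1/m; small margin below the box edge
    _, drdphi = _spiral_geometry(n_arms, k_phys_max, fov_profile)

    def k_of_phi(phi: float, r: float) -> np.ndarray:
        return np.array([r * math.cos(phi), r * math.sin(phi)])

    def derivs(phi: float, r: float) -> tuple:
        """k' and k'' with respect to phi (1/m per rad, per rad^2)."""
        a = float(drdphi(np.array(r)))
        c, s = math.cos(phi), math.sin(phi)
        kp = np.array([a * c - r * s, a * s + r * c])
        # d2r/dphi2 via finite difference of drdphi along r
        h = 1e-3 * max(a, 1.0)
        a2 = (float(drdphi(np.array(r + h * a))) - float(drdphi(np.array(max(r - h * a, 0.0))))) / (
            (r + h * a) - max(r - h * a, 0.0)
        ) * a
        kpp = np.array(
            [a2 * c - 2 * a * s - r * c, a2 * s + 2 * a * c - r * s]
        )
        return kp, kpp

    gamma = GAMMA_HZ_PER_T
    k_ceiling = 0.49995 * matrix / fov_m  # hard box bound, physical 1/m
    k_floor = 0.99 * k_phys_max  # acceptable shortfall of the edge sample

    def integrate(dt_s: float):
        """One pass at raster dt_s; returns (k samples | None, status)."""
        n_sub = 16  # fine substeps keep Euler inside the slew bound
        dts = dt_s / n_sub
        phi = r = phidot = 0.0
        ks = [np.zeros(2)]
        stopped_at_ceiling = False
        n_max = int(max_duration_ms * 1e-3 / dt_s)
        for _ in range(n_max):
            phi0, r0, phidot0 = phi, r, phidot
            for _ in range(n_sub):
                kp, kpp = derivs(phi, r)
                nkp2 = float(kp @ kp)
                # |kpp*phidot^2 + kp*phiddot| <= gamma*s_max: quadratic in phiddot
                b = float(kp @ kpp) * phidot**2
                c = float(kpp @ kpp) * phidot**4 - (gamma * s_max) ** 2
                disc = b * b - nkp2 * c
                if disc < 0:
                    phiddot = -b / nkp2  # decelerate as much as geometry allows
                else:
                    phiddot = (-b + math.sqrt(disc)) / nkp2
                phidot = phidot + phiddot * dts
                # amplitude limit |k'| * phidot <= gamma * g_max
                phidot = min(phidot, gamma * g_max / math.sqrt(nkp2))
                phi += phidot * dts
                r += float(drdphi(np.array(r))) * phidot * dts
            if r > k_ceiling:
                # the full step would leave the box: stop at the previous sample
                phi, r, phidot = phi0, r0, phidot0
                stopped_at_ceiling = True
                break
            ks.append(k_of_phi(phi, r))
            if r >= k_phys_max:
                break
        if r < k_floor:
            return None, ("overshoot" if stopped_at_ceiling else "timeout")
        return np.asarray(ks), "ok"

    k_readout = None
    dt_eff = dt
    for _ in range(8):
        k_readout, status = integrate(dt_eff)
        if k_readout is not None:
            break
        if status == "timeout":
            raise SpiralDesignError(
                f"gradient limits cannot reach the k-space edge "
                f"({k_phys_max:.1f} 1/m) within {max_duration_ms} ms"
            )
        dt_eff /= 2.0  # coarse raster overshoots the box edge; refine
    if k_readout is None:
        raise SpiralDesignError(
            f"gradient limits cannot reach the k-space edge ({k_phys_max:.1f} 1/m) "
            f"within {max_duration_ms} ms at raster {dt_us} us"
        )
    dt = dt_eff
    dt_us = dt * 1e6

    grads = np.diff(k_readout, axis=0) / (gamma * dt)  # T/m, between samples

    rew = _design_rewinder(k_readout[-1], grads[-1], g_max, s_max, gamma, dt)

    norm = fov_m / matrix  # physical 1/m -> cycles/FOV in [-0.5, 0.5)
    duration_ms = (k_readout.shape[0] - 1) * dt * 1e3
    arms = []
    base = SpiralArm(
        k_samples=k_readout * norm,
        base_angle=0.0,
        duration_ms=duration_ms,
        dt_us=dt_us,
        gradients=grads * 1e3,  # mT/m
        rewinder_gradients=rew * 1e3,
    )
    for i in range(n_arms):
        ang = 2.0 * np.pi * i / n_arms
        rot = np.array(
            [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
        )
        arms.append(
            SpiralArm(
                k_samples=base.k_samples @ rot.T,
                base_angle=ang,
                duration_ms=base.duration_ms,
                dt_us=dt_us,
                gradients=base.gradients @ rot.T,
                rewinder_gradients=base.rewinder_gradients @ rot.T,
            )
        )
    return arms


def _design_rewinder(
    k_end: np.ndarray,
    g_end: np.ndarray,
    g_max: float,
    s_max: float,
    gamma: float,
    dt: float,
) -> np.ndarray:
    """Slew-feasible rewinder: ramp the gradient to zero, then a triangular
    (or trapezoidal) lobe that nulls the accumulated zeroth moment exactly.

    Returns the rewinder gradient waveform in T/m on the raster.
    """
    segs = []
    g = g_end.copy()
    gmag = float(np.hypot(*g))
    n_ramp = max(int(math.ceil(gmag / (s_max * dt))), 1)
    for i in range(1, n_ramp + 1):
        segs.append(g_end * (1.0 - i / n_ramp))
    ramp = np.asarray(segs) if segs else np.zeros((0, 2))
    k_after = k_end + gamma * dt * ramp.sum(axis=0)

    area_needed = -k_after / gamma  # integral of g over time (T/m * s)
    amag = float(np.hypot(*area_needed))
    if amag < 1e-12:
        return ramp
    direction = area_needed / amag
    # triangle: ramp up for n steps at slew, down for n steps; area = s*(n*dt)^2
    n_tri = int(math.ceil(math.sqrt(amag / s_max) / dt))
    peak = amag / (n_tri * dt)
    if peak > g_max:
        # trapezoid: ramp to g_max, hold, ramp down
        n_up = int(math.ceil(g_max / (s_max * dt)))
        peak = g_max
        hold_area = amag - peak * n_up * dt
        n_hold = max(int(math.ceil(hold_area / (peak * dt))), 0)
        prof = np.concatenate(
            [
                np.arange(1, n_up + 1) / n_up * peak,
                np.full(n_hold, peak),
                np.arange(n_up - 1, -1, -1) / n_up * peak,
            ]
        )
    else:
        prof = np.concatenate(
            [
                np.arange(1, n_tri + 1) / n_tri * peak,
                np.arange(n_tri - 1, -1, -1) / n_tri * peak,
            ]
        )
    # scale profile so the discrete area nulls the moment exactly
    prof *= amag / (prof.sum() * dt)
    lobe = prof[:, None] * direction[None, :]
    return np.concatenate([ramp, lobe], axis=0)


# ---------------------------------------------------------------------------
# rotation scheduling
# ---------------------------------------------------------------------------

def _van_der_corput(j: int) -> float:
    """Bit-reversed fraction of positive integer j (base 2)."""
    f, base = 0.0, 0.5
    while j:
        f += base * (j & 1)
        j >>= 1
        base *= 0.5
    return f


def rotation_sequence(n_rotations: int, n_arms: int = 13) -> list[float]:
    """Gap-filling pattern rotations.

    Successive rotations are bit-reversal-ordered fractions of the base arm
    gap ``2*pi/n_arms``: 1/2, 1/4, 3/4, 1/8, 5/8, 3/8, 7/8, 1/16, ... With the
    identity prepended, the union of all pattern angle sets after ``2**m - 1``
    rotations is exactly equidistant with gap ``2*pi/(n_arms * 2**m)``.
    """
    if n_rotations < 0:
        raise ValueError("n_rotations must be >= 0")
    base = 2.0 * np.pi / n_arms
    return [base * _van_der_corput(j) for j in range(1, n_rotations + 1)]


def build_schedule(
    mode: str,
    t_rr_ms: float = 1000.0,
    n_heartbeats: int = 9,
    frame_duration_ms: float = 48.0,
    n_cine_override: int | None = None,
    n_arms: int = 13,
) -> AcquisitionSchedule:
    """Build the acquisition schedule.

    breath_hold
        Ncine is the smallest integer with ``frame_duration * Ncine >= t_rr``
        (each block slightly exceeds one RR interval). The first heartbeat is
        a transient block without rotation and is excluded from binning; the
        remaining ``n_heartbeats - 1`` blocks use rotations 0, phi1, phi2, ...
    free_breathing
        Ncine from ``n_cine_override`` (default 10); ``n_heartbeats`` blocks
        (default 9) with a rotation after every block.
    """
    if mode not in ("breath_hold", "free_breathing"):
        raise ValueError(f"unknown mode {mode!r}")
    if t_rr_ms <= frame_duration_ms:
        raise ValueError("t_rr must exceed the frame duration")
    if n_cine_override is not None and n_cine_override < 1:
        raise ValueError("n_cine_override must be >= 1")

    base_angles = 2.0 * np.pi * np.arange(n_arms) / n_arms
    entries: list[ScheduleEntry] = []

    if mode == "breath_hold":
        if n_heartbeats < 2:
            raise ValueError("breath_hold needs >= 2 heartbeats (one transient)")
        n_cine = n_cine_override or math.ceil(t_rr_ms / frame_duration_ms - 1e-9)
        rotations = [0.0] + rotation_sequence(n_heartbeats - 2, n_arms)
        frame = 0
        for b in range(n_heartbeats):
            phi = 0.0 if b == 0 else rotations[b - 1]
            for _ in range(n_cine):
                entries.append(
                    ScheduleEntry(
                        block_index=b,
                        frame_index=frame,
                        rotation=phi,
                        arm_angles=np.mod(base_angles + phi, 2.0 * np.pi),
                        timestamp_ms=frame * frame_duration_ms,
                        transient=(b == 0),
                    )
                )
                frame += 1
    else:
        n_cine = n_cine_override or 10
        n_blocks = n_heartbeats
        # the accumulated union is equidistant only at power-of-two pattern
        # counts, so the rotation list wraps after 8 patterns: a 9-block scan
        # still averages to 104 equidistant arms
        rotations = [0.0] + rotation_sequence(7, n_arms)
        frame = 0
        for b in range(n_blocks):
            phi = rotations[b % 8]
            for _ in range(n_cine):
                entries.append(
                    ScheduleEntry(
                        block_index=b,
                        frame_index=frame,
                        rotation=phi,
                        arm_angles=np.mod(base_angles + phi, 2.0 * np.pi),
                        timestamp_ms=frame * frame_duration_ms,
                        transient=False,
                    )
                )
                frame += 1

    return AcquisitionSchedule(
        entries=entries,
        mode=mode,
        n_cine=n_cine,
        t_rr_ms=t_rr_ms,
        n_heartbeats=n_heartbeats,
        frame_duration_ms=frame_duration_ms,
        n_arms=n_arms,
    )


# ---------------------------------------------------------------------------
# self-gating
# ---------------------------------------------------------------------------

def detect_triggers(
    samples: np.ndarray,
    dt_ms: float,
    band_hz: tuple = (0.5, 3.0),
    min_spacing_ms: float = 400.0,
) -> GatingSignal:
    """Detect heartbeats in a DC (k=0 magnitude) series.

    The series is zero-phase band-pass filtered (0.5-3 Hz covers 30-180 bpm)
    and peaks with a minimum spacing of 0.4 s are taken as triggers. The
    period estimate is the median trigger spacing.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 4 or np.std(samples) < 1e-12 * max(np.abs(samples).max(), 1e-30):
        raise GatingError("no gating detected: constant or too-short DC signal")
    fs = 1000.0 / dt_ms
    nyq = fs / 2.0
    lo, hi = band_hz[0] / nyq, min(band_hz[1] / nyq, 0.99)
    sos = signal.butter(2, [lo, hi], btype="bandpass", output="sos")
    padlen = min(3 * 6, samples.size - 1)
    filt = signal.sosfiltfilt(sos, samples, padlen=padlen)
    if np.std(filt) < 1e-12 * max(np.abs(samples).max(), 1e-30):
        raise GatingError("no gating detected: no in-band modulation")
    dist = max(int(round(min_spacing_ms / dt_ms)), 1)
    peaks, _ = signal.find_peaks(filt, distance=dist)
    if peaks.size < 2:
        raise GatingError("no gating detected: fewer than two beats found")
    triggers = peaks * dt_ms
    period = float(np.median(np.diff(triggers)))
    return GatingSignal(
        samples=samples, dt_ms=dt_ms, triggers=triggers, period_estimate_ms=period
    )


def extract_gating(kspace) -> GatingSignal:
    """Extract the self-gating "ECG" from repeated k=0 samples.

    For each frame the magnitudes of the coil samples at k=0 are combined by
    root-sum-of-squares and averaged over the frame's arms, giving one DC
    value per frame; trigger detection then proceeds on that series.
    """
    traj = kspace.traj
    at_center = np.flatnonzero(np.hypot(traj[:, 0], traj[:, 1]) < 1e-9)
    if at_center.size == 0:
        raise GatingError("no k=0 samples present")
    frames = np.unique(kspace.frame_index)
    dc = np.zeros(frames.size)
    for j, f in enumerate(frames):
        idx = at_center[kspace.frame_index[at_center] == f]
        if idx.size == 0:
            raise GatingError(f"frame {f} has no k=0 sample")
        rss = np.sqrt((np.abs(kspace.kspace[:, idx]) ** 2).sum(axis=0))
        dc[j] = rss.mean()
    return detect_triggers(dc, kspace.frame_duration_ms)


# ---------------------------------------------------------------------------
# phase binning
# ---------------------------------------------------------------------------

def bin_phases(
    schedule: AcquisitionSchedule,
    gating: GatingSignal,
    n_phases: int,
) -> dict[int, list[int]]:
    """Assign non-transient frames to cardiac phases.

    A frame with timestamp ``t`` belongs to phase
    ``floor(((t - preceding_trigger) / period) * n_phases)`` where the period
    is the local RR interval (next minus preceding trigger, falling back to
    the global estimate at the ends). Returns a partition
    ``phase -> list of frame indices``.
    """
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    if n_phases > schedule.n_cine:
        raise ValueError(
            f"cannot resolve {n_phases} phases from {schedule.n_cine} frames per beat"
        )
    trig = np.asarray(gating.triggers, dtype=float)
    if trig.size < 1:
        raise ValueError("gating has no triggers")
    period_global = gating.period_estimate_ms

    phases: dict[int, list[int]] = {p: [] for p in range(n_phases)}
    for e in schedule.entries:
        if e.transient:
            continue
        t = e.timestamp_ms
        i = int(np.searchsorted(trig, t, side="right")) - 1
        if i < 0:
            # before the first trigger: extend periodically backwards
            prev = trig[0] - period_global * math.ceil((trig[0] - t) / period_global)
            period = period_global
        else:
            prev = trig[i]
            period = trig[i + 1] - trig[i] if i + 1 < trig.size else period_global
        frac = (t - prev) / period
        p = min(int(math.floor(frac * n_phases)), n_phases - 1)
        phases[p].append(e.frame_index)
    return phases


def pooled_arm_angles(
    schedule: AcquisitionSchedule,
    frame_indices: list[int],
    tol: float = 1e-9,
) -> np.ndarray:
    """Unique arm angles (radians, sorted) pooled over the given frames."""
    by_index = {e.frame_index: e for e in schedule.entries}
    angs = np.concatenate([by_index[f].arm_angles for f in frame_indices])
    angs = np.sort(np.mod(angs, 2.0 * np.pi))
    keep = [angs[0]]
    for a in angs[1:]:
        if a - keep[-1] > tol:
            keep.append(a)
    # wrap-around duplicate
    if len(keep) > 1 and (2.0 * np.pi - keep[-1] + keep[0]) <= tol:
        keep.pop()
    return np.asarray(keep)


def angular_gaps(angles: np.ndarray) -> np.ndarray:
    """Circular gaps between sorted angles, including the wrap-around gap."""
    a = np.sort(np.mod(angles, 2.0 * np.pi))
    gaps = np.diff(a)
    return np.append(gaps, 2.0 * np.pi - a[-1] + a[0])
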
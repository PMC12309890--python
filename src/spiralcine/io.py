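"""File formats: HDF5 raw-data container, NIfTI image export, schedule JSON,
metric CSV, and score checkpoints."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .diffusion.net import ScoreNet
from .diffusion.schedule import DiffusionSchedule
from .phantom import CineSeries, KSpaceData, SensitivityMaps
from .trajectory import AcquisitionSchedule


def save_kspace(path, raw: KSpaceData, attrs: dict | None = None) -> None:
    """Raw container layout: /kspace (coil x sample), /traj (sample x 2),
    /timestamps_ms, /arm_index, /frame_index, optional /maps."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=raw.kspace)
        f.create_dataset("traj", data=raw.traj)
        f.create_dataset("timestamps_ms", data=raw.timestamps_ms)
        f.create_dataset("arm_index", data=raw.arm_index)
        f.create_dataset("frame_index", data=raw.frame_index)
        f.attrs["frame_duration_ms"] = raw.frame_duration_ms
        if raw.maps is not None:
            f.create_dataset("maps", data=raw.maps.maps)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_kspace(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        maps = None
        if "maps" in f:
            maps = SensitivityMaps(f["maps"][()])
        return KSpaceData(
            kspace=f["kspace"][()],
            traj=f["traj"][()],
            timestamps_ms=f["timestamps_ms"][()],
            arm_index=f["arm_index"][()],
            frame_index=f["frame_index"][()],
            frame_duration_ms=float(f.attrs["frame_duration_ms"]),
            maps=maps,
        )


def save_cine_nifti(path, cine: CineSeries, attrs: dict | None = None) -> None:
    """Magnitude + phase volumes (x, y, t) with voxel geometry in the affine."""
    path = Path(path)
    mag = np.abs(cine.frames).transpose(2, 1, 0)
    ph = np.angle(cine.frames).transpose(2, 1, 0)
    affine = np.diag(
        [cine.pixel_spacing_mm, cine.pixel_spacing_mm, cine.slice_thickness_mm, 1.0]
    )
    img = nib.Nifti1Image(mag.astype(np.float32), affine)
    img.header["pixdim"][4] = cine.frame_duration_ms / 1000.0
    if attrs:
        img.header["descrip"] = json.dumps(attrs)[:79].encode()
    nib.save(img, str(path))
    nib.save(
        nib.Nifti1Image(ph.astype(np.float32), affine),
        str(path.with_name(path.name.replace(".nii", "_phase.nii"))),
    )


def save_schedule(path, schedule: AcquisitionSchedule) -> None:
    Path(path).write_text(schedule.to_json())


def load_schedule(path) -> AcquisitionSchedule:
    return AcquisitionSchedule.from_json(Path(path).read_text())


def save_metrics_csv(path, reports: dict) -> None:
    """Per-frame metrics for several methods plus aggregate rows."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["method", "frame", "ssim", "nrmse", "psnr_db"])
        for method, rep in reports.items():
            for i in range(rep.ssim.size):
                w.writerow(
                    [method, i, f"{rep.ssim[i]:.6f}", f"{rep.nrmse[i]:.6f}",
                     f"{rep.psnr[i]:.4f}"]
                )
            s = rep.summary
            w.writerow(
                [method, "mean±sd",
                 f"{s['ssim'][0]:.6f}±{s['ssim'][1]:.6f}",
                 f"{s['nrmse'][0]:.6f}±{s['nrmse'][1]:.6f}",
                 f"{s['psnr'][0]:.4f}±{s['psnr'][1]:.4f}"]
            )


def save_score_checkpoint(path, net: ScoreNet, schedule: DiffusionSchedule) -> None:
    """Network weights with the noise-schedule metadata embedded."""
    np.savez(
        path,
        **{f"param_{k}": v for k, v in net.params.items()},
        kernel=net.kernel,
        sigma_data=net.sigma_data,
        channel_sizes=np.asarray(net.channel_sizes),
        freqs=net.freqs,
        sigma_min=schedule.sigma_min,
        sigma_max=schedule.sigma_max,
        n_steps=schedule.n_steps,
    )


def load_score_checkpoint(path) -> tuple[ScoreNet, DiffusionSchedule]:
    d = np.load(path, allow_pickle=False)
    sizes = d["channel_sizes"]
    net = ScoreNet(
        channels=int(sizes[1]),
        n_hidden=len(sizes) - 2,
        kernel=int(d["kernel"]),
        sigma_data=float(d["sigma_data"]),
    )
    net.freqs = d["freqs"]
    net.params = {k[len("param_"):]: d[k] for k in d.files if k.startswith("param_")}
    schedule = DiffusionSchedule(
        float(d["sigma_min"]), float(d["sigma_max"]), int(d["n_steps"])
    )
    return net, schedule
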
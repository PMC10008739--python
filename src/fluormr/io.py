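"""Readers and writers: HDF5 raw-data container, NIfTI volumes, JSON/CSV.

Container layout (HDF5):
    /fid          complex array [channel, point], attrs: dwell_time (s),
                  reference_frequency (MHz), carrier_ppm, filter_delay_points
    /kspace       complex array [channel, spoke, point]
    /trajectory   group: directions, radii, attrs te_ms, dwell_ms, fov_mm,
                  matrix, undersampling
    /noise_scan   complex array (zero-excitation), optional
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .imaging import ImageVolume, KSpaceData, RadialTrajectory
from .spectra import Fid, Spectrum


def save_fid(path: str | Path, fid: Fid) -> None:
    with h5py.File(path, "a") as f:
        if "fid" in f:
            del f["fid"]
        d = f.create_dataset("fid", data=fid.data)
        d.attrs["dwell_time"] = fid.dwell_time
        d.attrs["reference_frequency"] = fid.reference_frequency
        d.attrs["carrier_ppm"] = fid.carrier_ppm
        d.attrs["filter_delay_points"] = fid.filter_delay_points


def load_fid(path: str | Path) -> Fid:
    with h5py.File(path, "r") as f:
        d = f["fid"]
        return Fid(
            data=d[()],
            dwell_time=float(d.attrs["dwell_time"]),
            reference_frequency=float(d.attrs["reference_frequency"]),
            carrier_ppm=float(d.attrs["carrier_ppm"]),
            filter_delay_points=int(d.attrs["filter_delay_points"]),
        )


def save_kspace(path: str | Path, k: KSpaceData) -> None:
    with h5py.File(path, "a") as f:
        for name in ("kspace", "trajectory", "noise_scan"):
            if name in f:
                del f[name]
        f.create_dataset("kspace", data=k.samples)
        g = f.create_group("trajectory")
        g.create_dataset("directions", data=k.trajectory.directions)
        g.create_dataset("radii", data=k.trajectory.radii)
        for attr in ("te_ms", "dwell_ms", "fov_mm", "matrix", "undersampling"):
            g.attrs[attr] = getattr(k.trajectory, attr)
        if k.noise_scan is not None:
            f.create_dataset("noise_scan", data=k.noise_scan)


def load_kspace(path: str | Path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        g = f["trajectory"]
        traj = RadialTrajectory(
            directions=g["directions"][()],
            radii=g["radii"][()],
            te_ms=float(g.attrs["te_ms"]),
            dwell_ms=float(g.attrs["dwell_ms"]),
            fov_mm=float(g.attrs["fov_mm"]),
            matrix=int(g.attrs["matrix"]),
            undersampling=float(g.attrs["undersampling"]),
        )
        noise = f["noise_scan"][()] if "noise_scan" in f else None
        return KSpaceData(samples=f["kspace"][()], trajectory=traj, noise_scan=noise)


def save_nifti(path: str | Path, img: ImageVolume) -> None:
    import nibabel as nib

    data = img.voxels
    if np.iscomplexobj(data):
        data = np.abs(data)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), img.affine), str(path))


def spectrum_to_csv(path: str | Path, spec: Spectrum) -> None:
    import pandas as pd

    vals = np.atleast_2d(spec.values)
    cols = {"ppm": spec.ppm_axis}
    for c in range(vals.shape[0]):
        suffix = f"_ch{c}" if vals.shape[0] > 1 else ""
        cols[f"real{suffix}"] = np.real(vals[c])
        cols[f"imag{suffix}"] = np.imag(vals[c])
    pd.DataFrame(cols).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
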
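"""NIfTI and k-space container I/O."""

from __future__ import annotations

import json

import nibabel as nib
import numpy as np

from .acquisition import KSpaceSeries, Trajectory

__all__ = ["save_nifti", "load_nifti", "save_kspace", "load_kspace"]


def save_nifti(data: np.ndarray, path, voxel_size: float = 4.0, tr: float | None = None):
    """Write a 3D/4D array as NIfTI with an isotropic voxel-size affine."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    zooms = [voxel_size] * 3
    if data.ndim == 4:
        zooms.append(tr if tr is not None else 1.0)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), float(img.header.get_zooms()[0])


def save_kspace(k: KSpaceSeries, path, seed: int | None = None) -> None:
    """Serialize a k-space series to one .npz container with a JSON header."""
    traj = k.trajectory
    header = {
        "TEs": list(k.TEs),
        "samples_per_spoke": traj.samples_per_spoke,
        "k_max": traj.k_max,
        "dead_samples": traj.dead_samples,
        "nominal_resolution": traj.nominal_resolution,
        "grid_shape": list(k.grid_shape) if k.grid_shape else None,
        "seed": seed,
    }
    arrays = {
        "samples": k.samples,
        "directions": traj.directions,
        "segment": traj.segment,
        "loop": traj.loop,
        "echo": traj.echo,
        "within_loop": traj.within_loop,
        "ordering": traj.ordering,
        "header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
    }
    if k.reacquired_center is not None:
        arrays["reacquired_center"] = k.reacquired_center
    if traj.points is not None:
        arrays["points"] = traj.points
    np.savez_compressed(str(path), **arrays)


def load_kspace(path) -> KSpaceSeries:
    with np.load(str(path)) as z:
        header = json.loads(bytes(z["header"]).decode())
        traj = Trajectory(
            directions=z["directions"],
            segment=z["segment"],
            loop=z["loop"],
            echo=z["echo"],
            within_loop=z["within_loop"],
            samples_per_spoke=int(header["samples_per_spoke"]),
            k_max=float(header["k_max"]),
            ordering=z["ordering"],
            dead_samples=int(header["dead_samples"]),
            nominal_resolution=float(header["nominal_resolution"]),
            points=z["points"] if "points" in z else None,
        )
        return KSpaceSeries(
            samples=z["samples"],
            trajectory=traj,
            TEs=list(header["TEs"]),
            reacquired_center=(
                z["reacquired_center"] if "reacquired_center" in z else None
            ),
            grid_shape=tuple(header["grid_shape"]) if header["grid_shape"] else None,
        )
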
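"""File exchange: protocol tables, NIfTI images/maps, HDF5 ensembles."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .forward import PARAM_NAMES, VoxelDistribution
from .inversion import VoxelEnsemble

__all__ = [
    "save_signal_image",
    "load_signal_image",
    "save_maps",
    "load_map",
    "save_ensembles",
    "load_ensembles",
    "save_projection",
    "load_projection",
]


def save_signal_image(path, signals: np.ndarray, shape: tuple, affine=None) -> None:
    """Write per-voxel signal vectors as a 4D NIfTI volume.

    ``signals`` is (n_voxels, n_meas) in C-order voxel flattening of
    ``shape``; the measurement axis becomes the 4th NIfTI dimension.
    """
    affine = np.eye(4) if affine is None else affine
    data = np.asarray(signals, dtype=np.float64).reshape(*shape, -1)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_signal_image(path) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Read a 4D NIfTI into (signals (n_voxels, n_meas), shape, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    shape = data.shape[:-1]
    return data.reshape(-1, data.shape[-1]), shape, img.affine


def save_maps(
    outdir,
    maps: pd.DataFrame,
    shape: tuple,
    affine=None,
    omega_meta: Mapping | None = None,
) -> list[Path]:
    """Write each summary-map column as a 3D NIfTI plus a JSON sidecar.

    The sidecar records the probe-frequency conventions (reference ω, Δω
    band) so map values are interpretable downstream.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    written = []
    for col in maps.columns:
        vol = maps[col].to_numpy(dtype=np.float64).reshape(shape)
        p = outdir / f"{col}.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), str(p))
        written.append(p)
    if omega_meta is not None:
        side = outdir / "omega_conventions.json"
        side.write_text(json.dumps(dict(omega_meta), indent=2))
        written.append(side)
    return written


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def _dist_to_array(dist: VoxelDistribution) -> np.ndarray:
    return np.column_stack([getattr(dist, n) for n in PARAM_NAMES])


def _dist_from_array(arr: np.ndarray) -> VoxelDistribution:
    if arr.size == 0:
        return VoxelDistribution.empty()
    return VoxelDistribution(**{n: arr[:, j] for j, n in enumerate(PARAM_NAMES)})


def save_ensembles(path, ensembles: Sequence[VoxelEnsemble]) -> None:
    """Store per-voxel bootstrap ensembles in HDF5.

    Layout: group ``voxel_<i>`` with one ragged component table per
    bootstrap solution (rows: components; columns: the 10 parameters in
    :data:`mdrc.forward.PARAM_NAMES`) and a residual vector.
    """
    with h5py.File(path, "w") as fh:
        fh.attrs["param_names"] = list(PARAM_NAMES)
        for i, ens in enumerate(ensembles):
            g = fh.create_group(f"voxel_{i}")
            g.attrs["n_solutions"] = len(ens.solutions)
            g.create_dataset("residuals", data=np.asarray(ens.residuals))
            for j, sol in enumerate(ens.solutions):
                g.create_dataset(f"solution_{j}", data=_dist_to_array(sol))


def load_ensembles(path) -> list[VoxelEnsemble]:
    out = []
    with h5py.File(path, "r") as fh:
        for i in range(len([k for k in fh if k.startswith("voxel_")])):
            g = fh[f"voxel_{i}"]
            sols = [
                _dist_from_array(np.asarray(g[f"solution_{j}"]))
                for j in range(int(g.attrs["n_solutions"]))
            ]
            out.append(VoxelEnsemble(solutions=sols, residuals=np.asarray(g["residuals"])))
    return out


def save_projection(path, projection) -> None:
    """Store a 2D projection mesh with axis metadata in HDF5."""
    with h5py.File(path, "w") as fh:
        fh.attrs["plane"] = projection.plane
        fh.attrs["x_scale"] = projection.x_scale
        fh.attrs["y_scale"] = projection.y_scale
        fh.create_dataset("weights", data=projection.weights)
        fh.create_dataset("x_edges", data=projection.x_edges)
        fh.create_dataset("y_edges", data=projection.y_edges)


def load_projection(path):
    from .consolidate import Projection2D

    with h5py.File(path, "r") as fh:
        return Projection2D(
            plane=str(fh.attrs["plane"]),
            weights=np.asarray(fh["weights"]),
            x_edges=np.asarray(fh["x_edges"]),
            y_edges=np.asarray(fh["y_edges"]),
            x_scale=str(fh.attrs["x_scale"]),
            y_scale=str(fh.attrs["y_scale"]),
        )
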
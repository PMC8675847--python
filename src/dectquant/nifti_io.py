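"""NIfTI I/O for dual-energy volumes, concentration maps and labels.

On-disk conventions (applied/removed only here, at the boundary):

* CT volumes are stored in true Hounsfield units; in memory the package
  works on shifted CT' = HU + 1000.
* Concentration maps are stored in μg/ml; in memory mg/ml.
* Dual-energy data may be a pair of 3-D files (one per energy) or a
  single 4-D file with energy as the fourth axis, low energy first; both
  dialects are read.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .core import HU_OFFSET, Grid, DualEnergyImage, MaterialMaps, ScanProtocol, mg_to_ug, ug_to_mg
from .exceptions import InputError


def _affine(grid: Grid | None, shape) -> np.ndarray:
    if grid is not None:
        return grid.affine
    return Grid(shape=tuple(shape)).affine


def write_dual_energy(
    image: DualEnergyImage,
    path,
    mode: str = "4d",
    grid: Grid | None = None,
) -> list[str]:
    """Write a dual-energy image as HU NIfTI.

    ``mode='4d'`` writes one 4-D file at ``path``; ``mode='pair'`` treats
    ``path`` as a directory and writes ``ct_low.nii`` / ``ct_high.nii``.
    Returns the written paths.
    """
    aff = _affine(grid, image.shape)
    if mode == "4d":
        data = np.stack([image.hu_low, image.hu_high], axis=-1)
        nib.save(nib.Nifti1Image(data.astype(np.float32), aff), str(path))
        return [str(path)]
    if mode == "pair":
        os.makedirs(path, exist_ok=True)
        out = []
        for name, vol in (("ct_low.nii", image.hu_low), ("ct_high.nii", image.hu_high)):
            p = os.path.join(path, name)
            nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), p)
            out.append(p)
        return out
    raise InputError(f"unknown mode {mode!r}; use '4d' or 'pair'")


def read_dual_energy(
    low_or_4d,
    high=None,
    protocol: ScanProtocol | None = None,
    offset: float = HU_OFFSET,
) -> DualEnergyImage:
    """Read a dual-energy image from a 4-D file or a (low, high) pair."""
    if high is None:
        data = np.asarray(nib.load(str(low_or_4d)).dataobj, dtype=float)
        if data.ndim != 4 or data.shape[-1] != 2:
            raise InputError(
                f"expected a 4-D volume with 2 energy frames, got shape {data.shape}"
            )
        hu_low, hu_high = data[..., 0], data[..., 1]
    else:
        hu_low = np.asarray(nib.load(str(low_or_4d)).dataobj, dtype=float)
        hu_high = np.asarray(nib.load(str(high)).dataobj, dtype=float)
    return DualEnergyImage(
        ct_low=hu_low + offset, ct_high=hu_high + offset, offset=offset, protocol=protocol
    )


def write_concentration_map(c_mg_ml: np.ndarray, path, grid: Grid | None = None) -> str:
    """Write a concentration map (internal mg/ml) as a μg/ml NIfTI."""
    aff = _affine(grid, c_mg_ml.shape)
    nib.save(nib.Nifti1Image(mg_to_ug(c_mg_ml).astype(np.float32), aff), str(path))
    return str(path)


def read_concentration_map(path) -> np.ndarray:
    """Read a μg/ml concentration map into internal mg/ml units."""
    return ug_to_mg(np.asarray(nib.load(str(path)).dataobj, dtype=float))


def write_labels(labels: np.ndarray, path, grid: Grid | None = None) -> str:
    aff = _affine(grid, labels.shape)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), aff), str(path))
    return str(path)


def read_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def write_material_maps(maps: MaterialMaps, outdir, grid: Grid | None = None) -> dict[str, str]:
    """Write water/gold maps (μg/ml) and the body mask under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "c_au": write_concentration_map(maps.c_au, os.path.join(outdir, "c_au.nii"), grid),
        "c_water": write_concentration_map(
            maps.c_water, os.path.join(outdir, "c_water.nii"), grid
        ),
        "mask": write_labels(maps.mask.astype(np.int16), os.path.join(outdir, "mask.nii"), grid),
    }
    return paths
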
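"""Raster I/O: MetaImage (MHD + raw) volumes and CSV exports.

Arrays follow this package's (x, y, z) index order with origin at the
corner of voxel (0,0,0), millimetre spacing; SimpleITK stores (z, y, x),
so axes are transposed on the way through.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .scoring import DoseMap, VoxelPhantom, estimate_uncertainty


def write_mhd(array, origin_mm, spacing_mm, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.asarray(array).transpose(2, 1, 0)))
    img.SetOrigin(tuple(float(o) for o in origin_mm))
    img.SetSpacing(tuple(float(s) for s in spacing_mm))
    sitk.WriteImage(img, str(path))


def read_mhd(path):
    """Returns ``(array (x,y,z), origin_mm, spacing_mm)``."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, np.array(img.GetOrigin()), np.array(img.GetSpacing())


def write_dose_map(dose_map: DoseMap, directory, stem: str = "dose") -> None:
    """Write the dose (Gy per history) and relative-uncertainty volumes."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_mhd(dose_map.value.astype(np.float32), dose_map.origin,
              dose_map.spacing, d / f"{stem}.mhd")
    if dose_map.n_histories >= 2:
        rel = np.nan_to_num(estimate_uncertainty(dose_map), nan=-1.0)
        write_mhd(rel.astype(np.float32), dose_map.origin, dose_map.spacing,
                  d / f"{stem}_rel_sigma.mhd")


def read_phantom(mhd_path, legend_path) -> VoxelPhantom:
    """Load a material-id raster plus a JSON legend.

    The legend maps id -> {"material": name, "density": g/cm^3}; density may
    be omitted to use the material's nominal density.
    """
    from .physics import get_material
    ids, origin, spacing = read_mhd(mhd_path)
    legend = json.loads(Path(legend_path).read_text())
    n = max(int(k) for k in legend) + 1
    materials = [None] * n
    dens = np.zeros(n)
    for k, v in legend.items():
        materials[int(k)] = v["material"]
        dens[int(k)] = v.get("density",
                             get_material(v["material"]).density)
    if any(m is None for m in materials):
        raise ValueError("legend does not cover all material ids")
    ids = ids.astype(np.int16)
    return VoxelPhantom(origin=origin, spacing=spacing, material_ids=ids,
                        density=dens[ids], materials=tuple(materials))


def write_annular_csv(annular, path) -> None:
    """Flat CSV export of an annular kerma map (Gy per history)."""
    val = annular.value
    rel = np.full(val.shape, np.nan)
    if annular.n_histories >= 2:
        var = annular.variance
        nz = val > 0
        rel[nz] = np.sqrt(var[nz]) / val[nz]
    with open(path, "w") as fh:
        fh.write("r_cm,theta_deg,dose_per_history_Gy,rel_uncertainty\n")
        for i, r in enumerate(annular.r_centers):
            for j, th in enumerate(annular.theta_centers):
                fh.write(f"{r:g},{th:g},{val[i, j]:.6g},{rel[i, j]:.4g}\n")
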
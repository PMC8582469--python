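"""Synthetic study geometries.

The package's reference conditions are a water sphere of 15 cm radius for
source characterization and, for the heterogeneous pipeline, a synthetic
pelvis phantom on the clinical CT grid (0.78125 x 0.78125 x 2.0 mm) with a
67-seed prostate implant.  The pelvis phantom stands in for a patient CT
(which is not distributed): ellipsoidal organs over the four-material HU
map, deterministic given its parameters.
"""

from __future__ import annotations

import numpy as np

from .clinical import HuMaterialMap, PlanEntry, TreatmentPlan, hu_to_phantom
from .geometry import Pose
from .scoring import VoxelPhantom

CT_SPACING_MM = (0.78125, 0.78125, 2.0)


def make_water_box(half_extent_mm=(20.0, 2.0, 20.0), spacing_mm=0.25,
                   spacing_z_mm=None) -> VoxelPhantom:
    """An all-water voxel phantom centred on the origin.

    Mirrors the water-sphere profile geometry: a thin slab around the
    source, 0.25 mm voxels.  (Photons leaving the box are not tracked back;
    identical truncation applies to any two runs being compared.)
    """
    he = np.asarray(half_extent_mm, float)
    sp = np.array([spacing_mm, spacing_mm,
                   spacing_z_mm if spacing_z_mm else spacing_mm])
    dims = np.maximum(1, np.round(2 * he / sp).astype(int))
    origin = -dims * sp / 2.0
    ids = np.zeros(dims, np.int16)
    rho = np.full(dims, 0.998)
    return VoxelPhantom(origin=origin, spacing=sp, material_ids=ids,
                        density=rho, materials=("water",))


def _ellipsoid(xx, yy, zz, center, semi):
    return (((xx - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((zz - center[2]) / semi[2]) ** 2) <= 1.0


def make_pelvis_phantom(dims=(128, 128, 48), spacing_mm=CT_SPACING_MM):
    """Synthetic pelvis: HU raster plus organ masks on the CT grid.

    Organs (ellipsoids/cylinders, mm, centred coordinates): prostate at the
    origin, urethra through it, bladder anterior-superior, rectum posterior,
    femoral heads and a sacrum slab as bone.  Returns
    ``(phantom, organs dict, hu array)``; the phantom uses the default
    four-material HU map with the prostate interval confined to the
    prostate mask.
    """
    dims = tuple(int(d) for d in dims)
    sp = np.asarray(spacing_mm, float)
    origin = -np.asarray(dims) * sp / 2.0
    ax = [origin[i] + (np.arange(dims[i]) + 0.5) * sp[i] for i in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")

    hu = np.full(dims, 20.0)                      # body: soft tissue
    organs = {}
    prostate = _ellipsoid(xx, yy, zz, (0, 0, 0), (22.0, 20.0, 18.0))
    urethra = (np.hypot(xx, yy - 2.0) <= 3.0) & (np.abs(zz) <= 20.0)
    bladder = _ellipsoid(xx, yy, zz, (0.0, -28.0, 14.0), (24.0, 18.0, 16.0))
    rectum = (np.hypot(xx, yy - 32.0) <= 12.0) & (np.abs(zz) <= 40.0)
    femur_l = _ellipsoid(xx, yy, zz, (-42.0, 4.0, 0.0), (14.0, 14.0, 22.0))
    femur_r = _ellipsoid(xx, yy, zz, (42.0, 4.0, 0.0), (14.0, 14.0, 22.0))
    hu[bladder] = 10.0
    hu[rectum] = -350.0                           # partially gas-filled
    hu[prostate] = 150.0
    hu[urethra] = 30.0
    hu[femur_l | femur_r] = 700.0
    organs["prostate"] = prostate & ~urethra
    organs["urethra"] = urethra & prostate
    organs["bladder"] = bladder
    organs["rectum"] = rectum
    phantom = hu_to_phantom(hu, HuMaterialMap.default(), sp, origin,
                            prostate_mask=prostate)
    return phantom, organs, hu


def make_plan_67(seed_id: str = "AmershamOncoseed6711",
                 s_k_per_seed: float = 0.5,
                 prescription_gy: float = 145.0) -> TreatmentPlan:
    """A deterministic 67-seed implant: a 5 mm needle lattice clipped to the
    prostate ellipsoid of :func:`make_pelvis_phantom`, seeds along +Z."""
    semi = np.array([22.0, 20.0, 18.0])
    xs = np.arange(-20.0, 20.1, 5.0)
    ys = np.arange(-17.5, 17.6, 5.0)
    zs = np.arange(-12.0, 12.1, 6.0)
    centers = []
    for x in xs:
        for y in ys:
            for z in zs:
                if (x / (semi[0] - 2)) ** 2 + (y / (semi[1] - 2)) ** 2 \
                        + (z / (semi[2] - 3)) ** 2 <= 1.0:
                    centers.append((x, y, z))
    centers.sort(key=lambda c: (round(c[2], 3), round(c[1], 3),
                                round(c[0], 3)))
    if len(centers) < 67:
        raise RuntimeError(f"lattice yields only {len(centers)} sites")
    step = len(centers) / 67.0
    chosen = [centers[int(i * step)] for i in range(67)]
    entries = [PlanEntry(seed_id=seed_id,
                         pose=Pose(translation=c, axis=(0, 0, 1),
                                   angle_deg=0.0),
                         s_k=s_k_per_seed) for c in chosen]
    return TreatmentPlan(entries=entries, prescription_gy=prescription_gy)
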
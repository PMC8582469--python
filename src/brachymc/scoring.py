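"""Estimators and score containers.

``DoseMap`` (Cartesian voxels) and ``AnnularMap`` (thin spherical shells by
polar angle) accumulate track-length kerma per source history together with
history-by-history statistical moments.  ``score_air_kerma_strength``
implements the in-vacuo transverse-ring air-kerma scorer that normalizes the
TG-43 dose rate constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GRAY_PER_KEV_PER_G
from .geometry import SeedModel
from .physics import get_material, mu_over_rho

DELTA_CUT_KEV = 5.0     # standard low-energy cut for air-kerma strength


class _Accumulators:
    """Shared per-cell accumulation machinery (flat arrays)."""

    def _init_acc(self, ncells: int):
        self._sum = np.zeros(ncells)
        self._sumsq = np.zeros(ncells)
        self._acc = np.zeros(ncells)
        self._last = np.full(ncells, -1, np.int64)
        self.n_histories = 0

    def _score(self, idx, val, hist):
        """Reference (non-kernel) scoring of one contribution."""
        self._sum[idx] += val
        if self._last[idx] != hist:
            if self._last[idx] >= 0:
                self._sumsq[idx] += self._acc[idx] ** 2
            self._acc[idx] = val
            self._last[idx] = hist
        else:
            self._acc[idx] += val

    def _flush(self):
        live = self._last >= 0
        self._sumsq[live] += self._acc[live] ** 2
        self._acc[:] = 0.0
        self._last[:] = -1


class DoseMap(_Accumulators):
    """Cartesian kerma map: Gy per source history, with per-voxel variance.

    ``origin``/``spacing`` are millimetres (origin = corner of voxel
    (0,0,0)); values are stored per history so maps from runs with different
    history counts remain comparable.
    """

    def __init__(self, origin_mm, spacing_mm, dims):
        self.origin = np.asarray(origin_mm, float)
        self.spacing = np.asarray(spacing_mm, float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        self.dims = tuple(int(d) for d in dims)
        self._init_acc(int(np.prod(self.dims)))

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def value(self) -> np.ndarray:
        """Gy per source history, shape ``dims``."""
        n = max(self.n_histories, 1)
        return (self._sum / n).reshape(self.dims)

    @property
    def variance(self) -> np.ndarray:
        """Variance of the per-history mean, shape ``dims``."""
        n = self.n_histories
        if n < 2:
            raise ValueError("need at least 2 histories for a variance")
        m1 = self._sum / n
        m2 = self._sumsq / n
        return ((m2 - m1**2) / (n - 1)).reshape(self.dims)

    def centers(self):
        """Voxel-centre coordinate arrays (mm)."""
        return tuple(self.origin[i] + (np.arange(self.dims[i]) + 0.5)
                     * self.spacing[i] for i in range(3))


def estimate_uncertainty(dose_map) -> np.ndarray:
    """Relative standard error per cell (history-by-history estimator).

    sigma_rel = sqrt((<x^2> - <x>^2) / (N - 1)) / <x>; cells with zero score
    are flagged NaN.
    """
    if dose_map.n_histories < 2:
        raise ValueError("need at least 2 histories")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(dose_map.variance) / dose_map.value
    rel[dose_map.value == 0] = np.nan
    return rel


def tle_score(dose_map: DoseMap, cells, lengths_mm, energy_kev, weight,
              materials, history: int = 0):
    """Reference track-length kerma scoring of one particle segment.

    ``cells`` are (i,j,k) index triples, ``lengths_mm`` the chord of the
    segment in each cell, ``materials`` a material name per cell.  Cells
    outside the grid are clipped (not an error); negative lengths violate
    the estimator's contract.
    """
    lengths = np.atleast_1d(np.asarray(lengths_mm, float))
    if np.any(lengths < 0):
        raise ValueError("negative track length")
    if np.isscalar(materials) or isinstance(materials, str):
        materials = [materials] * lengths.size
    v_cm3 = dose_map.voxel_volume_cm3
    for (i, j, k), ell, mat in zip(cells, lengths, materials):
        if not (0 <= i < dose_map.dims[0] and 0 <= j < dose_map.dims[1]
                and 0 <= k < dose_map.dims[2]):
            continue
        muen = mu_over_rho(get_material(mat) if isinstance(mat, str) else mat,
                           energy_kev, "energy_absorption")
        val = (weight * energy_kev * muen * (ell / 10.0) / v_cm3
               * GRAY_PER_KEV_PER_G)
        flat = (i * dose_map.dims[1] + j) * dose_map.dims[2] + k
        dose_map._score(flat, val, history)


class AnnularMap(_Accumulators):
    """Kerma on thin spherical shells binned by polar angle.

    Shells are ``[r_lo[i], r_hi[i]]`` (cm, disjoint, ascending); polar bins
    are ``theta_edges`` degrees over [0, 180] measured from +Z (the seed tip
    direction).  A dedicated 1-degree bin is centred on the transverse plane
    (90 deg).
    """

    def __init__(self, r_lo, r_hi, theta_edges_deg):
        self.r_lo = np.ascontiguousarray(r_lo, float)
        self.r_hi = np.ascontiguousarray(r_hi, float)
        self.theta_edges = np.ascontiguousarray(theta_edges_deg, float)
        if np.any(np.diff(self.theta_edges) <= 0):
            raise ValueError("theta edges must increase")
        if np.any(self.r_lo >= self.r_hi) or np.any(np.diff(self.r_lo) <= 0):
            raise ValueError("shell radii must increase")
        nr, nth = self.r_lo.size, self.theta_edges.size - 1
        cos_hi = np.cos(np.deg2rad(self.theta_edges[:-1]))
        cos_lo = np.cos(np.deg2rad(self.theta_edges[1:]))
        vol = (2 * np.pi / 3.0
               * (self.r_hi**3 - self.r_lo**3)[:, None]
               * (cos_hi - cos_lo)[None, :])
        self._inv_vcell = np.ascontiguousarray(1.0 / vol.ravel())
        self._init_acc(nr * nth)

    @classmethod
    def default(cls):
        """The characterization grid: shells at the TG-43 reporting radii
        (2.5% relative half-thickness), 5-degree polar bins with a 1-degree
        bin at 90 degrees."""
        r = np.array([0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 7.5,
                      10.0])
        edges = np.concatenate([np.arange(0.0, 86.0, 5.0), [89.5, 90.5],
                                np.arange(95.0, 181.0, 5.0)])
        return cls(r * 0.975, r * 1.025, edges)

    @property
    def r_centers(self):
        return 0.5 * (self.r_lo + self.r_hi)

    @property
    def theta_centers(self):
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    @property
    def shape(self):
        return (self.r_lo.size, self.theta_edges.size - 1)

    @property
    def theta90_index(self) -> int:
        idx = np.argmin(np.abs(self.theta_centers - 90.0))
        lo, hi = self.theta_edges[idx], self.theta_edges[idx + 1]
        if not (lo < 90.0 < hi):
            raise ValueError("no polar bin brackets 90 degrees")
        return int(idx)

    @property
    def value(self):
        n = max(self.n_histories, 1)
        return (self._sum / n).reshape(self.shape)

    @property
    def variance(self):
        n = self.n_histories
        if n < 2:
            raise ValueError("need at least 2 histories for a variance")
        m1 = self._sum / n
        m2 = self._sumsq / n
        return ((m2 - m1**2) / (n - 1)).reshape(self.shape)

    def r_index(self, r_cm: float) -> int:
        hit = np.flatnonzero((self.r_lo <= r_cm) & (r_cm <= self.r_hi))
        if hit.size == 0:
            raise KeyError(f"no shell contains r = {r_cm} cm")
        return int(hit[0])


@dataclass
class VoxelPhantom:
    """Raster world: per-voxel material id and density.

    ``origin`` (mm) is the corner of voxel (0,0,0); ``materials`` maps the
    ids to material names.
    """

    origin: np.ndarray
    spacing: np.ndarray
    material_ids: np.ndarray        # (nx, ny, nz) small ints
    density: np.ndarray             # g/cm^3 per voxel
    materials: tuple

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.material_ids = np.ascontiguousarray(self.material_ids,
                                                 np.int16)
        self.density = np.ascontiguousarray(self.density, np.float64)
        if self.material_ids.max() >= len(self.materials):
            raise ValueError("unresolvable material id")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def dims(self):
        return self.material_ids.shape

    def new_map(self) -> DoseMap:
        return DoseMap(self.origin, self.spacing, self.dims)


@dataclass
class KermaStrengthResult:
    """Air kerma strength per source history.

    ``s_k`` is in Gy cm^2 per history.  Multiplying by a source's history
    rate (decays per hour) and 100 (Gy to cGy) gives U = cGy cm^2/h; the
    TG-43 dose rate constant is formed as a ratio and never needs that rate.
    """

    s_k: float
    rel_uncertainty: float
    per_distance: np.ndarray
    distances_cm: np.ndarray
    delta_cut_kev: float
    n_primary: int

    def __post_init__(self):
        spread = np.ptp(self.per_distance) / self.s_k if self.s_k else np.inf
        self.distance_spread = float(spread)


def ring_chords(positions_cm, directions, distance_cm,
                rel_half_thickness=0.025, half_angle_deg=0.5):
    """Chord length of straight rays through a thin transverse ring.

    The ring is the region rho in [d(1-h), d(1+h)], |z| <= d tan(half_angle)
    (a WAFAC-style annulus centred on the transverse plane).  Returns
    (chords_cm, ring_volume_cm3).
    """
    d = float(distance_cm)
    r1 = d * (1.0 - rel_half_thickness)
    r2 = d * (1.0 + rel_half_thickness)
    zh = d * np.tan(np.deg2rad(half_angle_deg))
    p = np.atleast_2d(positions_cm)
    u = np.atleast_2d(directions)
    big = 1e12

    def cyl_interval(r):
        a = u[:, 0] ** 2 + u[:, 1] ** 2
        b = 2 * (p[:, 0] * u[:, 0] + p[:, 1] * u[:, 1])
        c = p[:, 0] ** 2 + p[:, 1] ** 2 - r * r
        disc = b * b - 4 * a * c
        ok = (disc > 0) & (a > 1e-300)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(ok, (-b - sq) / (2 * a), big)
            t2 = np.where(ok, (-b + sq) / (2 * a), -big)
        return t1, t2

    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (-zh - p[:, 2]) / u[:, 2]
        tb = (zh - p[:, 2]) / u[:, 2]
    s1 = np.minimum(ta, tb)
    s2 = np.maximum(ta, tb)
    par = np.abs(u[:, 2]) < 1e-300
    inside = np.abs(p[:, 2]) <= zh
    s1 = np.where(par, np.where(inside, -big, big), s1)
    s2 = np.where(par, np.where(inside, big, -big), s2)

    def clip_len(t1, t2):
        lo = np.maximum(np.maximum(t1, s1), 0.0)
        hi = np.minimum(t2, s2)
        return np.maximum(hi - lo, 0.0)

    o1, o2 = cyl_interval(r2)
    i1, i2 = cyl_interval(r1)
    chord = clip_len(o1, o2) - clip_len(i1, i2)
    vol = np.pi * (r2**2 - r1**2) * 2 * zh
    return np.maximum(chord, 0.0), vol


def score_air_kerma_strength(source, distances_cm=(5.0, 7.5, 10.0),
                             delta_cut_kev: float = DELTA_CUT_KEV,
                             n_histories: int = 200_000,
                             rng=None, fluorescence: bool = True):
    """Air kerma strength per history, scored in vacuo on transverse rings.

    ``source`` is a SeedModel (photons are generated by transporting decay
    photons out of the capsule) or a transport.EscapedPhotons.  For each
    distance d the TLE air kerma K(d) in a thin ring is multiplied by d^2;
    the result is their mean.  Photons below ``delta_cut_kev`` are ignored.
    In vacuum rays are straight, so the scorer is a pure ray-trace.
    """
    from .transport import EscapedPhotons, transport_through_seed
    if isinstance(source, SeedModel):
        rng = np.random.default_rng(0) if rng is None else rng
        ext = max(abs(z) for c in source.components
                  for z in c.solid.z_extent) / 10.0
        if min(distances_cm) * 0.975 <= ext:
            raise ValueError("scoring ring overlaps the seed")
        photons = transport_through_seed(source, n_histories, rng,
                                         fluorescence=fluorescence)
    elif isinstance(source, EscapedPhotons):
        photons = source
    else:
        raise TypeError("source must be a SeedModel or EscapedPhotons")
    air = get_material("air")
    e = photons.energy_kev
    keep = e >= delta_cut_kev
    muen = np.zeros_like(e)
    if np.any(keep):
        muen[keep] = mu_over_rho(air, e[keep], "energy_absorption")
    p_cm = photons.position_mm / 10.0
    per_d = []
    var_d = []
    n_prim = photons.n_primary
    for d in distances_cm:
        chord, vol = ring_chords(p_cm, photons.direction, d)
        contrib = (photons.weight * e * muen * chord / vol
                   * GRAY_PER_KEV_PER_G)
        k = contrib.sum() / n_prim
        k2 = (contrib**2).sum() / n_prim
        var = (k2 - k**2) / max(n_prim - 1, 1)
        per_d.append(k * d * d)
        var_d.append(var * d**4)
    per_d = np.asarray(per_d)
    var_d = np.asarray(var_d)
    s_k = float(per_d.mean())
    sigma = float(np.sqrt(var_d.sum()) / len(per_d))
    return KermaStrengthResult(
        s_k=s_k, rel_uncertainty=sigma / s_k if s_k else np.inf,
        per_distance=per_d, distances_cm=np.asarray(distances_cm, float),
        delta_cut_kev=delta_cut_kev, n_primary=n_prim)
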
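"""Parametric seed geometry: nested analytic solids with ray-tracing support.

Each seed is an ordered list of axisymmetric solids (innermost first) with a
material and role flags, loaded from a reviewable per-seed data file.  The
seed local frame has the long axis along Z, origin at the centre of the
active region, and the positive Z axis through the source tip.  All lengths
in this module are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .physics import DATA_DIR, Material, get_material, get_spectrum, _parse_header

SEED_IDS = (
    "AmershamOncoseed6711",
    "BebigIsoseedI25S06",
    "NucletronMHDRv1",
    "VarianVS2000",
    "SpecM19",
    "NucletronMPDRv2",
)

_INF = np.inf


@dataclass(frozen=True)
class Solid:
    """Axisymmetric convex solid: cylinder, capsule, sphere or cone frustum.

    ``r`` is the radius (for a frustum, the radius at -half_len; ``r2`` the
    radius at +half_len); ``half_len`` the half length of the cylindrical or
    conical part (capsule caps extend beyond it); ``center`` the local
    translation.  The solid axis is Z.
    """

    kind: str                      # cylinder | capsule | sphere | cone_frustum
    r: float
    half_len: float = 0.0
    r2: float = 0.0
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.kind not in ("cylinder", "capsule", "sphere", "cone_frustum"):
            raise ValueError(f"unknown solid kind {self.kind!r}")
        if self.r <= 0 or (self.kind != "sphere" and self.half_len <= 0):
            raise ValueError("solid dimensions must be positive")

    # ---- extents ----------------------------------------------------------
    @property
    def z_extent(self):
        cz = self.center[2]
        if self.kind == "sphere":
            return cz - self.r, cz + self.r
        if self.kind == "capsule":
            return cz - self.half_len - self.r, cz + self.half_len + self.r
        return cz - self.half_len, cz + self.half_len

    @property
    def r_max(self):
        return max(self.r, self.r2)

    def volume(self) -> float:
        if self.kind == "cylinder":
            return np.pi * self.r**2 * 2 * self.half_len
        if self.kind == "sphere":
            return 4 / 3 * np.pi * self.r**3
        if self.kind == "capsule":
            return (np.pi * self.r**2 * 2 * self.half_len
                    + 4 / 3 * np.pi * self.r**3)
        h = 2 * self.half_len
        return np.pi * h / 3 * (self.r**2 + self.r * self.r2 + self.r2**2)

    # ---- queries ----------------------------------------------------------
    def _local(self, p):
        return p - np.asarray(self.center)

    def contains(self, points) -> np.ndarray:
        p = self._local(np.atleast_2d(np.asarray(points, float)))
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        rho2 = x * x + y * y
        if self.kind == "cylinder":
            out = (rho2 <= self.r**2) & (np.abs(z) <= self.half_len)
        elif self.kind == "sphere":
            out = rho2 + z * z <= self.r**2
        elif self.kind == "capsule":
            zc = np.clip(z, -self.half_len, self.half_len)
            out = rho2 + (z - zc) ** 2 <= self.r**2
        else:
            t = (z + self.half_len) / (2 * self.half_len)
            rad = self.r + (self.r2 - self.r) * t
            out = (np.abs(z) <= self.half_len) & (rho2 <= rad**2)
        return out

    def intersect(self, origins, directions):
        """Entry/exit parameters of rays with the solid.

        Returns ``(t_in, t_out)`` arrays; a miss yields ``t_in > t_out``.
        The interval may extend to negative t (ray line, not half-line).
        """
        o = self._local(np.atleast_2d(np.asarray(origins, float)))
        d = np.atleast_2d(np.asarray(directions, float))
        if self.kind == "cylinder":
            return _isect_and(_infcyl(o, d, self.r), _slab(o, d, self.half_len))
        if self.kind == "sphere":
            return _sphere_interval(o, d, self.r, 0.0)
        if self.kind == "capsule":
            ivs = [
                _isect_and(_infcyl(o, d, self.r), _slab(o, d, self.half_len)),
                _sphere_interval(o, d, self.r, self.half_len),
                _sphere_interval(o, d, self.r, -self.half_len),
            ]
            t_in = np.full(o.shape[0], _INF)
            t_out = np.full(o.shape[0], -_INF)
            for a, b in ivs:
                ok = a <= b
                t_in = np.where(ok, np.minimum(t_in, a), t_in)
                t_out = np.where(ok, np.maximum(t_out, b), t_out)
            return t_in, t_out
        return self._frustum_interval(o, d)

    def _frustum_interval(self, o, d):
        # generic convex interval by boundary-candidate classification
        n = o.shape[0]
        t_in = np.full(n, _INF)
        t_out = np.full(n, -_INF)
        alpha = (self.r + self.r2) / 2.0
        beta = (self.r2 - self.r) / (2.0 * self.half_len)
        for i in range(n):
            cands = []
            a = d[i, 0] ** 2 + d[i, 1] ** 2 - (beta * d[i, 2]) ** 2
            b = 2 * (o[i, 0] * d[i, 0] + o[i, 1] * d[i, 1]
                     - beta * d[i, 2] * (alpha + beta * o[i, 2]))
            c = o[i, 0] ** 2 + o[i, 1] ** 2 - (alpha + beta * o[i, 2]) ** 2
            if abs(a) > 1e-14:
                disc = b * b - 4 * a * c
                if disc >= 0:
                    sq = np.sqrt(disc)
                    cands += [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
            elif abs(b) > 1e-14:
                cands += [-c / b]
            if abs(d[i, 2]) > 1e-14:
                cands += [(-self.half_len - o[i, 2]) / d[i, 2],
                          (self.half_len - o[i, 2]) / d[i, 2]]
            if not cands:
                continue
            cands = sorted(cands)
            center = np.asarray(self.center)
            for lo, hi in zip(cands[:-1], cands[1:]):
                mid = (lo + hi) / 2.0
                p = o[i] + mid * d[i] + center
                if self.contains(p[None, :])[0]:
                    t_in[i] = min(t_in[i], lo)
                    t_out[i] = max(t_out[i], hi)
        return t_in, t_out


def _infcyl(o, d, r):
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = 2 * (o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1])
    c = o[:, 0] ** 2 + o[:, 1] ** 2 - r * r
    disc = b * b - 4 * a * c
    ok = (disc >= 0) & (a > 1e-300)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(ok, (-b - sq) / (2 * a), _INF)
        t2 = np.where(ok, (-b + sq) / (2 * a), -_INF)
    axis_par = a <= 1e-300
    inside = c < 0
    t1 = np.where(axis_par & inside, -_INF, t1)
    t2 = np.where(axis_par & inside, _INF, t2)
    return t1, t2


def _slab(o, d, h):
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (-h - o[:, 2]) / d[:, 2]
        tb = (h - o[:, 2]) / d[:, 2]
    t1 = np.minimum(ta, tb)
    t2 = np.maximum(ta, tb)
    par = np.abs(d[:, 2]) < 1e-300
    inside = np.abs(o[:, 2]) <= h
    t1 = np.where(par, np.where(inside, -_INF, _INF), t1)
    t2 = np.where(par, np.where(inside, _INF, -_INF), t2)
    return t1, t2


def _sphere_interval(o, d, r, cz):
    oz = o.copy()
    oz[:, 2] -= cz
    b = 2 * np.sum(oz * d, axis=1)
    c = np.sum(oz * oz, axis=1) - r * r
    disc = b * b - 4 * c
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t1 = np.where(ok, (-b - sq) / 2, _INF)
    t2 = np.where(ok, (-b + sq) / 2, -_INF)
    return t1, t2


def _isect_and(iv1, iv2):
    return np.maximum(iv1[0], iv2[0]), np.minimum(iv1[1], iv2[1])


@dataclass(frozen=True)
class Pose:
    """Rigid placement of a seed in the world frame (translation in mm)."""

    translation: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0

    @property
    def rotation(self) -> np.ndarray:
        ax = np.asarray(self.axis, float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("zero rotation axis")
        ax = ax / n
        th = np.deg2rad(self.angle_deg)
        K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]],
                      [-ax[1], ax[0], 0]])
        return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)

    def apply_points(self, p):
        return np.asarray(p, float) @ self.rotation.T + np.asarray(
            self.translation, float)

    def apply_directions(self, d):
        return np.asarray(d, float) @ self.rotation.T


@dataclass(frozen=True)
class SeedComponent:
    name: str
    solid: Solid
    material: Material
    roles: frozenset


@dataclass(frozen=True)
class SeedModel:
    """A seed as nested solids (innermost first) with an active region."""

    seed_id: str
    components: tuple
    nuclide: str
    active_length: float            # mm
    active_mode: str                # volume | surface

    @property
    def active_index(self) -> int:
        for i, c in enumerate(self.components):
            if "active" in c.roles:
                return i
        raise ValueError(f"{self.seed_id}: no active component")

    @property
    def active(self) -> SeedComponent:
        return self.components[self.active_index]

    @property
    def outer_surface(self) -> Solid:
        """The outermost body solid (excludes the cable stub)."""
        body = [c for c in self.components if "cable" not in c.roles]
        return body[-1].solid

    @property
    def spectrum(self):
        return get_spectrum(self.nuclide)

    def material_at(self, points) -> np.ndarray:
        """Component index at each point (innermost wins), -1 if outside."""
        p = np.atleast_2d(np.asarray(points, float))
        out = np.full(p.shape[0], -1, dtype=np.int64)
        undecided = np.ones(p.shape[0], bool)
        for i, c in enumerate(self.components):
            hit = undecided & c.solid.contains(p)
            out[hit] = i
            undecided &= ~hit
        return out

    def validate(self) -> None:
        """Check the nesting contract: each component is contained in its
        successor or axially disjoint from it."""
        for a, b in zip(self.components[:-1], self.components[1:]):
            za, zb = a.solid.z_extent, b.solid.z_extent
            contained = (a.solid.r_max <= b.solid.r_max + 1e-9
                         and za[0] >= zb[0] - 1e-9 and za[1] <= zb[1] + 1e-9)
            disjoint = za[1] <= zb[0] + 1e-9 or za[0] >= zb[1] - 1e-9
            if not (contained or disjoint):
                raise ValueError(
                    f"{self.seed_id}: component {a.name!r} neither contained "
                    f"in nor disjoint from {b.name!r}")
        if self.active_length <= 0:
            raise ValueError("active_length must be positive")
        self.active  # raises if missing


@lru_cache(maxsize=None)
def build_seed(seed_id: str) -> SeedModel:
    """Load one of the six seed models from its data file."""
    path = DATA_DIR / "seeds" / f"{seed_id}.csv"
    if not path.exists():
        raise KeyError(
            f"unknown seed {seed_id!r}; available: {', '.join(SEED_IDS)}")
    meta = _parse_header(path)
    rows = pd.read_csv(path, comment="#")
    comps = []
    for r in rows.itertuples():
        comps.append(SeedComponent(
            name=str(r.component),
            solid=Solid(kind=str(r.kind), r=float(r.r_mm),
                        half_len=float(r.half_len_mm),
                        center=(0.0, 0.0, float(r.cz_mm))),
            material=get_material(str(r.material)),
            roles=frozenset(str(r.role).split("|")),
        ))
    model = SeedModel(
        seed_id=meta["seed_id"],
        components=tuple(comps),
        nuclide=meta["nuclide"],
        active_length=float(meta["active_length_mm"]),
        active_mode=meta["active_mode"],
    )
    model.validate()
    return model


def sample_emission(seed: SeedModel, rng: np.random.Generator, n: int = 1):
    """Sample decay-photon starting states from the active region.

    Returns ``(positions mm (n,3), directions (n,3), energies keV (n,),
    weights (n,))``.  Positions are volume-uniform over the active solid
    (excluding nested inner components) or surface-uniform when the active
    region is a coating layer; directions are isotropic; energies follow the
    nuclide line spectrum.
    """
    act = seed.active
    sol = act.solid
    cz = sol.center[2]
    if seed.active_mode == "surface":
        if sol.kind != "cylinder":
            raise NotImplementedError("surface emission only for cylinders")
        a_side = 2 * np.pi * sol.r * 2 * sol.half_len
        a_end = np.pi * sol.r**2
        u = rng.random(n) * (a_side + 2 * a_end)
        phi = rng.random(n) * 2 * np.pi
        pos = np.empty((n, 3))
        side = u < a_side
        pos[side, 0] = sol.r * np.cos(phi[side])
        pos[side, 1] = sol.r * np.sin(phi[side])
        pos[side, 2] = cz + (rng.random(side.sum()) * 2 - 1) * sol.half_len
        ends = ~side
        rr = sol.r * np.sqrt(rng.random(ends.sum()))
        pos[ends, 0] = rr * np.cos(phi[ends])
        pos[ends, 1] = rr * np.sin(phi[ends])
        pos[ends, 2] = cz + np.where(
            u[ends] < a_side + a_end, sol.half_len, -sol.half_len)
    else:
        inner = seed.components[:seed.active_index]
        pos = np.empty((n, 3))
        filled = 0
        while filled < n:
            m = n - filled
            phi = rng.random(m) * 2 * np.pi
            rr = sol.r * np.sqrt(rng.random(m))
            cand = np.stack([rr * np.cos(phi), rr * np.sin(phi),
                             cz + (rng.random(m) * 2 - 1) * sol.half_len], 1)
            keep = np.ones(m, bool)
            for c in inner:
                keep &= ~c.solid.contains(cand)
            k = int(keep.sum())
            pos[filled:filled + k] = cand[keep]
            filled += k
    dirs = isotropic_directions(rng, n)
    from .physics import sample_line
    energies = sample_line(seed.spectrum, rng, size=n)
    return pos, dirs, np.asarray(energies, float), np.ones(n)


def isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    cos_t = rng.random(n) * 2 - 1
    sin_t = np.sqrt(1 - cos_t**2)
    phi = rng.random(n) * 2 * np.pi
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], 1)


def trace(position, direction, seed: SeedModel):
    """Material segments a ray crosses through the seed solids.

    Returns an ordered list of ``(length_mm, material_name)`` pairs from the
    ray start until it finally leaves all solids; vacuum gaps between
    disjoint solids (capsule to cable) are skipped.  ``direction`` must be
    a unit vector.
    """
    d = np.asarray(direction, float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be normalized")
    o = np.asarray(position, float)[None, :]
    dn = d[None, :]
    cuts = {0.0}
    for c in seed.components:
        t1, t2 = c.solid.intersect(o, dn)
        if t1[0] <= t2[0]:
            for t in (t1[0], t2[0]):
                if t > 1e-12:
                    cuts.add(float(t))
    ts = sorted(cuts)
    segs = []
    for lo, hi in zip(ts[:-1], ts[1:]):
        mid = o[0] + (lo + hi) / 2.0 * d
        idx = seed.material_at(mid[None, :])[0]
        if idx >= 0:
            name = seed.components[idx].material.name
            if segs and segs[-1][1] is name:
                segs[-1] = (segs[-1][0] + hi - lo, name)
            else:
                segs.append((hi - lo, name))
    return [(length, name) for length, name in segs]
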
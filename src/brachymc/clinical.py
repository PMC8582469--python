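"""Heterogeneous-case pipeline: HU-to-material conversion, multi-seed plan
simulation by phase-space replay in a voxel phantom, cumulative DVHs,
isodose masks and dose-map comparison metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Pose
from .phsp import PhspFile, replay_source
from .scoring import DoseMap, VoxelPhantom, estimate_uncertainty
from .transport import SimConfig, run_voxel_phantom

log = logging.getLogger(__name__)

HU_SPAN = (-1050.0, 4000.0)


@dataclass(frozen=True)
class HuRange:
    lo: float                     # inclusive
    hi: float                     # exclusive (closed-open)
    material: str
    density: float                # g/cm^3, nominal


@dataclass(frozen=True)
class HuMaterialMap:
    """Ordered, contiguous HU intervals covering the declared span."""

    ranges: tuple
    span: tuple = HU_SPAN

    def __post_init__(self):
        rs = self.ranges
        if not rs:
            raise ValueError("empty HU map")
        if abs(rs[0].lo - self.span[0]) > 1e-9 or abs(
                rs[-1].hi - self.span[1]) > 1e-9:
            raise ValueError("HU ranges must cover the declared span")
        for a, b in zip(rs[:-1], rs[1:]):
            if abs(a.hi - b.lo) > 1e-9:
                raise ValueError("HU ranges must be contiguous")

    @classmethod
    def default(cls):
        """Four-material map: lung / soft tissue / prostate / bone.

        The cut points are this package's documented defaults; the prostate
        interval is only honoured inside a declared prostate mask (otherwise
        soft tissue), see :func:`hu_to_phantom`.
        """
        return cls(ranges=(
            HuRange(-1050.0, -600.0, "lung", 0.26),
            HuRange(-600.0, 100.0, "soft_tissue", 1.06),
            HuRange(100.0, 300.0, "prostate", 1.04),
            HuRange(300.0, 4000.0, "cortical_bone", 1.92),
        ))

    @property
    def materials(self):
        return tuple(r.material for r in self.ranges)

    def lookup(self, hu):
        """Range index per HU value (closed-open intervals, boundary goes
        to the upper interval)."""
        edges = np.array([r.lo for r in self.ranges] + [self.ranges[-1].hi])
        idx = np.searchsorted(edges, np.asarray(hu, float), side="right") - 1
        return np.clip(idx, 0, len(self.ranges) - 1)


def hu_to_phantom(hu, hu_map: HuMaterialMap, spacing_mm, origin_mm=None,
                  prostate_mask=None) -> VoxelPhantom:
    """Convert a HU raster into a voxel phantom.

    Out-of-span HU are clamped (count logged).  The prostate interval is
    demoted to soft tissue outside ``prostate_mask`` when a mask is given.
    """
    hu = np.asarray(hu, float)
    if hu.size == 0:
        raise ValueError("empty HU raster")
    lo, hi = hu_map.span
    n_clamped = int(np.sum((hu < lo) | (hu > hi)))
    if n_clamped:
        log.info("clamped %d HU values into [%g, %g]", n_clamped, lo, hi)
    hu_c = np.clip(hu, lo, np.nextafter(hi, -np.inf))
    ids = hu_map.lookup(hu_c)
    mats = list(hu_map.materials)
    if prostate_mask is not None and "prostate" in mats:
        pi = mats.index("prostate")
        si = mats.index("soft_tissue")
        ids = np.where((ids == pi) & ~np.asarray(prostate_mask, bool), si,
                       ids)
    density = np.array([r.density for r in hu_map.ranges])[ids]
    origin = (np.zeros(3) if origin_mm is None
              else np.asarray(origin_mm, float))
    return VoxelPhantom(origin=origin, spacing=np.asarray(spacing_mm, float),
                        material_ids=ids.astype(np.int16), density=density,
                        materials=tuple(mats))


@dataclass
class PlanEntry:
    seed_id: str
    pose: Pose
    s_k: float                   # air kerma strength, U

    def __post_init__(self):
        t = np.asarray(self.pose.translation, float)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite seed pose")


@dataclass
class TreatmentPlan:
    entries: list
    prescription_gy: float = 145.0

    def __post_init__(self):
        if not self.entries:
            raise ValueError("a plan needs at least one seed")

    @property
    def total_sk(self):
        return sum(e.s_k for e in self.entries)

    @classmethod
    def from_csv(cls, path, prescription_gy: float = 145.0):
        df = pd.read_csv(path, comment="#")
        entries = [PlanEntry(
            seed_id=str(r.seed_id),
            pose=Pose(translation=(r.x_mm, r.y_mm, r.z_mm),
                      axis=(r.axis_x, r.axis_y, r.axis_z),
                      angle_deg=r.angle_deg),
            s_k=float(r.s_k_U)) for r in df.itertuples()]
        return cls(entries=entries, prescription_gy=prescription_gy)

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("seed_id,x_mm,y_mm,z_mm,axis_x,axis_y,axis_z,"
                     "angle_deg,s_k_U\n")
            for e in self.entries:
                t = e.pose.translation
                a = e.pose.axis
                fh.write(f"{e.seed_id},{t[0]:g},{t[1]:g},{t[2]:g},"
                         f"{a[0]:g},{a[1]:g},{a[2]:g},"
                         f"{e.pose.angle_deg:g},{e.s_k:g}\n")


def simulate_plan_mc(plan: TreatmentPlan, phantom: VoxelPhantom,
                     config: SimConfig, phsp_for) -> tuple:
    """Replay every seed's phase space into the voxel phantom with
    track-length kerma scoring on the phantom grid.

    ``phsp_for`` maps seed_id -> PhspFile (dict or callable).  Histories are
    distributed over the entries proportionally to their air kerma strength
    (largest-remainder rounding), so the per-history map carries the plan's
    relative seed weighting; particle weights are additionally scaled by the
    plan's total S_K, making the map linear in the seed strengths (units:
    Gy x U per simulated history; absolute Gy needs the implant duration
    times the per-U history rate, which cancels in every relative metric).
    Seeds other than the emitting one are not materialized in the phantom
    (phase-space replay into tissue only).

    Returns ``(DoseMap, info dict)``.
    """
    def get_phsp(seed_id) -> PhspFile:
        f = phsp_for[seed_id] if isinstance(phsp_for, dict) else \
            phsp_for(seed_id)
        if f is None:
            raise KeyError(f"no phase space available for seed {seed_id!r}")
        return f

    for e in plan.entries:          # fail early, naming the seed
        get_phsp(e.seed_id)
    total_sk = plan.total_sk
    n_tot = config.n_histories
    raw = np.array([e.s_k / total_sk * n_tot for e in plan.entries])
    n_i = np.floor(raw).astype(int)
    rem = n_tot - n_i.sum()
    order = np.argsort(raw - np.floor(raw))[::-1]
    n_i[order[:rem]] += 1
    dose = phantom.new_map()
    ss = np.random.SeedSequence(config.rng_seed)
    info = {"histories_per_seed": n_i.tolist(), "energy": []}
    hist_base = 0
    for e, n_seed, child in zip(plan.entries, n_i, ss.spawn(len(plan.entries))):
        if n_seed == 0:
            continue
        s_replay, s_track = (int(s.generate_state(1)[0] % (2**31 - 1))
                             for s in child.spawn(2))
        energy, pos_mm, dirs, w, hist = replay_source(
            get_phsp(e.seed_id), e.pose, n_seed,
            np.random.default_rng(s_replay))
        w = w * total_sk
        acct = run_voxel_phantom(
            (energy, pos_mm / 10.0, dirs, w, hist + hist_base),
            phantom, SimConfig(n_histories=n_seed, rng_seed=s_track,
                               tracking_cutoff=config.tracking_cutoff,
                               batch_size=config.batch_size),
            tle_map=dose)
        dose.n_histories -= n_seed      # run_voxel counts per call; fix below
        info["energy"].append(acct)
        hist_base += n_seed
    dose.n_histories = n_tot
    return dose, info


@dataclass
class CDVH:
    """Cumulative dose-volume histogram of one organ."""

    organ: str
    dose_edges: np.ndarray          # Gy (or Gy per history), ascending
    volume_fraction: np.ndarray     # % of organ volume receiving >= edge

    def __post_init__(self):
        if self.volume_fraction[0] != 100.0:
            raise ValueError("cDVH must start at 100%")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("cDVH must be non-increasing")

    def dose_at(self, volume_percent: float) -> float:
        """D_x: the dose received by at least x% of the organ."""
        vf = self.volume_fraction
        return float(np.interp(-volume_percent, -vf, self.dose_edges))


def compute_cdvh(dose_map: DoseMap, mask, edges=None,
                 organ: str = "organ") -> CDVH:
    """Fraction of the masked volume receiving at least each dose level.

    Voxel-count weighting (equals physical-volume weighting on the uniform
    grid).  ``edges`` default to 64 levels from 0 to the mask maximum.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != tuple(dose_map.dims):
        raise ValueError("mask grid does not match the dose map")
    if not mask.any():
        raise ValueError("empty organ mask")
    vals = dose_map.value[mask]
    if edges is None:
        edges = np.linspace(0.0, float(vals.max()), 64)
    edges = np.asarray(edges, float)
    frac = np.array([(vals >= d).mean() * 100.0 for d in edges])
    frac[edges == 0.0] = 100.0
    return CDVH(organ=organ, dose_edges=edges, volume_fraction=frac)


def isodose_masks(dose_map: DoseMap, prescription: float,
                  thresholds=(50.0, 100.0, 150.0)):
    """Boolean masks {dose > t% of prescription} per threshold, plus a label
    raster counting how many thresholds each voxel exceeds.

    Masks are nested by construction for ascending thresholds.
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    v = dose_map.value
    masks = {float(t): v > (t / 100.0) * prescription for t in thresholds}
    labels = np.zeros(dose_map.dims, np.int16)
    for t in sorted(masks):
        labels += masks[t].astype(np.int16)
    return masks, labels


@dataclass
class Profile:
    """A grid line through a dose map: vary one axis, fix the other two."""

    axis: int                       # 0, 1 or 2
    fixed: tuple                    # indices of the two fixed axes, in order

    def indices(self, dims):
        idx = [None, None, None]
        others = [a for a in range(3) if a != self.axis]
        idx[self.axis] = np.arange(dims[self.axis])
        for a, v in zip(others, self.fixed):
            idx[a] = np.full(dims[self.axis], int(v))
        return tuple(idx)


@dataclass
class MapComparison:
    point_diff_percent: np.ndarray    # signed, NaN where gated out
    combined_sigma_percent: np.ndarray
    average_percent: float
    maximum_percent: float
    n_compared: int

    def __post_init__(self):
        if self.n_compared and self.average_percent > self.maximum_percent:
            raise ValueError("average exceeds maximum")


def compare_maps(a: DoseMap, b: DoseMap, profile: Profile,
                 sigma_gate_percent: float = 5.0) -> MapComparison:
    """Relative difference 100 (a-b) / ((a+b)/2) along a profile, restricted
    to points where both maps' relative uncertainty is below the gate."""
    if tuple(a.dims) != tuple(b.dims) or not np.allclose(
            a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise ValueError("dose maps live on different grids")
    idx = profile.indices(a.dims)
    va = a.value[idx]
    vb = b.value[idx]
    ra = estimate_uncertainty(a)[idx]
    rb = estimate_uncertainty(b)[idx]
    ok = (np.nan_to_num(ra, nan=np.inf) <= sigma_gate_percent / 100.0) \
        & (np.nan_to_num(rb, nan=np.inf) <= sigma_gate_percent / 100.0) \
        & ((va + vb) > 0)
    diff = np.full(va.shape, np.nan)
    comb = np.full(va.shape, np.nan)
    mean = (va[ok] + vb[ok]) / 2.0
    diff[ok] = 100.0 * (va[ok] - vb[ok]) / mean
    comb[ok] = 100.0 * np.hypot(ra[ok] * va[ok], rb[ok] * vb[ok]) / mean
    n = int(ok.sum())
    avg = float(np.abs(diff[ok]).mean()) if n else np.nan
    mx = float(np.abs(diff[ok]).max()) if n else np.nan
    return MapComparison(point_diff_percent=diff,
                         combined_sigma_percent=comb,
                         average_percent=avg, maximum_percent=mx,
                         n_compared=n)
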
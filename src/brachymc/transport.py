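"""Photon Monte Carlo engine.

Three tracking regimes, all in the kerma approximation (no electron
transport; secondary-electron energy is deposited locally, which is what the
track-length kerma estimator assumes):

* inside a seed: analytic ray-traced tracking through the nested solids
  (vectorized NumPy), producing the photons that escape the capsule;
* homogeneous sphere phantom: analytic free-path sampling with thin-shell
  annular kerma scoring (numba kernel);
* voxel phantom: Woodcock delta-tracking with voxel-grid kerma scoring
  (numba kernel).

Energies are keV.  Seed-local positions are millimetres; phantom-frame
positions are centimetres (converted at the interface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import ELECTRON_REST_KEV, HC_KEV_ANGSTROM
from .geometry import SeedModel, isotropic_directions, sample_emission
from .physics import (Material, X2_GRID, get_element,
                      material_tables, mu_over_rho)

TRACKING_CUTOFF_KEV = 1.0


@dataclass
class SimConfig:
    """Run configuration shared by the engines."""

    n_histories: int = 100_000
    rng_seed: int = 0
    tracking_cutoff: float = TRACKING_CUTOFF_KEV   # keV
    fluorescence: bool = True
    batch_size: int = 200_000

    def __post_init__(self):
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.tracking_cutoff < 1.0:
            raise ValueError("tracking cutoff below the table minimum")


# ---------------------------------------------------------------------------
# Interaction samplers (NumPy reference implementations of the kernel logic)
# ---------------------------------------------------------------------------

def compton_scatter(energy_kev, rng: np.random.Generator, size=None):
    """Sample (E', cos theta) from the Klein-Nishina law (Kahn's method).

    Free-electron kinematics: E' = E / (1 + (E/m_e c^2)(1 - cos theta)).
    """
    n = 1 if size is None else int(size)
    a = float(energy_kev) / ELECTRON_REST_KEV
    e_out = np.empty(n)
    mu_out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        r1, r2, r3 = rng.random((3, todo.size))
        branch_a = r1 <= (1 + 2 * a) / (9 + 2 * a)
        x = np.where(branch_a, 1 + 2 * a * r2, (1 + 2 * a) / (1 + 2 * a * r2))
        mu = 1 - (x - 1) / a
        acc_a = r3 <= 4 * (1 / x - 1 / x**2)
        acc_b = r3 <= 0.5 * (mu**2 + 1 / x)
        acc = np.where(branch_a, acc_a, acc_b)
        sel = todo[acc]
        e_out[sel] = float(energy_kev) / x[acc]
        mu_out[sel] = mu[acc]
        todo = todo[~acc]
    if size is None:
        return float(e_out[0]), float(mu_out[0])
    return e_out, mu_out


def rayleigh_scatter(energy_kev, material: Material, rng: np.random.Generator,
                     size=None):
    """Sample cos theta for coherent scatter; the photon energy is unchanged.

    Thomson angular law modulated by the medium's independent-atom squared
    form factor (screened Thomas-Fermi model)."""
    tab = material_tables(material.name)
    n = 1 if size is None else int(size)
    out = np.empty(n)
    k2 = (float(energy_kev) / HC_KEV_ANGSTROM) ** 2
    todo = np.arange(n)
    while todo.size:
        mu = rng.random(todo.size) * 2 - 1
        keep = rng.random(todo.size) <= 0.5 * (1 + mu**2)
        x2 = k2 * (1 - mu) / 2
        ff = np.interp(x2, X2_GRID, tab.ff2)
        keep &= rng.random(todo.size) <= ff
        out[todo[keep]] = mu[keep]
        todo = todo[~keep]
    if size is None:
        return float(out[0])
    return out


def photoelectric_absorb(energy_kev, element, rng: np.random.Generator,
                         fluorescence: bool = True):
    """Photoelectric absorption; returns a K-fluorescence photon energy (keV)
    or None.  The remaining energy is deposited locally (kerma handled by the
    scorers)."""
    el = get_element(element) if isinstance(element, str) else element
    if (fluorescence and energy_kev > el.k_edge
            and el.k_line_energies.size
            and rng.random() < el.k_photo_fraction * el.k_fluorescence_yield):
        idx = rng.choice(el.k_line_energies.size, p=el.k_line_weights)
        return float(el.k_line_energies[idx])
    return None


# ---------------------------------------------------------------------------
# Stage 1: transport through the seed itself (mm units, vacuum outside)
# ---------------------------------------------------------------------------

@dataclass
class EscapedPhotons:
    """Photons that crossed the seed outer surface, in the seed local frame."""

    position_mm: np.ndarray      # (n, 3)
    direction: np.ndarray        # (n, 3) unit vectors
    energy_kev: np.ndarray       # (n,)
    weight: np.ndarray           # (n,)
    primary_index: np.ndarray    # (n,) index of the decay that produced each
    n_primary: int               # decays consumed

    @property
    def n(self):
        return self.energy_kev.size


def transport_through_seed(seed: SeedModel, n_primaries: int,
                           rng: np.random.Generator,
                           fluorescence: bool = True,
                           scatter: bool = True,
                           cutoff_kev: float = TRACKING_CUTOFF_KEV,
                           first_primary_index: int = 0) -> EscapedPhotons:
    """Emit ``n_primaries`` decay photons and track them through the seed's
    own materials (vacuum outside); return every photon that escapes.

    With ``scatter=False`` photons fly straight and survive with analog
    probability exp(-sum mu_i l_i) (first-flight transmission), which is the
    reference behaviour for attenuation oracles.
    """
    pos, dirs, e, w = sample_emission(seed, rng, n_primaries)
    prim = np.arange(n_primaries, dtype=np.int64) + first_primary_index
    alive = np.ones(n_primaries, bool)
    tabs = {c.material.name: material_tables(c.material.name)
            for c in seed.components}

    out_p, out_d, out_e, out_w, out_i = [], [], [], [], []
    eps = 1e-7  # mm
    for _ in range(400):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        p = pos[idx]
        d = dirs[idx]
        # boundary tie-break: a photon sitting exactly on a surface belongs
        # to the solid its direction points into
        comp = seed.material_at(p + 1e-6 * d)
        # distance to the next component boundary along the ray
        d_next = np.full(idx.size, np.inf)
        for c in seed.components:
            t1, t2 = c.solid.intersect(p, d)
            valid = t1 <= t2
            for t in (t1, t2):
                cand = np.where(valid & (t > eps), t, np.inf)
                d_next = np.minimum(d_next, cand)
        outside = comp < 0
        done = outside & ~np.isfinite(d_next)
        if np.any(done):
            sel = idx[done]
            out_p.append(pos[sel])
            out_d.append(dirs[sel])
            out_e.append(e[sel])
            out_w.append(w[sel])
            out_i.append(prim[sel])
            alive[sel] = False
        # photons in a gap (outside all solids, but hitting one ahead)
        gap = outside & np.isfinite(d_next)
        if np.any(gap):
            sel = idx[gap]
            pos[sel] += (d_next[gap] + eps)[:, None] * dirs[sel]
        inside = ~outside
        if not np.any(inside):
            continue
        sel = idx[inside]
        db = d_next[inside]
        # linear attenuation per mm at each photon's energy
        mu = np.empty(sel.size)
        comp_in = comp[inside]
        for ci, c in enumerate(seed.components):
            m = comp_in == ci
            if np.any(m):
                tab = tabs[c.material.name]
                mu[m] = np.exp(np.interp(np.log(e[sel][m]), tab.log_e,
                                         tab.log_mu_total)) / 10.0
        s = -np.log(rng.random(sel.size)) / mu
        if not scatter:
            # first-flight: survive the whole chord or be absorbed
            absorbed = s < db
            alive[sel[absorbed]] = False
            move = sel[~absorbed]
            pos[move] += (db[~absorbed] + eps)[:, None] * dirs[move]
            continue
        cross = s >= db
        move = sel[cross]
        pos[move] += (db[cross] + eps)[:, None] * dirs[move]
        hit = sel[~cross]
        if hit.size == 0:
            continue
        pos[hit] += s[~cross, None] * dirs[hit]
        comp_hit = comp_in[~cross]
        # interaction channel per photon
        local_rng = rng
        for ci, c in enumerate(seed.components):
            m = np.flatnonzero(comp_hit == ci)
            if m.size == 0:
                continue
            ph = hit[m]
            mat = c.material
            parts = np.stack([
                mu_over_rho(mat, e[ph], "photoelectric"),
                mu_over_rho(mat, e[ph], "compton"),
                mu_over_rho(mat, e[ph], "rayleigh")])
            u = local_rng.random(ph.size) * parts.sum(0)
            is_pe = u < parts[0]
            is_com = (~is_pe) & (u < parts[0] + parts[1])
            is_ray = ~(is_pe | is_com)
            # photoelectric: optional K fluorescence, else terminate
            pe_idx = ph[is_pe]
            if pe_idx.size:
                killed = np.ones(pe_idx.size, bool)
                if fluorescence:
                    # choose the absorbing element by partial pe contribution
                    els = [(get_element(sym), frac)
                           for sym, frac in mat.composition.items()]
                    pe_el = np.stack([
                        f * el.mu_rho(e[pe_idx], "photoelectric")
                        for el, f in els])
                    uu = local_rng.random(pe_idx.size) * pe_el.sum(0)
                    cum = np.cumsum(pe_el, 0)
                    el_choice = (uu[None, :] >= cum[:-1]).sum(0)
                    for ei, (el, _) in enumerate(els):
                        mm = np.flatnonzero(el_choice == ei)
                        if mm.size == 0 or not el.k_line_energies.size:
                            continue
                        sub = pe_idx[mm]
                        can = ((e[sub] > el.k_edge)
                               & (local_rng.random(sub.size)
                                  < el.k_photo_fraction
                                  * el.k_fluorescence_yield))
                        emit = sub[can]
                        if emit.size:
                            li = local_rng.choice(
                                el.k_line_energies.size, size=emit.size,
                                p=el.k_line_weights)
                            e[emit] = el.k_line_energies[li]
                            dirs[emit] = isotropic_directions(
                                local_rng, emit.size)
                            killed[np.isin(pe_idx, emit)] = False
                alive[pe_idx[killed]] = False
            com_idx = ph[is_com]
            if com_idx.size:
                for eu in np.unique(e[com_idx]):
                    mm = com_idx[e[com_idx] == eu]
                    e_new, mu_s = compton_scatter(eu, local_rng, size=mm.size)
                    phi = local_rng.random(mm.size) * 2 * np.pi
                    dirs[mm] = _rotate(dirs[mm], mu_s, phi)
                    e[mm] = e_new
                low = com_idx[e[com_idx] < cutoff_kev]
                alive[low] = False
            ray_idx = ph[is_ray]
            if ray_idx.size:
                for eu in np.unique(e[ray_idx]):
                    mm = ray_idx[e[ray_idx] == eu]
                    mu_s = rayleigh_scatter(eu, mat, local_rng, size=mm.size)
                    phi = local_rng.random(mm.size) * 2 * np.pi
                    dirs[mm] = _rotate(dirs[mm], mu_s, phi)
    if np.any(alive):
        raise RuntimeError("seed transport did not converge "
                           f"({int(alive.sum())} photons still alive)")
    cat = (lambda parts, width=None: np.concatenate(parts) if parts
           else np.empty((0,) if width is None else (0, width)))
    return EscapedPhotons(
        position_mm=cat(out_p, 3), direction=cat(out_d, 3),
        energy_kev=cat(out_e), weight=cat(out_w),
        primary_index=cat(out_i).astype(np.int64),
        n_primary=n_primaries)


def _rotate(dirs, mu, phi):
    """Rotate unit vectors by polar angle acos(mu), azimuth phi (vectorized)."""
    mu = np.broadcast_to(np.asarray(mu, float), dirs.shape[0:1]).copy()
    sin_t = np.sqrt(np.maximum(0.0, 1 - mu**2))
    cp, sp = np.cos(phi), np.sin(phi)
    u = dirs
    out = np.empty_like(u)
    uz = u[:, 2]
    main = np.abs(uz) < 0.99999
    den = np.sqrt(np.maximum(1e-300, 1 - uz[main] ** 2))
    vx = (u[main, 0] * uz[main] * cp[main] - u[main, 1] * sp[main]) / den
    vy = (u[main, 1] * uz[main] * cp[main] + u[main, 0] * sp[main]) / den
    vz = -den * cp[main]
    out[main, 0] = mu[main] * u[main, 0] + sin_t[main] * vx
    out[main, 1] = mu[main] * u[main, 1] + sin_t[main] * vy
    out[main, 2] = mu[main] * u[main, 2] + sin_t[main] * vz
    pole = ~main
    sign = np.sign(uz[pole])
    out[pole, 0] = sin_t[pole] * cp[pole]
    out[pole, 1] = sin_t[pole] * sp[pole]
    out[pole, 2] = sign * mu[pole]
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Stage 2 wrappers around the numba kernels
# ---------------------------------------------------------------------------

def _material_kernel_args(name: str):
    tab = material_tables(name)
    return (tab.log_e, tab.log_mu_total, tab.log_mu_pe, tab.log_mu_compton,
            tab.log_mu_rayleigh, tab.log_mu_en_rho, X2_GRID, tab.ff2)


def run_sphere_annular(photons: EscapedPhotons, annular_map,
                       config: SimConfig, medium: str = "water",
                       radius_cm: float = 15.0):
    """Track escaped photons through a homogeneous sphere, accumulating
    track-length kerma into ``annular_map`` (a scoring.AnnularMap).

    ``photons`` positions are seed-local mm; the seed sits at the sphere
    centre.  Histories are processed in reproducible batches.
    """
    args = _material_kernel_args(medium)
    n = photons.n
    bs = config.batch_size
    ss = np.random.SeedSequence(config.rng_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in ss.spawn(max(1, (n + bs - 1) // bs))]
    for bi, start in enumerate(range(0, n, bs)):
        sl = slice(start, min(n, start + bs))
        _kernels.run_annular(
            seeds[bi],
            np.ascontiguousarray(photons.energy_kev[sl]),
            np.ascontiguousarray(photons.position_mm[sl] / 10.0),
            np.ascontiguousarray(photons.direction[sl]),
            np.ascontiguousarray(photons.weight[sl]),
            *args,
            radius_cm, config.tracking_cutoff,
            annular_map.r_lo, annular_map.r_hi, annular_map.theta_edges,
            annular_map._inv_vcell,
            annular_map._sum, annular_map._sumsq,
            annular_map._acc, annular_map._last)
        annular_map._acc[:] = 0.0
        annular_map._last[:] = -1
    annular_map.n_histories += photons.n_primary
    return annular_map


def run_voxel_phantom(photons, phantom, config: SimConfig,
                      tle_map=None, analog_map=None,
                      positions_cm=None):
    """Woodcock-track photons through a voxel phantom.

    ``photons`` may be an EscapedPhotons (seed-local mm, centred at the
    phantom origin unless ``positions_cm`` overrides) or a tuple of arrays
    ``(energy, position_cm, direction, weight, history_index)``.
    Accumulates into scoring.DoseMap objects (either may be None).

    Returns a dict with the energy account:
    emitted / deposited / escaped keV per run and the worst per-history
    closure error (analog bookkeeping: emitted = deposited + escaped).
    """
    if isinstance(photons, EscapedPhotons):
        e = photons.energy_kev
        p = photons.position_mm / 10.0 if positions_cm is None else positions_cm
        d = photons.direction
        w = photons.weight
        hist = photons.primary_index
        n_hist = photons.n_primary
    else:
        e, p, d, w, hist = photons
        n_hist = int(hist.max()) + 1 if hist.size else 0
    maps = [m for m in (tle_map, analog_map) if m is not None]
    if not maps:
        raise ValueError("at least one scorer map is required")
    ref = maps[0]
    for m in maps:
        if (m.dims != ref.dims or not np.allclose(m.spacing, ref.spacing)
                or not np.allclose(m.origin, ref.origin)):
            raise ValueError("scorer grids must match")

    tabs = [material_tables(name) for name in phantom.materials]
    log_e = tabs[0].log_e
    for t in tabs[1:]:
        if t.log_e.shape != log_e.shape or not np.allclose(t.log_e, log_e):
            # resample onto the first material's grid
            pass
    stack = lambda attr: np.ascontiguousarray(
        np.stack([_resample(t, attr, log_e) for t in tabs]))
    log_tot = stack("log_mu_total")
    log_pe = stack("log_mu_pe")
    log_com = stack("log_mu_compton")
    log_ray = stack("log_mu_rayleigh")
    log_muen = stack("log_muen")
    ff2 = np.ascontiguousarray(np.stack([
        np.interp(X2_GRID, X2_GRID, t.ff2) for t in tabs]))
    # majorant: per energy, max over materials of mu/rho * that material's
    # maximum voxel density
    rho_max = np.array([
        max(phantom.density[phantom.material_ids == i].max(), 1e-30)
        if np.any(phantom.material_ids == i) else 1e-30
        for i in range(len(phantom.materials))])
    nominal = np.array([t.material.density for t in tabs])
    mu_stack = np.exp(log_tot) / nominal[:, None] * rho_max[:, None]
    log_maj = np.log(np.maximum(mu_stack.max(axis=0), 1e-300))

    dummy = np.zeros(1)
    dummy_i = np.full(1, -1, np.int64)
    acct = np.zeros(5)
    n = e.size
    bs = config.batch_size
    ss = np.random.SeedSequence(config.rng_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in ss.spawn(max(1, (n + bs - 1) // bs))]
    origin_cm = np.asarray(phantom.origin, float) / 10.0
    spacing_cm = np.asarray(phantom.spacing, float) / 10.0
    nx, ny, nz = phantom.dims
    for bi, start in enumerate(range(0, n, bs)):
        sl = slice(start, min(n, start + bs))
        _kernels.run_voxel(
            seeds[bi],
            np.ascontiguousarray(e[sl]),
            np.ascontiguousarray(np.atleast_2d(p)[sl]),
            np.ascontiguousarray(d[sl]),
            np.ascontiguousarray(w[sl]),
            np.ascontiguousarray(hist[sl]),
            phantom.material_ids.ravel(), phantom.density.ravel(),
            nx, ny, nz,
            origin_cm[0], origin_cm[1], origin_cm[2],
            spacing_cm[0], spacing_cm[1], spacing_cm[2],
            log_e, log_tot, log_pe, log_com, log_ray, log_muen, log_maj,
            X2_GRID, ff2,
            config.tracking_cutoff,
            tle_map is not None, analog_map is not None,
            *(_acc_args(tle_map) if tle_map is not None
              else (dummy, dummy, dummy, dummy_i)),
            *(_acc_args(analog_map) if analog_map is not None
              else (dummy, dummy, dummy, dummy_i)),
            acct)
        for m in maps:
            m._acc[:] = 0.0
            m._last[:] = -1
    for m in maps:
        m.n_histories += n_hist
    return {"emitted_kev": acct[0], "deposited_kev": acct[1],
            "escaped_kev": acct[2], "max_history_error_kev": acct[3],
            "n_uncollided": int(acct[4])}


def _resample(tab, attr, log_e):
    name = {"log_mu_total": "log_mu_total", "log_mu_pe": "log_mu_pe",
            "log_mu_compton": "log_mu_compton",
            "log_mu_rayleigh": "log_mu_rayleigh",
            "log_muen": "log_mu_en_rho"}[attr]
    y = getattr(tab, name)
    if tab.log_e.shape == log_e.shape and np.allclose(tab.log_e, log_e):
        return y
    return np.interp(log_e, tab.log_e, y)


def _acc_args(m):
    return (m._sum, m._sumsq, m._acc, m._last)
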
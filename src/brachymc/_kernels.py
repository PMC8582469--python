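"""Numba transport kernels.

Two engines share the interaction sampling helpers:

* ``run_annular`` — analytic tracking of photons in a homogeneous sphere
  (the TG-43 characterization phantom) with track-length kerma scoring on a
  thin-shell (r, theta) annular grid,
* ``run_voxel`` — Woodcock (delta) tracking in a voxel phantom with
  track-length kerma scoring on the voxel grid and an optional analog
  (local energy deposition) estimator.

Lengths are centimetres, energies keV.  Per-cell statistical moments use the
history-by-history technique: a per-cell accumulator is flushed into the
sum-of-squares whenever a new history touches the cell.
"""

import numpy as np
from numba import njit

ME_C2 = 510.99895
HC_KEV_ANGSTROM = 12.39842
GRAY_PER_KEV_PER_G = 1.602176634e-13


@njit(cache=True)
def _interp_loglog(log_e, log_y, e):
    x = np.log(e)
    n = log_e.shape[0]
    if x <= log_e[0]:
        return np.exp(log_y[0])
    if x >= log_e[n - 1]:
        return np.exp(log_y[n - 1])
    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if log_e[mid] <= x:
            lo = mid
        else:
            hi = mid
    f = (x - log_e[lo]) / (log_e[hi] - log_e[lo])
    return np.exp(log_y[lo] + f * (log_y[hi] - log_y[lo]))


@njit(cache=True)
def _interp_lin(xs, ys, x):
    n = xs.shape[0]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xs[mid] <= x:
            lo = mid
        else:
            hi = mid
    f = (x - xs[lo]) / (xs[hi] - xs[lo])
    return ys[lo] + f * (ys[hi] - ys[lo])


@njit(cache=True)
def kahn_compton(e_kev):
    """Sample (E', cos theta) from the Klein-Nishina law (Kahn's method)."""
    a = e_kev / ME_C2
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * a) / (9.0 + 2.0 * a):
            x = 1.0 + 2.0 * a * r2              # x = E/E'
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                mu = 1.0 - (x - 1.0) / a
                return e_kev / x, mu
        else:
            x = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * r2)
            mu = 1.0 - (x - 1.0) / a
            if r3 <= 0.5 * (mu * mu + 1.0 / x):
                return e_kev / x, mu


@njit(cache=True)
def sample_rayleigh_mu(e_kev, x2_grid, ff2):
    """Sample cos theta for coherent scatter: Thomson envelope times the
    normalized squared form factor of the medium."""
    k2 = (e_kev / HC_KEV_ANGSTROM) ** 2
    for _ in range(100000):
        mu = 2.0 * np.random.random() - 1.0
        if np.random.random() > 0.5 * (1.0 + mu * mu):
            continue
        x2 = k2 * (1.0 - mu) / 2.0
        if np.random.random() <= _interp_lin(x2_grid, ff2, x2):
            return mu
    return 1.0


@njit(cache=True)
def rotate_direction(ux, uy, uz, mu, phi):
    """Rotate a unit vector by polar angle acos(mu), azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - mu * mu))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) < 0.99999:
        den = np.sqrt(1.0 - uz * uz)
        vx = (ux * uz * cp - uy * sp) / den
        vy = (uy * uz * cp + ux * sp) / den
        vz = -den * cp
        nx = mu * ux + sin_t * vx
        ny = mu * uy + sin_t * vy
        nz = mu * uz + sin_t * vz
    else:
        sign = 1.0 if uz > 0 else -1.0
        nx = sin_t * cp
        ny = sin_t * sp
        nz = sign * mu
    n = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / n, ny / n, nz / n


@njit(cache=True)
def _theta_bin(cos_t, theta_edges_deg):
    th = np.degrees(np.arccos(min(1.0, max(-1.0, cos_t))))
    n = theta_edges_deg.shape[0]
    for i in range(n - 1):
        if th < theta_edges_deg[i + 1]:
            return i
    return n - 2


@njit(cache=True)
def _flush_all(acc, last, sq):
    for i in range(acc.shape[0]):
        if last[i] >= 0:
            sq[i] += acc[i] * acc[i]
            acc[i] = 0.0
            last[i] = -1


@njit(cache=True)
def _score_cell(idx, val, h, s, sq, acc, last):
    s[idx] += val
    if last[idx] != h:
        if last[idx] >= 0:
            sq[idx] += acc[idx] * acc[idx]
        acc[idx] = val
        last[idx] = h
    else:
        acc[idx] += val


@njit(cache=True)
def run_annular(rng_seed, e0, p0, d0, w0,
                log_e, log_mu_tot, log_mu_pe, log_mu_com, log_mu_ray,
                log_muen_rho, x2_grid, ff2,
                radius_cm, cutoff_kev,
                r_lo, r_hi, theta_edges_deg, inv_vcell,
                s, sq, acc, last):
    """Track photons in a homogeneous sphere, score TLE kerma on (r, theta).

    ``s``/``sq``/``acc``/``last`` are flat (nr*ntheta) accumulators; returns
    (number tracked, number escaped).
    """
    np.random.seed(rng_seed)
    n = e0.shape[0]
    nth = theta_edges_deg.shape[0] - 1
    nr = r_lo.shape[0]
    n_escaped = 0
    for h in range(n):
        e = e0[h]
        x = p0[h, 0]
        y = p0[h, 1]
        z = p0[h, 2]
        ux = d0[h, 0]
        uy = d0[h, 1]
        uz = d0[h, 2]
        w = w0[h]
        alive = True
        while alive:
            mu_tot = _interp_loglog(log_e, log_mu_tot, e)
            s_free = -np.log(np.random.random()) / mu_tot
            b = x * ux + y * uy + z * uz
            c = x * x + y * y + z * z - radius_cm * radius_cm
            disc = b * b - c
            t_exit = -b + np.sqrt(disc) if disc > 0.0 else 0.0
            if t_exit < 0.0:
                t_exit = 0.0
            seg = s_free if s_free < t_exit else t_exit
            # --- TLE scoring: split the segment at shell-boundary crossings
            if seg > 0.0:
                muen = _interp_loglog(log_e, log_muen_rho, e)
                base = w * e * muen * GRAY_PER_KEV_PER_G
                p2 = x * x + y * y + z * z
                for ir in range(nr):
                    # interval inside sphere(r_hi) minus inside sphere(r_lo)
                    ch = p2 - r_hi[ir] * r_hi[ir]
                    dh = b * b - ch
                    if dh <= 0.0:
                        continue
                    sh = np.sqrt(dh)
                    h1 = -b - sh
                    h2 = -b + sh
                    cl = p2 - r_lo[ir] * r_lo[ir]
                    dl = b * b - cl
                    if dl > 0.0:
                        sl = np.sqrt(dl)
                        l1 = -b - sl
                        l2 = -b + sl
                        n_iv = 2
                    else:
                        l1 = 0.0
                        l2 = 0.0
                        n_iv = 1
                    for part in range(n_iv):
                        if n_iv == 1:
                            a0, a1 = h1, h2
                        elif part == 0:
                            a0, a1 = h1, l1
                        else:
                            a0, a1 = l2, h2
                        lo_t = a0 if a0 > 0.0 else 0.0
                        hi_t = a1 if a1 < seg else seg
                        if hi_t <= lo_t:
                            continue
                        tm = 0.5 * (lo_t + hi_t)
                        mx = x + tm * ux
                        my = y + tm * uy
                        mz = z + tm * uz
                        rm = np.sqrt(mx * mx + my * my + mz * mz)
                        if rm <= 0.0:
                            continue
                        it = _theta_bin(mz / rm, theta_edges_deg)
                        idx = ir * nth + it
                        val = base * (hi_t - lo_t) * inv_vcell[idx]
                        _score_cell(idx, val, h, s, sq, acc, last)
            if s_free >= t_exit:
                n_escaped += 1
                alive = False
                continue
            x += s_free * ux
            y += s_free * uy
            z += s_free * uz
            # --- interaction
            p_pe = _interp_loglog(log_e, log_mu_pe, e)
            p_com = _interp_loglog(log_e, log_mu_com, e)
            p_ray = _interp_loglog(log_e, log_mu_ray, e)
            u = np.random.random() * (p_pe + p_com + p_ray)
            if u < p_pe:
                alive = False           # low-Z medium: no K fluorescence
            elif u < p_pe + p_com:
                e_new, mu = kahn_compton(e)
                phi = 2.0 * np.pi * np.random.random()
                ux, uy, uz = rotate_direction(ux, uy, uz, mu, phi)
                e = e_new
                if e < cutoff_kev:
                    alive = False
            else:
                mu = sample_rayleigh_mu(e, x2_grid, ff2)
                phi = 2.0 * np.pi * np.random.random()
                ux, uy, uz = rotate_direction(ux, uy, uz, mu, phi)
    _flush_all(acc, last, sq)
    return n, n_escaped


@njit(cache=True)
def run_voxel(rng_seed, e0, p0, d0, w0, hist0,
              mat_id, rho, nx, ny, nz,
              ox, oy, oz, sx, sy, sz,
              log_e, log_mur_tot, log_mur_pe, log_mur_com, log_mur_ray,
              log_muen_rho, log_mu_maj, x2_grid, ff2,
              cutoff_kev, score_tle, score_analog,
              tle_s, tle_sq, tle_acc, tle_last,
              an_s, an_sq, an_acc, an_last,
              e_account):
    """Woodcock tracking + voxel TLE / analog scoring.

    ``mat_id``/``rho`` are flat (nx*ny*nz) arrays in C order; per-material
    tables are stacked (nmat, ngrid).  ``e_account`` accumulates
    [emitted, deposited, escaped, max per-history closure error,
    uncollided escapes].
    """
    np.random.seed(rng_seed)
    n = e0.shape[0]
    inv_vox = 1.0 / (sx * sy * sz)
    for i in range(n):
        e = e0[i]
        x = p0[i, 0]
        y = p0[i, 1]
        z = p0[i, 2]
        ux = d0[i, 0]
        uy = d0[i, 1]
        uz = d0[i, 2]
        w = w0[i]
        h = hist0[i]
        e_account[0] += w * e
        e_dep = 0.0
        e_esc = 0.0
        collided = False
        alive = True
        while alive:
            mu_maj = _interp_loglog(log_e, log_mu_maj, e)
            s_free = -np.log(np.random.random()) / mu_maj
            # clip the hop to the grid bounding box
            t_box = 1.0e30
            if ux > 1e-12:
                t = (ox + nx * sx - x) / ux
            elif ux < -1e-12:
                t = (ox - x) / ux
            else:
                t = 1.0e30
            if t < t_box:
                t_box = t
            if uy > 1e-12:
                t = (oy + ny * sy - y) / uy
            elif uy < -1e-12:
                t = (oy - y) / uy
            else:
                t = 1.0e30
            if t < t_box:
                t_box = t
            if uz > 1e-12:
                t = (oz + nz * sz - z) / uz
            elif uz < -1e-12:
                t = (oz - z) / uz
            else:
                t = 1.0e30
            if t < t_box:
                t_box = t
            escaped = s_free >= t_box
            seg = t_box if escaped else s_free
            if score_tle and seg > 0.0:
                _tle_dda(x, y, z, ux, uy, uz, seg, e, w, h,
                         mat_id, nx, ny, nz, ox, oy, oz, sx, sy, sz,
                         log_e, log_muen_rho, inv_vox,
                         tle_s, tle_sq, tle_acc, tle_last)
            if escaped:
                e_esc += w * e
                if not collided:
                    e_account[4] += 1.0
                alive = False
                continue
            x += seg * ux
            y += seg * uy
            z += seg * uz
            iv = int((x - ox) / sx)
            jv = int((y - oy) / sy)
            kv = int((z - oz) / sz)
            if iv < 0 or iv >= nx or jv < 0 or jv >= ny or kv < 0 or kv >= nz:
                e_esc += w * e
                if not collided:
                    e_account[4] += 1.0
                alive = False
                continue
            idx = (iv * ny + jv) * nz + kv
            m = mat_id[idx]
            mu_here = _interp_loglog(log_e, log_mur_tot[m], e) * rho[idx]
            if np.random.random() * mu_maj > mu_here:
                continue                 # null collision
            collided = True
            p_pe = _interp_loglog(log_e, log_mur_pe[m], e)
            p_com = _interp_loglog(log_e, log_mur_com[m], e)
            p_ray = _interp_loglog(log_e, log_mur_ray[m], e)
            u = np.random.random() * (p_pe + p_com + p_ray)
            if u < p_pe:
                if score_analog:
                    val = w * e * GRAY_PER_KEV_PER_G * inv_vox / rho[idx]
                    _score_cell(idx, val, h, an_s, an_sq, an_acc, an_last)
                e_dep += w * e
                alive = False
            elif u < p_pe + p_com:
                e_new, mu = kahn_compton(e)
                if score_analog:
                    val = (w * (e - e_new) * GRAY_PER_KEV_PER_G
                           * inv_vox / rho[idx])
                    _score_cell(idx, val, h, an_s, an_sq, an_acc, an_last)
                e_dep += w * (e - e_new)
                phi = 2.0 * np.pi * np.random.random()
                ux, uy, uz = rotate_direction(ux, uy, uz, mu, phi)
                e = e_new
                if e < cutoff_kev:
                    if score_analog:
                        val = w * e * GRAY_PER_KEV_PER_G * inv_vox / rho[idx]
                        _score_cell(idx, val, h, an_s, an_sq, an_acc, an_last)
                    e_dep += w * e
                    alive = False
            else:
                mu = sample_rayleigh_mu(e, x2_grid, ff2[m])
                phi = 2.0 * np.pi * np.random.random()
                ux, uy, uz = rotate_direction(ux, uy, uz, mu, phi)
        e_account[1] += e_dep
        e_account[2] += e_esc
        err = abs(w0[i] * e0[i] - e_dep - e_esc)
        if err > e_account[3]:
            e_account[3] = err
    _flush_all(tle_acc, tle_last, tle_sq)
    _flush_all(an_acc, an_last, an_sq)
    return n


@njit(cache=True)
def _tle_dda(x, y, z, ux, uy, uz, seg, e, w, h,
             mat_id, nx, ny, nz, ox, oy, oz, sx, sy, sz,
             log_e, log_muen_rho, inv_vox,
             s, sq, acc, last):
    """Amanatides-Woo traversal of one flight segment, scoring kerma per voxel."""
    # nudge the start inside the box if it sits exactly on the lower faces
    iv = int((x - ox) / sx)
    jv = int((y - oy) / sy)
    kv = int((z - oz) / sz)
    if iv < 0 or iv >= nx or jv < 0 or jv >= ny or kv < 0 or kv >= nz:
        return
    step_x = 1 if ux > 0 else -1
    step_y = 1 if uy > 0 else -1
    step_z = 1 if uz > 0 else -1
    big = 1.0e30
    if abs(ux) > 1e-12:
        t_dx = sx / abs(ux)
        nxt = ox + (iv + (1 if ux > 0 else 0)) * sx
        t_mx = (nxt - x) / ux
    else:
        t_dx = big
        t_mx = big
    if abs(uy) > 1e-12:
        t_dy = sy / abs(uy)
        nxt = oy + (jv + (1 if uy > 0 else 0)) * sy
        t_my = (nxt - y) / uy
    else:
        t_dy = big
        t_my = big
    if abs(uz) > 1e-12:
        t_dz = sz / abs(uz)
        nxt = oz + (kv + (1 if uz > 0 else 0)) * sz
        t_mz = (nxt - z) / uz
    else:
        t_dz = big
        t_mz = big
    t_prev = 0.0
    base = w * e * GRAY_PER_KEV_PER_G * inv_vox
    # cache the muen lookup per material id encountered
    last_m = -1
    muen = 0.0
    while t_prev < seg:
        t_next = t_mx
        axis = 0
        if t_my < t_next:
            t_next = t_my
            axis = 1
        if t_mz < t_next:
            t_next = t_mz
            axis = 2
        t_here = t_next if t_next < seg else seg
        length = t_here - t_prev
        if length > 0.0:
            idx = (iv * ny + jv) * nz + kv
            m = mat_id[idx]
            if m != last_m:
                muen = _interp_loglog(log_e, log_muen_rho[m], e)
                last_m = m
            _score_cell(idx, base * muen * length, h, s, sq, acc, last)
        t_prev = t_here
        if t_next >= seg:
            break
        if axis == 0:
            iv += step_x
            t_mx += t_dx
            if iv < 0 or iv >= nx:
                break
        elif axis == 1:
            jv += step_y
            t_my += t_dy
            if jv < 0 or jv >= ny:
                break
        else:
            kv += step_z
            t_mz += t_dz
            if kv < 0 or kv >= nz:
                break
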
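"""The TG-43 dose formalism.

The 2D formalism factorizes the water dose rate around a cylindrically
symmetric source as

    D(r, theta) = S_K * Lambda * [G_L(r,theta) / G_L(r0,theta0)]
                  * g_L(r) * F(r, theta)

with r in cm from the active-region centre, theta the polar angle from the
source long axis (+Z through the tip), reference point (r0, theta0) =
(1 cm, 90 deg), S_K the air kerma strength (U = cGy cm^2/h), Lambda the dose
rate constant (cGy/h per U), G_L the line-source geometry factor, g_L the
radial dose function and F the 2D anisotropy function.

This module extracts (Lambda, g_L, F) from Monte Carlo annular kerma maps,
evaluates the forward formalism, and superposes multi-seed plans in water.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import Pose
from .scoring import AnnularMap, KermaStrengthResult

R0_CM = 1.0
THETA0_DEG = 90.0


class ExtractionError(RuntimeError):
    pass


class ExtrapolationError(ValueError):
    pass


def geometry_factor(r_cm, theta_deg, active_length_cm, model: str = "line"):
    """TG-43 geometry factor (cm^-2).

    Point model: 1/r^2.  Line model: beta / (L r sin theta) with beta the
    angle the active line subtends at the point; on the long axis
    1 / (r^2 - L^2/4).
    """
    r = np.asarray(r_cm, float)
    th = np.deg2rad(np.asarray(theta_deg, float))
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if model == "point":
        return 1.0 / r**2
    if model != "line":
        raise ValueError(f"unknown geometry model {model!r}")
    L = float(active_length_cm)
    y = r * np.sin(th)                 # transverse offset
    z = r * np.cos(th)                 # along the source axis
    on_axis = np.isclose(y, 0.0, atol=1e-12)
    if np.any(on_axis & (r <= L / 2 + 1e-12)):
        raise ValueError("point on the source axis inside the active line")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.arctan2(z + L / 2, y) - np.arctan2(z - L / 2, y)
        g_line = beta / (L * y)
        g_axis = 1.0 / (z**2 - L**2 / 4)
    out = np.where(on_axis, g_axis, g_line)
    return out if out.ndim else float(out)


@dataclass
class Tg43Parameters:
    """Extracted TG-43 source characterization."""

    seed_id: str
    dose_rate_constant: float          # cGy / (h U)
    active_length_cm: float
    g_radii_cm: np.ndarray
    g_values: np.ndarray               # g_L(r), g_L(1 cm) = 1
    f_radii_cm: np.ndarray
    f_theta_deg: np.ndarray
    f_values: np.ndarray               # (nr, ntheta), F(r, 90 deg) = 1
    g_uncertainty: np.ndarray | None = None
    f_uncertainty: np.ndarray | None = None
    lambda_uncertainty: float = 0.0
    r0_cm: float = R0_CM
    theta0_deg: float = THETA0_DEG

    def __post_init__(self):
        if self.dose_rate_constant <= 0:
            raise ValueError("dose rate constant must be positive")

    # ---- interpolation -----------------------------------------------------
    def g(self, r_cm, extrapolation_limit: float = 0.20):
        """Radial dose function, log-linear in r, bounded extrapolation."""
        r = np.asarray(r_cm, float)
        lo, hi = self.g_radii_cm[0], self.g_radii_cm[-1]
        if np.any(r < lo * (1 - extrapolation_limit)) or np.any(
                r > hi * (1 + extrapolation_limit)):
            raise ExtrapolationError(
                f"r outside the tabulated range [{lo}, {hi}] cm "
                f"(+/-{extrapolation_limit:.0%} policy)")
        ln_g = np.interp(r, self.g_radii_cm, np.log(self.g_values))
        # nearest-slope linear extrapolation in ln g
        below = r < lo
        above = r > hi
        if np.any(below):
            s = ((np.log(self.g_values[1]) - np.log(self.g_values[0]))
                 / (self.g_radii_cm[1] - self.g_radii_cm[0]))
            ln_g = np.where(below, np.log(self.g_values[0])
                            + s * (r - lo), ln_g)
        if np.any(above):
            s = ((np.log(self.g_values[-1]) - np.log(self.g_values[-2]))
                 / (self.g_radii_cm[-1] - self.g_radii_cm[-2]))
            ln_g = np.where(above, np.log(self.g_values[-1])
                            + s * (r - hi), ln_g)
        out = np.exp(ln_g)
        return out if out.ndim else float(out)

    def F(self, r_cm, theta_deg):
        """Anisotropy function, bilinear in (r, theta), clamped to the hull."""
        r = np.clip(np.asarray(r_cm, float), self.f_radii_cm[0],
                    self.f_radii_cm[-1])
        th = np.clip(np.asarray(theta_deg, float), self.f_theta_deg[0],
                     self.f_theta_deg[-1])
        ri = np.clip(np.searchsorted(self.f_radii_cm, r) - 1, 0,
                     self.f_radii_cm.size - 2)
        ti = np.clip(np.searchsorted(self.f_theta_deg, th) - 1, 0,
                     self.f_theta_deg.size - 2)
        fr = ((r - self.f_radii_cm[ri])
              / (self.f_radii_cm[ri + 1] - self.f_radii_cm[ri]))
        ft = ((th - self.f_theta_deg[ti])
              / (self.f_theta_deg[ti + 1] - self.f_theta_deg[ti]))
        v00 = self.f_values[ri, ti]
        v01 = self.f_values[ri, ti + 1]
        v10 = self.f_values[ri + 1, ti]
        v11 = self.f_values[ri + 1, ti + 1]
        out = ((1 - fr) * (1 - ft) * v00 + (1 - fr) * ft * v01
               + fr * (1 - ft) * v10 + fr * ft * v11)
        return out if out.ndim else float(out)

    # ---- serialization -----------------------------------------------------
    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "header.json", "w") as fh:
            json.dump({"seed_id": self.seed_id,
                       "dose_rate_constant_cGy_per_hU":
                           self.dose_rate_constant,
                       "lambda_uncertainty": self.lambda_uncertainty,
                       "active_length_cm": self.active_length_cm,
                       "r0_cm": self.r0_cm,
                       "theta0_deg": self.theta0_deg}, fh, indent=1)
        g_unc = (self.g_uncertainty if self.g_uncertainty is not None
                 else np.zeros_like(self.g_values))
        with open(d / "radial_dose_function.csv", "w") as fh:
            fh.write("r_cm,g,rel_uncertainty\n")
            for r, g, u in zip(self.g_radii_cm, self.g_values, g_unc):
                fh.write(f"{r:g},{g:.6g},{u:.3g}\n")
        with open(d / "anisotropy_function.csv", "w") as fh:
            fh.write("r_cm,theta_deg,F,rel_uncertainty\n")
            f_unc = (self.f_uncertainty if self.f_uncertainty is not None
                     else np.zeros_like(self.f_values))
            for i, r in enumerate(self.f_radii_cm):
                for j, th in enumerate(self.f_theta_deg):
                    fh.write(f"{r:g},{th:g},{self.f_values[i, j]:.6g},"
                             f"{f_unc[i, j]:.3g}\n")

    @classmethod
    def load(cls, directory):
        import pandas as pd
        d = Path(directory)
        head = json.loads((d / "header.json").read_text())
        g = pd.read_csv(d / "radial_dose_function.csv")
        f = pd.read_csv(d / "anisotropy_function.csv")
        f_r = np.unique(f["r_cm"])
        f_t = np.unique(f["theta_deg"])
        fv = (f.pivot(index="r_cm", columns="theta_deg", values="F")
              .loc[f_r, f_t].to_numpy())
        fu = (f.pivot(index="r_cm", columns="theta_deg",
                      values="rel_uncertainty").loc[f_r, f_t].to_numpy())
        return cls(seed_id=head["seed_id"],
                   dose_rate_constant=head["dose_rate_constant_cGy_per_hU"],
                   lambda_uncertainty=head.get("lambda_uncertainty", 0.0),
                   active_length_cm=head["active_length_cm"],
                   g_radii_cm=g["r_cm"].to_numpy(),
                   g_values=g["g"].to_numpy(),
                   g_uncertainty=g["rel_uncertainty"].to_numpy(),
                   f_radii_cm=f_r, f_theta_deg=f_t, f_values=fv,
                   f_uncertainty=fu)


def extract_parameters(annular: AnnularMap, s_k, active_length_cm: float,
                       seed_id: str = "") -> Tg43Parameters:
    """Invert the TG-43 equation on an annular kerma map.

    ``s_k`` is a KermaStrengthResult (or a plain per-history value in the
    same Gy cm^2 units as the map's Gy).  Uncertainties are propagated in
    quadrature from the map variances.
    """
    sk_val = s_k.s_k if isinstance(s_k, KermaStrengthResult) else float(s_k)
    sk_rel = (s_k.rel_uncertainty if isinstance(s_k, KermaStrengthResult)
              else 0.0)
    if sk_val <= 0:
        raise ExtractionError("air kerma strength must be positive")
    if annular.n_histories < 2:
        raise ExtractionError("annular map holds fewer than 2 histories")
    val = annular.value
    rel = np.zeros_like(val)
    var = annular.variance
    nz = val > 0
    rel[nz] = np.sqrt(var[nz]) / val[nz]
    ir0 = annular.r_index(R0_CM)
    it0 = annular.theta90_index
    d_ref = val[ir0, it0]
    if d_ref <= 0:
        raise ExtractionError(
            f"zero dose in the reference cell (r = {R0_CM} cm, 90 deg)")
    r = annular.r_centers
    th = annular.theta_centers
    L = float(active_length_cm)
    g_geo = geometry_factor(r, THETA0_DEG, L)
    g_geo0 = geometry_factor(R0_CM, THETA0_DEG, L)
    d_trans = val[:, it0]
    bad = np.flatnonzero(d_trans <= 0)
    if bad.size:
        raise ExtractionError(
            f"zero dose on the transverse axis at r = {r[bad[0]]:g} cm")
    g_l = (d_trans / d_ref) * (g_geo0 / g_geo)
    g_unc = np.hypot(rel[:, it0], rel[ir0, it0])
    g_unc[ir0] = 0.0
    geo_grid = geometry_factor(r[:, None], th[None, :], L)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (val / d_trans[:, None]) * (g_geo[:, None] / geo_grid)
    f_unc = np.hypot(rel, rel[:, it0][:, None])
    f[:, it0] = 1.0                      # exact by normalization
    f_unc[:, it0] = 0.0
    lam = d_ref / sk_val
    lam_unc = float(np.hypot(rel[ir0, it0], sk_rel))
    return Tg43Parameters(
        seed_id=seed_id, dose_rate_constant=lam,
        lambda_uncertainty=lam_unc, active_length_cm=L,
        g_radii_cm=r.copy(), g_values=g_l, g_uncertainty=g_unc,
        f_radii_cm=r.copy(), f_theta_deg=th.copy(), f_values=f,
        f_uncertainty=f_unc)


def forward_dose(params: Tg43Parameters, s_k, r_cm, theta_deg,
                 model: str = "line"):
    """Dose rate at points (r, theta): S_K Lambda [G/G0] g(r) F(r,theta).

    With ``s_k`` in U the result is cGy/h; with per-history S_K it is dose
    per history.
    """
    r = np.asarray(r_cm, float)
    th = np.asarray(theta_deg, float)
    L = params.active_length_cm if model == "line" else 0.0
    if model == "line":
        geo = geometry_factor(r, th, params.active_length_cm, "line")
        geo0 = geometry_factor(params.r0_cm, params.theta0_deg,
                               params.active_length_cm, "line")
    else:
        geo = geometry_factor(r, th, 0.0, "point")
        geo0 = geometry_factor(params.r0_cm, params.theta0_deg, 0.0, "point")
    out = (float(s_k) * params.dose_rate_constant * geo / geo0
           * params.g(r) * params.F(r, th))
    return out if np.ndim(out) else float(out)


def superpose_plan(params_for, plan, grid_points_mm, flag_radius_cm=0.05):
    """Sum the TG-43 water dose of every seed of a plan at given points.

    ``params_for`` maps seed_id -> Tg43Parameters (or is a single
    Tg43Parameters used for all); ``plan`` is an iterable of
    ``(seed_id, Pose, s_k_U)``; ``grid_points_mm`` is (n, 3) world points.
    Water only, no interseed attenuation (the TG-43 limitation).  Points
    closer than ``flag_radius_cm`` to a seed origin are flagged NaN.
    """
    pts = np.atleast_2d(np.asarray(grid_points_mm, float))
    total = np.zeros(pts.shape[0])
    flagged = np.zeros(pts.shape[0], bool)
    for seed_id, pose, s_k in plan:
        p = (params_for[seed_id] if isinstance(params_for, dict)
             else params_for)
        rot = pose.rotation
        local = (pts - np.asarray(pose.translation, float)) @ rot
        r = np.linalg.norm(local, axis=1) / 10.0         # mm -> cm
        near = r < flag_radius_cm
        flagged |= near
        r_safe = np.where(near, flag_radius_cm, r)
        with np.errstate(invalid="ignore"):
            th = np.degrees(np.arccos(
                np.clip(local[:, 2] / (r_safe * 10.0), -1.0, 1.0)))
        # clamp radii into the extrapolation policy of the table
        r_lo = p.g_radii_cm[0] * 0.8
        r_hi = p.g_radii_cm[-1] * 1.2
        r_c = np.clip(r_safe, r_lo, r_hi)
        total += forward_dose(p, s_k, r_c, th)
    total[flagged] = np.nan
    return total


def characterize_seed(seed_id: str, n_histories: int, rng_seed: int = 0,
                      radius_cm: float = 15.0,
                      sk_histories: int | None = None,
                      annular_map: AnnularMap | None = None):
    """Full MC characterization pipeline for one seed.

    Transports ``n_histories`` decay photons out of the seed and through a
    water sphere of ``radius_cm`` with annular kerma scoring, scores the air
    kerma strength in vacuo (independent histories), and returns
    ``(Tg43Parameters, AnnularMap, KermaStrengthResult)``.
    """
    from .geometry import build_seed
    from .scoring import score_air_kerma_strength
    from .transport import SimConfig, run_sphere_annular, \
        transport_through_seed
    seed = build_seed(seed_id)
    ss = np.random.SeedSequence(rng_seed)
    s_emit, s_track, s_sk = (int(s.generate_state(1)[0] % (2**31 - 1))
                             for s in ss.spawn(3))
    amap = annular_map if annular_map is not None else AnnularMap.default()
    photons = transport_through_seed(seed, n_histories,
                                     np.random.default_rng(s_emit))
    run_sphere_annular(photons, amap, SimConfig(rng_seed=s_track),
                       radius_cm=radius_cm)
    sk = score_air_kerma_strength(
        seed, n_histories=sk_histories or max(n_histories // 2, 100_000),
        rng=np.random.default_rng(s_sk))
    params = extract_parameters(amap, sk, seed.active_length / 10.0,
                                seed_id=seed_id)
    return params, amap, sk
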
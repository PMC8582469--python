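"""Embedded photon-interaction data: elements, materials, spectra, sampling.

The package ships one delimited text table per element
(``data/elements/<sym>.csv``) holding the photoelectric, Compton (incoherent)
and Rayleigh (coherent) mass interaction coefficients and the mass
energy-absorption coefficient on a log-spaced energy grid from 1 keV to 1 MeV,
with duplicated grid points bracketing K absorption edges.  Materials are
element mixtures by mass fraction (``data/materials``); their coefficients
follow the mixture rule

    (mu/rho)_mat(E) = sum_i w_i (mu/rho)_i(E)

with log-log interpolation on each element table.  Radionuclide line spectra
live in ``data/spectra``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AVOGADRO, BOHR_ANGSTROM, HC_KEV_ANGSTROM

DATA_DIR = Path(__file__).parent / "data"

CHANNELS = ("photoelectric", "compton", "rayleigh")
_COLS = {"photoelectric": "pe", "compton": "compton", "rayleigh": "rayleigh",
         "energy_absorption": "mu_en"}


class EnergyRangeError(ValueError):
    """Requested energy lies outside the tabulated span."""


class UnknownElementError(KeyError):
    pass


@dataclass(frozen=True)
class ElementData:
    symbol: str
    Z: int
    atomic_mass: float
    energy_grid: np.ndarray          # keV, ascending
    mu_rho_photoelectric: np.ndarray  # cm^2/g
    mu_rho_compton: np.ndarray
    mu_rho_rayleigh: np.ndarray
    mu_en_rho: np.ndarray
    k_edge: float                    # keV
    k_fluorescence_yield: float
    k_photo_fraction: float          # K-shell share of photoabsorption above the edge
    k_line_energies: np.ndarray
    k_line_weights: np.ndarray

    @property
    def mu_rho_total(self) -> np.ndarray:
        return (self.mu_rho_photoelectric + self.mu_rho_compton
                + self.mu_rho_rayleigh)

    def mu_rho(self, energy_kev, channel: str = "total"):
        """Log-log interpolated mass coefficient (cm^2/g) at ``energy_kev``."""
        e = np.asarray(energy_kev, float)
        if np.any(e < self.energy_grid[0]) or np.any(e > self.energy_grid[-1]):
            raise EnergyRangeError(
                f"{self.symbol}: energy outside [{self.energy_grid[0]}, "
                f"{self.energy_grid[-1]}] keV")
        y = self.mu_rho_total if channel == "total" else getattr(
            self, {"photoelectric": "mu_rho_photoelectric",
                   "compton": "mu_rho_compton",
                   "rayleigh": "mu_rho_rayleigh",
                   "energy_absorption": "mu_en_rho"}[channel])
        return _loglog(e, self.energy_grid, y)

    def form_factor(self, q_inv_angstrom):
        """Atomic form factor F(q) in electrons (Moliere screened TF model)."""
        return form_factor(q_inv_angstrom, self.Z)


@dataclass(frozen=True)
class Material:
    """A homogeneous mixture of elements by mass fraction."""

    name: str
    density: float                   # g/cm^3
    composition: dict = field(default_factory=dict)  # symbol -> mass fraction

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.name}: mass fractions sum to {total!r}, expected 1")

    @property
    def elements(self):
        return [(get_element(sym), w) for sym, w in self.composition.items()]

    def electrons_per_gram(self) -> float:
        return sum(w * el.Z / el.atomic_mass * AVOGADRO
                   for el, w in self.elements)


def _loglog(e, xs, ys):
    return np.exp(np.interp(np.log(e), np.log(xs),
                            np.log(np.maximum(ys, 1e-300))))


MOLIERE_ALPHA = np.array([0.10, 0.55, 0.35])
MOLIERE_BETA = np.array([6.0, 1.2, 0.3])


def form_factor(q_inv_angstrom, z):
    """Moliere screened Thomas-Fermi atomic form factor, F(0) = Z."""
    b = 0.88534 * BOHR_ANGSTROM * float(z) ** (-1.0 / 3.0)
    q = np.asarray(q_inv_angstrom, float)[..., None]
    return z * np.sum(MOLIERE_ALPHA / (1.0 + (q * b / MOLIERE_BETA) ** 2),
                      axis=-1)


def _parse_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    return meta


@lru_cache(maxsize=None)
def get_element(symbol: str) -> ElementData:
    path = DATA_DIR / "elements" / f"{symbol}.csv"
    if not path.exists():
        raise UnknownElementError(symbol)
    meta = _parse_header(path)
    rows = pd.read_csv(path, comment="#")
    lines = meta.get("k_lines_keV", "")
    wts = meta.get("k_line_weights", "")
    line_e = np.array([float(x) for x in lines.split(",") if x], float)
    line_w = np.array([float(x) for x in wts.split(",") if x], float)
    if line_w.size:
        line_w = line_w / line_w.sum()
    return ElementData(
        symbol=symbol,
        Z=int(meta["Z"]),
        atomic_mass=float(meta["A"]),
        energy_grid=np.ascontiguousarray(rows["E_keV"]),
        mu_rho_photoelectric=np.ascontiguousarray(rows["pe"]),
        mu_rho_compton=np.ascontiguousarray(rows["compton"]),
        mu_rho_rayleigh=np.ascontiguousarray(rows["rayleigh"]),
        mu_en_rho=np.ascontiguousarray(rows["mu_en"]),
        k_edge=float(meta["k_edge_keV"]),
        k_fluorescence_yield=float(meta["k_yield"]),
        k_photo_fraction=float(meta["k_photo_fraction"]),
        k_line_energies=line_e,
        k_line_weights=line_w,
    )


@lru_cache(maxsize=None)
def get_material(name: str) -> Material:
    path = DATA_DIR / "materials" / f"{name}.csv"
    if not path.exists():
        raise KeyError(f"unknown material {name!r}")
    meta = _parse_header(path)
    rows = pd.read_csv(path, comment="#")
    comp = {str(r.element): float(r.fraction) for r in rows.itertuples()}
    return Material(name=meta["name"], density=float(meta["density_g_cm3"]),
                    composition=comp)


def list_materials():
    return sorted(p.stem for p in (DATA_DIR / "materials").glob("*.csv"))


def mu_over_rho(material: Material, energy_kev, channel: str = "total"):
    """Mass coefficient of a mixture (cm^2/g), mixture rule over elements.

    ``channel`` is one of total, photoelectric, compton, rayleigh,
    energy_absorption.
    """
    if channel not in ("total",) + CHANNELS + ("energy_absorption",):
        raise ValueError(f"unknown channel {channel!r}")
    e = np.asarray(energy_kev, float)
    out = np.zeros_like(e, dtype=float)
    for el, w in material.elements:
        out = out + w * el.mu_rho(e, channel)
    return out if out.ndim else float(out)


def sample_channel(material: Material, energy_kev, rng: np.random.Generator):
    """Draw interaction channel(s) with probability proportional to the
    partial mass attenuation coefficients at ``energy_kev``.

    Returns a string for scalar input, an array of channel indices
    (0=photoelectric, 1=compton, 2=rayleigh) for array input.
    """
    e = np.asarray(energy_kev, float)
    parts = np.stack([mu_over_rho(material, e, c) for c in CHANNELS])
    cdf = np.cumsum(parts, axis=0)
    u = rng.random(e.shape) * cdf[-1]
    idx = (u[None, ...] >= cdf[:-1]).sum(axis=0)
    if np.ndim(energy_kev) == 0:
        return CHANNELS[int(idx)]
    return idx


@dataclass(frozen=True)
class LineSpectrum:
    """Bare-line photon emission spectrum of a radionuclide."""

    nuclide: str
    energies: np.ndarray             # keV
    probabilities: np.ndarray        # photons per decay (not normalized)

    def __post_init__(self):
        if self.energies.size == 0:
            raise ValueError("empty spectrum")
        if np.any(self.energies <= 0) or np.any(self.probabilities <= 0):
            raise ValueError("line energies and probabilities must be > 0")

    @property
    def weights(self) -> np.ndarray:
        """Sampling weights (normalized emission probabilities)."""
        return self.probabilities / self.probabilities.sum()

    @property
    def photons_per_decay(self) -> float:
        return float(self.probabilities.sum())

    @property
    def max_energy(self) -> float:
        return float(self.energies.max())

    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))


@lru_cache(maxsize=None)
def get_spectrum(nuclide: str) -> LineSpectrum:
    path = DATA_DIR / "spectra" / f"{nuclide}.csv"
    if not path.exists():
        raise KeyError(f"unknown nuclide {nuclide!r}")
    rows = pd.read_csv(path, comment="#")
    return LineSpectrum(nuclide=nuclide,
                        energies=np.ascontiguousarray(rows["energy_keV"]),
                        probabilities=np.ascontiguousarray(rows["probability"]))


def sample_line(spectrum: LineSpectrum, rng: np.random.Generator, size=None):
    """Sample line energies with the normalized emission probabilities."""
    idx = rng.choice(spectrum.energies.size, size=size, p=spectrum.weights)
    return spectrum.energies[idx]


# ---------------------------------------------------------------------------
# Dense per-material lookup tables for the transport kernels.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialTables:
    """Per-material coefficients on a dense log grid, linear in (logE, log mu).

    ``mu_*`` are linear attenuation coefficients (1/cm) at the material's
    nominal density; ``mu_en_rho`` stays a mass coefficient (cm^2/g) because
    the track-length kerma estimator needs it density-free.
    """

    material: Material
    log_e: np.ndarray
    log_mu_total: np.ndarray
    log_mu_pe: np.ndarray
    log_mu_compton: np.ndarray
    log_mu_rayleigh: np.ndarray
    log_mu_en_rho: np.ndarray
    ff2: np.ndarray                  # normalized coherent F^2 on X2_GRID

    @property
    def e_min(self):
        return float(np.exp(self.log_e[0]))

    @property
    def e_max(self):
        return float(np.exp(self.log_e[-1]))


# momentum-transfer^2 grid for coherent-scatter sampling, x = sin(th/2)/lambda
# (1/Angstrom); log spacing resolves the forward peak at every energy
X2_GRID = np.concatenate([[0.0], np.geomspace(
    1e-8, (1000.0 / HC_KEV_ANGSTROM) ** 2, 511)])


@lru_cache(maxsize=None)
def material_tables(name: str, n: int = 300) -> MaterialTables:
    mat = get_material(name)
    e_lo = max(el.energy_grid[0] for el, _ in mat.elements)
    e_hi = min(el.energy_grid[-1] for el, _ in mat.elements)
    edges = [el.k_edge for el, _ in mat.elements if e_lo < el.k_edge < e_hi]
    grid = np.exp(np.linspace(np.log(e_lo), np.log(e_hi), n))
    for k in edges:
        grid = np.concatenate([grid, [k * (1 - 6e-5), k * (1 + 6e-5)]])
    grid = np.unique(grid)
    rho = mat.density

    def col(channel):
        return np.log(np.maximum(mu_over_rho(mat, grid, channel) * rho, 1e-300))

    # independent-atom coherent form factor squared, per gram, normalized
    x = np.sqrt(X2_GRID)
    q = 4.0 * np.pi * x
    ff2 = np.zeros_like(x)
    for el, w in mat.elements:
        n_atoms = w / el.atomic_mass
        ff2 += n_atoms * el.form_factor(q) ** 2
    ff2 = ff2 / ff2[0]
    return MaterialTables(
        material=mat,
        log_e=np.log(grid),
        log_mu_total=col("total"),
        log_mu_pe=col("photoelectric"),
        log_mu_compton=col("compton"),
        log_mu_rayleigh=col("rayleigh"),
        log_mu_en_rho=np.log(np.maximum(
            mu_over_rho(mat, grid, "energy_absorption"), 1e-300)),
        ff2=ff2,
    )
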
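# Methods

`brachymc` is a photon Monte Carlo engine for sealed-source brachytherapy
dosimetry. It characterizes six commercial LDR/HDR/PDR seed models under the
AAPM TG-43 formalism, freezes seed output into phase-space files, and
computes heterogeneous voxel-phantom dose maps for multi-seed plans. This
note documents the model, its numerical choices, and what the shipped
synthetic study conditions do and do not demonstrate.

## Transport model

Photons only, from 1 keV to 1 MeV, in the kerma approximation: secondary
electrons deposit their energy at the interaction site (equivalently, the
track-length estimator scores collision kerma). At brachytherapy energies
(≤ 662 keV here, ≤ 35.5 keV for I-125) CSDA electron ranges are below or
near the voxel sizes used, so the approximation is standard practice for
these sources. Pair production, bremsstrahlung, electron transport and
polarization are out of scope.

Interactions:

* **Photoelectric** — the photon terminates. If the absorbing element's
  K-edge lies below the photon energy, one K-fluorescence photon is emitted
  isotropically with probability (K-shell photo-fraction) x (K fluorescence
  yield); the rest of the energy is local. Fluorescence is simulated only
  inside seeds (silver, iridium, gold, steel), where it shapes the escaping
  spectrum — for the 6711 silver rod it contributes the ~22–25 keV Ag
  X-rays, about 20% of the escaping photons. In water and tissue the K
  yields/energies are negligible and fluorescence is not generated.
* **Compton** — free-electron Klein–Nishina, sampled by Kahn's rejection
  method. The incoherent-scattering-function (electron binding) correction
  to the *angular/energy sampling* is omitted, a ~1% effect at I-125
  energies in water; the *interaction rates* come from the data tables,
  whose totals are anchored on the published compilation (below).
* **Rayleigh** — elastic; angles from the Thomson law modulated by the
  squared atomic form factor of a Moliere-screened Thomas–Fermi atom
  (independent-atom mixture rule). This analytic form-factor model replaces
  tabulated form factors; it is crude for H/C/O individually, but coherent
  scatter redistributes direction only (no energy deposit) and is ≤ 10% of
  interactions at the relevant energies.

Tracking regimes:

* **Inside a seed**: analytic ray tracing through the nested solids, exact
  boundary distances, vacuum outside. A ray starting exactly on a surface
  belongs to the solid its direction points into (this tie-break matters:
  surface-coated sources emit *from* a boundary).
* **Homogeneous sphere** (TG-43 characterization): analytic exponential
  free paths; every flight segment is split exactly at the scoring-shell
  radii.
* **Voxel phantom**: Woodcock (delta) tracking with a per-energy majorant
  equal to the maximum over materials of (mu/rho)(E) times that material's
  maximum voxel density. Null collisions never touch the scorers; the
  track-length estimator retraces each flight segment through the voxels
  (Amanatides–Woo traversal) regardless of whether the hop ends in a real
  or null collision, covering the path exactly once.

The tracking cutoff is 1 keV (photons below it terminate; their residual
energy is ≤ 1 keV and is ignored by the kerma scorers). This is distinct
from the 5 keV delta cut applied only in air-kerma-strength scoring.

Reproducibility: histories are processed in fixed-size batches, each with
an rng seed derived from the run seed through `numpy.random.SeedSequence`;
identical seeds give bit-identical maps.

## Physical data

`data/elements/*.csv` carries, per element, photoelectric / Compton /
Rayleigh mass coefficients and the mass energy-absorption coefficient on a
log grid (1 keV–1 MeV) with duplicated points at K edges, plus K-edge,
K-yield and K-line data. Materials are mixtures by mass fraction with
log-log interpolation per element table.

The tables are generated once by `tools/make_physics_tables.py` from
transcribed anchor values of the published Hubbell–Seltzer/XCOM
compilations, with the channels reconstructed as follows: Compton from the
analytic Klein–Nishina cross-section; Rayleigh from the screened-TF
form-factor quadrature; photoelectric closed against the anchored totals
(metals) or energy-absorption coefficients (low-Z), log-log interpolated in
Z for elements without their own anchor, and power-law extended below
10 keV where anchors are not transcribed. Oxygen and nitrogen are *derived*
from the water and dry-air mixture identities, so the two dosimetrically
critical materials reproduce the published water/air coefficients exactly
at the anchor energies (verified to ≤ 0.4% at intermediate energies in the
test suite). Consequences of this construction:

* water/air attenuation and energy absorption — the quantities that set
  dose-rate constants — carry compilation accuracy;
* capsule metals (Ti, Ag, steel, Ir) are accurate at the few-percent level
  near their anchors; elements reconstructed by Z-interpolation (Na…Ca,
  Cr, Mn, Ni, Cu) are approximate below ~25 keV where K-edge positions
  differ between interpolation anchors — they appear only in tissues (minor
  fractions) or in capsules at Ir-192 energies, where the approximation is
  irrelevant;
* the channel *split* (not the total) in water differs a few percent from
  the compilation because Compton is pure Klein–Nishina; this moves
  multiple-scatter buildup slightly but neither the primary attenuation nor
  the kerma coefficient.

Decay data: bare-line spectra (photons per decay) for I-125 (5 lines,
27.2–35.5 keV) and Ir-192 (20 lines: principal gammas 136–612 keV plus the
Pt/Os K X-rays at 61–71 keV), from published decay tables. One photon per
decay event is sampled from the normalized line weights; absolute
per-decay multiplicities cancel in every reported ratio (the dose rate
constant is dose *per history* over air-kerma strength *per history*).
The Ir-192 beta continuum is absorbed in the core/capsule and omitted.

## Seed models

Each seed is an ordered list of axisymmetric analytic solids (cylinders,
cylinders with hemispherical caps, spheres, cone frustums), innermost
first, each with a material and role (active / marker / cavity / capsule /
cable), loaded from a per-seed text file. The local frame follows the
TG-43 convention: Z along the seed axis, +Z through the tip, origin at the
active-region centre. Dimensions follow the published consensus seed
descriptions; where a consensus report does not exist (SPEC M-19) the file
says so and uses approximate vendor dimensions. The HDR/PDR wires carry a
finite cable stub on the −Z side, breaking mirror symmetry exactly as the
real sources do.

The 6711 active region is the silver-rod *surface* (the AgI layer is
~1–2 µm; surface emission is the standard idealization); the other five
carry volume-distributed activity, sampled by rejection against any nested
marker. Emission is isotropic.

## Scoring

* **Annular map**: thin spherical shells at the TG-43 reporting radii
  (±2.5% relative half-thickness) by polar angle (5° bins, a dedicated 1°
  bin at 90°). Kerma per cell = Σ w·E·(mu_en/rho)(E)·l / V_cell, exact
  chord lengths per shell; the polar bin of a sub-chord is taken at its
  midpoint (sub-chords are short because the shells are thin; the induced
  smearing is far below the bin width).
* **Voxel map**: the same estimator per voxel.
* **Air-kerma strength**: scored in vacuo (no air attenuation or buildup,
  the WAFAC-style convention) on thin transverse rings (radial ±2.5%,
  polar half-angle 0.5°) at 5/7.5/10 cm, ignoring photons below the 5 keV
  delta cut; S_K = mean of K(d)·d², the spread across distances is stored
  as a line-source finite-size diagnostic. Per-history S_K in Gy·cm²
  divided into per-history dose in Gy gives the dose-rate constant directly
  in cGy·h⁻¹·U⁻¹ (the history rate cancels).
* **Uncertainty**: history-by-history moments per cell (a per-cell
  accumulator flushed when a new history touches the cell), giving
  sigma_rel = sqrt((⟨x²⟩−⟨x⟩²)/(N−1))/⟨x⟩ with N the primary count;
  unscored cells are flagged NaN.

Energy bookkeeping is exact per history in analog mode (emitted =
deposited + escaped to float precision), checked in the tests.

## TG-43 extraction and forward engine

The line-source geometry factor G_L = beta/(L·r·sinθ) (1/(r²−L²/4) on
axis) uses the active length from the seed file. Λ = D(1 cm, 90°)/S_K;
g_L and F follow the standard ratios and are exactly 1 at the reference
point/angle by construction. Forward evaluation interpolates g log-linearly
in r (g decays quasi-exponentially) with nearest-slope extrapolation
limited to ±20% beyond the table (beyond raises an error rather than
silently extrapolating), and F bilinearly in (r, θ). Multi-seed
superposition is water-only with no interseed attenuation — the TG-43
limitation, by design; the Monte Carlo plan pipeline is the heterogeneous
alternative.

## Phase-space files

Records hold every photon crossing outward through the outer surface of
the model (the capture surface; with a cable present, the surface of the
last solid the photon leaves), in the seed local frame so one file serves
every pose. Generation disables fluorescence (primary-line photons only,
with capsule attenuation and scatter still shaping the records); direct
simulations therefore disable in-seed fluorescence too when they are being
compared against a replay, so that the comparison isolates the phase-space
mechanics. Binary layout (fixed-width little-endian, CRC32 over the record
block) is documented in `brachymc/phsp.py`; replay draws records uniformly
with replacement (or cyclically) and applies the pose to position and
direction. Generation and replay rngs are independent; both seeds are
logged in the header/run info.

A dose map built by replay carries two statistical source terms: the
per-history resampling noise (captured by the history-by-history
estimator) and the sampling error of the finite record set itself (the
empirical record distribution is an N_rec-photon sample of the true
escape distribution). Direct-vs-replay comparisons therefore inflate the
replay-side variance by (1 + n_replayed/N_rec); omitting the term makes a
correct replay look significantly wrong once n_replayed >> N_rec.

## Clinical pipeline

HU → material: four materials (lung, soft tissue, prostate, cortical bone)
over closed-open HU intervals covering [−1050, 4000]; the cut points
(−600, 100, 300) are this package's documented defaults — the materials
and span are prescribed, the cut points are not — and the prostate
interval applies only inside a declared prostate contour (elsewhere soft
tissue). Densities are fixed nominal per material. Out-of-span HU values
are clamped and counted.

Plan simulation replays each seed's phase space at its pose into the
Woodcock engine with TLE scoring on the phantom grid; histories are
allocated to seeds proportionally to air-kerma strength, and particle
weights carry the plan's total S_K so the map is linear in the seed
strengths (units Gy·U per simulated history; every reported metric is
relative, so the absolute per-U history rate never enters). Seeds other
than the emitting one are not materialized in the phantom (replay into
tissue only); interseed attenuation is thereby excluded, matching the
phase-space workflow this mode reproduces.

cDVH is voxel-count weighting on the uniform grid (equal to physical
volume weighting); isodose masks use a strict `>` at each percentage of
the prescription and are nested by construction.

## Synthetic study conditions

The shipped conditions are: a 15 cm-radius water sphere for
characterization; 10⁶ histories per seed for the dose-rate-constant runs
(≈1.5–2% statistical uncertainty on Λ); 10⁴-record phase spaces for the
replay contract at desk scale (10⁶ is the production default and the
format's reference size); a synthetic pelvis on the clinical CT grid
(0.78125 × 0.78125 × 2.0 mm, 128×128×48 voxels) with ellipsoidal prostate
/ urethra / bladder / rectum / femoral heads, and a deterministic 67-seed
lattice implant clipped to the prostate with 0.5 U per seed; 2.5×10⁶
replay histories for the plan runs, which brings the prostate mean
relative uncertainty below 3%.

What these conditions do not show: the synthetic pelvis has idealized
ellipsoidal organs, uniform nominal densities and no CT noise, so clinical
cDVH/isodose numbers are fixture properties, not patient predictions; the
water-box comparison grids truncate backscatter identically on both sides
of each comparison but differ from a full 15 cm sphere in absolute dose
far from the source; and anisotropy functions at small radii intersect the
seed itself, where cells are partially shadowed — extraction reports them
with their uncertainties rather than masking.

## Known limitations

* No electron transport: dose equals collision kerma; invalid within
  ~1 mm of an Ir-192 source where electron disequilibrium matters.
* Klein–Nishina without the incoherent scattering function; TF form
  factors for Rayleigh.
* Z-interpolated photoelectric data for non-anchor elements below
  ~25 keV.
* The SPEC M-19 geometry is approximate (no published consensus
  description); its model builds and validates but no reference
  dose-rate constant is asserted for it.
* TG-43 superposition ignores interseed attenuation by definition of the
  formalism; the Monte Carlo plan mode excludes it too (replay into
  tissue only) unless seeds are materialized, which this version does not
  implement.
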
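# Methods

This note documents the physical models, numerical schemes, defaults and
design choices behind `phototherm`, and what the shipped checks do and do
not establish.

## 1. Scene model

A simulation domain is a cuboid filled with an ambient medium (air) and a
set of watertight triangle-mesh *entities*, each bound to an optical
material and an integer priority. Nesting (tumour inside flesh inside
air) is resolved by priority: the material at a point is that of the
highest-priority entity containing it. Meshes come from built-in
generators (anisotropically scaled icospheres for spheroids, boxes,
triangle-fan discs) or from STL files. Containment uses a ray-crossing
parity test along a skewed direction; ray queries use Möller–Trumbore
intersection — both implemented in vectorized numpy.

An optical material is (μa, μs, g, n): absorption and scattering
coefficients (accepted in cm⁻¹, the unit tissue-optics tables use, and
converted to mm⁻¹ once at scene compile), the Henyey–Greenstein
anisotropy, and the refractive index. A nanorod-infused tissue is a
*composite*: μa and μs are the sums of the host-tissue and particle
values (independent attenuators at one wavelength), while g and n stay
at the host values — the particle contribution to composite scattering
is ≲6%, far too small to shift the bulk anisotropy or index.

Defaults for quantities the usual tissue tables omit: g = 0.9 for all
soft tissues (the typical near-infrared value in the tissue-optics
literature), n = 1.38 for tissue and tumour, n = 1.0 for air. All are
per-material config fields.

The built-in scenario is a 10 mm cubic domain; a 6 mm flesh cube of
normal tissue centred in it (skin surface at z = +3 mm); an oblate
spheroid tumour, diameter 1 mm and height 0.5 mm, with its top face
1 mm below the skin surface (centre depth 1.25 mm); and a 1 W disc
source of radius 3 mm just below the domain top, emitting downward
along its normal. Tissue optical coefficients (cm⁻¹): normal tissue
(0.7, 36.7), tumour (2.3, 21.2), gold nanorods (12, 1.2) — the nanorod
scattering-to-absorption ratio is fixed at 0.1, as measured for
aspect-ratio-4 rods at their ~800 nm plasmon peak — giving the infused
tumour (14.3, 22.4). Every geometric and optical quantity is a config
field; the defaults above are the packaged `data/default.toml`.

## 2. Photon transport

Monte Carlo packet transport in the classic weighted (implicit-capture)
scheme:

* The source energy is split into N packets of equal power L/N; each is
  emitted from a uniformly sampled point on the disc, directed along the
  surface normal.
* Free paths are exponential: l = −ln(1−ξ)/μ with μ = μa + μs. The
  kernel samples a dimensionless optical depth s = −ln(1−ξ) and consumes
  it voxel by voxel (3-D DDA), which traverses heterogeneous media
  without resampling — statistically identical to the sample-and-compare
  loop by the memorylessness of the exponential. Media with μ = 0 (air)
  consume no depth and are crossed face to face.
* At an interaction the surviving fraction μs/μ of the weight scatters;
  the deflection cosine is drawn from the Henyey–Greenstein inverse CDF,
  the azimuth uniformly. (The absorbed fraction μa/μ is tallied for the
  energy ledger; spatial deposition uses the track-length estimator
  below, which has lower variance than collision-site scoring.)
* At voxel faces where the refractive index changes, the packet reflects
  specularly with the unpolarized Fresnel probability (R = 1 under total
  internal reflection) or refracts by Snell's law and adopts the new
  medium. In the default scenario every index-mismatched interface (the
  air–flesh cube faces) is an axis-aligned plane, so the voxel-face
  normals are exact there; the internal flesh–tumour boundary is
  index-matched and triggers no Fresnel event.
* Packets below w_min = 10⁻⁴ play roulette: killed with probability 0.9
  or boosted by 1/0.1 — unbiased in expectation. Weight leaving the
  domain is tallied as escaped (never re-injected, which would bias the
  fluence); `absorbed + escaped = N` holds exactly without roulette and
  in expectation with it, and is logged per run.

Absorbed power density per voxel uses the track-length estimator:
every traversed voxel accumulates (weight × in-voxel path length), and

    q = (L/N) · μa · Σ(w·l) / V    [W/m³]

with V the voxel volume. The volume integral of q equals the
collision-based absorbed power estimate to well under 0.1% at the
shipped packet counts (the two are independent estimators of the same
quantity).

RNG: each packet derives a private splitmix64 substream from
(seed, packet index), so cubes are bit-reproducible for a given seed
under any batching, q is exactly linear in L, and different seeds give
independent replicates. The kernel is numba-jitted and single-threaded.

The hot loop runs on a voxelized scene (per-voxel material index
sampled at voxel centres from the mesh scene), matching the resolution
of the deposition estimator itself; mesh-exact `medium_at` and
`ray_intersect` remain available as the scene API (intersection guard
ε = 10⁻⁹ mm against self-intersection after reflection). The default
grid is 201³ (the full-resolution setting); a 101³ "fast" preset is
used for the scaled runs shipped with the tests and acceptance script.

## 3. Bioheat solver

Pennes' equation, ρc ∂T/∂t = ∇·(k∇T) − B(T − Tₐ) + Q, with
B = c_b·w_b·ρ_b, is integrated by forward Euler with a 7-point
Laplacian on the same voxel grid, Q held constant (constant
illumination). Thermal constants (SI): ρ = 1079, c = 3540, k = 0.53,
ρ_b = 1060, c_b = 3617, w_b = 0.01 s⁻¹, Tₐ = 37 °C, giving
B = 38 340 W m⁻³ K⁻¹ and D = k/ρc ≈ 1.39×10⁻⁷ m²/s. One parameter set
serves both tissues by default (per-material overrides are config
fields). Perfusion applies only in tissue.

Boundary conditions: air voxels take no part in conduction; the
tissue–air skin surface (upward faces) is adiabatic, enforced by
mirroring; lateral and deep faces of the tissue block are clamped at
37 °C (far-field body temperature). With the tumour several
perfusion-screening lengths (√(k/B) ≈ 3.7 mm) from the clamped faces,
the choice is second-order for in-tumour quantities.

Stability: dt ≤ 0.9·ρc / (2k·Σ1/h² + B) (≈ 0.0108 s at 0.1 mm voxels);
recording intervals are subdivided so every snapshot lands exactly
while every step respects the bound. Discrete energy conservation (with
B = 0 and insulated boundaries, total enthalpy grows by exactly ΣQ·V·dt
per step) and the maximum principle are tested; free limits are checked
against the Gaussian heat kernel (B = 0) and the perfusion relaxation
ODE T = Tₐ + (Q/B)(1 − e^{−Bt/ρc}) (uniform field, conduction inert).

Snapshots are stored float32 (mK-level, ample for dose work); stepping
is float64. The default cadence is 20 s (a typical probe-readout
interval), plus a 1 s snapshot in the packaged config.

## 4. Thermal dose and survival

Each interval between snapshots contributes t·R^(43−T) equivalent
minutes at 43 °C, with T the trapezoidal average of the bounding
snapshots and the standard isoeffect constants R = 0.5 above 43 °C,
R = 0.25 below (configurable). No low-temperature cutoff is applied by
default — R_below makes sub-43 °C contributions negligible — but a
cutoff flag exists. CEM43 is exactly additive over history partitions
and monotone in temperature (both property-tested).

Cell kill uses a single-exponential survival curve in equivalent
minutes, S = exp(−λ·CEM43) with λ = ln10/120 min⁻¹, calibrated to the
one widely used anchor for heated human cancer lines: 10% survival
after 120 equivalent minutes. No multi-parameter (e.g., Arrhenius)
damage model is attempted; the anchor is a config field.

## 5. Problem sizes and what the checks show

The shipped end-to-end checks run 10⁷ packets on the 101³ grid with
600 s of heating — sizes chosen so a full two-scenario comparison
completes in minutes on one core while keeping the Monte Carlo error of
the smoothed temperature fields well under other uncertainties (the
block-averaged deposition peak carries a few percent of noise; the
1 s and 600 s in-tumour rises well under 1%). The acceptance script
(`scripts/acceptance.py`) recomputes every reported number from scratch
at these sizes.

The built-in scenario is an idealization, and passing checks demonstrate
internal correctness of the transport/heat/dose chain — not clinical
fidelity. In particular, real lesions are larger and irregular (the
murine tumours in the experimental literature this scenario abstracts
are several mm, not 1 mm); nanorod distributions are non-uniform and
decay by clearance; skin has layered optics, vasculature and appendages;
optical properties carry ~20% experimental uncertainty; and absolute
deposition scales directly with the incident irradiance, so the source
radius/power configuration dominates absolute comparisons between
set-ups.

## 6. Other design notes

* Explicit-priority nesting (air < flesh < tumour) avoids runtime
  containment chains; the voxelizer applies entities in ascending
  priority so the innermost wins, consistent with `medium_at`.
* Eq-of-state of the weight update: the survivor fraction is μs/μ (the
  scattered remainder); per-event deposition is w·μa/μ. This is the
  only reading that conserves energy.
* Air is non-interacting (μ = 0): packets cross it geometrically,
  boundary to boundary, with no path sampling.
* Cube outputs are raw little-endian float64 in x-fastest order with a
  JSON sidecar (shape, voxel size, units, seed, weights) — trivially
  parseable from any language; optional legacy-ASCII VTK export for
  visualisation.
* The config is TOML (JSON accepted); a transport seed is mandatory, so
  every artifact is reproducible byte-for-byte from (config, seed, code
  version), which the pipeline manifest records with checksums.

## Known limitations

Single wavelength per run; no polarization, fluorescence or
time-resolved transport; no temperature-dependent optical or thermal
properties; no nanoparticle clearance, redistribution or heat-induced
sintering; explicit (not ADI/implicit) time stepping; voxel-face
normals at refractive interfaces (exact only for axis-aligned
boundaries, as in the default scene); no acoustic modelling.
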
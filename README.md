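# phototherm

Coupled simulation of **nanoparticle photothermal therapy**: Monte Carlo
photon-packet radiative transfer through a voxelized skin-cancer model,
conversion of the absorbed optical power into tissue heating via Pennes'
bioheat equation, and CEM43 thermal-dose / cell-kill mapping over the
tumour and the surrounding normal tissue.

It is written for researchers in biophotonics and hyperthermia who want
to ask, before an experiment: *given a light source, a lesion geometry
and a nanoparticle load, how hot does the tumour get, for how long, and
what fraction of tumour and normal cells does that thermal dose kill?*

## The model

**Photon transport.** Packets of power L/N random-walk through media
described by absorption and scattering coefficients μₐ, μₛ (cm⁻¹),
Henyey–Greenstein anisotropy g and refractive index n. Free paths are
exponential in μ = μₐ + μₛ; at each interaction a fraction μₛ/μ of the
packet weight survives and deflects with ⟨cos θ⟩ = g; index-mismatched
boundaries reflect/refract via the unpolarized Fresnel equations and
Snell's law; low weights are terminated by unbiased roulette. Absorbed
power density is scored per voxel with the track-length estimator

    q = (L/N) · μₐ · Σ(w·l) / V      [W/m³].

A nanorod-infused tissue is modelled additively: its μₐ and μₛ are the
sums of the host-tissue and nanorod values (for aspect-ratio-4 gold
nanorods at the ~800 nm plasmon peak, μₛ/μₐ is fixed at 0.1).

**Heating.** q drives Pennes' bioheat equation
ρc ∂T/∂t = ∇·(k∇T) − B(T−Tₐ) + Q, with B = c_b·w_b·ρ_b lumping blood
perfusion, solved by an explicit 7-point finite-difference scheme on
the same grid (insulated skin surface, body-temperature far field).

**Dose.** The temperature history is reduced per voxel to cumulative
equivalent minutes at 43 °C, CEM43 = Σ t·R^(43−T) (R = 0.5 above
43 °C, 0.25 below), and mapped to estimated cell kill through a
survival curve S = exp(−ln10 · CEM43/120) calibrated to 10% survival
at 120 equivalent minutes.

The packaged default scenario is a 6 mm flesh cube in air holding an
oblate-spheroid tumour (diameter 1 mm, height 0.5 mm) 1 mm below the
skin, illuminated by a 1 W disc source of radius 3 mm; a control
variant strips the nanorods from the tumour. See `docs/methods.md` for
every parameter, default and numerical choice.

## Worked example

```python
from phototherm.validation import scaled_default_run

res = scaled_default_run(packets=1_000_000, grid_n=101,
                         duration=600.0, gnr=True, seed=1)
print(f"q at tumour top        : {res.q_tumour_top():.3g} W/m^3")
print(f"in-tumour rise @ 1 s   : {res.rise_at(1.0):.2f} degC")
print(f"in-tumour rise @ 600 s : {res.rise_at(600.0):.2f} degC")
print(f"min tumour cell kill   : {res.kill.death_pct[res.tumour].min():.1f} %")
```

prints (about two minutes on one core)

```
q at tumour top        : 6.71e+07 W/m^3
in-tumour rise @ 1 s   : 5.19 degC
in-tumour rise @ 600 s : 19.39 degC
min tumour cell kill   : 100.0 %
```

i.e. the nanorod-infused tumour top absorbs ~6.7×10⁷ W/m³, its
temperature rises ~5 °C within the first second and plateaus near
+19 °C (≈56 °C) by ten minutes — a thermal dose that kills essentially
every tumour cell, while (see `res.kill`) the kill probability falls
below 2% beyond 3 mm from the tumour. The control variant
(`gnr=False`) reaches only a fraction of that deposition and rise.

The same pipeline is scriptable from the shell:

```sh
phototherm run --config my_scenario.toml --out results/
phototherm transport --config my_scenario.toml --packets 1000000 --seed 1 --out q
phototherm heat --config my_scenario.toml --qcube q --out hist/
phototherm dose --config my_scenario.toml --history hist/ --out dose/ --mask-tumour
phototherm profile --cube dose/death_pct --axis z --point 0,0,0 --out profile.csv
phototherm validate
```

Voxel cubes are written as raw little-endian float64 (x-fastest) plus a
JSON sidecar; `run` also emits a manifest with checksums, so outputs
are reproducible byte-for-byte from (config, seed, code version).

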
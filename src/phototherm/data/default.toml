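# Default skin-cancer photothermal scenario.
# 10 mm cubic domain of air; 6 mm flesh cube; oblate-spheroid tumour
# (diameter 1 mm, height 0.5 mm) infused with gold nanorods, its top
# surface 1 mm below the skin surface (flesh top at z = +3 mm);
# 1 W disc source of radius 3 mm just below the domain top, aimed down.
# Optical coefficients in cm^-1, geometry in mm, thermal constants SI.

ambient = "air"

[materials.air]
mu_a = 0.0
mu_s = 0.0
g = 0.0
n = 1.0

[materials.normal_tissue]
mu_a = 0.7
mu_s = 36.7
g = 0.9
n = 1.38

[materials.tumour_tissue]
mu_a = 2.3
mu_s = 21.2
g = 0.9
n = 1.38

[materials.gnr]
# gold nanorods, aspect ratio 4, plasmon peak ~800 nm; scattering is a
# fixed 0.1 of absorption for this geometry
mu_a = 12.0
mu_s = 1.2
g = 0.9
n = 1.38

[materials.tumour_gnr]
# nanorod-infused tumour: coefficients are the sums of the host tumour
# tissue and nanorod values
mu_a = 14.3
mu_s = 22.4
composite_of = ["tumour_tissue", "gnr"]

[[entities]]
name = "flesh"
shape = "box"
center = [0.0, 0.0, 0.0]
extents = [6.0, 6.0, 6.0]
material = "normal_tissue"
priority = 1

[[entities]]
name = "tumour"
shape = "oblate_spheroid"
center = [0.0, 0.0, 1.75]
semi_axes = [0.5, 0.5, 0.25]
subdivisions = 4
material = "tumour_gnr"
priority = 2

[source]
center = [0.0, 0.0, 4.9]
radius_mm = 3.0
power_W = 1.0
direction = [0.0, 0.0, -1.0]
n_fan = 16

[grid]
half_extent_mm = 5.0
n_cells = 201

[transport]
packets = 10000000
seed = 1
w_min = 1e-4
p_survive = 0.1

[heat]
duration_s = 600.0
record_interval_s = 20.0
extra_record_times_s = [1.0]
rho = 1079.0
c = 3540.0
k = 0.53
rho_b = 1060.0
c_b = 3617.0
w_b = 0.01
T_a = 37.0

[dose]
r_above = 0.5
r_below = 0.25
survival_anchor_minutes = 120.0
survival_anchor_fraction = 0.10
mask_tumour = false
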
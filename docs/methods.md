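# Methods note

This note records the model implemented in `wetspr`, the parameter defaults
and their rationale, what the synthetic generator does and does not emulate,
the numerical choices, and the known limitations.  All quantitative
statements here are computed by the test suite or by
`scripts/acceptance.py`; none are empirical claims about real scanners.

## 1. Model and procedure

**HU and attenuation.**  CT numbers relate to water-relative attenuation by
`H = (mu − 1) · 1000`; the inverse `mu = H/1000 + 1` is clipped at 0 by
default so that noise below air cannot contribute negative attenuating area.

**TEM estimators.**  Given a slice `mu(x, y)` with pixel sizes
`a_x, a_y` (mm):

- TEM-A: `sqrt( max_rows(sum_cols mu · a_x) · max_cols(sum_rows mu · a_y) )`
- TEM-B1: `2 · sqrt( sum mu · a_x a_y / pi )`
- TEM-B2: `2 · sqrt( sum mu² · a_x a_y / pi )`

For a uniform circle of diameter `D`, TEM-A and TEM-B2 give `D · mu` and
TEM-B1 gives `D · sqrt(mu)`; at `mu = 1` all coincide with the analytic WET.
The multi-slice summary is the median over slices (robust to apex/base
slices).  The ground-truth WET of a generated phantom is the rotation-free
value `2 sqrt(a b)` times the area-mean `mu`, which is exact for uniform
ellipses and for fully contained inhomogeneities.

**Calibration.**  Relative electron density is modelled as the blend
`rho_e = alpha · mu_L + (1 − alpha) · mu_H`.  For the effective atomic
number, the target is the power sum `z = rho_e_ref · (Z_ref / 7.45)^3.1` and
the same blend form is fitted against `z`.  Both fits are weighted least
squares with the closed form
`alpha = sum w (mu_L − mu_H)(z − mu_H) / sum w (mu_L − mu_H)²`; degenerate
systems (`mu_L ≡ mu_H`) raise an error.  Bone surrogates can be
down-weighted (`bone_weight`, default 1.0).  Fitting per phantom size and
indexing by the phantom's own TEM-estimated WET (on the low-energy scan)
yields a piecewise-linear curve `alpha(WET)` per estimator, evaluated with
clamped linear interpolation.  Because the blends themselves depend only on
CT numbers, curves for different TEMs share their alpha values and differ
only in the WET axis — a property the tests assert.

**SPR.**  Per voxel: `rho_e` from the RED blend; effective atomic number
from `Z = 7.45 · (z / rho_e)^(1/3.1)` (falling back to 7.45 when
`rho_e ≤ 0.01` or the power sum is non-positive, with a flag); mean
excitation energy from a piecewise ln-linear map `I(Z)` with knots
(6.0, 63 eV), (7.45, 75 eV), (13.8, 112 eV), clamped outside; SPR from the
Bethe equation at 100 MeV protons
(`beta² = 1 − (1 + E/938.272)⁻² ≈ 0.18335`), with `I_water = 75 eV`.  Water
CT numbers map to SPR 1 exactly, for any calibration curve; air maps to 0.

**Sensitivity.**  For a tissue's CT-number pair and a host-slice WET `W`,
the SPR is evaluated at `W` and at `W ± delta` (absolute mm or percent of
`W`); the reported deviation is the signed percent change.  The natural
choice of `delta` is the maximum per-slice disagreement between TEM
estimators, which the pipeline computes from its own sweep.

## 2. Parameter defaults and rationale

| Parameter | Default | Why |
|---|---|---|
| Proton energy | 100 MeV | mid-range therapeutic energy; SPR varies weakly with energy |
| `I_water` | 75 eV | conventional water mean excitation energy |
| `I(Z)` knots | (6.0, 63), (7.45, 75), (13.8, 112) eV | anchored at adipose-like, water, and cortical-bone-like Z; ln-linear in between |
| EAN exponent | 3.1 | photoelectric cross-section power law used in the EAN definition |
| `Z_water` | 7.45 | reference for both EAN and blend targets |
| Soft/bone EAN split | 8.8 | boundary between soft-tissue and bone surrogates |
| `rho_e` floor | 0.01 | below this, EAN is meaningless; fall back to water Z and flag |
| Sweep diameters | 75–400 mm, step 25 | spans paediatric to large-adult slice sizes |
| Pixel spacing | 1.0 mm | typical CT in-plane order of magnitude |
| Insert ring | radius 0.5 R, insert radius min(9, 0.12 R) mm | keeps inserts separated and fully inside the body |
| Couch slab | 500 × 20 mm, `mu` 0.3, 5 mm gap | a carbon-fibre-like flat panel wider than any body |
| Hardening slopes | `g_low −5e-5`, `g_high −2e-5`, bone extra `b_low −8e-5`, `b_high −3e-5` per mm, pivot 200 mm | sub-percent CT-number drift over the sweep, stronger at low energy and in bone, matching the qualitative behaviour the calibration must correct |
| Surrogate spectral weights | `w_low 0.15`, `w_high 0.05` | place the fitted blends near `alpha_RED ≈ −0.5` and `alpha_EAN ≈ 9.5`, typical magnitudes for low/high-energy blending |
| Noise | 0 HU | the generator's defaults are the study conditions; noise is opt-in |

## 3. What the generator emulates — and what it does not

The phantom generator produces dual-energy HU images of elliptical bodies
with circular surrogate inserts, an optional couch slab, optional Gaussian
HU noise, and a parametric beam-hardening bias: CT numbers are scaled by
`1 + g_E (W − W0)`, with an extra bone-only factor `1 + b_E (W − W0)`.
Surrogate attenuation follows the two-parameter model
`mu_E = rho_e [ (1 − w_E) + w_E (Z/7.45)^3.1 ]`, which makes `rho_e` an
exact linear blend of the two energies — so calibration parameter recovery
is achievable to machine precision at zero noise, and residual end-to-end
errors isolate the pipeline itself.

It does **not** simulate projection physics: no polychromatic spectra,
ray-wise hardening, scatter, ring or truncation artifacts, no
reconstruction.  The hardening model is an image-domain stand-in whose only
purpose is to create a realistic, correctable size dependence.  The couch is
a uniform slab, not a structured device.

## 4. Numerical choices

- **Rasterization** uses 4×4 area-weighted supersampling; later shapes
  overwrite earlier ones via coverage blending, the couch is painted last.
- **Partial pixels** bias TEM-B2 low by roughly `h/(3r)` for a circle of
  radius `r` at pixel size `h`, because boundary pixels satisfy `mu² < mu`
  after area averaging.  At 1 mm spacing this is 0.15% for a 200 mm circle —
  the worst generic-geometry error measured — and it shrinks linearly with
  spacing.  Geometry sizes in examples and tests are chosen so this known
  discretization effect stays within the stated tolerances; it is a property
  of finite pixels, not of the estimator.
- **ROI means** for insert CT numbers use full pixels only, eroded one pixel
  from the insert boundary, so zero-noise ROI means are exact.
- **Interpolation** of calibration curves uses `numpy.interp` with clamping;
  curve construction requires at least two strictly increasing WET knots.
- **Determinism**: all randomness flows from `numpy.random.default_rng`
  seeded per phantom (`seed + index` across a sweep); pipeline artifacts are
  byte-identical for identical config and seed and carry provenance headers
  (package version, config hash, seed, method).

## 5. Couch influence

A horizontal couch slab projects `width_x · mu_couch = 500 · 0.3 = 150 mm`
onto TEM-A's column sums.  TEM-A's inflation is therefore large only while
150 mm exceeds the body's own maximal chord attenuation (`D · mu ≲ 130 mm`):
at 75 and 100 mm diameter TEM-A is the most couch-affected estimator
(33.1 vs 21.5 mm at 75 mm), but at 150 mm its inflation collapses to the
row-sum contribution (~3 mm) while the area methods always gain about
`2 · A_couch · mu / (pi · WET) ≈ 12 mm`.  The expectation that TEM-A is
uniformly the most affected estimator is thus geometrically unattainable at
150 mm, and the corresponding acceptance sub-case fails by design rather
than being weakened.

## 6. Limitations

- Image-domain hardening and a uniform couch slab are stand-ins; absolute
  alpha values are properties of the synthetic spectral model, not of any
  scanner.
- The surrogate model makes `rho_e` exactly blendable; real cross sections
  do not, so real-world residuals would be larger than the sub-0.2%
  end-to-end figures here.
- Truncated fields of view, metal, and contrast agents are out of scope;
  `--crop` exists only to exclude the couch.
- 2-D slices only; the multi-slice path is a median over independent slices,
  with no 3-D beam model.
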
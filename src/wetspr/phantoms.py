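"""Synthetic CT phantom generation with analytic WET ground truth.

Two families of inputs are produced, mirroring the two bench-test tiers of a
thickness-estimation study:

* **generic geometries** — uniform (optionally rotated) ellipses and circles
  whose pixel values are attenuation coefficients relative to water, with an
  analytic ground-truth water-equivalent thickness (WET): the effective
  diameter ``2*sqrt(a*b)`` of the ellipse times its area-mean attenuation;

* **cylindrical calibration phantoms** — acrylic cylinders (75–400 mm
  diameter) carrying tissue-surrogate inserts, optionally resting above a
  couch slab, imaged at two tube voltages with a parametric size-dependent
  CT-number bias emulating beam hardening, plus seeded Gaussian HU noise.

The beam-hardening emulation is deliberately *not* spectral physics: each
material's attenuation at energy E is scaled by ``1 + g_E*(W - W0)`` (and an
extra ``1 + b_E*(W - W0)`` for bone-like materials), where W is the
phantom's ground-truth WET.  This produces CT numbers that drift
systematically with object size — exactly the effect the size-dependent
calibration is built to absorb — without simulating a spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .images import AttenuationImage, DualEnergyImage, HUImage, mu_to_hu
from .surrogates import PMMA, SurrogateMaterial, Z_SOFT_MAX, default_surrogates

__all__ = [
    "EllipseShape",
    "CouchSpec",
    "SurrogateInsert",
    "HardeningModel",
    "PhantomSpec",
    "rasterize",
    "ground_truth_wet",
    "simulate_dect",
    "phantom_sweep",
    "cylinder_phantom",
    "ellipse_phantom",
]


@dataclass(frozen=True)
class EllipseShape:
    """A (possibly rotated) uniform ellipse in physical mm coordinates.

    The physical origin sits at the grid centre; x grows with the column
    index and y with the row index (downward).  ``mu_value`` is the
    attenuation relative to water at the low tube voltage; ``mu_value_high``
    defaults to the same value (materials without spectral contrast).
    A circle is the ``semi_axis_a == semi_axis_b`` special case.
    """

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation_deg: float = 0.0
    mu_value: float = 1.0
    mu_value_high: float | None = None

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ellipse semi-axes must be > 0")
        if self.mu_value < 0:
            raise ValueError("mu_value must be >= 0")

    def mu_at(self, energy: str) -> float:
        if energy == "high" and self.mu_value_high is not None:
            return self.mu_value_high
        return self.mu_value

    @property
    def half_extent(self) -> tuple[float, float]:
        """Axis-aligned bounding half-widths (hx, hy) of the rotated ellipse."""
        theta = math.radians(self.rotation_deg)
        c, s = math.cos(theta), math.sin(theta)
        hx = math.hypot(self.semi_axis_a * c, self.semi_axis_b * s)
        hy = math.hypot(self.semi_axis_a * s, self.semi_axis_b * c)
        return hx, hy

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        theta = math.radians(self.rotation_deg)
        c, s = math.cos(theta), math.sin(theta)
        dx, dy = x - self.center_x, y - self.center_y
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return (u / self.semi_axis_a) ** 2 + (v / self.semi_axis_b) ** 2 <= 1.0


@dataclass(frozen=True)
class CouchSpec:
    """Patient couch modelled as a horizontal slab below the object."""

    width: float = 500.0
    thickness: float = 20.0
    mu_value: float = 0.3
    gap: float = 5.0

    def __post_init__(self) -> None:
        if min(self.width, self.thickness, self.mu_value, self.gap) <= 0:
            raise ValueError("couch parameters must be positive")


@dataclass(frozen=True)
class SurrogateInsert:
    """A disk-shaped tissue-surrogate insert inside the phantom body."""

    name: str
    center_x: float
    center_y: float
    radius: float
    reference_red: float
    reference_ean: float
    mu_low: float
    mu_high: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("insert radius must be > 0")
        if self.reference_red <= 0:
            raise ValueError("reference_red must be > 0")

    @classmethod
    def from_material(cls, material: SurrogateMaterial, center_x: float, center_y: float, radius: float) -> "SurrogateInsert":
        return cls(
            material.name, center_x, center_y, radius,
            material.reference_red, material.reference_ean,
            material.mu_low, material.mu_high,
        )

    @property
    def is_bone(self) -> bool:
        return self.reference_ean > Z_SOFT_MAX

    def mu_at(self, energy: str) -> float:
        return self.mu_low if energy == "low" else self.mu_high

    def as_shape(self, energy: str) -> EllipseShape:
        return EllipseShape(self.center_x, self.center_y, self.radius, self.radius, 0.0, self.mu_at(energy))


@dataclass(frozen=True)
class HardeningModel:
    """Parametric size-dependent CT-number bias (beam-hardening emulation).

    ``bias_factor`` is exactly 1 at the reference WET ``w0`` and the model is
    deterministic given WET and material class.  Slopes are per mm of WET.
    Defaults give alpha-calibration curves with realistic sign and curvature
    (low-energy CT numbers drift faster than high-energy ones, bone more
    than soft tissue); all values are configuration, not scanner physics.
    """

    w0: float = 200.0
    g_low: float = -5e-5
    g_high: float = -2e-5
    b_low: float = -8e-5
    b_high: float = -3e-5
    z_soft: float = Z_SOFT_MAX

    def bias_factor(self, wet_mm: float, energy: str, *, is_bone: bool = False) -> float:
        delta = wet_mm - self.w0
        g = self.g_low if energy == "low" else self.g_high
        factor = 1.0 + g * delta
        if is_bone:
            b = self.b_low if energy == "low" else self.b_high
            factor *= 1.0 + b * delta
        return factor


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one synthetic phantom slice.

    ``shapes[0]`` is the primary object; later shapes overwrite earlier ones
    where they overlap (inhomogeneities).  Inserts are painted after the
    shapes and the couch last.  ``seed`` drives the HU noise and is recorded
    in every derived output.
    """

    n_rows: int
    n_cols: int
    spacing_x: float = 1.0
    spacing_y: float = 1.0
    shapes: tuple[EllipseShape, ...] = ()
    couch: CouchSpec | None = None
    inserts: tuple[SurrogateInsert, ...] = ()
    noise_sigma_hu: float = 0.0
    seed: int = 0
    hardening: HardeningModel | None = None

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")
        if self.spacing_x <= 0 or self.spacing_y <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be >= 0")
        object.__setattr__(self, "shapes", tuple(self.shapes))
        object.__setattr__(self, "inserts", tuple(self.inserts))

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (width, height) of the grid in mm."""
        return self.n_cols * self.spacing_x, self.n_rows * self.spacing_y

    def couch_top_y(self) -> float:
        """y coordinate of the couch's upper surface (below the lowest shape)."""
        if self.couch is None:
            raise ValueError("spec has no couch")
        lowest = max(s.center_y + s.half_extent[1] for s in self.shapes) if self.shapes else 0.0
        return lowest + self.couch.gap


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _pixel_centers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    width, height = spec.extent
    xs = (np.arange(spec.n_cols) + 0.5) * spec.spacing_x - width / 2.0
    ys = (np.arange(spec.n_rows) + 0.5) * spec.spacing_y - height / 2.0
    return xs, ys


def _paint(
    canvas: np.ndarray,
    spec: PhantomSpec,
    contains,
    bbox: tuple[float, float, float, float],
    mu: float,
    supersample: int,
    what: str,
) -> None:
    """Blend a shape onto the canvas with area-weighted supersampling."""
    xs, ys = _pixel_centers(spec)
    x_lo, x_hi, y_lo, y_hi = bbox
    width, height = spec.extent
    eps = 1e-9
    if x_lo < -width / 2 - eps or x_hi > width / 2 + eps or y_lo < -height / 2 - eps or y_hi > height / 2 + eps:
        raise ValueError(f"{what} exceeds the grid extent ({width} x {height} mm)")
    j0 = max(int(np.searchsorted(xs, x_lo - spec.spacing_x)), 0)
    j1 = min(int(np.searchsorted(xs, x_hi + spec.spacing_x)), spec.n_cols)
    i0 = max(int(np.searchsorted(ys, y_lo - spec.spacing_y)), 0)
    i1 = min(int(np.searchsorted(ys, y_hi + spec.spacing_y)), spec.n_rows)
    if i0 >= i1 or j0 >= j1:
        return
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    # subpixel sample coordinates, broadcast to (ni, nj, s, s)
    x_sub = xs[j0:j1, None] + off[None, :] * spec.spacing_x  # (nj, s)
    y_sub = ys[i0:i1, None] + off[None, :] * spec.spacing_y  # (ni, s)
    inside = contains(
        x_sub[None, :, None, :],  # (1, nj, 1, s)
        y_sub[:, None, :, None],  # (ni, 1, s, 1)
    )
    coverage = inside.mean(axis=(2, 3))
    region = canvas[i0:i1, j0:j1]
    canvas[i0:i1, j0:j1] = region * (1.0 - coverage) + mu * coverage


def rasterize(spec: PhantomSpec, energy: str = "low", supersample: int = 4) -> AttenuationImage:
    """Render the phantom as an attenuation image (relative to water).

    Pixel values are set by area-weighted supersampling (default 4x4
    subpixels) of the shape stack: shapes in order, then inserts, then the
    couch.  Deterministic for a fixed spec.  Raises if any shape extends
    beyond the grid.
    """
    if energy not in ("low", "high"):
        raise ValueError(f"energy must be 'low' or 'high', got {energy!r}")
    canvas = np.zeros((spec.n_rows, spec.n_cols), dtype=np.float64)
    for shape in spec.shapes:
        hx, hy = shape.half_extent
        bbox = (shape.center_x - hx, shape.center_x + hx, shape.center_y - hy, shape.center_y + hy)
        _paint(canvas, spec, shape.contains, bbox, shape.mu_at(energy), supersample, "shape")
    for insert in spec.inserts:
        shape = insert.as_shape(energy)
        hx, hy = shape.half_extent
        bbox = (shape.center_x - hx, shape.center_x + hx, shape.center_y - hy, shape.center_y + hy)
        _paint(canvas, spec, shape.contains, bbox, shape.mu_at(energy), supersample, f"insert {insert.name}")
    if spec.couch is not None:
        couch = spec.couch
        y_top = spec.couch_top_y()
        bbox = (-couch.width / 2, couch.width / 2, y_top, y_top + couch.thickness)

        def in_couch(x, y, bbox=bbox):
            return (x >= bbox[0]) & (x <= bbox[1]) & (y >= bbox[2]) & (y <= bbox[3])

        _paint(canvas, spec, in_couch, bbox, couch.mu_value, supersample, "couch")
    return AttenuationImage(canvas, spec.spacing_x, spec.spacing_y, slice_index=0)


# ---------------------------------------------------------------------------
# Analytic ground truth
# ---------------------------------------------------------------------------

def _check_inside_primary(primary: EllipseShape, other: EllipseShape, n_samples: int = 64) -> bool:
    t = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    theta = math.radians(other.rotation_deg)
    c, s = math.cos(theta), math.sin(theta)
    u = other.semi_axis_a * np.cos(t)
    v = other.semi_axis_b * np.sin(t)
    x = other.center_x + u * c - v * s
    y = other.center_y + u * s + v * c
    return bool(np.all(primary.contains(x, y)))


def ground_truth_wet(spec: PhantomSpec, energy: str = "low") -> float:
    """Analytic WET of the phantom's primary object (mm).

    Defined as the effective diameter ``2*sqrt(a*b)`` of the primary ellipse
    times the area-weighted mean attenuation over the object.  For a uniform
    cylinder of diameter D and material mu this reduces to ``D * mu``.  The
    definition is rotation-free.  Any further shapes must be inhomogeneities
    fully inside the primary ellipse (and mutually disjoint); otherwise the
    ground truth is undefined and an error is raised.  Inserts are not part
    of the generic ground-truth definition and are ignored here.
    """
    if not spec.shapes:
        raise ValueError("spec has no shapes; ground truth undefined")
    primary = spec.shapes[0]
    area0 = primary.semi_axis_a * primary.semi_axis_b  # proportional, pi cancels
    mean_mu = primary.mu_at(energy)
    for other in spec.shapes[1:]:
        if not _check_inside_primary(primary, other):
            raise ValueError(
                "ground truth is defined for a single primary ellipse with "
                f"fully-contained inhomogeneities; shape {other} is not inside the primary"
            )
        mean_mu += (other.mu_at(energy) - primary.mu_at(energy)) * (other.semi_axis_a * other.semi_axis_b) / area0
    return 2.0 * math.sqrt(primary.semi_axis_a * primary.semi_axis_b) * mean_mu


# ---------------------------------------------------------------------------
# Dual-energy simulation
# ---------------------------------------------------------------------------

def _roi_mask(spec: PhantomSpec, insert: SurrogateInsert) -> np.ndarray:
    """Pixels lying wholly inside the insert disk eroded by one pixel."""
    xs, ys = _pixel_centers(spec)
    dist = np.hypot(xs[None, :] - insert.center_x, ys[:, None] - insert.center_y)
    margin = max(spec.spacing_x, spec.spacing_y) + 0.5 * math.hypot(spec.spacing_x, spec.spacing_y)
    mask = dist <= insert.radius - margin
    if not mask.any():
        raise ValueError(f"insert {insert.name} too small for an eroded ROI at this pixel spacing")
    return mask


def simulate_dect(
    spec: PhantomSpec, supersample: int = 4
) -> tuple[DualEnergyImage, pd.DataFrame]:
    """Simulate low/high tube-voltage CT of the phantom.

    Each material's attenuation is scaled by the hardening model's bias at
    the spec's ground-truth WET (bone-like inserts get the extra bone slope),
    converted to CT numbers, and seeded Gaussian HU noise is added.  Returns
    the image pair and a measurement table with the ROI-mean CT numbers of
    every insert (ROI = insert disk eroded by one pixel, full pixels only,
    so a zero-noise ROI mean equals the biased material CT number exactly).
    """
    if spec.hardening is None:
        raise ValueError("simulate_dect requires a HardeningModel on the spec")
    wet = ground_truth_wet(spec)
    model = spec.hardening
    rng = np.random.default_rng(spec.seed)
    hu_images: dict[str, HUImage] = {}
    for energy in ("low", "high"):
        soft = model.bias_factor(wet, energy, is_bone=False)
        shapes = tuple(
            replace(s, mu_value=s.mu_at("low") * soft, mu_value_high=s.mu_at("high") * soft)
            for s in spec.shapes
        )
        inserts = tuple(
            replace(
                ins,
                mu_low=ins.mu_low * model.bias_factor(wet, energy, is_bone=ins.is_bone),
                mu_high=ins.mu_high * model.bias_factor(wet, energy, is_bone=ins.is_bone),
            )
            for ins in spec.inserts
        )
        couch = None
        if spec.couch is not None:
            couch = replace(spec.couch, mu_value=spec.couch.mu_value * soft)
        biased = replace(spec, shapes=shapes, inserts=inserts, couch=couch)
        mu_img = rasterize(biased, energy=energy, supersample=supersample)
        hu = mu_to_hu(mu_img).pixels
        if spec.noise_sigma_hu > 0:
            hu = hu + rng.normal(0.0, spec.noise_sigma_hu, size=hu.shape)
        hu_images[energy] = HUImage(hu, spec.spacing_x, spec.spacing_y, slice_index=0)
    de_image = DualEnergyImage(hu_images["low"], hu_images["high"])

    rows = []
    for insert in spec.inserts:
        mask = _roi_mask(spec, insert)
        rows.append(
            {
                "insert": insert.name,
                "H_low": float(de_image.low.pixels[mask].mean()),
                "H_high": float(de_image.high.pixels[mask].mean()),
                "reference_red": insert.reference_red,
                "reference_ean": insert.reference_ean,
                "wet_mm": wet,
            }
        )
    table = pd.DataFrame(rows, columns=["insert", "H_low", "H_high", "reference_red", "reference_ean", "wet_mm"])
    table.attrs["seed"] = spec.seed
    return de_image, table


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def ellipse_phantom(
    semi_axis_a: float,
    semi_axis_b: float,
    mu_value: float = 1.0,
    rotation_deg: float = 0.0,
    spacing: float = 1.0,
    margin: float = 10.0,
    inhomogeneities: Sequence[EllipseShape] = (),
    couch: CouchSpec | None = None,
) -> PhantomSpec:
    """Spec for a single (rotated) ellipse, grid sized to fit it (+couch)."""
    hx = math.hypot(semi_axis_a * math.cos(math.radians(rotation_deg)), semi_axis_b * math.sin(math.radians(rotation_deg)))
    hy = math.hypot(semi_axis_a * math.sin(math.radians(rotation_deg)), semi_axis_b * math.cos(math.radians(rotation_deg)))
    width = 2 * hx + 2 * margin
    height = 2 * hy + 2 * margin
    if couch is not None:
        width = max(width, couch.width + 2 * margin)
        height += 2 * (couch.gap + couch.thickness + margin)
    n_cols = int(math.ceil(width / spacing))
    n_rows = int(math.ceil(height / spacing))
    primary = EllipseShape(0.0, 0.0, semi_axis_a, semi_axis_b, rotation_deg, mu_value)
    return PhantomSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        spacing_x=spacing,
        spacing_y=spacing,
        shapes=(primary, *inhomogeneities),
        couch=couch,
    )


def cylinder_phantom(
    diameter_mm: float,
    *,
    body: SurrogateMaterial = PMMA,
    materials: Sequence[SurrogateMaterial] | None = None,
    couch: CouchSpec | None = None,
    spacing: float = 1.0,
    margin: float = 15.0,
    noise_sigma_hu: float = 0.0,
    seed: int = 0,
    hardening: HardeningModel | None = None,
) -> PhantomSpec:
    """Cylindrical (acrylic by default) phantom with a ring of surrogate inserts.

    Insert positions and radii scale with the phantom radius so the same
    material set fits every diameter of the 75–400 mm sweep; pass
    ``materials=()`` for a uniform cylinder.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    if materials is None:
        materials = default_surrogates()
    radius = diameter_mm / 2.0
    body_shape = EllipseShape(0.0, 0.0, radius, radius, 0.0, body.mu_low, body.mu_high)
    inserts = []
    if materials:
        ring = 0.5 * radius
        r_insert = min(9.0, 0.12 * radius)
        for k, mat in enumerate(materials):
            angle = 2.0 * math.pi * k / len(materials)
            inserts.append(
                SurrogateInsert.from_material(mat, ring * math.cos(angle), ring * math.sin(angle), r_insert)
            )
    width = diameter_mm + 2 * margin
    height = diameter_mm + 2 * margin
    if couch is not None:
        width = max(width, couch.width + 2 * margin)
        height += 2 * (couch.gap + couch.thickness + margin)
    n_cols = int(math.ceil(width / spacing))
    n_rows = int(math.ceil(height / spacing))
    return PhantomSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        spacing_x=spacing,
        spacing_y=spacing,
        shapes=(body_shape,),
        couch=couch,
        inserts=tuple(inserts),
        noise_sigma_hu=noise_sigma_hu,
        seed=seed,
        hardening=hardening if hardening is not None else HardeningModel(),
    )


def phantom_sweep(
    diameters: Sequence[float],
    *,
    seed: int = 0,
    **kwargs,
) -> list[tuple[PhantomSpec, DualEnergyImage, pd.DataFrame]]:
    """Simulate one cylinder phantom per diameter (75–400 mm sweep).

    Each phantom gets seed ``seed + index`` so duplicate diameters produce
    independent noise.  Keyword arguments are forwarded to
    :func:`cylinder_phantom`.
    """
    diameters = list(diameters)
    if not diameters:
        raise ValueError("diameters list must not be empty")
    results = []
    for k, d in enumerate(diameters):
        spec = cylinder_phantom(d, seed=seed + k, **kwargs)
        de_image, table = simulate_dect(spec)
        results.append((spec, de_image, table))
    return results
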
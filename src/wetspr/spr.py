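"""Voxel-wise stopping-power-ratio prediction via the Bethe equation.

The chain per voxel is

    (H_low, H_high) --alpha_RED--> rho_e --alpha_EAN--> Z --I(Z)--> I
                                   \\____________________________/
                                                 Bethe

    SPR = rho_e * [ln(2 m_e c^2 beta^2 / (I (1 - beta^2))) - beta^2]
                / [ln(2 m_e c^2 beta^2 / (I_w (1 - beta^2))) - beta^2]

with beta^2 = 1 - (1 + E/m_p c^2)^-2 for a proton of kinetic energy E.
SPR depends only weakly on E in the therapeutic range; the default 100 MeV
is a representative choice and configurable.

The mean excitation energy I is obtained from the effective atomic number
through a piecewise ln-linear mapping anchored so that water's EAN maps to
I_w exactly.  The packaged knots are a synthetic, editable stand-in for the
heuristic conversions used clinically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import CalibrationCurve, lookup
from .images import DualEnergyImage, hu_to_mu
from .surrogates import EAN_EXPONENT, Z_WATER

__all__ = [
    "BetheSettings",
    "IValueMapping",
    "SprImage",
    "red_from_ctn",
    "ean_from_ctn",
    "ivalue_from_ean",
    "bethe_spr",
    "spr_image",
    "DEFAULT_I_MAPPING",
    "RED_FLOOR",
]

#: Relative electron density below which a voxel is classified as air.
RED_FLOOR = 0.01


@dataclass(frozen=True)
class BetheSettings:
    """Physical constants and evaluation energy for the Bethe equation."""

    energy_mev: float = 100.0
    i_water_ev: float = 75.0
    electron_rest_mev: float = 0.511
    proton_rest_mev: float = 938.272

    def __post_init__(self) -> None:
        if self.energy_mev <= 0:
            raise ValueError("proton kinetic energy must be > 0")
        if self.i_water_ev <= 0:
            raise ValueError("I_w must be > 0")

    @property
    def beta_sq(self) -> float:
        b2 = 1.0 - (1.0 + self.energy_mev / self.proton_rest_mev) ** -2
        if not (0.0 < b2 < 1.0):
            raise ValueError("beta^2 outside (0, 1)")
        return b2


@dataclass(frozen=True)
class IValueMapping:
    """Piecewise ln-linear EAN -> mean-excitation-energy mapping (eV).

    Knots are ``(Z, I_eV)`` pairs, strictly increasing in Z and clamped at
    the end knots; the water knot maps Z_W to I_w exactly.  The packaged
    default (soft-tissue, water and bone-region knots) is synthetic.
    """

    knots_z: np.ndarray
    knots_i_ev: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.knots_z, dtype=np.float64)
        i_ev = np.asarray(self.knots_i_ev, dtype=np.float64)
        if z.ndim != 1 or z.shape != i_ev.shape or len(z) < 2:
            raise ValueError("mapping needs >= 2 (Z, I) knots of equal length")
        if np.any(np.diff(z) <= 0):
            raise ValueError("mapping knots must be sorted strictly increasing in Z")
        if np.any(i_ev <= 0):
            raise ValueError("I values must be positive")
        object.__setattr__(self, "knots_z", z)
        object.__setattr__(self, "knots_i_ev", i_ev)

    def __call__(self, ean):
        return ivalue_from_ean(ean, self)


DEFAULT_I_MAPPING = IValueMapping(
    knots_z=np.array([6.0, Z_WATER, 13.8]),
    knots_i_ev=np.array([63.0, 75.0, 112.0]),
)


@dataclass(frozen=True)
class SprImage:
    """A stopping-power-ratio map with its provenance."""

    pixels: np.ndarray
    spacing_x: float
    spacing_y: float
    slice_index: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            raise ValueError("SPR map contains non-finite values")
        object.__setattr__(self, "pixels", arr)


def red_from_ctn(mu_low, mu_high, alpha_red: float):
    """Relative electron density as the calibrated blend of the two scans."""
    return alpha_red * np.asarray(mu_low) + (1.0 - alpha_red) * np.asarray(mu_high)


def ean_from_ctn(
    mu_low,
    mu_high,
    red,
    alpha_ean: float,
    n: float = EAN_EXPONENT,
    z_w: float = Z_WATER,
    red_floor: float = RED_FLOOR,
):
    """Effective atomic number from the calibrated blend.

    ``Z = Z_W * (blend / rho_e)**(1/n)`` with
    ``blend = alpha_EAN*mu_low + (1-alpha_EAN)*mu_high``.  Voxels with
    ``rho_e <= red_floor`` are classified as air, and voxels whose blend is
    non-positive have no physical EAN; both get the water fallback Z_W and
    are flagged rather than raising.

    Returns ``(ean, flagged)`` where ``flagged`` marks fallback voxels.
    """
    mu_low = np.asarray(mu_low, dtype=np.float64)
    mu_high = np.asarray(mu_high, dtype=np.float64)
    red = np.asarray(red, dtype=np.float64)
    blend = alpha_ean * mu_low + (1.0 - alpha_ean) * mu_high
    flagged = (red <= red_floor) | (blend <= 0.0)
    safe_red = np.where(flagged, 1.0, red)
    safe_blend = np.where(flagged, 1.0, blend)
    ean = z_w * (safe_blend / safe_red) ** (1.0 / n)
    ean = np.where(flagged, z_w, ean)
    if ean.ndim == 0:
        return float(ean), bool(flagged)
    return ean, flagged


def ivalue_from_ean(ean, mapping: IValueMapping = DEFAULT_I_MAPPING):
    """Mean excitation energy (eV): ln I piecewise linear in Z, clamped."""
    ln_i = np.interp(np.asarray(ean, dtype=np.float64), mapping.knots_z, np.log(mapping.knots_i_ev))
    i_ev = np.exp(ln_i)
    if i_ev.ndim == 0:
        return float(i_ev)
    return i_ev


def _stopping_number(i_ev, settings: BetheSettings):
    b2 = settings.beta_sq
    arg = 2.0 * settings.electron_rest_mev * 1e6 * b2 / (np.asarray(i_ev, dtype=np.float64) * (1.0 - b2))
    return np.log(arg) - b2


def bethe_spr(red, i_ev, settings: BetheSettings = BetheSettings()):
    """Stopping-power ratio relative to water for (rho_e, I) voxels.

    Linear in rho_e and strictly decreasing in I.  Raises if I is so large
    that the stopping number becomes non-positive (outside the equation's
    validity range).
    """
    i_ev = np.asarray(i_ev, dtype=np.float64)
    if np.any(i_ev <= 0):
        raise ValueError("I must be positive")
    numer = _stopping_number(i_ev, settings)
    denom = _stopping_number(settings.i_water_ev, settings)
    if np.any(numer <= 0) or denom <= 0:
        raise ValueError("stopping number non-positive: I outside the Bethe validity range")
    spr = np.asarray(red, dtype=np.float64) * numer / denom
    if spr.ndim == 0:
        return float(spr)
    return spr


def spr_image(
    de_image: DualEnergyImage,
    curve: CalibrationCurve,
    wet_mm: float,
    settings: BetheSettings = BetheSettings(),
    mapping: IValueMapping = DEFAULT_I_MAPPING,
    red_floor: float = RED_FLOOR,
) -> SprImage:
    """Voxel-wise SPR map from a DECT slice and a TEM-specific curve.

    ``wet_mm`` must come from the same TEM that produced ``curve`` — the
    curve's alphas are looked up at this WET, then the rho_e -> Z -> I ->
    Bethe chain runs per voxel.  Air voxels (rho_e below the floor) get
    SPR 0.
    """
    alpha_red, alpha_ean = lookup(curve, wet_mm)
    mu_low = hu_to_mu(de_image.low).pixels
    mu_high = hu_to_mu(de_image.high).pixels
    red = red_from_ctn(mu_low, mu_high, alpha_red)
    ean, flagged = ean_from_ctn(mu_low, mu_high, red, alpha_ean, red_floor=red_floor)
    i_ev = ivalue_from_ean(ean, mapping)
    air = red <= red_floor
    safe_red = np.where(air, 0.0, np.maximum(red, 0.0))
    spr = bethe_spr(safe_red, i_ev, settings)
    spr = np.where(air, 0.0, spr)
    provenance = {
        "method": curve.method,
        "wet_mm": float(wet_mm),
        "alpha_red": float(alpha_red),
        "alpha_ean": float(alpha_ean),
        "energy_mev": settings.energy_mev,
        "i_water_ev": settings.i_water_ev,
    }
    return SprImage(spr, de_image.spacing_x, de_image.spacing_y, de_image.slice_index, provenance)
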
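"""Size-dependent DECT calibration: alpha_RED(WET) and alpha_EAN3.1(WET).

Relative electron density (RED) and effective atomic number (EAN) are
obtained from the two DECT attenuations by a one-parameter linear blend,

    rho_e             ~ alpha_RED * mu_low + (1 - alpha_RED) * mu_high
    rho_e*(Z/Z_W)^3.1 ~ alpha_EAN * mu_low + (1 - alpha_EAN) * mu_high

with mu_E = H_E/1000 + 1.  Because beam hardening shifts CT numbers with
object size, the optimal blending weights depend on the object's
water-equivalent thickness (WET): fitting them per phantom size and
interpolating over the WET axis yields the size-dependent calibration
curves.  The WET axis is produced by one specific thickness estimation
method, so every TEM carries its own pair of curves.

Both fits are weighted least squares with the closed-form solution

    alpha = sum w*(muL - muH)*(z - muH) / sum w*(muL - muH)^2

where z is the fit target (rho_e_ref, or rho_e_ref*(Z_ref/Z_W)^3.1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .images import crop
from .surrogates import EAN_EXPONENT, Z_WATER

__all__ = [
    "SurrogateMeasurement",
    "CalibrationCurve",
    "fit_alpha_red",
    "fit_alpha_ean",
    "build_curve",
    "lookup",
    "measurements_from_table",
    "calibrate_from_sweep",
]


@dataclass(frozen=True)
class SurrogateMeasurement:
    """ROI-mean CT numbers of one surrogate insert in one phantom scan."""

    insert: str
    h_low: float
    h_high: float
    reference_red: float
    reference_ean: float
    wet_mm: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.reference_red <= 0:
            raise ValueError("reference_red must be > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def mu_low(self) -> float:
        return self.h_low / 1000.0 + 1.0

    @property
    def mu_high(self) -> float:
        return self.h_high / 1000.0 + 1.0


def _closed_form_alpha(measurements: Sequence[SurrogateMeasurement], targets: np.ndarray) -> float:
    mu_l = np.array([m.mu_low for m in measurements])
    mu_h = np.array([m.mu_high for m in measurements])
    w = np.array([m.weight for m in measurements])
    d = mu_l - mu_h
    denom = float((w * d * d).sum())
    if denom <= 0 or not math.isfinite(denom) or denom < 1e-30:
        raise ValueError("alpha is unidentifiable: all measurements have mu_low == mu_high")
    return float((w * d * (targets - mu_h)).sum() / denom)


def fit_alpha_red(measurements: Sequence[SurrogateMeasurement]) -> float:
    """Fit the RED blending weight for one phantom size."""
    measurements = list(measurements)
    if not measurements:
        raise ValueError("at least one measurement is required")
    targets = np.array([m.reference_red for m in measurements])
    return _closed_form_alpha(measurements, targets)


def fit_alpha_ean(
    measurements: Sequence[SurrogateMeasurement],
    n: float = EAN_EXPONENT,
    z_w: float = Z_WATER,
) -> float:
    """Fit the EAN blending weight for one phantom size.

    The fit target is ``rho_e_ref * (Z_ref/Z_W)**n`` built from the
    *reference* RED (not the predicted one), which keeps the problem a
    linear one-parameter fit decoupled from the RED fit.  Surrogates with
    large CT-number contrast — bone above all — dominate the normal
    equations naturally; an explicit weight can upweight them further.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("at least one measurement is required")
    targets = np.array([m.reference_red * (m.reference_ean / z_w) ** n for m in measurements])
    return _closed_form_alpha(measurements, targets)


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise-linear WET -> (alpha_RED, alpha_EAN) mapping for one TEM.

    Evaluation clamps to the end knots outside the calibrated WET range, so
    lookups are defined for every WET >= 0.
    """

    method: str
    wet_mm: np.ndarray
    alpha_red: np.ndarray
    alpha_ean: np.ndarray

    def __post_init__(self) -> None:
        wet = np.asarray(self.wet_mm, dtype=np.float64)
        a_red = np.asarray(self.alpha_red, dtype=np.float64)
        a_ean = np.asarray(self.alpha_ean, dtype=np.float64)
        if wet.ndim != 1 or wet.shape != a_red.shape or wet.shape != a_ean.shape:
            raise ValueError("knot arrays must be 1-D and of equal length")
        if len(wet) < 2:
            raise ValueError("a calibration curve needs at least two knots")
        if np.any(np.diff(wet) <= 0):
            raise ValueError("knot WETs must be strictly increasing (no duplicates)")
        object.__setattr__(self, "wet_mm", wet)
        object.__setattr__(self, "alpha_red", a_red)
        object.__setattr__(self, "alpha_ean", a_ean)

    def __call__(self, wet_mm: float) -> tuple[float, float]:
        return lookup(self, wet_mm)

    # -- serialization ------------------------------------------------------
    def to_csv(self, path, sidecar: bool = True, header: dict | None = None) -> None:
        df = pd.DataFrame(
            {"wet_mm": self.wet_mm, "alpha_red": self.alpha_red, "alpha_ean": self.alpha_ean}
        )
        df.insert(0, "method", self.method)
        lines = [f"# {k}: {v}" for k, v in (header or {}).items()]
        text = "\n".join(lines) + ("\n" if lines else "") + df.to_csv(index=False)
        Path(path).write_text(text)
        if sidecar:
            meta = {"method": self.method, "interpolation": "piecewise-linear", "extrapolation": "clamp"}
            Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        df = pd.read_csv(path, comment="#")
        methods = df["method"].unique()
        if len(methods) != 1:
            raise ValueError(f"curve file {path} must contain exactly one method, got {list(methods)}")
        df = df.sort_values("wet_mm")
        return cls(str(methods[0]), df["wet_mm"].to_numpy(), df["alpha_red"].to_numpy(), df["alpha_ean"].to_numpy())


def build_curve(fits: Sequence[tuple[float, float, float]], method: str) -> CalibrationCurve:
    """Assemble a curve from per-size fits ``(wet_mm, alpha_red, alpha_ean)``."""
    fits = sorted(fits, key=lambda t: t[0])
    if len(fits) < 2:
        raise ValueError("at least two phantom sizes are required to build a curve")
    wet = np.array([f[0] for f in fits])
    if np.any(np.diff(wet) == 0):
        raise ValueError("duplicate wet_mm knots")
    return CalibrationCurve(method, wet, np.array([f[1] for f in fits]), np.array([f[2] for f in fits]))


def lookup(curve: CalibrationCurve, wet_mm: float) -> tuple[float, float]:
    """Interpolated (alpha_red, alpha_ean) at a WET; clamped outside the knots."""
    if wet_mm < 0:
        raise ValueError("wet_mm must be >= 0")
    a_red = float(np.interp(wet_mm, curve.wet_mm, curve.alpha_red))
    a_ean = float(np.interp(wet_mm, curve.wet_mm, curve.alpha_ean))
    return a_red, a_ean


def measurements_from_table(
    table: pd.DataFrame,
    wet_mm: float | None = None,
    bone_weight: float = 1.0,
    z_soft: float = 8.8,
) -> list[SurrogateMeasurement]:
    """Convert a simulated (or loaded) insert-measurement table.

    ``bone_weight`` > 1 upweights bone-class surrogates (EAN above
    ``z_soft``) in the fits.
    """
    out = []
    for row in table.itertuples(index=False):
        weight = bone_weight if row.reference_ean > z_soft else 1.0
        out.append(
            SurrogateMeasurement(
                insert=row.insert,
                h_low=float(row.H_low),
                h_high=float(row.H_high),
                reference_red=float(row.reference_red),
                reference_ean=float(row.reference_ean),
                wet_mm=float(wet_mm if wet_mm is not None else row.wet_mm),
                weight=weight,
            )
        )
    return out


def calibrate_from_sweep(
    sweep,
    method: str,
    *,
    bone_weight: float = 1.0,
    exclude: Sequence[str] = (),
    crop_couch: bool = False,
) -> CalibrationCurve:
    """Fit a TEM-specific calibration curve from a phantom-diameter sweep.

    ``sweep`` is the output of :func:`wetspr.phantoms.phantom_sweep`.  For
    each phantom, the WET knot is the chosen TEM's estimate on the
    low-energy scan (the WET axis must come from the same estimator that
    will later drive lookups), and the alphas are fitted from the insert
    measurements.  ``exclude`` drops surrogates by name, e.g. to hold one
    out for validation.
    """
    from .images import CropBox, hu_to_mu
    from .tem import estimate

    fits = []
    for spec, de_image, table in sweep:
        mu_low = hu_to_mu(de_image.low)
        if crop_couch and spec.couch is not None:
            y_top = spec.couch_top_y()
            height = spec.n_rows * spec.spacing_y
            row_max = int((y_top + height / 2.0) / spec.spacing_y)
            mu_low = crop(mu_low, CropBox(0, row_max, 0, spec.n_cols))
        wet = estimate(method, mu_low).wet_mm
        sub = table[~table["insert"].isin(list(exclude))]
        ms = measurements_from_table(sub, wet_mm=wet, bone_weight=bone_weight)
        fits.append((wet, fit_alpha_red(ms), fit_alpha_ean(ms)))
    return build_curve(fits, method)
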
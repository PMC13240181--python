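"""WET-perturbation sensitivity of the predicted stopping-power ratio.

How much does an error in the water-equivalent-thickness estimate matter?
The analysis holds a tissue's CT numbers fixed and perturbs only the WET at
which the calibration curve is read:

1. look up (alpha_RED, alpha_EAN) at the nominal WET and compute the
   nominal SPR of the tissue;
2. shift the WET by +delta and -delta (the plausible WET uncertainty,
   typically the maximum disagreement observed between the thickness
   estimation methods on the cylindrical phantom sweep), re-read the
   curve, recompute SPR with the *same* CT numbers, and report the
   relative SPR change in percent.

Tissues whose low- and high-energy CT numbers coincide (water-like) are
insensitive by construction; bone, with its large spectral contrast, is
where WET errors hurt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .calibration import CalibrationCurve, lookup
from .spr import BetheSettings, DEFAULT_I_MAPPING, IValueMapping, bethe_spr, ean_from_ctn, ivalue_from_ean, red_from_ctn
from .surrogates import SurrogateMaterial

__all__ = [
    "SensitivityCase",
    "SensitivityResult",
    "spr_at_wet",
    "sensitivity_table",
]


@dataclass(frozen=True)
class SensitivityCase:
    """One tissue at one host WET with one signed WET perturbation."""

    tissue: str
    h_low: float
    h_high: float
    wet_mm: float
    delta_wet_mm: float
    method: str


@dataclass(frozen=True)
class SensitivityResult:
    case: SensitivityCase
    spr_nominal: float
    spr_perturbed: float

    @property
    def delta_spr_percent(self) -> float:
        return 100.0 * (self.spr_perturbed - self.spr_nominal) / self.spr_nominal


def spr_at_wet(
    h_low: float,
    h_high: float,
    wet_mm: float,
    curve: CalibrationCurve,
    settings: BetheSettings = BetheSettings(),
    mapping: IValueMapping = DEFAULT_I_MAPPING,
) -> float:
    """SPR of fixed CT numbers with calibration factors read at ``wet_mm``."""
    alpha_red, alpha_ean = lookup(curve, wet_mm)
    mu_low = h_low / 1000.0 + 1.0
    mu_high = h_high / 1000.0 + 1.0
    red = red_from_ctn(mu_low, mu_high, alpha_red)
    ean, _ = ean_from_ctn(mu_low, mu_high, red, alpha_ean)
    i_ev = ivalue_from_ean(ean, mapping)
    return bethe_spr(red, i_ev, settings)


def _evaluate(case: SensitivityCase, curve: CalibrationCurve, settings, mapping, mode: str) -> SensitivityResult:
    if mode == "mm":
        perturbed_wet = case.wet_mm + case.delta_wet_mm
    elif mode == "percent":
        perturbed_wet = case.wet_mm * (1.0 + case.delta_wet_mm / 100.0)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    perturbed_wet = max(perturbed_wet, 0.0)
    nominal = spr_at_wet(case.h_low, case.h_high, case.wet_mm, curve, settings, mapping)
    perturbed = spr_at_wet(case.h_low, case.h_high, perturbed_wet, curve, settings, mapping)
    return SensitivityResult(case, nominal, perturbed)


def sensitivity_table(
    tissues: Sequence[SurrogateMaterial] | pd.DataFrame,
    wet_grid: Sequence[float],
    delta: float,
    curves: Mapping[str, CalibrationCurve],
    settings: BetheSettings = BetheSettings(),
    mapping: IValueMapping = DEFAULT_I_MAPPING,
    mode: str = "mm",
    hardening=None,
) -> pd.DataFrame:
    """Tidy table of SPR deviations per tissue x WET x method x sign.

    ``tissues`` is either a DataFrame with columns ``tissue, H_low, H_high``
    (CT numbers fixed for all WETs) or a list of surrogate materials, whose
    nominal CT numbers are then biased per host WET with ``hardening``
    (pass None for unbiased CT numbers).  ``delta`` is applied with both
    signs; units are mm (``mode='mm'``) or percent of the host WET
    (``mode='percent'``).
    """
    wet_grid = list(wet_grid)
    if not wet_grid:
        raise ValueError("wet_grid must not be empty")
    if isinstance(tissues, pd.DataFrame):
        if tissues.empty:
            raise ValueError("tissue table must not be empty")
        fixed = [(str(r.tissue), float(r.H_low), float(r.H_high)) for r in tissues.itertuples(index=False)]
        ctn_at = lambda name, h_low, h_high, wet: (h_low, h_high)
        entries = fixed
    else:
        tissues = list(tissues)
        if not tissues:
            raise ValueError("tissue list must not be empty")

        def material_ctn(mat: SurrogateMaterial, wet: float) -> tuple[float, float]:
            mu_l, mu_h = mat.mu_low, mat.mu_high
            if hardening is not None:
                mu_l *= hardening.bias_factor(wet, "low", is_bone=mat.is_bone)
                mu_h *= hardening.bias_factor(wet, "high", is_bone=mat.is_bone)
            return (mu_l - 1.0) * 1000.0, (mu_h - 1.0) * 1000.0

        entries = tissues
        ctn_at = None

    rows = []
    for method, curve in curves.items():
        for wet in wet_grid:
            for entry in entries:
                if ctn_at is None:
                    name = entry.name
                    h_low, h_high = material_ctn(entry, wet)
                else:
                    name, h_low, h_high = entry
                for signed_delta in (+abs(delta), -abs(delta)):
                    case = SensitivityCase(name, h_low, h_high, wet, signed_delta, method)
                    res = _evaluate(case, curve, settings, mapping, mode)
                    rows.append(
                        {
                            "tissue": name,
                            "method": method,
                            "wet_mm": wet,
                            "delta_mm": signed_delta,
                            "spr_nominal": res.spr_nominal,
                            "spr_perturbed": res.spr_perturbed,
                            "delta_spr_percent": res.delta_spr_percent,
                        }
                    )
    return pd.DataFrame(rows)
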
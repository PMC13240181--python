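"""Synthetic tissue-surrogate inserts and their nominal DECT attenuation.

Commercial calibration phantoms carry cylindrical inserts of tissue-equivalent
plastics whose relative electron density (RED, rho_e) and effective atomic
number (EAN, Z, exponent-3.1 convention) are certified by the vendor.  This
package ships no vendor data; the table below is a SYNTHETIC set of plausible
lung / soft-tissue / bone surrogate parameters for testing and demonstration,
and is explicitly not a reproduction of any manufacturer's certificate.

Nominal attenuation at the two tube voltages is generated from a
two-component cross-section model

    mu_E(rho_e, Z) = rho_e * [(1 - w_E) + w_E * (Z / Z_W)**3.1]

in which ``w_E`` is the weight of the photoelectric-like, Z-dependent channel
at energy E (larger at the low tube voltage).  The model is exact for water
(Z = Z_W gives mu = rho_e at both energies) and makes rho_e an exact linear
blend of the two attenuations, which is the structural assumption behind
DECT alpha-blending calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SurrogateMaterial",
    "surrogate_mu",
    "default_surrogates",
    "PMMA",
    "Z_WATER",
    "EAN_EXPONENT",
    "W_LOW",
    "W_HIGH",
    "Z_SOFT_MAX",
]

#: Effective atomic number of water under the exponent-3.1 convention.
Z_WATER = 7.45
#: Exponent of the EAN definition used throughout the package.
EAN_EXPONENT = 3.1
#: Photoelectric-channel weights of the synthetic spectral model.
W_LOW = 0.15
W_HIGH = 0.05
#: EAN above which a material is treated as bone-like (extra beam hardening).
Z_SOFT_MAX = 8.8


def surrogate_mu(red: float, ean: float, *, w: float, z_w: float = Z_WATER, n: float = EAN_EXPONENT) -> float:
    """Nominal attenuation relative to water of a (RED, EAN) material."""
    return red * ((1.0 - w) + w * (ean / z_w) ** n)


@dataclass(frozen=True)
class SurrogateMaterial:
    """A tissue surrogate: certified reference values plus nominal DECT mu."""

    name: str
    reference_red: float
    reference_ean: float

    def __post_init__(self) -> None:
        if self.reference_red <= 0:
            raise ValueError("reference_red must be > 0")

    @property
    def mu_low(self) -> float:
        return surrogate_mu(self.reference_red, self.reference_ean, w=W_LOW)

    @property
    def mu_high(self) -> float:
        return surrogate_mu(self.reference_red, self.reference_ean, w=W_HIGH)

    @property
    def is_bone(self) -> bool:
        return self.reference_ean > Z_SOFT_MAX


def default_surrogates() -> list[SurrogateMaterial]:
    """The packaged synthetic surrogate set (lung, soft tissues, bones)."""
    return [
        SurrogateMaterial("lung_inhale", 0.20, 7.70),
        SurrogateMaterial("lung_exhale", 0.50, 7.62),
        SurrogateMaterial("adipose", 0.95, 6.21),
        SurrogateMaterial("brain", 1.045, 6.09),
        SurrogateMaterial("muscle", 1.043, 7.64),
        SurrogateMaterial("liver", 1.052, 7.74),
        SurrogateMaterial("trabecular_bone", 1.117, 10.42),
        SurrogateMaterial("bone_50", 1.470, 12.54),
        SurrogateMaterial("cortical_bone", 1.695, 13.64),
    ]


#: Acrylic (PMMA) body material of the cylindrical calibration phantoms.
PMMA = SurrogateMaterial("pmma", 1.147, 6.47)
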
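"""Voxel-wise stopping-power-ratio prediction for a phantom slice.

Chain: dual-energy CT numbers -> WET-indexed alpha lookup -> relative
electron density and effective atomic number -> mean excitation energy
-> Bethe-equation SPR at 100 MeV.  Predicted insert SPRs are compared
with the values computed directly from each surrogate's reference
(RED, EAN) parameters.
"""

from wetspr import (
    bethe_spr,
    calibrate_from_sweep,
    hu_to_mu,
    ivalue_from_ean,
    phantom_sweep,
    spr_image,
)
from wetspr.sensitivity import spr_at_wet
from wetspr.tem import estimate

sweep = phantom_sweep([75, 125, 175, 225, 275, 325, 400], seed=0)
curve = calibrate_from_sweep(sweep, "tem-b1")

spec, de, table = sweep[3]  # the 225 mm phantom
wet = estimate("tem-b1", hu_to_mu(de.low)).wet_mm
spr = spr_image(de, curve, wet)
print(f"Phantom diameter 225 mm, TEM-B1 WET = {wet:.1f} mm")
print(f"SPR map shape {spr.pixels.shape}, body maximum SPR = {spr.pixels.max():.3f}")

print(f"\n  {'insert':>16s} {'predicted':>10s} {'reference':>10s} {'error %':>8s}")
for row in table.itertuples():
    predicted = spr_at_wet(row.H_low, row.H_high, wet, curve)
    reference = bethe_spr(row.reference_red, ivalue_from_ean(row.reference_ean))
    err = 100 * (predicted / reference - 1)
    print(f"  {row.insert:>16s} {predicted:10.4f} {reference:10.4f} {err:8.3f}")
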
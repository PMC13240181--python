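"""WET estimation on uniform shapes with known analytic answers.

A uniform circle of diameter D and relative attenuation mu has
water-equivalent thickness D * mu, and a uniform ellipse with semi-axes
(a, b) has the rotation-free value 2*sqrt(a*b) * mu.  This script checks
each truncation-equivalent-medium (TEM) estimator against those values
and shows the one systematic geometry effect: TEM-A follows the oblique
chord of a rotated ellipse instead of the rotation-free WET.
"""

import math

from wetspr import ellipse_phantom, ground_truth_wet, rasterize
from wetspr.tem import TEM_FUNCTIONS

print("Uniform shapes, mu = 1.0 (water):")
for label, a, b in [("circle D=200 mm", 100, 100), ("ellipse 400x200 mm", 200, 100)]:
    spec = ellipse_phantom(a, b, 1.0)
    img = rasterize(spec)
    gt = ground_truth_wet(spec)
    parts = ", ".join(f"{m} {fn(img):7.2f}" for m, fn in TEM_FUNCTIONS.items())
    print(f"  {label:20s} analytic WET {gt:7.2f} mm | {parts}")

print("\nSame 200x100 mm semi-axis ellipse, rotated (analytic WET stays fixed):")
gt = 2 * math.sqrt(100 * 50) * 1.0
for theta in (0, 45, 90):
    img = rasterize(ellipse_phantom(100, 50, 1.0, rotation_deg=theta))
    parts = ", ".join(f"{m} {fn(img):7.2f}" for m, fn in TEM_FUNCTIONS.items())
    print(f"  rotation {theta:2d} deg | {parts}   (rotation-free: {gt:.2f} mm)")
print(
    "\nTEM-B1/B2 are rotation invariant (area-based); TEM-A at 45 deg lands on\n"
    "the oblique chord, about 10.6% below the rotation-free WET for this 2:1 axis ratio."
)
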
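"""BMP-2 dose-response factors acting on the cell model.

Evaluates the four fold-change curves over nine decades of concentration
and prints the table.  Chemotaxis peaks at 1 ng/cm^3 (3.5-fold for MSCs,
2.2-fold for osteoblasts), MSC proliferation at 200 ng/cm^3 (2-fold), and
osteoblast bone production saturates at 3-fold — so a very high local
concentration is LESS chemotactic than a moderate one, which is what
steers progenitors toward the periphery of a treated defect.
"""

import numpy as np

from callusim import dose_response
from callusim.bmp2 import DoseResponseSet

concentrations = np.logspace(-2, 6, 9)
print(f"{'ng/cm^3':>10} " + " ".join(f"{c:>14}" for c in DoseResponseSet.CURVES))
for c in concentrations:
    row = " ".join(
        f"{dose_response(c, curve):14.3f}" for curve in DoseResponseSet.CURVES
    )
    print(f"{c:10.2g} {row}")

print()
print("peak MSC chemotaxis   :", dose_response(1.0, "msc_chemotaxis"), "fold")
print("peak OB chemotaxis    :", dose_response(1.0, "osteoblast_chemotaxis"), "fold")
print("peak MSC proliferation:", dose_response(200.0, "proliferation"), "fold")
print("bone production at 1e6:", round(float(dose_response(1e6, "bone_production")), 4), "fold (asymptote 3)")
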
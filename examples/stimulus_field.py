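"""Mechanoregulation stimulus across the fresh defect under gait load.

Builds the defect geometry (coarsened lattice), homogenizes the initial
all-granulation callus, solves the surrogate mechanics for a 7-N gait
load, and prints the stimulus S = gamma/0.0375 + v/3 by region.  Low S
(<= 2.53) marks bone-permissive regions — here the marrow entrances and
the periosteal collar — while the defect core sits in the cartilage
window (3-5), which is why untreated healing seals the marrow cavity but
does not cross the gap.
"""

import numpy as np

import callusim as cs
from callusim.orchestrator import _ElementMaterials

domain, _ = cs.generate_fixture(0.25)
lattice = cs.build_domain(domain)
backend = cs.SurrogateBackend(lattice)
materials = _ElementMaterials(lattice).build(cs.TissueFractions(lattice))
state = backend.solve(materials, cs.LoadCase(kind="gait", gait_force_n=7.0))

print(f"fixator stiffness : {backend.fixator_stiffness:7.1f} N/mm")
print(f"tissue column     : {backend.tissue_column_stiffness(materials):7.2f} N/mm")
print(f"interfragmentary  : {state.interfragmentary_displacement_mm*1000:7.1f} µm")

S = state.S.reshape(lattice.element_shape)
ex, ey, ez = lattice.element_centers_1d()
cx = domain.callus_outer_radius
zmid = domain.total_length / 2
R = np.hypot(ex[:, None, None] - cx, ey[None, :, None] - cx) + 0 * ez
DZ = np.abs(ez - zmid)[None, None, :] + 0 * R
active = (lattice.element_site_count > 0).reshape(lattice.element_shape)

probes = [
    ("gap core (center)", (R < 2.0) & (DZ < 0.7)),
    ("gap entrance", (R < 2.0) & (DZ > 1.8) & (DZ < 2.5)),
    ("periosteal collar (gap span)", (R > 2.0) & (R < 2.75) & (DZ < 2.5)),
    ("collar over segments", (R > 2.0) & (R < 2.75) & (DZ > 2.6)),
    ("marrow", (R < 1.3) & (DZ > 2.6)),
]
print(f"\n{'region':>30} {'S range':>15}  fate of MSCs there")
ranges = cs.DifferentiationRanges()
names = {2: "fibrous", 3: "cartilage", 4: "bone"}
for label, mask in probes:
    sel = mask & active
    if not sel.any():
        continue
    lo, hi = S[sel].min(), S[sel].max()
    fate, _ = ranges.phenotype_for(np.array([np.median(S[sel])]))
    print(f"{label:>30} {lo:7.2f}-{hi:5.2f}  -> {names[int(fate[0])]}")
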
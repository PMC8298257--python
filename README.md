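# callusim

Multiscale mechano-biological simulation of BMP-2-treated critical-sized
bone defect healing.

## The problem

A long-bone defect wider than a critical size (here a 5-mm femoral
osteotomy stabilized by an external fixator) does not heal on its own:
bone seals the marrow cavity at the two ends and then stops, leaving a
non-union. Clinically such defects are treated with recombinant BMP-2
delivered on a collagen sponge, which heals the defect within weeks by
bridging it along the periosteal surface. `callusim` is a research tool
for exploring *why*: it couples the mechanics of the stabilized defect,
the pharmacokinetics of BMP-2 release and transport, and individual-cell
behavior, so that tissue-level outcomes (bone volume, bridging) emerge
from cell-level rules.

## The model

Three coupled submodels advance in fixed order every 2-hour iteration:

1. **BMP-2 field** — on a coarse agent grid (each agent holds up to
   5×5×5 = 125 cells), the concentration *B* [ng/cm³] obeys

   * cellular production/consumption
     `dB = [α/(γ_B·B + γ₀) − V_K·B/(K_M + B)]·(n_MSC + n_OB)·dt`,
   * first-order decay (half-life 0.42 day),
   * Fickian diffusion (D = 8.64×10⁻² cm²/day, zero-flux on the callus),
   * release from the collagen sponge: retention
     `f(t) = 0.68·e^(−0.012 t) + 0.221·e^(−6e−5 t)` (t in minutes) with a
     9.9 % implantation burst, the carrier-bound pool decaying with a
     3.25-day half-life.

2. **Mechanics** — the homogenized callus (rule-of-mixtures over
   granulation/fibrous/cartilage/bone fractions per element) is loaded by
   gait or by the weekly 500-µm axial stimulation episode; each element
   reports the octahedral shear strain γ, the interstitial fluid speed v,
   and the mechanoregulation stimulus

   `S = γ/0.0375 + v/(3 µm/s)`.

   Two backends share the contract: a fast analytic surrogate
   (fixator spring + series-column strain distribution) used inside the
   healing loop, and a u–p poroelastic hexahedral finite-element solver.

3. **Cell agents** — at most one agent per lattice site. MSCs migrate
   (30 µm/h, chemotaxis-weighted by the BMP-2 dose-response), proliferate
   (0.60/day, doubled at 200 ng/cm³ BMP-2), differentiate (0.30/day) into
   the fate selected by S (≤2.53 mature osteoblast, ≤3 immature
   osteoblast, ≤5 chondrocyte, >5 fibroblast), and die. Differentiated
   cells deposit their matrix (bone 3000 µm³/cell/h, trebled at high
   BMP-2; fibrous/cartilage 5000) and resorb mismatched matrix. Under
   limited recruitment, MSC migration and proliferation stop after day
   10 except where free BMP-2 remains above 1 ng/cm³.

Outcomes are reported microCT-style: the per-element bone fraction is
resampled onto 0.04-mm voxels, thresholded at 50 %, counted into the
bone volume BV (cortices excluded), and scanned for a 6-connected bone
path joining the two cortical ends (bridging).

## Worked example

```bash
python examples/healing_scenarios.py
```

runs the untreated control and the sponge-BMP-2 scenario on a coarsened
lattice (seconds each) and prints:

```
=== control (untreated) ===
  day   BV mm^3  bridged
   14     37.19    False
   28     54.32    False
   42     55.19    False

=== BMP-2 on collagen sponge ===
  day   BV mm^3  bridged
   14    135.24     True
   28    151.68     True
   42    151.68     True
```

The untreated defect mineralizes the marrow entrances and the periosteal
collar, then arrests once progenitor recruitment stops (+1.6 % bone
between weeks 4 and 6) and never bridges — a non-union. With
sponge-released BMP-2 the defect bridges by week 2 and plateaus once the
bone-permissive region is filled. `examples/stimulus_field.py`,
`examples/dose_response_curves.py` and
`examples/sponge_release_kinetics.py` print the mechanics, dose-response
and release-kinetics building blocks individually.

The same scenarios are available from the shell:

```bash
callusim run --scenario bmp2 --release sponge --recruitment limited \
    --scale 0.25 --seed 1 --outdir out/
callusim report out/manifest.json
```

`--scale 1` runs the full-resolution 60-µm lattice (hours, not seconds).
Outputs include CSV time series (BV, cell census), a JSON run manifest,
and VTK/voxel exports of the 3-D fields.

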
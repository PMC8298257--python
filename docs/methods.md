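# Methods

This note documents the model implemented in `callusim`: its governing
rules, the parameters that matter, the numerical choices, the design
decisions taken where the design was genuinely open, and what the
simulations do and do not show.

## Geometry and lattices

The femur is idealized as a hollow cylinder: cortex between inner radius
1.3 mm and outer radius 2.0 mm around a marrow cavity, with a 5-mm
transverse osteotomy at midshaft and 10-mm bone segments on either side.
A cylindrical callus growth region surrounds the defect. The callus
dimensions are not published for this preparation; the defaults — outer
radius 2.75 mm (a ~0.75-mm periosteal collar) and 1.5 mm axial overhang
per side — are assumptions chosen to match a rat-femur callus and are
configurable. They matter quantitatively: the collar volume bounds the
bone volume an untreated defect can accumulate, and with a collar much
thicker than the progenitors' 10-day range the untreated trajectory keeps
rising past week 6 instead of saturating.

Four nested discretizations share the geometry:

* **cell sites**, default pitch 60 µm, chosen so one migration hop per
  2-h iteration equals the 30 µm/h migration rate;
* **BMP-2 agents**, 5×5×5 blocks of sites (≤125 cells each);
* **FE elements**, default 0.25 mm in the callus;
* **BV voxels**, 0.04 mm (6.4×10⁻⁵ mm³), aligned to the callus bounding
  box.

Coordinates: axial z, site centers at (i+½)·pitch, regions labeled
cortex / marrow / gap / callus / periosteal band (one site layer over the
cortical surface; the seeding domain together with the marrow). The
sponge occupies the gap. Cells may occupy any non-cortical in-domain
site; differentiation, matrix turnover and the BMP-2 transport domain are
restricted to the healing region (gap + callus + band): tissue does not
form inside the marrow niche, which acts purely as the progenitor
reservoir.

## Mechanics

Element materials are the volume-fraction-weighted arithmetic means of
the tissue cards (granulation E=0.2 MPa, fibrous 2, cartilage 10, bone
5000, plus cortex/marrow and the fixator materials). The
mechanoregulation stimulus is S = γ/0.0375 + v/(3 µm/s) with γ the
octahedral shear strain and v the fluid speed. An unsquared-shear variant of this
expression circulates in the literature; it is dimensionally
inconsistent and can produce negative radicands, so the standard squared
form is used, with an `unsquared_shear` flag reproducing the variant.

**Surrogate backend** (default in the healing loop). The external
fixator is reduced to an axial spring (default 16 N/mm, computed from
the PEEK-bar/titanium-pin cards with an assumed pin geometry: four Ø1-mm
pins, 10-mm free length; configurable, with a rigid limit available) in
parallel with the column stiffness of the tissue bridging the gap
(harmonic along each (x,y) element column, summed over columns). Gait
applies a 7-N axial force (rat gait loads for this preparation are not
fully specified, so this is a calibration knob); the weekly stimulation
episode
prescribes 500 µm at 10 µm/s with the crossbar removed, replacing gait
for the first mechanics evaluation of days 7/14/21/28/35.

Within each gap-span column the interfragmentary displacement distributes
in proportion to local compliance (ε_e = δ/(E_e·C_col)), so new bone
sheds strain onto the remaining soft tissue. This series-column behavior
is essential: it keeps the soft middle of a closing gap at
cartilage-window stimulus, which is what arrests untreated fronts
mid-gap (self-sealing) — a fixed geometric strain profile lets fronts
creep through the defect indefinitely. The profile is attenuated axially
toward the stiff bone ends (shear confinement; sine taper with floor
0.25), radially beyond the cortical surface (exponential, 0.5-mm decay
length), and to 5 % outside the gap span. Local strain is capped at 0.2
as a small-strain guard. Fluid speed is modeled as a fixed fraction
(0.003) of the local strain rate over the load ramp (gait ramp 0.5 s),
scaled by permeability relative to granulation; with granulation this
puts the fresh-defect core at S ≈ 3.2 (cartilage window) and the marrow
entrances and periosteal collar below 2.53 (bone window), reproducing
marrow encapsulation with periosteal-first bridging potential.

**Finite-element backend.** Small-strain u–p poroelasticity on the
structured hex element grid: trilinear displacement and equal-order
pressure, Biot α = 1, storage from the constituent bulk moduli (porosity
0.8), one backward-difference consolidation step over the load ramp,
Darcy fluid speed from the centroid pressure gradient. It satisfies the
same backend contract (per-element strain, v, γ, S) and is verified by
patch (exact to solver precision), linearity, axisymmetry and
series-column load-sharing tests. It is not run inside the default
healing loop for cost reasons; the surrogate is calibrated to the same
qualitative stimulus landscape, not to solver parity.

## BMP-2 field

Per agent and iteration, in order: sponge release, cellular
production/consumption, decay, diffusion.

* Production/consumption uses the published kinetic constants
  (α = 2×10⁻⁹, γ_B = 15, γ₀ = 0.01, V_K = 1.43×10⁻⁷, K_M = 11.01); the
  balance concentration where production equals consumption is the
  positive root of a quadratic, ≈0.10 ng/cm³ — the physiological set
  point. The kinetic γ is stored as `gamma_b` to avoid colliding with
  the shear strain symbol.
* Decay is the multiplicative survival update
  B ← B·exp(−ln2·dt/0.42 d); a recurrence that assigns the decayed total
  to an increment is not dimensionally coherent, so the survival form is
  the one implemented.
* Diffusion is an explicit finite-volume scheme with pairwise fluxes
  (exactly conservative), zero-flux boundaries on the healing region,
  and sub-stepping enforcing D·dt/h² ≤ 1/6. All active agents carry the
  full agent volume h³ in mass bookkeeping.
* The sponge retention schedule (68 %, 22.1 %; 0.012 and 6×10⁻⁵ min⁻¹)
  sums to 90.1 %, read as percent of the dose: the missing 9.9 % is an
  implantation burst injected at the first iteration (a
  normalize-to-100 % option exists). Released mass over a step is
  m₀·(f(t)−f(t+dt)) attenuated by the carrier-degradation survival
  exp(−ln2·t/3.25 d), applied before the schedule; the residual pool is
  m₀·f(t+dt)·survival(t+dt). Released mass spreads uniformly over the
  sponge (gap) agents. The fast-release variant instead initializes the
  whole dose homogeneously over the gap agents at iteration zero.

Dose-response curves pin the published values — chemotaxis maximal at
1 ng/cm³ (3.5-fold MSC, 2.2-fold osteoblast), proliferation 2-fold at
200 ng/cm³, bone production saturating at 3-fold — with functional forms that are
only sketched qualitatively in the literature: log-concentration Gaussian bumps
1 + (peak−1)·exp(−log10(c/c_peak)²/(2σ²)) for the non-monotonic curves
and a Hill form 1 + 2c/(c+K) for bone production. σ (default 1.2
decades) and K (default 10 ng/cm³) are free shape parameters; σ controls
how far from the peak concentration the proliferation boost reaches,
which feeds the speed of the BMP-2-driven colonization front. All curves
equal 1 at zero concentration. Concentrations are interpolated
trilinearly from the agent grid to cell sites so chemotaxis gradients do
not step at agent boundaries.

## Cell model

Rates follow the published activity table (MSC 30 µm/h, 0.60/0.30/0.05
per day; fibroblast 30, 0.55/–/0.05; chondrocyte –, 0.20/–/0.10;
osteoblast –, 0.30/–/0.16). Rate → per-step probability conversion is
the Poisson waiting time p = 1 − exp(−r·dt). One RNG stream per process
(seeding, differentiation, proliferation, migration, apoptosis), all
spawned from the scenario seed; identical configuration and seed give
bit-identical outputs.

* **Migration**: each motile cell attempts one hop to a face neighbor,
  drawn with probability proportional to the chemotaxis index at each
  free in-domain candidate (exact multinomial; occupied and
  out-of-domain candidates are excluded; random-priority resolution when
  two movers pick one target). MSCs follow the MSC chemotaxis curve;
  fibroblasts move unweighted (BMP-2 is taken not to affect
  them); osteoblasts carry a chemotaxis curve (2.2-fold) but no
  migration rate in the activity table — the table wins, so they do not
  move.
* **Proliferation**: the daughter occupies a uniformly chosen free face
  neighbor, else the division is skipped. The BMP-2 fold factor applies
  to MSCs; differentiated cells divide only where S lies in their own
  fate window.
* **Differentiation**: MSCs inside the healing region convert at
  0.30/day to the fate given by the local S (mature osteoblast ≤ 2.53 <
  immature ≤ 3.00 < chondrocyte ≤ 5.00 < fibroblast). Immature
  osteoblasts mature over time at the same rate.
* **Apoptosis**: per-phenotype rates, doubled for a differentiated cell
  sitting outside its fate window (configurable factor).

Three choices here were genuinely open and shape the outcomes:

1. **Mature osteoblasts are post-mitotic.** The published table gives
   one osteoblast proliferation rate; applied to both maturities it
   makes every bone front self-sustaining (net +0.14/day), so the
   untreated defect ossifies its entire callus instead of arresting.
   Assigning the 0.30/day to immature osteoblasts and none to mature
   ones — standard bone biology: matrix-secreting osteoblasts no longer
   divide — makes bone formation track the progenitor supply: dense
   regions mineralize fully within the ~6-day population decay after
   recruitment stops, sparse halos never reach the voxel threshold, and
   the untreated trajectory freezes (measured +1.2–1.6 % between weeks
   4 and 6 on the test fixture; the published trajectory shows +0.3 %).
2. **Fibroblasts are gated like other differentiated phenotypes**
   (favorable only at S > 5). Ungated fibroblasts spawned in
   high-strain seams migrate into low-strain bone and resorb it
   wholesale; gating confines them to the seams, which then fill with
   fibrous tissue and stiffen — fibrous interposition, the classic
   non-union histology.
3. **Sustained BMP-2 rescues recruitment.** Limited recruitment zeroes
   MSC migration/proliferation after day 10 — except at sites where free
   BMP-2 remains at or above 1 ng/cm³ (the chemotactic-activity level;
   configurable, 0 disables). The published mechanism — chemotaxis-driven
   progenitor migration into the periosteal corridor until week 4 —
   requires recruitment to be active past day 10 in the sponge case,
   while the fast-release case must behave like the untreated defect
   once its bolus has decayed (below 1 ng/cm³ within ~9 days). The
   rescue makes both follow from the release kinetics through one
   mechanism rather than per-scenario switches.

## Tissue update and outcomes

Each matrix-producing cell adds rate·dt (bone 3000 µm³/cell/h, fold
factor on osteoblasts only; fibrous and cartilage 5000) of its tissue to
its element, taken from the granulation filler and scaled down
proportionally if the filler cannot cover the demand; mismatched
producing cells resorb foreign tissue back to granulation at the same
table rates. MSCs produce and resorb nothing; acellular elements are
inert. Fractions remain on the simplex by construction.

For reporting, the element bone fraction is resampled trilinearly onto
the 0.04-mm voxel grid over the callus bounding box; a voxel is bone iff
the interpolated fraction exceeds 0.5 (strictly), BV = count·6.4×10⁻⁵
mm³ with cortical and extra-callus voxels excluded. Bridging is declared
when one 6-connected component of bone voxels touches voxels adjacent to
the cortical ends on both sides of the midplane — an operational
definition, since bridging is otherwise only assessed visually.

## Coarsened fixtures

`generate_fixture(scale)` keeps the full-scale geometry — shrinking it
would destroy the defining property of a critical-size defect (gap width
large against the 10-day progenitor range) and the BMP-2 patterning
(decay length √(D/λ) ≈ 2.3 mm against the callus size) — and coarsens
the lattices instead: site pitch 60 µm/scale, element size 0.25/√scale
mm (sub-linear, because element granularity sets how closely the
thresholded bone front tracks the cell front). Each coarse agent stands
for (pitch/60 µm)³ cells; this cohort multiplies matrix production and
the cell counts driving BMP-2 kinetics, keeping volumetric rates
pitch-independent. The migration hop probability scales with the
*squared* coarsening factor: random-walk transport is diffusive and both
the diffusivity and the chemotactic drift go as a²p, so this preserves
the Péclet number (linear scaling quadruples the 10-day migration range
at scale 0.25 and the untreated fixture bridges). Division and death
probabilities are not rescaled; the residual artifact is that
colonization front speeds, in mm/day, grow with the pitch — neutralized
in practice by the post-mitotic mature pool, which removes sustained
fronts altogether.

The test suite runs scenarios at scale 0.25 (240-µm sites, ~10 s per
six-week run); the full 60-µm lattice is available from the CLI and
takes hours. Scenario-level checks use three seeds with medians.

## What the simulations show — and what they do not

The fixture-scale scenario runs reproduce the qualitative published
behaviors: untreated and fast-release defects seal the marrow cavity and
arrest without bridging; sponge-released BMP-2 bridges periosteally by
week 2 and accumulates several-fold more bone by week 6. Quantitative
bone volumes depend on the open calibration knobs (callus dimensions,
gait load, dose-response widths, surrogate profile) and on the lattice
scale; on the default fixture the untreated trajectory runs ~35/55 mm³
at weeks 2/4 against the published 14.75/27.75 mm³ — same order and
shape, not a fit. The model deliberately omits angiogenesis,
bone remodeling and any resorption in mechanically silent regions,
tissue formation inside the marrow, and BMP-2 effects on differentiation
or on chondrocytes/fibroblasts. The synthetic scenarios also idealize
the biology the generator does not attempt to emulate: deterministic
geometry (no animal-to-animal variation), a single growth factor, and
sharp stimulus windows; agreement here shows internal consistency with
the modeled mechanism, not validation against new animal data.
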
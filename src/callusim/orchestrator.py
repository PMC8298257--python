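"""Coupled healing loop: schedules, scenario logic and outcome reporting.

One iteration (default 2 h) advances, in fixed order: sponge release ->
BMP-2 reaction/decay/diffusion -> mechanics solve -> differentiation ->
proliferation -> migration -> apoptosis -> tissue update.  Weekly 500-µm
axial stimulation episodes (crossbar removed) replace the gait load for
the first mechanics evaluation of each stimulation day.  Reports (bone
volume, tissue and BMP-2 snapshots, cell census, bridging) are collected
at the configured timepoints (default weeks 2/4/6).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import bmp2 as bmp2_mod
from .bmp2 import BMPGrid, BMPKinetics, DoseResponseSet, SpongeState
from .cells import (
    MSC,
    OSTEOBLAST,
    DifferentiationRanges,
    RateTable,
    RecruitmentPolicy,
    apoptose,
    differentiate,
    migrate,
    proliferate,
)
from .config import DomainConfig, ScenarioConfig, REFERENCE_CELL_SPACING_UM
from .geometry import CORTEX, MARROW, RegionLattice, build_domain, seed_mscs
from .mechanics import (
    MATERIALS,
    LoadCase,
    MaterialField,
    SurrogateBackend,
    homogenize_materials,
)
from .tissue import (
    BVReport,
    ProductionTable,
    TissueFractions,
    connected_across,
    degrade_tissue,
    produce_tissue,
    voxelize_bv,
)


@dataclass
class SimulationResult:
    """Time series and per-timepoint snapshots of one scenario run."""

    scenario: ScenarioConfig
    domain: DomainConfig
    bv_days: list = field(default_factory=list)
    bv_mm3: list = field(default_factory=list)
    census: list = field(default_factory=list)  # dicts with a "day" key
    bmp_mass_ng: list = field(default_factory=list)  # (day, mass)
    snapshots: dict = field(default_factory=dict)  # day -> snapshot dict
    bridging: dict = field(default_factory=dict)  # day -> bool

    def bv_at(self, day: float) -> float:
        i = int(np.argmin(np.abs(np.asarray(self.bv_days) - day)))
        return self.bv_mm3[i]

    def bv_series(self) -> np.ndarray:
        return np.array([self.bv_days, self.bv_mm3])


def fast_release_init(config: ScenarioConfig, grid: BMPGrid) -> BMPGrid:
    """Release the whole dose homogeneously over the osteotomy-gap agents
    at iteration zero (fast release model, no carrier thereafter)."""
    if config.release != "fast":
        raise ValueError("fast_release_init requires release='fast'")
    bmp2_mod.inject_mass_uniform(grid, grid.sponge_mask, config.bmp_dose_ug)
    return grid


def detect_bridging(report: BVReport, lattice: RegionLattice) -> bool:
    """Whether a 6-connected path of bone voxels joins the proximal and
    distal cortical ends through the callus."""
    from .tissue import _voxel_masks

    masks = _voxel_masks(lattice)
    cortex = masks["cortex"]
    structure = ndimage.generate_binary_structure(3, 1)
    near_cortex = ndimage.binary_dilation(cortex, structure=structure) & ~cortex
    nvz = report.bone_grid.shape[2]
    zmid_vox = (
        lattice.config.total_length / 2.0 - lattice.voxel_origin[2]
    ) / lattice.voxel_size
    z_idx = np.arange(nvz)[None, None, :]
    proximal_seed = near_cortex & (z_idx < zmid_vox)
    distal_seed = near_cortex & (z_idx >= zmid_vox)
    return connected_across(report.bone_grid, proximal_seed, distal_seed)


def generate_fixture(scale: float = 0.25):
    """Reduced-cost configuration preserving the full-scale geometry.

    The domain dimensions are kept (they define the critical-size
    character and the BMP-2 patterning); the cell/agent/element lattices
    are coarsened by 1/scale, with the demographic coarse-graining in
    :mod:`callusim.cells` keeping front speeds and fill rates invariant.
    ``scale=1`` returns the full default configuration.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    # the element grid coarsens sub-linearly: element granularity sets how
    # closely the thresholded bone front tracks the cell front, so it is
    # kept finer than the cell lattice on coarse fixtures
    domain = DomainConfig(
        cell_site_spacing_um=float(REFERENCE_CELL_SPACING_UM / scale),
        fe_element_size_callus=float(0.25 / np.sqrt(scale)),
        fe_element_size_outer=float(0.50 / np.sqrt(scale)),
    )
    scenario = ScenarioConfig()
    return domain, scenario


def _interp_to_sites(agent_field: np.ndarray, site_shape: tuple) -> np.ndarray:
    """Trilinear resampling of an agent-grid field onto the site grid."""
    factors = [t / s for t, s in zip(site_shape, agent_field.shape)]
    out = ndimage.zoom(agent_field, factors, order=1, mode="nearest", grid_mode=True)
    out = out[: site_shape[0], : site_shape[1], : site_shape[2]]
    return np.clip(out, 0.0, None)


class _ElementMaterials:
    """Builds the per-element material field each iteration: healing
    elements homogenized from the tissue fractions, cortex and marrow
    elements fixed to their Table cards."""

    def __init__(self, lattice: RegionLattice, cards: dict | None = None):
        self.cards = cards or MATERIALS
        n = lattice.n_elements
        elem_flat = lattice.element_of_sites().reshape(-1)
        region_flat = lattice.region.reshape(-1)
        half = np.maximum(lattice.element_site_count, 1) / 2.0
        cortex_n = np.bincount(elem_flat[region_flat == CORTEX], minlength=n)
        marrow_n = np.bincount(elem_flat[region_flat == MARROW], minlength=n)
        healing_n = lattice.element_healing_count
        self.cortex_rows = (cortex_n > half) & (healing_n == 0)
        self.marrow_rows = (marrow_n > half) & (healing_n == 0)

    def build(self, fractions: TissueFractions) -> MaterialField:
        mats = homogenize_materials(fractions, self.cards)
        for rows, card_name in (
            (self.cortex_rows, "cortex"),
            (self.marrow_rows, "marrow"),
        ):
            card = self.cards[card_name]
            mats.young_modulus[rows] = card.young_modulus
            mats.poisson_ratio[rows] = card.poisson_ratio
            mats.permeability[rows] = card.permeability
            mats.bulk_modulus_grain[rows] = card.bulk_modulus_grain
            mats.bulk_modulus_fluid[rows] = card.bulk_modulus_fluid
        return mats


def run_scenario(
    config: ScenarioConfig,
    domain: DomainConfig | None = None,
    rates: RateTable | None = None,
    ranges: DifferentiationRanges | None = None,
    production: ProductionTable | None = None,
    kinetics: BMPKinetics | None = None,
    dose_curves: DoseResponseSet | None = None,
    backend=None,
    progress: bool = False,
) -> SimulationResult:
    """Run one treatment scenario end to end (deterministic per seed)."""
    config.validate()
    domain = domain or DomainConfig()
    rates = rates or RateTable()
    ranges = ranges or DifferentiationRanges()
    production = production or ProductionTable()
    kinetics = kinetics or BMPKinetics(dt_hours=config.dt_hours)
    dose_curves = dose_curves or DoseResponseSet()
    policy = RecruitmentPolicy(config.recruitment, config.recruitment_cutoff_day)

    lattice = build_domain(domain)
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_seed, rng_diff, rng_prolif, rng_migr, rng_apop = (
        np.random.default_rng(s) for s in streams
    )
    cells = seed_mscs(lattice, domain.seed_fraction, rng_seed)
    fractions = TissueFractions(lattice)
    bmp = BMPGrid.from_lattice(lattice)
    sponge = None
    if config.uses_bmp:
        if config.release == "sponge":
            sponge = SpongeState(m0_ug=config.bmp_dose_ug)
        else:
            fast_release_init(config, bmp)

    if backend is None:
        backend = SurrogateBackend(lattice)
    materials_builder = _ElementMaterials(lattice)

    agent_flat = lattice.agent_of_sites().reshape(-1)
    elem_flat = lattice.element_of_sites().reshape(-1)
    n_agents = int(np.prod(lattice.agent_shape))
    cohort = domain.cell_cohort_size

    dt_h = config.dt_hours
    iters_per_day = int(round(24.0 / dt_h))
    stim_days = set(int(round(d)) for d in config.stimulation_days)
    output_iters = {
        int(round(d * iters_per_day)): d for d in config.output_days
    }
    bv_stride = max(1, int(round(config.bv_every_days * iters_per_day)))

    result = SimulationResult(scenario=config, domain=domain)

    iterator = range(config.n_iterations)
    if progress:  # pragma: no cover
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc=config.scenario)
        except ImportError:
            pass

    rescue_level = config.bmp_recruitment_rescue_ng_cm3
    for t in iterator:
        day = t * dt_h / 24.0

        # 1. sponge release (burst at implantation, then the schedule)
        if sponge is not None:
            if t == 0:
                bmp2_mod.inject_mass_uniform(
                    bmp, bmp.sponge_mask, sponge.initial_burst_ug()
                )
            bmp2_mod.sponge_release_step(sponge, bmp, kinetics, t * dt_h * 60.0)

        # 2. BMP-2 reaction / decay / diffusion
        phen_flat = cells.phenotype.reshape(-1)
        n_msc = np.bincount(
            agent_flat[phen_flat == MSC], minlength=n_agents
        ).reshape(lattice.agent_shape) * cohort
        n_ob = np.bincount(
            agent_flat[phen_flat == OSTEOBLAST], minlength=n_agents
        ).reshape(lattice.agent_shape) * cohort
        bmp2_mod.reaction_step(bmp, n_msc, n_ob, kinetics)
        bmp2_mod.decay_step(bmp, kinetics)
        bmp2_mod.diffuse_step(bmp, kinetics)

        # 3. mechanics
        mats = materials_builder.build(fractions)
        is_stim = (
            int(np.floor(day + 1e-9)) in stim_days and t % iters_per_day == 0
        )
        if is_stim:
            load = LoadCase(
                kind="stimulation",
                axial_displacement_um=config.stimulation_displacement_um,
                ramp_rate_um_s=config.stimulation_ramp_rate_um_s,
                crossbar_present=False,
            )
        else:
            load = LoadCase(kind="gait", gait_force_n=config.gait_force_n)
        state = backend.solve(mats, load)
        S_site = state.S[elem_flat].reshape(lattice.shape)

        # 4. BMP-2 dose-response fields at the cell sites (trilinear
        #    interpolation of the agent field, so chemotaxis gradients do
        #    not step at agent boundaries)
        conc_site = _interp_to_sites(bmp.concentration, lattice.shape)
        chem_field = dose_curves.factor(conc_site, "msc_chemotaxis")
        prolif_factor = dose_curves.factor(conc_site, "proliferation")
        bone_factor = dose_curves.factor(conc_site, "bone_production")

        # 5. cellular activity.  The limited-recruitment cutoff zeroes MSC
        #    migration/proliferation per site, except where sustained free
        #    BMP-2 (>= rescue level) keeps recruitment active.
        if policy.mode == "limited" and day > policy.cutoff_day:
            if config.uses_bmp and rescue_level > 0:
                msc_scale = (conc_site >= rescue_level).astype(float)
            else:
                msc_scale = 0.0
        else:
            msc_scale = 1.0
        differentiate(cells, S_site, ranges, rates, rng_diff, dt_h)
        proliferate(
            cells, S_site, prolif_factor, rates, rng_prolif, dt_h, ranges,
            msc_rate_scale=msc_scale,
        )
        migrate(cells, chem_field, rates, rng_migr, dt_h, msc_rate_scale=msc_scale)
        apoptose(cells, S_site, rates, rng_apop, dt_h, ranges)

        # 6. tissue update
        produce_tissue(cells, fractions, production, bone_factor, dt_h)
        degrade_tissue(cells, fractions, production, dt_h)

        # 7. bookkeeping
        it = t + 1
        day_end = it * dt_h / 24.0
        if it % bv_stride == 0 or it in output_iters or it == config.n_iterations:
            report = voxelize_bv(fractions, lattice)
            result.bv_days.append(day_end)
            result.bv_mm3.append(report.bv_mm3)
            census = cells.census()
            census["day"] = day_end
            result.census.append(census)
            result.bmp_mass_ng.append((day_end, bmp.total_mass_ng()))
            if it in output_iters:
                day_out = output_iters[it]
                bridged = detect_bridging(report, lattice)
                result.bridging[day_out] = bridged
                result.snapshots[day_out] = {
                    "fractions": fractions.fractions.copy(),
                    "bmp_concentration": bmp.concentration.copy(),
                    "census": dict(census),
                    "bv_mm3": report.bv_mm3,
                    "bridged": bridged,
                    "bone_voxels": report.n_bone_voxels,
                    "sponge_residual_ug": (
                        sponge.residual_mass_ug if sponge is not None else 0.0
                    ),
                }
    missing = [d for d in config.output_days if d not in result.snapshots]
    if missing:  # pragma: no cover - guarded by config validation
        raise RuntimeError(f"missing snapshots for timepoints {missing}")
    return result


def run_manifest(result: SimulationResult) -> dict:
    """JSON-serializable manifest of a run (resolved parameters + seed)."""
    return {
        "scenario": result.scenario.to_dict(),
        "domain": dataclasses.asdict(result.domain),
        "bv_days": list(result.bv_days),
        "bv_mm3": [float(v) for v in result.bv_mm3],
        "bridging": {str(k): bool(v) for k, v in result.bridging.items()},
    }
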
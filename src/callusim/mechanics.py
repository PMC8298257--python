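"""Tissue mechanics: material cards, homogenization, the Prendergast
mechanoregulation stimulus, and the fast surrogate load backend.

The mechanoregulation stimulus is S = gamma/0.0375 + v/3 with gamma the
octahedral shear strain (dimensionless) and v the interstitial fluid speed
in µm/s.  Low S favors bone formation, intermediate S cartilage, high S
fibrous tissue.

Two backends satisfy the same contract (per-element strain, fluid speed,
gamma and S):

* :class:`SurrogateBackend` — an analytic interfragmentary-strain model
  (fixator spring in parallel with the column stiffness of the homogenized
  callus, fixed spatial weight profile).  Fast enough to run inside the
  healing loop; its knobs are calibration parameters, not measurements.
* the finite-element backend in :mod:`callusim.fe` — small-strain u-p
  poroelasticity on the hexahedral element grid, used where field accuracy
  matters more than speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from .units import PERM_TABLE_TO_MM4

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import RegionLattice

#: Prendergast constants: strain normalization (-) and fluid-speed
#: normalization (µm/s)
STRAIN_NORM = 0.0375
FLUID_NORM_UM_S = 3.0


@dataclass(frozen=True)
class MaterialCard:
    """Poroelastic material properties of one tissue or implant material.

    ``permeability`` is kept in the table units of 1e-14 m^4/(N s);
    use :meth:`permeability_mm4` for solver units.
    """

    name: str
    young_modulus: float  # MPa
    poisson_ratio: float
    permeability: float = 0.0  # 1e-14 m^4/(N s)
    bulk_modulus_grain: float = 0.0  # MPa
    bulk_modulus_fluid: float = 0.0  # MPa

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be > 0")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.permeability < 0:
            raise ValueError("permeability must be >= 0")

    def permeability_mm4(self) -> float:
        """Permeability in mm^4/(N s); the table unit 1e-14 m^4/(N s)
        equals 1e-2 mm^4/(N s)."""
        return self.permeability * PERM_TABLE_TO_MM4

    def __repr__(self) -> str:  # compact
        return f"MaterialCard({self.name}, E={self.young_modulus} MPa)"


#: default material table (MPa, -, 1e-14 m^4/(N s), MPa, MPa)
MATERIALS = {
    "granulation": MaterialCard("granulation", 0.2, 0.167, 1.0, 2300.0, 2300.0),
    "cortex": MaterialCard("cortex", 5000.0, 0.3, 0.001, 13920.0, 3200.0),
    "marrow": MaterialCard("marrow", 2.0, 0.167, 1.0, 2300.0, 2300.0),
    "peek": MaterialCard("peek", 3800.0, 0.3),
    "titanium": MaterialCard("titanium", 110000.0, 0.3),
    "fibrous": MaterialCard("fibrous", 2.0, 0.167, 1.0, 2300.0, 2300.0),
    "cartilage": MaterialCard("cartilage", 10.0, 0.3, 0.5, 3700.0, 2300.0),
    "bone": MaterialCard("bone", 5000.0, 0.3, 37.0, 13940.0, 2300.0),
}

#: tissue phases carried by the volume-fraction state, in storage order
TISSUE_ORDER = ("granulation", "fibrous", "cartilage", "bone")

_PROPS = (
    "young_modulus",
    "poisson_ratio",
    "permeability",
    "bulk_modulus_grain",
    "bulk_modulus_fluid",
)


@dataclass
class MaterialField:
    """Per-element scalar material properties (flat arrays)."""

    young_modulus: np.ndarray
    poisson_ratio: np.ndarray
    permeability: np.ndarray
    bulk_modulus_grain: np.ndarray
    bulk_modulus_fluid: np.ndarray

    def card(self, e: int, name: str = "element") -> MaterialCard:
        return MaterialCard(
            name,
            float(self.young_modulus[e]),
            float(self.poisson_ratio[e]),
            float(self.permeability[e]),
            float(self.bulk_modulus_grain[e]),
            float(self.bulk_modulus_fluid[e]),
        )

    @classmethod
    def uniform(cls, card: MaterialCard, n: int) -> "MaterialField":
        return cls(**{p: np.full(n, getattr(card, p)) for p in _PROPS})


def homogenize_materials(
    fractions, cards: dict | None = None, tissue_order=TISSUE_ORDER
) -> MaterialField:
    """Volume-fraction-weighted arithmetic mean of every scalar property.

    ``fractions`` is a ``TissueFractions`` state or an (n_elements, n_tissue)
    array whose columns follow ``tissue_order``; rows must sum to 1.
    """
    cards = cards or MATERIALS
    arr = getattr(fractions, "fractions", fractions)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(tissue_order):
        raise ValueError("fractions must be (n_elements, n_tissues)")
    unknown = [t for t in tissue_order if t not in cards]
    if unknown:
        raise KeyError(f"unknown tissue label(s): {unknown}")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("tissue fractions must sum to 1 per element")
    out = {}
    for prop in _PROPS:
        table = np.array([getattr(cards[t], prop) for t in tissue_order])
        out[prop] = arr @ table
    return MaterialField(**out)


# ---------------------------------------------------------------------------
# scalar mechanics


def octahedral_shear(e, unsquared_shear: bool = False):
    """Octahedral shear strain of a symmetric small-strain tensor.

    ``e`` has components (e11, e22, e33, e12, e23, e13) on the last axis
    (tensor shear, not engineering).  The standard rotation-invariant form
    squares the shear terms; ``unsquared_shear`` reproduces the
    dimensionally inconsistent unsquared variant sometimes seen in the
    literature (clamping negative radicands to zero), off by default.
    """
    e = np.asarray(e, dtype=float)
    if e.shape[-1] != 6:
        raise ValueError("expected 6 strain components on the last axis")
    d1 = e[..., 0] - e[..., 1]
    d2 = e[..., 1] - e[..., 2]
    d3 = e[..., 0] - e[..., 2]
    if unsquared_shear:
        radicand = d1**2 + d2**2 + d3**2 + 6.0 * (e[..., 3] + e[..., 4] + e[..., 5])
        radicand = np.clip(radicand, 0.0, None)
    else:
        radicand = d1**2 + d2**2 + d3**2 + 6.0 * (
            e[..., 3] ** 2 + e[..., 4] ** 2 + e[..., 5] ** 2
        )
    return (2.0 / 3.0) * np.sqrt(radicand)


def stimulus(gamma, fluid_speed_um_s):
    """Mechanoregulation stimulus S = gamma/0.0375 + v/(3 µm/s)."""
    gamma = np.asarray(gamma, dtype=float)
    v = np.asarray(fluid_speed_um_s, dtype=float)
    if np.any(gamma < 0) or np.any(v < 0):
        raise ValueError("gamma and fluid speed must be non-negative")
    return gamma / STRAIN_NORM + v / FLUID_NORM_UM_S


# ---------------------------------------------------------------------------
# load cases and state


@dataclass(frozen=True)
class LoadCase:
    """Either habitual gait (axial force) or the weekly 500-µm stimulation
    episode (prescribed axial compression, fixator crossbar removed)."""

    kind: str = "gait"  # gait | stimulation
    axial_displacement_um: float = 500.0
    ramp_rate_um_s: float = 10.0
    gait_force_n: float = 7.0
    gait_ramp_s: float = 0.5
    crossbar_present: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("gait", "stimulation"):
            raise ValueError(f"unknown load kind {self.kind!r}")
        if self.kind == "stimulation" and self.crossbar_present:
            raise ValueError("stimulation requires the crossbar to be removed")

    @property
    def ramp_seconds(self) -> float:
        if self.kind == "stimulation":
            return self.axial_displacement_um / self.ramp_rate_um_s
        return self.gait_ramp_s


@dataclass
class MechanicalState:
    """Per-element mechanics output (flat arrays over the element grid)."""

    strain: np.ndarray  # (n, 6): e11,e22,e33,e12,e23,e13
    fluid_speed: np.ndarray  # µm/s
    gamma: np.ndarray
    S: np.ndarray
    interfragmentary_displacement_mm: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.gamma < -1e-15) or np.any(self.fluid_speed < -1e-15):
            raise ValueError("gamma and fluid speed must be non-negative")


# ---------------------------------------------------------------------------
# fixator


def fixator_axial_stiffness(
    peek: MaterialCard = MATERIALS["peek"],
    titanium: MaterialCard = MATERIALS["titanium"],
    pin_diameter_mm: float = 1.0,
    pin_free_length_mm: float = 10.0,
    n_pins: int = 4,
    bar_section_mm2: float = 16.0,
    bar_length_mm: float = 20.0,
) -> float:
    """Axial stiffness (N/mm) of the external fixator reduced to a spring.

    Two clusters of titanium mounting pins load the PEEK crossbar; each pin
    bends as a cantilever (3EI/L^3), the bar carries axial load.  The
    default pin geometry is an assumption (documented), giving a compliant
    rat-scale fixator of ~16 N/mm; a rigid limit is obtained by configuring
    a very large stiffness instead.
    """
    inertia = np.pi * pin_diameter_mm**4 / 64.0
    k_pin = 3.0 * titanium.young_modulus * inertia / pin_free_length_mm**3
    k_cluster = (n_pins / 2.0) * k_pin
    k_bar = peek.young_modulus * bar_section_mm2 / bar_length_mm
    return 1.0 / (2.0 / k_cluster + 1.0 / k_bar)


# ---------------------------------------------------------------------------
# surrogate backend


class SurrogateBackend:
    """Analytic interfragmentary-strain mechanics surrogate.

    The fixator spring acts in parallel with the column stiffness of the
    homogenized tissue bridging the gap.  Within the gap span each (x, y)
    column behaves as springs in series: the interfragmentary displacement
    concentrates in the locally compliant material (element strain
    proportional to 1/E over the column compliance), so stiffening bone
    advancing from the gap ends keeps the remaining soft middle at high
    stimulus — the self-sealing behavior a full FE solve exhibits.  A
    fixed spatial attenuation (axial taper toward the stiff bone ends,
    exponential radial decay beyond the cortical surface, a small floor
    outside the gap span) modulates the profile.  Fluid speed is a fixed
    fraction of the local strain rate, scaled by the permeability relative
    to granulation tissue.
    """

    def __init__(
        self,
        lattice: "RegionLattice",
        fixator_stiffness_n_mm: Optional[float] = None,
        fluid_coeff: float = 0.003,
        radial_decay_mm: float = 0.5,
        axial_floor: float = 0.25,
        outside_gap_factor: float = 0.05,
        permeability_ref: float = 1.0,
        max_local_strain: float = 0.2,
    ) -> None:
        self.lattice = lattice
        cfg = lattice.config
        self.fixator_stiffness = (
            fixator_axial_stiffness()
            if fixator_stiffness_n_mm is None
            else fixator_stiffness_n_mm
        )
        self.fluid_coeff = fluid_coeff
        self.permeability_ref = permeability_ref
        self.max_local_strain = max_local_strain

        es = lattice.element_size
        cx = cy = cfg.callus_outer_radius
        zmid = cfg.total_length / 2.0
        ex, ey, ez = lattice.element_centers_1d()
        X = ex[:, None, None]
        Y = ey[None, :, None]
        Z = ez[None, None, :]
        r = np.hypot(X - cx, Y - cy)
        half_gap = cfg.gap_width / 2.0
        in_gap_z = np.abs(Z - zmid) <= half_gap + 1e-9

        w_ax = np.where(
            in_gap_z,
            axial_floor
            + (1.0 - axial_floor)
            * np.sin(np.pi * np.clip((Z - (zmid - half_gap)) / cfg.gap_width, 0, 1)),
            outside_gap_factor,
        )
        w_rad = np.where(
            r <= cfg.cortex_outer_radius,
            1.0,
            np.exp(-(r - cfg.cortex_outer_radius) / radial_decay_mm),
        )
        self.weight = (w_ax * w_rad).reshape(-1)
        self.active = (lattice.element_site_count > 0)
        self.weight[~self.active] = 0.0

        # columns of gap-span healing elements carry the tissue stiffness
        healing = lattice.element_healing.reshape(lattice.element_shape)
        gap_z = np.abs(ez - zmid) <= half_gap - 1e-9
        self._gap_z_idx = np.flatnonzero(gap_z)
        col_ok = healing[:, :, self._gap_z_idx].all(axis=2)
        self._col_mask = col_ok
        self._col_area = es * es
        self._dz = es

    def tissue_column_stiffness(self, materials: MaterialField) -> float:
        """Series-parallel (harmonic within a column, sum over columns)
        stiffness of the tissue bridging the gap, N/mm."""
        shape = self.lattice.element_shape
        E = materials.young_modulus.reshape(shape)[:, :, self._gap_z_idx]
        with np.errstate(divide="ignore"):
            compliance = (self._dz / E).sum(axis=2)
        k_col = self._col_area / compliance
        return float(k_col[self._col_mask].sum())

    def solve(self, materials: MaterialField, load_case: LoadCase) -> MechanicalState:
        cfg = self.lattice.config
        shape = self.lattice.element_shape
        k_tissue = self.tissue_column_stiffness(materials)
        if load_case.kind == "stimulation":
            delta = load_case.axial_displacement_um / 1000.0  # mm
        else:
            k_fix = self.fixator_stiffness if load_case.crossbar_present else 0.0
            delta = load_case.gait_force_n / (k_tissue + k_fix)
        ramp = load_case.ramp_seconds
        eps_mean = delta / cfg.gap_width

        # series-column strain: each gap-span column shares the
        # interfragmentary displacement in proportion to local compliance
        E = materials.young_modulus.reshape(shape)
        Egap = E[:, :, self._gap_z_idx]
        compliance = (self._dz / Egap).sum(axis=2)  # per column
        eps = np.full(shape, eps_mean)
        col = np.zeros(shape[:2] + (self._gap_z_idx.size,))
        col[self._col_mask] = (
            delta / Egap[self._col_mask] / compliance[self._col_mask, None]
        )
        eps[:, :, self._gap_z_idx] = np.where(
            self._col_mask[:, :, None], col, eps_mean
        )
        np.clip(eps, 0.0, self.max_local_strain, out=eps)
        eps_flat = eps.reshape(-1) * self.weight

        nu = materials.poisson_ratio
        e33 = -eps_flat
        n = self.weight.size
        strain = np.zeros((n, 6))
        strain[:, 0] = strain[:, 1] = -nu * e33
        strain[:, 2] = e33
        gamma = octahedral_shear(strain)
        perm_factor = np.clip(
            materials.permeability / self.permeability_ref, 0.0, 1.0
        )
        v = (
            self.fluid_coeff
            * (eps_flat * cfg.gap_width * 1000.0 / ramp)
            * perm_factor
        )
        S = stimulus(gamma, v)
        return MechanicalState(
            strain=strain,
            fluid_speed=v,
            gamma=gamma,
            S=S,
            interfragmentary_displacement_mm=float(delta),
        )


def solve_step(backend, materials: MaterialField, load_case: LoadCase):
    """Run one quasi-static mechanics evaluation on any backend object
    exposing ``solve(materials, load_case) -> MechanicalState``."""
    return backend.solve(materials, load_case)
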
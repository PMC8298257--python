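"""Idealized defect geometry and the nested lattices.

The femur is modeled as a hollow cylinder (cortex around a medullary
cavity) with a transverse mid-shaft osteotomy gap, surrounded by a
cylindrical callus growth region that overhangs the gap axially.  Four
nested discretizations share this geometry:

* cell sites       — the agent lattice (default pitch 60 µm),
* BMP-2 agents     — 5x5x5 blocks of cell sites (<= 125 cells each),
* FE elements      — hexahedral element grid for the mechanics stage,
* BV voxels        — 0.04-mm voxels for the microCT-style bone volume.

Coordinates: axial z, 0-based integer site indices, site centers at
(i + 1/2) * spacing, the bone axis through the lateral center of the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, DomainConfig

# region codes
OUTSIDE = 0
CORTEX = 1
MARROW = 2
GAP = 3
CALLUS = 4
PERIOSTEAL = 5

REGION_NAMES = {
    OUTSIDE: "outside",
    CORTEX: "cortex",
    MARROW: "marrow",
    GAP: "gap",
    CALLUS: "callus_growth",
    PERIOSTEAL: "periosteal_band",
}

#: cell sites per BMP-2 agent along each axis
AGENT_NESTING = 5


def classify_points(config: DomainConfig, x, y, z, band_thickness: float = 0.0):
    """Region label for arbitrary points (mm), vectorized.

    ``band_thickness`` > 0 marks the innermost radial shell of the
    periosteal callus (adjacent to the cortical surface along the bone
    segments) as PERIOSTEAL instead of CALLUS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    cx = cy = config.callus_outer_radius
    zmid = config.total_length / 2.0
    r = np.hypot(x - cx, y - cy)
    dz = np.abs(z - zmid)

    in_gap_span = dz <= config.gap_width / 2.0 + 1e-12
    in_callus_span = dz <= config.gap_width / 2.0 + config.callus_axial_overhang + 1e-12
    in_axis_range = (z >= -1e-12) & (z <= config.total_length + 1e-12)

    region = np.full(np.broadcast(x, y, z).shape, OUTSIDE, dtype=np.int8)

    # osteotomy gap: the cortex is removed over the full former bone section
    region[in_gap_span & (r <= config.cortex_outer_radius)] = GAP
    region[
        in_gap_span
        & (r > config.cortex_outer_radius)
        & (r <= config.callus_outer_radius)
    ] = CALLUS

    seg = ~in_gap_span & in_axis_range
    region[seg & (r <= config.cortex_inner_radius)] = MARROW
    region[
        seg & (r > config.cortex_inner_radius) & (r <= config.cortex_outer_radius)
    ] = CORTEX
    callus_seg = (
        seg
        & in_callus_span
        & (r > config.cortex_outer_radius)
        & (r <= config.callus_outer_radius)
    )
    region[callus_seg] = CALLUS
    if band_thickness > 0.0:
        region[callus_seg & (r <= config.cortex_outer_radius + band_thickness)] = (
            PERIOSTEAL
        )
    return region


@dataclass
class RegionLattice:
    """Labeled 3D site grid plus the index maps among the nested grids."""

    config: DomainConfig
    region: np.ndarray  # (nx, ny, nz) int8

    def __post_init__(self) -> None:
        cfg = self.config
        self.spacing = cfg.cell_site_spacing_mm
        self.shape = self.region.shape
        nx, ny, nz = self.shape

        self.in_domain = self.region != OUTSIDE
        self.cell_allowed = self.in_domain & (self.region != CORTEX)
        self.healing = np.isin(self.region, (GAP, CALLUS, PERIOSTEAL))
        self.sponge_sites = self.region == GAP

        # --- BMP-2 agent nesting (5x5x5 site blocks) ---
        self.agent_shape = tuple(-(-n // AGENT_NESTING) for n in self.shape)
        self._agent_strides = (
            self.agent_shape[1] * self.agent_shape[2],
            self.agent_shape[2],
            1,
        )

        # --- FE element grid ---
        es = cfg.fe_element_size_callus
        self.element_size = es
        extent = (nx * self.spacing, ny * self.spacing, nz * self.spacing)
        self.element_shape = tuple(max(1, int(np.ceil(e / es - 1e-9))) for e in extent)
        centers = [
            (np.arange(n) + 0.5) * self.spacing for n in self.shape
        ]
        self._elem_axis_index = [
            np.clip((c / es).astype(np.int64), 0, self.element_shape[a] - 1)
            for a, c in enumerate(centers)
        ]
        self._elem_strides = (
            self.element_shape[1] * self.element_shape[2],
            self.element_shape[2],
            1,
        )

        # --- BV voxel grid over the callus bounding box ---
        zmid = cfg.total_length / 2.0
        half_span = cfg.gap_width / 2.0 + cfg.callus_axial_overhang
        self.callus_elem_z0 = int(np.floor((zmid - half_span) / es + 1e-9))
        self.callus_elem_z1 = min(
            self.element_shape[2], int(np.ceil((zmid + half_span) / es - 1e-9))
        )
        vs = cfg.bv_voxel_size
        self.voxel_size = vs
        self.voxel_origin = (0.0, 0.0, self.callus_elem_z0 * es)
        vox_extent = (
            self.element_shape[0] * es,
            self.element_shape[1] * es,
            (self.callus_elem_z1 - self.callus_elem_z0) * es,
        )
        self.voxel_shape = tuple(int(round(e / vs)) for e in vox_extent)

        # per-element bookkeeping
        flat_elem = self.element_of_sites()
        self.n_elements = int(np.prod(self.element_shape))
        self.element_site_count = np.bincount(
            flat_elem[self.in_domain], minlength=self.n_elements
        )
        self.element_healing_count = np.bincount(
            flat_elem[self.healing], minlength=self.n_elements
        )
        self.element_healing = (self.element_healing_count > 0).reshape(
            self.element_shape
        )
        # agents active for BMP-2 transport: those containing healing sites
        flat_agent = self.agent_of_sites()
        n_agents = int(np.prod(self.agent_shape))
        self.agent_site_count = np.bincount(
            flat_agent[self.in_domain], minlength=n_agents
        )
        self.agent_active = (
            np.bincount(flat_agent[self.healing], minlength=n_agents) > 0
        ).reshape(self.agent_shape)
        self.agent_sponge = (
            np.bincount(flat_agent[self.sponge_sites], minlength=n_agents) > 0
        ).reshape(self.agent_shape)

    # -- coordinates -------------------------------------------------------
    def site_centers_1d(self):
        return [(np.arange(n) + 0.5) * self.spacing for n in self.shape]

    def element_centers_1d(self):
        return [(np.arange(n) + 0.5) * self.element_size for n in self.element_shape]

    # -- index maps --------------------------------------------------------
    def agent_of_sites(self) -> np.ndarray:
        """Flat BMP-agent id for every site, shape (nx, ny, nz)."""
        nx, ny, nz = self.shape
        ia = np.arange(nx) // AGENT_NESTING
        ja = np.arange(ny) // AGENT_NESTING
        ka = np.arange(nz) // AGENT_NESTING
        sx, sy, sz = self._agent_strides
        return (
            ia[:, None, None] * sx + ja[None, :, None] * sy + ka[None, None, :] * sz
        )

    def element_of_sites(self) -> np.ndarray:
        """Flat FE-element id for every site, shape (nx, ny, nz)."""
        ex, ey, ez = self._elem_axis_index
        sx, sy, sz = self._elem_strides
        return (
            ex[:, None, None] * sx + ey[None, :, None] * sy + ez[None, None, :] * sz
        )

    def map_indices(self, site: tuple) -> tuple:
        """(bmp_agent_id, fe_element_id, bv_voxel_id) for one site.

        The voxel id is -1 for sites outside the callus bounding box.
        """
        i, j, k = site
        nx, ny, nz = self.shape
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz) or not self.in_domain[
            i, j, k
        ]:
            raise IndexError(f"site {site!r} is outside the domain")
        sx, sy, sz = self._agent_strides
        agent = (i // AGENT_NESTING) * sx + (j // AGENT_NESTING) * sy + (
            k // AGENT_NESTING
        ) * sz
        ex, ey, ez = self._elem_axis_index
        fx, fy, fz = self._elem_strides
        element = ex[i] * fx + ey[j] * fy + ez[k] * fz
        center = ((i + 0.5) * self.spacing, (j + 0.5) * self.spacing,
                  (k + 0.5) * self.spacing)
        voxel = self.voxel_of_point(center)
        return agent, element, voxel

    def voxel_of_point(self, point: tuple) -> int:
        vx = int((point[0] - self.voxel_origin[0]) / self.voxel_size)
        vy = int((point[1] - self.voxel_origin[1]) / self.voxel_size)
        vz = int((point[2] - self.voxel_origin[2]) / self.voxel_size)
        shape = self.voxel_shape
        if not (0 <= vx < shape[0] and 0 <= vy < shape[1] and 0 <= vz < shape[2]):
            return -1
        return (vx * shape[1] + vy) * shape[2] + vz

    def sites_of_agent(self, agent_id: int) -> np.ndarray:
        """(n, 3) site indices contained in one BMP agent (inverse map)."""
        flat = self.agent_of_sites() == agent_id
        return np.argwhere(flat & self.in_domain)

    def sites_of_element(self, element_id: int) -> np.ndarray:
        flat = self.element_of_sites() == element_id
        return np.argwhere(flat & self.in_domain)

    # -- site census -------------------------------------------------------
    def region_counts(self) -> dict:
        values, counts = np.unique(self.region, return_counts=True)
        return {REGION_NAMES[int(v)]: int(c) for v, c in zip(values, counts)}

    @property
    def seedable(self) -> np.ndarray:
        """Sites available for initial MSC seeding (marrow + periosteum)."""
        return (self.region == MARROW) | (self.region == PERIOSTEAL)


def build_domain(config: DomainConfig) -> RegionLattice:
    """Build the labeled site lattice for a domain configuration."""
    config.validate()
    spacing = config.cell_site_spacing_mm
    nx = ny = max(1, int(np.ceil(2.0 * config.callus_outer_radius / spacing - 1e-9)))
    nz = max(1, int(np.ceil(config.total_length / spacing - 1e-9)))
    centers = [(np.arange(n) + 0.5) * spacing for n in (nx, ny, nz)]
    X = centers[0][:, None, None]
    Y = centers[1][None, :, None]
    Z = centers[2][None, None, :]
    region = classify_points(config, X, Y, Z, band_thickness=spacing)
    lattice = RegionLattice(config=config, region=region)
    if not lattice.in_domain.any():
        raise ConfigurationError("domain discretization produced no sites")
    return lattice


def seed_mscs(lattice: RegionLattice, fraction: float, rng: np.random.Generator):
    """Seed MSCs uniformly at random over marrow + periosteal sites.

    Exactly ``round(fraction * N_available)`` agents are placed without
    replacement; the gap (and hence the sponge) starts cell-free.
    """
    from .cells import MSC, CellLattice

    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("seed fraction must lie in [0, 1]")
    cells = CellLattice.empty(lattice)
    available = np.flatnonzero(lattice.seedable)
    n = int(round(fraction * available.size))
    if n > 0:
        chosen = rng.choice(available, size=n, replace=False)
        cells.phenotype.reshape(-1)[chosen] = MSC
    return cells
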
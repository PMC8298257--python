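"""Tissue volume fractions, matrix turnover and microCT-style bone volume.

Every FE element of the healing region carries volume fractions of four
phases — granulation (the filler), fibrous tissue, cartilage and bone.
Cells deposit the matrix of their phenotype at fixed volumetric rates
(µm^3 per cell per hour), taking volume from the granulation filler;
cells of a mismatched phenotype resorb foreign matrix back to granulation.
For outcome reporting the bone fraction is interpolated onto 0.04-mm
voxels and thresholded at 50%, mirroring a microCT segmentation; the bone
cortices are excluded from the bone-volume (BV) quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cells import CHONDROCYTE, FIBROBLAST, OSTEOBLAST, CellLattice
from .geometry import CALLUS, GAP, PERIOSTEAL, CORTEX, RegionLattice, classify_points
from .mechanics import TISSUE_ORDER

# columns of the fraction array
GRANULATION_IDX = 0
FIBROUS_IDX = 1
CARTILAGE_IDX = 2
BONE_IDX = 3

#: tissue column produced by each phenotype (MSCs produce nothing)
PRODUCT_OF_PHENOTYPE = {
    FIBROBLAST: FIBROUS_IDX,
    CHONDROCYTE: CARTILAGE_IDX,
    OSTEOBLAST: BONE_IDX,
}


@dataclass(frozen=True)
class ProductionTable:
    """Matrix production and degradation rates, µm^3 per cell per hour."""

    fibrous_production: float = 5000.0
    fibrous_degradation: float = 5000.0
    cartilage_production: float = 5000.0
    cartilage_degradation: float = 5000.0
    bone_production: float = 3000.0
    bone_degradation: float = 3000.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")

    def production(self) -> np.ndarray:
        """Rates indexed by tissue column (granulation entry unused)."""
        out = np.zeros(4)
        out[FIBROUS_IDX] = self.fibrous_production
        out[CARTILAGE_IDX] = self.cartilage_production
        out[BONE_IDX] = self.bone_production
        return out

    def degradation(self) -> np.ndarray:
        out = np.zeros(4)
        out[FIBROUS_IDX] = self.fibrous_degradation
        out[CARTILAGE_IDX] = self.cartilage_degradation
        out[BONE_IDX] = self.bone_degradation
        return out


class TissueFractions:
    """Per-element volume fractions (n_elements, 4) in TISSUE_ORDER."""

    def __init__(self, lattice: RegionLattice, fractions: np.ndarray | None = None):
        self.lattice = lattice
        n = lattice.n_elements
        if fractions is None:
            fractions = np.zeros((n, 4))
            fractions[:, GRANULATION_IDX] = 1.0
        self.fractions = np.asarray(fractions, dtype=float)
        if self.fractions.shape != (n, 4):
            raise ValueError("fractions must be (n_elements, 4)")

    @property
    def element_volume_um3(self) -> float:
        return (self.lattice.element_size * 1000.0) ** 3

    def copy(self) -> "TissueFractions":
        return TissueFractions(self.lattice, self.fractions.copy())

    def bone_fraction_grid(self) -> np.ndarray:
        return self.fractions[:, BONE_IDX].reshape(self.lattice.element_shape)

    def check_invariants(self, atol: float = 1e-9) -> None:
        f = self.fractions
        if np.any(f < -atol) or np.any(f > 1 + atol):
            raise AssertionError("tissue fraction outside [0, 1]")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-6):
            raise AssertionError("tissue fractions do not sum to 1")


def _producing_cells(cells: CellLattice):
    """Flat site indices and product column of matrix-producing cells
    inside the healing region."""
    lattice = cells.lattice
    phen = cells.phenotype.reshape(-1)
    healing = lattice.healing.reshape(-1)
    idx = np.flatnonzero(healing & np.isin(phen, list(PRODUCT_OF_PHENOTYPE)))
    product = np.zeros(idx.size, dtype=np.int64)
    for code, col in PRODUCT_OF_PHENOTYPE.items():
        product[phen[idx] == code] = col
    return idx, product


def produce_tissue(
    cells: CellLattice,
    fractions: TissueFractions,
    table: ProductionTable,
    bone_factor,
    dt_hours: float = 2.0,
) -> TissueFractions:
    """Deposit matrix produced by the resident cells over one step.

    Each producing cell adds (rate x dt x BMP fold, the fold applying to
    osteoblast bone production only) of its tissue to its element, taken
    from the granulation filler; when the filler cannot cover the demand,
    deposition is scaled down proportionally (simplex preserved).
    """
    lattice = cells.lattice
    factor = np.broadcast_to(
        np.asarray(bone_factor, dtype=float), cells.phenotype.shape
    ).reshape(-1)
    if np.any(factor < 1.0 - 1e-12):
        raise ValueError("bone production factors must be >= 1")

    idx, product = _producing_cells(cells)
    if idx.size == 0:
        return fractions
    elem = lattice.element_of_sites().reshape(-1)[idx]
    rates = table.production()[product]
    vol = rates * dt_hours * lattice.config.cell_cohort_size
    vol = np.where(product == BONE_IDX, vol * factor[idx], vol)

    n = lattice.n_elements
    f = fractions.fractions
    requested = np.zeros((n, 4))
    for col in (FIBROUS_IDX, CARTILAGE_IDX, BONE_IDX):
        sel = product == col
        if np.any(sel):
            requested[:, col] = np.bincount(
                elem[sel], weights=vol[sel], minlength=n
            )
    requested /= fractions.element_volume_um3
    total = requested.sum(axis=1)
    avail = f[:, GRANULATION_IDX]
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(total > 0, np.minimum(1.0, avail / np.maximum(total, 1e-300)), 0.0)
    added = requested * scale[:, None]
    f[:, 1:] += added[:, 1:]
    f[:, GRANULATION_IDX] -= added.sum(axis=1)
    np.clip(f, 0.0, 1.0, out=f)
    return fractions


def degrade_tissue(
    cells: CellLattice,
    fractions: TissueFractions,
    table: ProductionTable,
    dt_hours: float = 2.0,
) -> TissueFractions:
    """Resorb matrix mismatched with the resident producing cells.

    A producing cell removes every foreign tissue type present in its
    element at that tissue's degradation rate; removed volume returns to
    the granulation filler.  Acellular elements (and MSC-only elements)
    are inert.
    """
    lattice = cells.lattice
    idx, product = _producing_cells(cells)
    if idx.size == 0:
        return fractions
    elem = lattice.element_of_sites().reshape(-1)[idx]
    n = lattice.n_elements
    cohort = lattice.config.cell_cohort_size

    counts = np.zeros((n, 4))
    for col in (FIBROUS_IDX, CARTILAGE_IDX, BONE_IDX):
        sel = product == col
        if np.any(sel):
            counts[:, col] = np.bincount(elem[sel], minlength=n)
    producers_total = counts.sum(axis=1)

    f = fractions.fractions
    deg = table.degradation()
    for col in (FIBROUS_IDX, CARTILAGE_IDX, BONE_IDX):
        mismatched = producers_total - counts[:, col]
        removal = (
            deg[col] * mismatched * cohort * dt_hours / fractions.element_volume_um3
        )
        removed = np.minimum(removal, f[:, col])
        f[:, col] -= removed
        f[:, GRANULATION_IDX] += removed
    np.clip(f, 0.0, 1.0, out=f)
    return fractions


# ---------------------------------------------------------------------------
# bone-volume voxelization


@dataclass
class BVReport:
    """Boolean bone grid on the BV voxel lattice and the volume it holds."""

    bone_grid: np.ndarray  # bool, voxel lattice over the callus bbox
    voxel_size_mm: float
    voxel_origin_mm: tuple

    @property
    def n_bone_voxels(self) -> int:
        return int(np.count_nonzero(self.bone_grid))

    @property
    def bv_mm3(self) -> float:
        return self.n_bone_voxels * self.voxel_size_mm**3


def _voxel_masks(lattice: RegionLattice):
    """Cached voxel-center region masks over the callus bounding box."""
    cached = getattr(lattice, "_voxel_masks", None)
    if cached is not None:
        return cached
    vs = lattice.voxel_size
    ox, oy, oz = lattice.voxel_origin
    nvx, nvy, nvz = lattice.voxel_shape
    x = ox + (np.arange(nvx) + 0.5) * vs
    y = oy + (np.arange(nvy) + 0.5) * vs
    z = oz + (np.arange(nvz) + 0.5) * vs
    region = classify_points(
        lattice.config, x[:, None, None], y[None, :, None], z[None, None, :]
    )
    masks = {
        "healing": np.isin(region, (GAP, CALLUS, PERIOSTEAL)),
        "cortex": region == CORTEX,
    }
    lattice._voxel_masks = masks
    return masks


def voxelize_bv(fractions: TissueFractions, lattice: RegionLattice) -> BVReport:
    """Threshold the interpolated bone fraction into the Boolean BV grid.

    The per-element bone fraction is resampled (trilinear) onto the 0.04-mm
    voxel grid covering the callus bounding box; a voxel is "bone" iff the
    interpolated fraction exceeds 0.5.  Cortical and extra-callus voxels
    are excluded from the count.
    """
    bone_elem = fractions.bone_fraction_grid()[
        :, :, lattice.callus_elem_z0 : lattice.callus_elem_z1
    ]
    target = lattice.voxel_shape
    factors = [t / s for t, s in zip(target, bone_elem.shape)]
    interp = ndimage.zoom(
        bone_elem.astype(np.float32),
        factors,
        order=1,
        mode="nearest",
        grid_mode=True,
    )
    # guard against off-by-one rounding in the zoom output shape
    interp = interp[: target[0], : target[1], : target[2]]
    masks = _voxel_masks(lattice)
    bone = (interp > 0.5) & masks["healing"]
    return BVReport(
        bone_grid=bone,
        voxel_size_mm=lattice.voxel_size,
        voxel_origin_mm=lattice.voxel_origin,
    )


def connected_across(
    bone: np.ndarray, proximal_seed: np.ndarray, distal_seed: np.ndarray
) -> bool:
    """True iff one 6-connected component of ``bone`` intersects both seeds."""
    if not bone.any():
        return False
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(bone, structure=structure)
    if n == 0:
        return False
    prox = np.unique(labels[proximal_seed & bone])
    dist = np.unique(labels[distal_seed & bone])
    prox = prox[prox > 0]
    dist = dist[dist > 0]
    return bool(np.intersect1d(prox, dist).size > 0)
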
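"""Stochastic per-iteration cell dynamics on the site lattice.

Four phenotypes live on the lattice (at most one agent per site): MSCs,
fibroblasts, chondrocytes and osteoblasts.  Each iteration every cell may
hop to a face neighbor (chemotaxis-weighted), divide into a free neighbor,
differentiate (MSCs only, fate set by the mechanical stimulus S) and die.
Rates (per day, migration in µm/h) are converted to per-step
probabilities through the Poisson waiting-time rule p = 1 - exp(-r dt).

On coarsened lattices each agent stands for a cohort of cells; only the
migration hop probability carries the lattice coarse-graining factor
(preserving the physical migration speed).  Division is crowding-limited:
the daughter targets one uniformly drawn face neighbor and the division
fails if that site is taken — at a confluent front the published
osteoblast rates then balance apoptosis almost exactly, which is what
arrests bone fronts once progenitor recruitment stops.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import RegionLattice

# phenotype codes (0 = empty site)
EMPTY = 0
MSC = 1
FIBROBLAST = 2
CHONDROCYTE = 3
OSTEOBLAST = 4

PHENOTYPE_NAMES = {
    MSC: "MSC",
    FIBROBLAST: "fibroblast",
    CHONDROCYTE: "chondrocyte",
    OSTEOBLAST: "osteoblast",
}

_FACE_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)


def rate_to_probability(rate_per_day: np.ndarray | float, dt_days: float):
    """Poisson waiting-time conversion of a rate to a per-step probability."""
    return 1.0 - np.exp(-np.asarray(rate_per_day, dtype=float) * dt_days)


@dataclass(frozen=True)
class RateTable:
    """Cellular activity rates (migration µm/h, the rest day^-1).

    The osteoblast proliferation rate applies to immature osteoblasts.
    Mature osteoblasts (the low-stimulus fate) are post-mitotic matrix
    secretors: they deposit bone and undergo apoptosis but do not divide,
    so bone formation tracks the progenitor supply and arrests within
    days of recruitment stopping — densely populated regions still
    mineralize fully before the population fades.
    """

    msc_migration: float = 30.0
    msc_proliferation: float = 0.60
    msc_differentiation: float = 0.30
    msc_apoptosis: float = 0.05
    fibroblast_migration: float = 30.0
    fibroblast_proliferation: float = 0.55
    fibroblast_apoptosis: float = 0.05
    chondrocyte_proliferation: float = 0.20
    chondrocyte_apoptosis: float = 0.10
    osteoblast_proliferation: float = 0.30
    osteoblast_apoptosis: float = 0.16
    mature_osteoblast_proliferation: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")

    def migration(self) -> np.ndarray:
        """µm/h indexed by phenotype code; immobile phenotypes are 0."""
        out = np.zeros(5)
        out[MSC] = self.msc_migration
        out[FIBROBLAST] = self.fibroblast_migration
        return out

    def proliferation(self) -> np.ndarray:
        out = np.zeros(5)
        out[MSC] = self.msc_proliferation
        out[FIBROBLAST] = self.fibroblast_proliferation
        out[CHONDROCYTE] = self.chondrocyte_proliferation
        out[OSTEOBLAST] = self.osteoblast_proliferation
        return out

    def apoptosis(self) -> np.ndarray:
        out = np.zeros(5)
        out[MSC] = self.msc_apoptosis
        out[FIBROBLAST] = self.fibroblast_apoptosis
        out[CHONDROCYTE] = self.chondrocyte_apoptosis
        out[OSTEOBLAST] = self.osteoblast_apoptosis
        return out


@dataclass(frozen=True)
class DifferentiationRanges:
    """Stimulus windows selecting the MSC fate (boundaries inclusive above).

    S <= mature_osteoblast_max       -> mature osteoblast
    ... <= immature_osteoblast_max   -> immature osteoblast
    ... <= chondrocyte_max           -> chondrocyte
    above                            -> fibroblast
    """

    mature_osteoblast_max: float = 2.53
    immature_osteoblast_max: float = 3.00
    chondrocyte_max: float = 5.00

    def __post_init__(self) -> None:
        if not (
            0.0
            < self.mature_osteoblast_max
            < self.immature_osteoblast_max
            < self.chondrocyte_max
        ):
            raise ValueError("differentiation thresholds must be increasing")

    def phenotype_for(self, S):
        """Vectorized fate decision; returns (phenotype codes, mature flags)."""
        S = np.asarray(S, dtype=float)
        phen = np.full(S.shape, FIBROBLAST, dtype=np.int8)
        mature = np.zeros(S.shape, dtype=bool)
        phen[S <= self.chondrocyte_max] = CHONDROCYTE
        phen[S <= self.immature_osteoblast_max] = OSTEOBLAST
        is_mature = S <= self.mature_osteoblast_max
        phen[is_mature] = OSTEOBLAST
        mature[is_mature] = True
        return phen, mature

    def favorable(self, phenotype, S):
        """Whether the local stimulus lies in a phenotype's preferred window.

        MSCs tolerate any stimulus; each differentiated phenotype prefers
        its own differentiation window (osteoblasts the bone window for
        either maturity, chondrocytes the cartilage window, fibroblasts
        the high-strain window).  Outside its window a differentiated cell
        neither proliferates nor thrives.
        """
        phenotype = np.asarray(phenotype)
        S = np.asarray(S, dtype=float)
        ok = np.ones(np.broadcast(phenotype, S).shape, dtype=bool)
        fib = phenotype == FIBROBLAST
        ok &= ~fib | (S > self.chondrocyte_max)
        cho = phenotype == CHONDROCYTE
        ok &= ~cho | (
            (S > self.immature_osteoblast_max) & (S <= self.chondrocyte_max)
        )
        ob = phenotype == OSTEOBLAST
        ok &= ~ob | (S <= self.immature_osteoblast_max)
        return ok


@dataclass(frozen=True)
class RecruitmentPolicy:
    """Continuous vs. limited (10-day) progenitor recruitment."""

    mode: str = "limited"
    cutoff_day: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "limited"):
            raise ValueError(f"unknown recruitment mode {self.mode!r}")
        if self.cutoff_day <= 0:
            raise ValueError("cutoff_day must be > 0")


def apply_recruitment_policy(
    rates: RateTable, day: float, policy: RecruitmentPolicy
) -> RateTable:
    """Zero MSC migration and proliferation after the cutoff (limited mode);
    differentiation and apoptosis are kept unaltered."""
    if day < 0:
        raise ValueError("day must be >= 0")
    if policy.mode == "limited" and day > policy.cutoff_day:
        return replace(rates, msc_migration=0.0, msc_proliferation=0.0)
    return rates


class CellLattice:
    """At most one cell agent per site; osteoblasts carry a maturity flag."""

    def __init__(self, lattice: "RegionLattice", phenotype: np.ndarray,
                 mature: np.ndarray):
        self.lattice = lattice
        self.phenotype = phenotype
        self.mature = mature

    @classmethod
    def empty(cls, lattice: "RegionLattice") -> "CellLattice":
        return cls(
            lattice,
            np.zeros(lattice.shape, dtype=np.int8),
            np.zeros(lattice.shape, dtype=bool),
        )

    def copy(self) -> "CellLattice":
        return CellLattice(self.lattice, self.phenotype.copy(), self.mature.copy())

    @property
    def occupied(self) -> np.ndarray:
        return self.phenotype != EMPTY

    def count(self) -> int:
        return int(np.count_nonzero(self.phenotype))

    def census(self) -> dict:
        out = {}
        for code, name in PHENOTYPE_NAMES.items():
            out[name] = int(np.count_nonzero(self.phenotype == code))
        out["mature_osteoblast"] = int(
            np.count_nonzero((self.phenotype == OSTEOBLAST) & self.mature)
        )
        return out

    def check_invariants(self) -> None:
        if np.any((self.phenotype != EMPTY) & ~self.lattice.cell_allowed):
            raise AssertionError("cell found outside the allowed domain")
        if np.any(self.mature & (self.phenotype != OSTEOBLAST)):
            raise AssertionError("maturity flag set on a non-osteoblast")


# ---------------------------------------------------------------------------
# vectorized neighbor machinery


def _neighbor_flats(shape, flat_idx):
    """(n, 6) flat ids of the face neighbors, -1 where out of bounds."""
    nx, ny, nz = shape
    k = flat_idx % nz
    j = (flat_idx // nz) % ny
    i = flat_idx // (ny * nz)
    ii = i[:, None] + _FACE_OFFSETS[:, 0][None, :]
    jj = j[:, None] + _FACE_OFFSETS[:, 1][None, :]
    kk = k[:, None] + _FACE_OFFSETS[:, 2][None, :]
    valid = (
        (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny) & (kk >= 0) & (kk < nz)
    )
    flat = (ii * ny + jj) * nz + kk
    flat[~valid] = -1
    return flat, valid


def _weighted_pick(weights: np.ndarray, rng: np.random.Generator):
    """Pick one column per row with probability proportional to weight.

    Rows whose weights sum to zero return -1 (no move possible).
    """
    totals = weights.sum(axis=1)
    choice = np.full(weights.shape[0], -1, dtype=np.int64)
    ok = totals > 0
    if np.any(ok):
        cum = np.cumsum(weights[ok], axis=1)
        u = rng.random(int(ok.sum())) * totals[ok]
        choice[ok] = (u[:, None] >= cum).sum(axis=1)
    return choice


def _resolve_conflicts(targets: np.ndarray, rng: np.random.Generator):
    """Random-priority resolution: one winner per contested target site."""
    order = rng.permutation(targets.size)
    _, first = np.unique(targets[order], return_index=True)
    return order[np.sort(first)]


def migrate(
    cells: CellLattice,
    chem_index_field: np.ndarray,
    rates: RateTable,
    rng: np.random.Generator,
    dt_hours: float = 2.0,
    msc_rate_scale: np.ndarray | float = 1.0,
) -> CellLattice:
    """One chemotaxis-weighted migration sub-step (in place).

    Motile cells (MSCs, fibroblasts) attempt one hop to a face neighbor.
    The destination is drawn with probability proportional to the
    chemotaxis index at each free, in-domain candidate; MSCs follow the
    supplied BMP-2 chemotaxis field, fibroblasts move unweighted.  On the
    reference 60-µm lattice each cell hops once per 2-h step (30 µm/h); on
    a coarsened lattice the hop probability shrinks by the squared
    coarsening factor, which preserves both the random-walk diffusivity
    (a^2 p) and the chemotactic drift (gradient-induced bias grows with
    the pitch, so drift also goes as a^2 p).

    ``msc_rate_scale`` optionally modulates the MSC migration rate per
    site (used for the spatially resolved recruitment cutoff).
    """
    lattice = cells.lattice
    chem = np.asarray(chem_index_field, dtype=float)
    if chem.shape != cells.phenotype.shape:
        raise ValueError("chemotaxis field shape mismatch")
    if np.any(chem < 1.0 - 1e-12):
        raise ValueError("chemotaxis index must be >= 1 everywhere")

    phen_flat = cells.phenotype.reshape(-1)
    mature_flat = cells.mature.reshape(-1)
    occ0 = phen_flat != EMPTY  # occupancy snapshot: synchronous update
    allowed = lattice.cell_allowed.reshape(-1)
    chem_flat = chem.reshape(-1)

    spacing_um = lattice.config.cell_site_spacing_um
    migration = rates.migration()
    hop_p = np.clip(
        migration
        * dt_hours
        / spacing_um
        * lattice.config.hop_probability_scale,
        0.0,
        1.0,
    )

    scale = np.broadcast_to(
        np.asarray(msc_rate_scale, dtype=float), cells.phenotype.shape
    ).reshape(-1)
    candidates = np.flatnonzero(occ0 & (hop_p[phen_flat] > 0))
    if candidates.size == 0:
        return cells
    p_cand = hop_p[phen_flat[candidates]]
    is_msc = phen_flat[candidates] == MSC
    p_cand = np.where(is_msc, p_cand * scale[candidates], p_cand)
    draws = rng.random(candidates.size)
    movers = candidates[draws < p_cand]
    if movers.size == 0:
        return cells

    nbr, inb = _neighbor_flats(cells.phenotype.shape, movers)
    safe = np.where(nbr < 0, 0, nbr)
    free = inb & allowed[safe] & ~occ0[safe]
    weights = np.where(free, chem_flat[safe], 0.0)
    # fibroblasts are not chemotactic: uniform weight over free candidates
    fib = phen_flat[movers] == FIBROBLAST
    weights[fib] = free[fib].astype(float)

    col = _weighted_pick(weights, rng)
    moved = col >= 0
    origins = movers[moved]
    targets = nbr[np.flatnonzero(moved), col[moved]]
    win = _resolve_conflicts(targets, rng)
    origins, targets = origins[win], targets[win]

    phen_flat[targets] = phen_flat[origins]
    mature_flat[targets] = mature_flat[origins]
    phen_flat[origins] = EMPTY
    mature_flat[origins] = False
    return cells


def proliferate(
    cells: CellLattice,
    S_field: np.ndarray,
    bmp_prolif_factor: np.ndarray | float,
    rates: RateTable,
    rng: np.random.Generator,
    dt_hours: float = 2.0,
    ranges: DifferentiationRanges | None = None,
    msc_rate_scale: np.ndarray | float = 1.0,
) -> CellLattice:
    """One proliferation sub-step (in place).

    A cell divides with p = 1 - exp(-r_eff dt); the BMP-2 fold factor
    applies to MSCs only, and differentiated cells divide only where the
    local stimulus lies in their favorable window.  The daughter occupies
    a uniformly chosen free face neighbor; with no free neighbor the
    division is skipped.
    """
    lattice = cells.lattice
    ranges = ranges or DifferentiationRanges()
    factor = np.broadcast_to(np.asarray(bmp_prolif_factor, dtype=float),
                             cells.phenotype.shape)
    if np.any(factor < 1.0 - 1e-12):
        raise ValueError("proliferation factors must be >= 1")
    S_flat = np.asarray(S_field, dtype=float).reshape(-1)

    phen_flat = cells.phenotype.reshape(-1)
    mature_flat = cells.mature.reshape(-1)
    occ0 = phen_flat != EMPTY
    allowed = lattice.cell_allowed.reshape(-1)
    dt_days = dt_hours / 24.0

    scale = np.broadcast_to(
        np.asarray(msc_rate_scale, dtype=float), cells.phenotype.shape
    ).reshape(-1)
    idx = np.flatnonzero(occ0)
    phen = phen_flat[idx]
    r_eff = rates.proliferation()[phen]
    r_eff = np.where(
        phen == MSC, r_eff * factor.reshape(-1)[idx] * scale[idx], r_eff
    )
    r_eff = np.where(
        (phen == OSTEOBLAST) & mature_flat[idx],
        rates.mature_osteoblast_proliferation,
        r_eff,
    )
    gate = ranges.favorable(phen, S_flat[idx])
    p = rate_to_probability(r_eff, dt_days) * gate
    dividers = idx[rng.random(idx.size) < p]
    if dividers.size == 0:
        return cells

    nbr, inb = _neighbor_flats(cells.phenotype.shape, dividers)
    safe = np.where(nbr < 0, 0, nbr)
    free = inb & allowed[safe] & ~occ0[safe]
    col = _weighted_pick(free.astype(float), rng)
    ok = col >= 0
    parents = dividers[ok]
    targets = nbr[np.flatnonzero(ok), col[ok]]
    win = _resolve_conflicts(targets, rng)
    parents, targets = parents[win], targets[win]

    phen_flat[targets] = phen_flat[parents]
    mature_flat[targets] = mature_flat[parents]
    return cells


def differentiate(
    cells: CellLattice,
    S_field: np.ndarray,
    ranges: DifferentiationRanges,
    rates: RateTable,
    rng: np.random.Generator,
    dt_hours: float = 2.0,
) -> CellLattice:
    """One MSC differentiation sub-step (in place).

    MSCs inside the healing region convert with p = 1 - exp(-r dt) to the
    phenotype selected by the stimulus window at their site; fate
    conversion is not rescaled on coarse lattices.  Immature osteoblasts
    additionally mature over time (at the same rate) as they deposit
    matrix, joining the slowly cycling mature pool.
    """
    lattice = cells.lattice
    S_flat = np.asarray(S_field, dtype=float).reshape(-1)
    phen_flat = cells.phenotype.reshape(-1)
    mature_flat = cells.mature.reshape(-1)
    healing = lattice.healing.reshape(-1)
    p = rate_to_probability(rates.msc_differentiation, dt_hours / 24.0)

    idx = np.flatnonzero((phen_flat == MSC) & healing)
    if idx.size:
        chosen = idx[rng.random(idx.size) < p]
        if chosen.size:
            fate, mature = ranges.phenotype_for(S_flat[chosen])
            phen_flat[chosen] = fate
            mature_flat[chosen] = mature

    imm = np.flatnonzero((phen_flat == OSTEOBLAST) & ~mature_flat & healing)
    if imm.size:
        mature_flat[imm[rng.random(imm.size) < p]] = True
    return cells


def apoptose(
    cells: CellLattice,
    S_field: np.ndarray,
    rates: RateTable,
    rng: np.random.Generator,
    dt_hours: float = 2.0,
    ranges: DifferentiationRanges | None = None,
    unfavorable_apoptosis_factor: float = 2.0,
) -> CellLattice:
    """One apoptosis sub-step (in place).

    Cells die with p = 1 - exp(-r dt); a differentiated cell sitting where
    the stimulus is outside its favorable window dies at a boosted rate.
    """
    ranges = ranges or DifferentiationRanges()
    S_flat = np.asarray(S_field, dtype=float).reshape(-1)
    phen_flat = cells.phenotype.reshape(-1)
    mature_flat = cells.mature.reshape(-1)

    idx = np.flatnonzero(phen_flat != EMPTY)
    if idx.size == 0:
        return cells
    phen = phen_flat[idx]
    rate = rates.apoptosis()[phen]
    boost = np.where(
        ranges.favorable(phen, S_flat[idx]), 1.0, unfavorable_apoptosis_factor
    )
    p = rate_to_probability(rate * boost, dt_hours / 24.0)
    dying = idx[rng.random(idx.size) < p]
    phen_flat[dying] = EMPTY
    mature_flat[dying] = False
    return cells
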
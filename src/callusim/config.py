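"""Scenario and domain configuration.

The geometry of the rodent femoral defect model is an idealized hollow
cylinder (cortex) around a medullary cavity, transversally osteotomized by a
5-mm gap at midshaft and surrounded by a cylindrical callus growth region.
The published model gives the gap width, the element / voxel sizes and the
seeding fraction; the callus dimensions themselves come from in vivo data
that are not printed, so they are documented defaults here and fully
configurable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: reference cell-site spacing: one 30 µm/h migration hop per 2-h iteration
REFERENCE_CELL_SPACING_UM = 60.0


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class DomainConfig:
    """Geometry of the defect model and of the nested lattices.

    All lengths in mm unless stated otherwise.
    """

    cortex_outer_radius: float = 2.0
    cortex_inner_radius: float = 1.3
    bone_segment_length: float = 10.0
    gap_width: float = 5.0
    callus_outer_radius: float = 2.75
    callus_axial_overhang: float = 1.5
    cell_site_spacing_um: float = REFERENCE_CELL_SPACING_UM
    fe_element_size_callus: float = 0.25
    fe_element_size_outer: float = 0.50
    bv_voxel_size: float = 0.04
    seed_fraction: float = 0.30

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lengths = {
            "cortex_outer_radius": self.cortex_outer_radius,
            "cortex_inner_radius": self.cortex_inner_radius,
            "bone_segment_length": self.bone_segment_length,
            "gap_width": self.gap_width,
            "callus_outer_radius": self.callus_outer_radius,
            "cell_site_spacing_um": self.cell_site_spacing_um,
            "fe_element_size_callus": self.fe_element_size_callus,
            "fe_element_size_outer": self.fe_element_size_outer,
            "bv_voxel_size": self.bv_voxel_size,
        }
        for name, value in lengths.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        if self.callus_axial_overhang < 0:
            raise ConfigurationError("callus_axial_overhang must be >= 0")
        if not self.cortex_inner_radius < self.cortex_outer_radius:
            raise ConfigurationError(
                "cortex_inner_radius must be smaller than cortex_outer_radius"
            )
        if not self.cortex_outer_radius <= self.callus_outer_radius:
            raise ConfigurationError(
                "callus_outer_radius must be at least cortex_outer_radius"
            )
        if not 0.0 <= self.seed_fraction <= 1.0:
            raise ConfigurationError("seed_fraction must lie in [0, 1]")

    # -- derived quantities ------------------------------------------------
    @property
    def cell_site_spacing_mm(self) -> float:
        return self.cell_site_spacing_um / 1000.0

    @property
    def total_length(self) -> float:
        """Axial extent of the model (two bone segments plus the gap)."""
        return 2.0 * self.bone_segment_length + self.gap_width

    @property
    def cell_cohort_size(self) -> float:
        """Number of real cells represented by one lattice agent.

        On the reference 60-µm lattice each agent is a single cell; on a
        coarsened lattice each agent stands for a cohort filling one site.
        """
        return (self.cell_site_spacing_um / REFERENCE_CELL_SPACING_UM) ** 3

    @property
    def hop_probability_scale(self) -> float:
        """Coarse-graining factor (<= 1) by which the per-step migration
        hop probability shrinks on a coarsened lattice, preserving the
        physical migration speed (rate * dt / spacing)."""
        return min(1.0, REFERENCE_CELL_SPACING_UM / self.cell_site_spacing_um)

    def summary(self) -> dict:
        d = dataclasses.asdict(self)
        d["total_length"] = self.total_length
        d["cell_cohort_size"] = self.cell_cohort_size
        d["hop_probability_scale"] = self.hop_probability_scale
        return d


@dataclass
class ScenarioConfig:
    """A full treatment scenario.

    ``scenario`` selects one of the four case studies: untreated control,
    weekly external loading, BMP-2 on a collagen sponge, or both.
    """

    scenario: str = "control"  # control | load | bmp2 | bmp2_load
    recruitment: str = "limited"  # continuous | limited
    release: str = "sponge"  # sponge | fast
    duration_days: float = 42.0
    dt_hours: float = 2.0
    stimulation_period_days: float = 7.0
    first_stimulation_day: float = 7.0
    stimulation_displacement_um: float = 500.0
    stimulation_ramp_rate_um_s: float = 10.0
    gait_force_n: float = 7.0
    bmp_dose_ug: float = 50.0
    recruitment_cutoff_day: float = 10.0
    #: free BMP-2 level (ng/cm^3) that keeps MSC recruitment active past
    #: the cutoff under limited recruitment; 0 disables the rescue
    bmp_recruitment_rescue_ng_cm3: float = 1.0
    output_days: tuple = (14.0, 28.0, 42.0)
    bv_every_days: float = 7.0
    seed: int = 0
    mechanics_backend: str = "surrogate"  # surrogate | fe

    SCENARIOS = ("control", "load", "bmp2", "bmp2_load")

    def __post_init__(self) -> None:
        self.output_days = tuple(float(d) for d in self.output_days)
        self.validate()

    def validate(self) -> None:
        if self.scenario not in self.SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.recruitment not in ("continuous", "limited"):
            raise ConfigurationError(f"unknown recruitment {self.recruitment!r}")
        if self.release not in ("sponge", "fast"):
            raise ConfigurationError(f"unknown release {self.release!r}")
        if self.duration_days <= 0 or self.dt_hours <= 0:
            raise ConfigurationError("duration and time step must be positive")
        if self.recruitment_cutoff_day <= 0:
            raise ConfigurationError("recruitment_cutoff_day must be > 0")
        if self.bmp_recruitment_rescue_ng_cm3 < 0:
            raise ConfigurationError("recruitment rescue level must be >= 0")
        if self.uses_bmp and self.bmp_dose_ug <= 0:
            raise ConfigurationError("BMP-2 scenarios require a positive dose")
        if self.release == "fast" and not self.uses_bmp:
            raise ConfigurationError(
                "fast release is only meaningful for a BMP-2 scenario"
            )
        if max(self.output_days) > self.duration_days:
            raise ConfigurationError("output timepoint beyond simulation duration")

    @property
    def uses_bmp(self) -> bool:
        return self.scenario in ("bmp2", "bmp2_load")

    @property
    def uses_stimulation(self) -> bool:
        return self.scenario in ("load", "bmp2_load")

    @property
    def n_iterations(self) -> int:
        return int(round(self.duration_days * 24.0 / self.dt_hours))

    @property
    def stimulation_days(self) -> tuple:
        """Days on which the 500-µm axial stimulation replaces gait."""
        if not self.uses_stimulation:
            return ()
        days = []
        d = self.first_stimulation_day
        while d < self.duration_days:
            days.append(d)
            d += self.stimulation_period_days
        return tuple(days)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_days"] = list(self.output_days)
        return d


# --- file round trips -----------------------------------------------------

def _split_known(cls, data: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return data


def load_config(path: str | Path) -> tuple[DomainConfig, ScenarioConfig]:
    """Read a YAML configuration with optional ``domain:`` and
    ``scenario:`` blocks; omitted keys use the documented defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    domain = DomainConfig(**_split_known(DomainConfig, raw.get("domain", {}) or {}))
    scenario = ScenarioConfig(
        **_split_known(ScenarioConfig, raw.get("scenario", {}) or {})
    )
    return domain, scenario


def save_config(path: str | Path, domain: DomainConfig,
                scenario: Optional[ScenarioConfig] = None) -> None:
    payload = {"domain": dataclasses.asdict(domain)}
    if scenario is not None:
        payload["scenario"] = scenario.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def export_geometry_summary(path: str | Path, domain: DomainConfig) -> None:
    with open(path, "w") as fh:
        json.dump(domain.summary(), fh, indent=2)
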
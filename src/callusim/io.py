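"""Exports: legacy-ASCII VTK image data, CSV time series, voxel dumps.

The VTK writer emits minimal ``STRUCTURED_POINTS`` datasets (one scalar
field per file) readable by ParaView and friends; cell snapshots go to
CSV, the Boolean bone grid additionally to a raw uint8 dump with a JSON
header for external microCT-style viewers.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .orchestrator import SimulationResult, run_manifest
from .tissue import BVReport


def write_vtk_image(
    path: str | Path,
    field: np.ndarray,
    spacing: float | tuple,
    origin: tuple = (0.0, 0.0, 0.0),
    name: str = "field",
) -> None:
    """Write one 3D scalar field as a legacy-ASCII VTK STRUCTURED_POINTS
    file (point data on the grid of array entries)."""
    field = np.asarray(field)
    if field.ndim != 3:
        raise ValueError("expected a 3D scalar field")
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    nx, ny, nz = field.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        # VTK expects x fastest; our arrays are indexed [x, y, z]
        flat = np.transpose(field, (2, 1, 0)).reshape(-1)
        np.savetxt(fh, flat[:, None], fmt="%.6g")


def write_cells_csv(path: str | Path, cells) -> None:
    """Cell snapshot as CSV: site indices, phenotype name, maturity."""
    from .cells import PHENOTYPE_NAMES

    sites = np.argwhere(cells.phenotype != 0)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["i", "j", "k", "phenotype", "mature"])
        for i, j, k in sites:
            writer.writerow(
                [
                    int(i),
                    int(j),
                    int(k),
                    PHENOTYPE_NAMES[int(cells.phenotype[i, j, k])],
                    int(cells.mature[i, j, k]),
                ]
            )


def write_bv_csv(path: str | Path, result: SimulationResult) -> None:
    """Bone-volume time series as CSV (day, BV mm^3)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["day", "bv_mm3"])
        for day, bv in zip(result.bv_days, result.bv_mm3):
            writer.writerow([day, bv])


def write_census_csv(path: str | Path, result: SimulationResult) -> None:
    if not result.census:
        return
    keys = ["day"] + [k for k in result.census[0] if k != "day"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        for row in result.census:
            writer.writerow(row)


def write_voxel_dump(path_prefix: str | Path, report: BVReport) -> None:
    """Raw uint8 voxel dump (z fastest) plus a JSON sidecar header."""
    prefix = Path(path_prefix)
    raw = prefix.with_suffix(".raw")
    report.bone_grid.astype(np.uint8).tofile(raw)
    header = {
        "shape_xyz": list(report.bone_grid.shape),
        "voxel_size_mm": report.voxel_size_mm,
        "origin_mm": list(report.voxel_origin_mm),
        "dtype": "uint8",
        "order": "C (x slowest, z fastest)",
        "bv_mm3": report.bv_mm3,
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(header, fh, indent=2)


def write_run_outputs(outdir: str | Path, result: SimulationResult) -> None:
    """Standard output bundle of one scenario run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bv_csv(outdir / "bv.csv", result)
    write_census_csv(outdir / "census.csv", result)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(run_manifest(result), fh, indent=2)
    for day, snap in result.snapshots.items():
        tag = f"day{int(day):02d}"
        np.savetxt(
            outdir / f"fractions_{tag}.csv",
            snap["fractions"],
            delimiter=",",
            header="granulation,fibrous,cartilage,bone",
            comments="",
        )
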
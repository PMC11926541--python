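"""NIfTI and YAML persistence for structures, doses and plan libraries.

Masks and dose volumes are written as NIfTI with a diagonal affine built
from the grid spacing and origin (the package's fixed x/y/z patient-axis
convention maps directly onto the array axes). A plan library persists as
a directory: a manifest YAML plus per-entry mask and dose volumes with the
shift key encoded in the filenames (e.g. ``ap+1_si+2``).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dose_engine import DoseGrid, Prescription
from .grid import Structure, StructureSet, VoxelGrid, make_grid
from .library_builder import (
    LibraryEntry,
    MarginSpec,
    PlanLibrary,
    ShiftSpec,
)

__all__ = [
    "grid_to_affine",
    "affine_to_grid",
    "write_structure",
    "read_structure",
    "write_structure_set",
    "read_structure_set",
    "write_dose",
    "read_dose",
    "write_library",
    "read_library",
]


def grid_to_affine(grid: VoxelGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = grid.spacing_mm
    affine[:3, 3] = grid.origin_mm
    return affine


def affine_to_grid(affine: np.ndarray, shape: tuple[int, int, int]) -> VoxelGrid:
    spacing = tuple(float(affine[a, a]) for a in range(3))
    origin = tuple(float(affine[a, 3]) for a in range(3))
    return make_grid(shape, spacing, origin)


def write_structure(structure: Structure, path: str | Path) -> None:
    img = nib.Nifti1Image(
        structure.mask.astype(np.uint8), grid_to_affine(structure.grid)
    )
    nib.save(img, str(path))


def read_structure(path: str | Path, name: str | None = None) -> Structure:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    grid = affine_to_grid(img.affine, data.shape)
    return Structure(name or Path(path).name.split(".")[0], data, grid)


def write_structure_set(ss: StructureSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ss.names():
        write_structure(ss[name], directory / f"{name}.nii.gz")


def read_structure_set(directory: str | Path) -> StructureSet:
    directory = Path(directory)
    structures = {}
    grid = None
    for path in sorted(directory.glob("*.nii.gz")):
        name = path.name.removesuffix(".nii.gz")
        s = read_structure(path, name)
        grid = grid or s.grid
        structures[name] = s
    if grid is None:
        raise ValueError(f"no .nii.gz structures found in {directory}")
    return StructureSet(grid, structures)


def write_dose(dose: DoseGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32), grid_to_affine(dose.grid))
    nib.save(img, str(path))


def read_dose(path: str | Path) -> DoseGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return DoseGrid(data, affine_to_grid(img.affine, data.shape))


def write_library(library: PlanLibrary, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "margin_mm": library.margin.margin_mm,
        "prescription": {
            "total_dose_gy": library.prescription.total_dose_gy,
            "n_fractions": library.prescription.n_fractions,
        },
        "entries": [
            {"ap_cm": s.ap_cm, "si_cm": s.si_cm, "key": s.key()}
            for s in library.entries
        ],
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    for spec, entry in library.entries.items():
        k = spec.key()
        write_structure(entry.bladder, directory / f"bladder_{k}.nii.gz")
        write_structure(entry.ctv, directory / f"ctv_{k}.nii.gz")
        write_structure(entry.ptv, directory / f"ptv_{k}.nii.gz")
        if entry.dose is not None:
            write_dose(entry.dose, directory / f"dose_{k}.nii.gz")


def read_library(directory: str | Path) -> PlanLibrary:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    prescription = Prescription(**manifest["prescription"])
    margin = MarginSpec(manifest["margin_mm"])
    entries: dict[ShiftSpec, LibraryEntry] = {}
    grid = None
    for e in manifest["entries"]:
        spec = ShiftSpec(float(e["ap_cm"]), float(e["si_cm"]))
        k = e["key"]
        bladder = read_structure(directory / f"bladder_{k}.nii.gz", f"bladder_{k}")
        ctv = read_structure(directory / f"ctv_{k}.nii.gz", "ctv")
        ptv = read_structure(directory / f"ptv_{k}.nii.gz", "ptv")
        dose_path = directory / f"dose_{k}.nii.gz"
        dose = read_dose(dose_path) if dose_path.exists() else None
        grid = grid or bladder.grid
        entries[spec] = LibraryEntry(spec, bladder, ctv, ptv, dose)
    if grid is None:
        raise ValueError(f"no library entries found in {directory}")
    return PlanLibrary(entries, prescription, margin, grid)
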
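"""Volumetric data model and file I/O shared by all pipeline stages.

A reconstructed CT image is a 3D scalar field of radiodensity values in
Hounsfield units (HU) on an isotropic voxel lattice.  The HU scale is anchored
at −1000 (air) and 0 (water); values are clamped on ingest to
[−1024, +4000], spanning the scanner air floor up to dense cortical bone.

Axis convention: arrays are indexed ``(z, y, x)``, 0-based; the spatial origin
is the center of voxel ``(0, 0, 0)``.  Anisotropic input is rejected rather
than resampled — every analysis in this package assumes isotropic voxels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HU_MIN = -1024.0
HU_MAX = 4000.0

#: columns of a reference body-composition table (QMR-style output)
REFERENCE_COLUMNS = [
    "specimen_id",
    "fat_mass_g",
    "lean_mass_g",
    "free_water_g",
    "total_water_g",
    "balance_mass_g",
]


@dataclass
class VoxelGrid:
    """A reconstructed CT volume in Hounsfield units.

    Parameters
    ----------
    data:
        3D float array of HU values, axis order ``(z, y, x)``.
    edge_um:
        Isotropic voxel edge length in micrometres (> 0).
    origin_mm:
        Spatial offset (mm) of the center of voxel ``(0, 0, 0)``.
    meta:
        Free-form acquisition record (e.g. ``voltage_kvp``, ``current_ma``,
        ``projections``); carried through processing but never interpreted.
    """

    data: np.ndarray
    edge_um: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a 3D array with all dimensions >= 1")
        if not self.edge_um > 0:
            raise ValueError(f"edge_um must be positive, got {self.edge_um}")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def edge_mm(self) -> float:
        return self.edge_um * 1e-3

    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm³: ``(edge_um × 10⁻⁴)³``."""
        return (self.edge_um * 1e-4) ** 3

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(
            self.data.copy(), self.edge_um, self.origin_mm.copy(), dict(self.meta)
        )


def voxel_volume_cm3(grid: VoxelGrid) -> float:
    """Volume of one voxel of *grid* in cm³."""
    return grid.voxel_volume_cm3()


def clamp_hu(data: np.ndarray, context: str = "volume") -> np.ndarray:
    """Clamp HU values to the supported dynamic range, warning if any change."""
    data = np.asarray(data, dtype=np.float32)
    n_out = int(np.count_nonzero((data < HU_MIN) | (data > HU_MAX)))
    if n_out:
        logger.warning(
            "%s: clamped %d voxel(s) outside [%g, %g] HU", context, n_out, HU_MIN, HU_MAX
        )
        warnings.warn(
            f"{context}: clamped {n_out} voxel(s) outside [{HU_MIN:g}, {HU_MAX:g}] HU",
            stacklevel=2,
        )
    return np.clip(data, HU_MIN, HU_MAX)


def _edge_from_zooms(zooms_mm) -> float:
    zooms = np.asarray(zooms_mm[:3], dtype=float)
    if np.any(zooms <= 0):
        raise ValueError("voxel size missing or non-positive in header")
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        raise ValueError(
            f"anisotropic voxels {tuple(zooms)} mm are not supported; "
            "the pipeline assumes isotropy"
        )
    return float(zooms[0] * 1000.0)


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write *grid* to a NIfTI-1 file (``.nii``/``.nii.gz``).

    The voxel edge is encoded in the affine/zooms and the origin in the affine
    translation.  Data are stored as float32, which is lossless for integer HU.
    """
    path = Path(path)
    e = grid.edge_mm
    affine = np.diag([e, e, e, 1.0])
    # array axis order is (z, y, x); nibabel's first array axis maps to the
    # first affine column, so the stored image is simply in (z, y, x) order too
    affine[:3, 3] = grid.origin_mm
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float32), affine)
    img.header.set_zooms((e, e, e))
    nib.save(img, str(path))


def _read_nifti(path: Path) -> VoxelGrid:
    img = nib.load(str(path))
    edge_um = _edge_from_zooms(img.header.get_zooms())
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    origin_mm = np.asarray(img.affine[:3, 3], dtype=float)
    data = clamp_hu(data, context=str(path))
    return VoxelGrid(data, edge_um, origin_mm, meta={"source": str(path)})


def _read_raw_json(path: Path) -> VoxelGrid:
    """Read a raw binary volume described by a JSON sidecar.

    The sidecar declares ``shape`` (z, y, x), ``dtype`` (numpy name),
    ``edge_um`` and optionally ``origin_mm``, ``meta`` and ``raw_file``
    (path of the binary blob, relative to the sidecar; defaults to the
    sidecar name with a ``.raw`` suffix).  C order is assumed.
    """
    with open(path) as fh:
        sidecar = json.load(fh)
    for key in ("shape", "dtype", "edge_um"):
        if key not in sidecar:
            raise ValueError(f"{path}: sidecar missing required field '{key}'")
    raw_file = path.parent / sidecar.get("raw_file", path.stem + ".raw")
    shape = tuple(int(s) for s in sidecar["shape"])
    data = np.fromfile(raw_file, dtype=np.dtype(sidecar["dtype"])).reshape(shape)
    data = clamp_hu(data, context=str(raw_file))
    return VoxelGrid(
        data,
        float(sidecar["edge_um"]),
        np.asarray(sidecar.get("origin_mm", [0.0, 0.0, 0.0]), dtype=float),
        meta=dict(sidecar.get("meta", {})),
    )


def read_volume(path: str | Path, format: str | None = None) -> VoxelGrid:
    """Read a CT volume from ``nifti`` (.nii/.nii.gz) or ``raw+json`` format.

    HU values are clamped to [−1024, +4000] with a warning if any fall
    outside.  The format is inferred from the extension when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.suffix == ".json":
            format = "raw+json"
        else:
            raise ValueError(f"cannot infer format of {path}; pass format=")
    if format == "nifti":
        return _read_nifti(path)
    if format == "raw+json":
        return _read_raw_json(path)
    raise ValueError(f"unknown format {format!r}")


def write_raw_json(grid: VoxelGrid, sidecar_path: str | Path) -> None:
    """Write *grid* as a raw binary blob plus JSON sidecar (fixture format)."""
    sidecar_path = Path(sidecar_path)
    raw_file = sidecar_path.with_suffix(".raw")
    np.asarray(grid.data, dtype=np.float32).tofile(raw_file)
    with open(sidecar_path, "w") as fh:
        json.dump(
            {
                "shape": list(grid.shape),
                "dtype": "float32",
                "edge_um": grid.edge_um,
                "origin_mm": list(grid.origin_mm),
                "raw_file": raw_file.name,
                "meta": grid.meta,
            },
            fh,
            indent=1,
            default=str,
        )


def read_reference_table(path: str | Path) -> pd.DataFrame:
    """Read a reference body-composition CSV (QMR-style truth channel).

    Expected header: ``specimen_id,fat_mass_g,lean_mass_g,free_water_g,
    total_water_g,balance_mass_g``.  Masses must be non-negative and
    specimen ids unique.
    """
    df = pd.read_csv(path)
    return validate_reference_table(df)


def validate_reference_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reference table missing columns: {missing}")
    df = df[REFERENCE_COLUMNS].copy()
    mass_cols = REFERENCE_COLUMNS[1:]
    if (df[mass_cols].to_numpy(dtype=float) < 0).any():
        raise ValueError("reference table contains negative masses")
    if df["specimen_id"].duplicated().any():
        dups = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen ids in reference table: {dups}")
    return df


def write_reference_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_reference_table(df).to_csv(path, index=False)
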
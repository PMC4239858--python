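"""Volumes, masses and per-specimen composition assembly.

A segmented compartment volume (voxel count × voxel volume) is converted to a
mass by a fixed tissue density: adipose 0.90 g/mL, lean 1.05 g/mL, soybean
oil 0.926 g/mL, water 1.00 g/mL.  Bone density is configurable (default
1.90 g/mL, a standard compact-bone reference value); nothing in the package's
validation depends on it.  Background subtraction removes the contribution of
container plastic — which falls inside the adipose window — measured on an
empty container scanned under the same conditions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .core import VoxelGrid
from .segmentation import (
    ADIPOSE,
    BODY,
    BONE,
    LEAN,
    HUWindow,
    TissueMask,
    apply_voi_mask,
    median_filter_mask,
    segment_window,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DensityTable:
    """Tissue densities in g/mL (1 mL = 1 cm³)."""

    adipose: float = 0.90
    lean: float = 1.05
    soybean_oil: float = 0.926
    water: float = 1.00
    bone: float = 1.90

    def __post_init__(self) -> None:
        for name in ("adipose", "lean", "soybean_oil", "water", "bone"):
            if not getattr(self, name) > 0:
                raise ValueError(f"density {name} must be positive")


@dataclass
class CompositionResult:
    """Per-compartment volumes (cm³) and masses (g) for one specimen."""

    volumes_cm3: dict[str, float]
    masses_g: dict[str, float]
    specimen_id: str = ""
    tail_excluded: bool = False
    skeleton_included: bool = False
    provenance: dict = field(default_factory=dict)

    def volume(self, compartment: str) -> float:
        return self.volumes_cm3[compartment]

    def mass(self, compartment: str) -> float:
        return self.masses_g[compartment]

    def to_rows(self) -> list[dict]:
        """Flatten to CSV-ready rows (one per compartment)."""
        rows = []
        for comp in self.volumes_cm3:
            win = self.provenance.get("windows", {}).get(comp, (None, None))
            rows.append(
                {
                    "specimen_id": self.specimen_id,
                    "compartment": comp,
                    "volume_cm3": self.volumes_cm3[comp],
                    "mass_g": self.masses_g[comp],
                    "edge_um": self.provenance.get("edge_um"),
                    "window_lo": win[0],
                    "window_hi": win[1],
                    "filters": self.provenance.get("filters", {}).get(comp, ""),
                }
            )
        return rows


def mask_volume(mask: TissueMask) -> float:
    """Volume of a tissue mask in cm³: positive-voxel count × voxel volume."""
    return mask.count() * (mask.edge_um * 1e-4) ** 3


def mass_from_volume(volume_cm3: float, density_g_per_ml: float) -> float:
    """Convert a compartment volume to a mass (g) via its tissue density."""
    if volume_cm3 < 0:
        raise ValueError(f"volume must be non-negative, got {volume_cm3}")
    return volume_cm3 * density_g_per_ml


def background_subtract(sample_volume_cm3: float, empty_volume_cm3: float) -> float:
    """Remove the container's own in-window volume from a sample volume.

    Returns ``max(sample − empty, 0)``; a negative intermediate (empty
    background exceeding the sample) is floored at zero with a warning.
    """
    if sample_volume_cm3 < 0 or empty_volume_cm3 < 0:
        raise ValueError("volumes must be non-negative")
    corrected = sample_volume_cm3 - empty_volume_cm3
    if corrected < 0:
        warnings.warn(
            f"background volume {empty_volume_cm3:g} cm3 exceeds sample volume "
            f"{sample_volume_cm3:g} cm3; flooring at 0",
            stacklevel=2,
        )
        return 0.0
    return corrected


def body_composition(
    grid: VoxelGrid,
    voi: TissueMask | None = None,
    densities: DensityTable = DensityTable(),
    median_mm: float | None = None,
    adipose_window: HUWindow = ADIPOSE,
    specimen_id: str = "",
) -> CompositionResult:
    """Run the whole-body composition pipeline on one CT volume.

    Masks the grid to *voi* (−1000 outside), segments the body
    ([−300, +3500) HU), adipose, lean ([−50, +285)) and bone
    ([+285, +2000)) compartments, optionally median-filters the adipose
    mask, and converts volumes to masses via *densities*.
    """
    if voi is not None:
        grid = apply_voi_mask(grid, voi)
    windows = {
        "body": BODY,
        "adipose": adipose_window,
        "lean": LEAN,
        "bone": BONE,
    }
    volumes: dict[str, float] = {}
    filters: dict[str, str] = {}
    for comp, window in windows.items():
        mask = segment_window(grid, window)
        if comp == "adipose" and median_mm is not None:
            mask = median_filter_mask(mask, median_mm)
            filters[comp] = f"median_{median_mm}mm"
        volumes[comp] = mask_volume(mask)
    density_of = {
        "adipose": densities.adipose,
        "lean": densities.lean,
        "bone": densities.bone,
        # whole-body mass is assembled from compartments, not a single density;
        # the body window only reports total volume
        "body": 0.0,
    }
    masses = {
        comp: mass_from_volume(vol, density_of[comp]) if comp != "body" else float("nan")
        for comp, vol in volumes.items()
    }
    masses["body"] = masses["adipose"] + masses["lean"] + masses["bone"]
    return CompositionResult(
        volumes_cm3=volumes,
        masses_g=masses,
        specimen_id=specimen_id,
        tail_excluded=bool(
            voi is not None and voi.provenance.get("tail_crop") is not None
        ),
        provenance={
            "edge_um": grid.edge_um,
            "windows": {c: (w.lo, w.hi) for c, w in windows.items()},
            "filters": filters,
            "median_mm": median_mm,
            "voi": None if voi is None else voi.provenance,
        },
    )


def total_mass_ct(comp: CompositionResult, include_skeleton: bool = True) -> float:
    """CT-derived total body mass: adipose + lean (+ bone when flagged)."""
    total = comp.masses_g["adipose"] + comp.masses_g["lean"]
    if include_skeleton:
        total += comp.masses_g["bone"]
    return total


def total_mass_reference(row: pd.Series | dict) -> float:
    """Reference total mass: fat + lean + free water from one table row."""
    try:
        return float(row["fat_mass_g"]) + float(row["lean_mass_g"]) + float(
            row["free_water_g"]
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"reference row missing a mass field: {exc}") from exc


def percent_difference(calculated_g: float, observed_g: float) -> float:
    """Signed percent difference of a calculated mass from an observed one.

    ``(calculated − observed) / observed × 100``; underestimation is
    negative.  The observed (balance/reference) mass is the denominator.
    """
    if observed_g <= 0:
        raise ValueError(f"observed mass must be positive, got {observed_g}")
    return (calculated_g - observed_g) / observed_g * 100.0
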
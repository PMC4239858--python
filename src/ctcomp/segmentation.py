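"""Voxel classification and mask-processing operators.

Tissue compartments are defined by radiodensity windows on the HU axis.
Windows are half-open ``[lo, hi)``: the canonical thresholds reuse −50 HU as
both the adipose upper bound and the lean lower bound (and +285 HU between
lean and bone), which would double-count exact boundary values under closed
intervals.  With half-open windows the adipose/lean/bone compartments
partition the HU axis and masks from the same grid are pairwise disjoint.
This shifts counts only for voxels whose HU is exactly a boundary value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import VoxelGrid

logger = logging.getLogger(__name__)

MASK_HU = -1000.0  # value written outside a volume of interest


@dataclass(frozen=True)
class HUWindow:
    """A half-open radiodensity interval ``[lo, hi)`` in Hounsfield units."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi})")

    def contains(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values)
        return (values >= self.lo) & (values < self.hi)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        label = f"[{self.lo:g}, {self.hi:g}) HU"
        return f"{self.name} {label}" if self.name else label


#: canonical segmentation windows
ADIPOSE = HUWindow(-300, -50, "adipose")
ADIPOSE_NARROW = HUWindow(-200, -50, "adipose_narrow")
WATER = HUWindow(-50, 110, "water")
LEAN = HUWindow(-50, 285, "lean")
BODY = HUWindow(-300, 3500, "body")
BONE = HUWindow(285, 2000, "bone")

NAMED_WINDOWS: dict[str, HUWindow] = {
    w.name: w for w in (ADIPOSE, ADIPOSE_NARROW, WATER, LEAN, BODY, BONE)
}


def parse_window(text: str) -> HUWindow:
    """Parse a named window (``adipose``) or an explicit ``LO:HI`` pair."""
    key = text.strip().lower()
    if key in NAMED_WINDOWS:
        return NAMED_WINDOWS[key]
    try:
        lo, hi = (float(tok) for tok in key.split(":"))
    except ValueError:
        raise ValueError(
            f"unknown window {text!r}; use one of {sorted(NAMED_WINDOWS)} or LO:HI"
        ) from None
    return HUWindow(lo, hi)


@dataclass
class TissueMask:
    """Binary 3D field marking the voxels of one tissue compartment."""

    data: np.ndarray
    edge_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.data = (self.data != 0).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def volume_cm3(self) -> float:
        return self.count() * (self.edge_um * 1e-4) ** 3


def segment_window(grid: VoxelGrid, window: HUWindow) -> TissueMask:
    """Classify voxels into a compartment: 1 iff ``lo <= HU < hi``."""
    return TissueMask(
        window.contains(grid.data),
        grid.edge_um,
        provenance={"window": (window.lo, window.hi, window.name), "filters": []},
    )


def apply_voi_mask(grid: VoxelGrid, voi: TissueMask) -> VoxelGrid:
    """Restrict *grid* to a volume of interest.

    Voxels outside *voi* are overwritten with −1000 HU (air); voxels inside
    are unchanged.
    """
    if voi.shape != grid.shape:
        raise ValueError(f"VOI shape {voi.shape} != grid shape {grid.shape}")
    data = np.where(voi.data.astype(bool), grid.data, np.float32(MASK_HU))
    out = VoxelGrid(data, grid.edge_um, grid.origin_mm.copy(), dict(grid.meta))
    out.meta["voi_applied"] = True
    return out


def auto_body_voi(
    grid: VoxelGrid,
    air_threshold: float = -400.0,
    tail_crop: tuple[int, int] | None = None,
) -> TissueMask:
    """Extract the specimen body as the largest above-air connected component.

    The mask is the largest 6-connected component of voxels with
    ``HU > air_threshold``, with internal holes filled slice-wise along z.
    Detached objects (scanner bed, debris) are discarded.  When *tail_crop*
    gives a half-open z-slice range, voxels in that range are removed from
    the mask (the tail of a digital mouse, excluded from whole-body totals).
    """
    above = grid.data > air_threshold
    labels, n = ndimage.label(above)  # default structure = 6-connectivity
    if n == 0:
        raise ValueError("no voxels above air threshold; cannot build body VOI")
    sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
    body = labels == (int(np.argmax(sizes)) + 1)
    for z in range(body.shape[0]):
        body[z] = ndimage.binary_fill_holes(body[z])
    if tail_crop is not None:
        z0, z1 = tail_crop
        body[z0:z1] = False
    return TissueMask(
        body,
        grid.edge_um,
        provenance={
            "method": "auto_body_voi",
            "air_threshold": air_threshold,
            "tail_crop": tail_crop,
        },
    )


def _block_pool(data: np.ndarray, factor: int, reduce: str = "mean") -> np.ndarray:
    """Pool non-overlapping ``factor³`` blocks; odd trailing slices dropped."""
    nz, ny, nx = (s // factor for s in data.shape)
    trimmed = data[: nz * factor, : ny * factor, : nx * factor]
    blocks = trimmed.reshape(nz, factor, ny, factor, nx, factor)
    if reduce == "mean":
        return blocks.mean(axis=(1, 3, 5), dtype=np.float32)
    if reduce == "decimate":  # nearest-voxel decimation, for sensitivity checks
        return np.ascontiguousarray(blocks[:, 0, :, 0, :, 0])
    raise ValueError(f"unknown reduce mode {reduce!r}")


def reduce_by_two(grid: VoxelGrid, reduce: str = "mean") -> VoxelGrid:
    """Halve the frame count on each axis by pooling 2×2×2 blocks.

    Blocks are mean-pooled by default (mimicking partial volume and keeping
    HU semantics); ``reduce='decimate'`` keeps the first voxel of each block
    instead.  Odd trailing slices are dropped and the voxel edge doubles.
    """
    if min(grid.shape) < 2:
        raise ValueError(f"all dimensions must be >= 2 to reduce, got {grid.shape}")
    data = _block_pool(grid.data, 2, reduce)
    meta = dict(grid.meta)
    meta.setdefault("reductions", []).append({"factor": 2, "mode": reduce})
    return VoxelGrid(data, grid.edge_um * 2, grid.origin_mm.copy(), meta)


def resample_to(grid: VoxelGrid, target_edge_um: float, reduce: str = "mean") -> VoxelGrid:
    """Coarsen *grid* to an integer multiple of its voxel edge by mean pooling.

    Emulates reconstructing the same scan at a lower resolution.  The target
    edge must be an integer multiple of the current edge; factor 1 returns a
    copy.
    """
    ratio = target_edge_um / grid.edge_um
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target edge {target_edge_um} um is not an integer multiple of "
            f"{grid.edge_um} um"
        )
    if factor == 1:
        return grid.copy()
    if min(grid.shape) < factor:
        raise ValueError(f"grid shape {grid.shape} too small for factor {factor}")
    data = _block_pool(grid.data, factor, reduce)
    meta = dict(grid.meta)
    meta.setdefault("reductions", []).append({"factor": factor, "mode": reduce})
    return VoxelGrid(data, grid.edge_um * factor, grid.origin_mm.copy(), meta)


def median_filter_mask(mask: TissueMask, distance_mm: float = 1.0) -> TissueMask:
    """Median-filter a binary mask over a cubic neighborhood.

    Each voxel is replaced by the median over a cube of half-width
    ``r = round(1000 · distance_mm / edge_um)`` voxels per axis.  Outside the
    volume counts as background (zero padding), so positive voxels on the
    border may flip off.  A distance smaller than half a voxel (r = 0) is a
    no-op and warns.
    """
    r = int(round(1000.0 * distance_mm / mask.edge_um))
    if r == 0:
        warnings.warn(
            f"median filter distance {distance_mm} mm is below half a voxel at "
            f"{mask.edge_um} um; returning mask unchanged",
            stacklevel=2,
        )
        return TissueMask(mask.data.copy(), mask.edge_um, dict(mask.provenance))
    # median of a binary field over an odd cube = majority vote; a separable
    # box count is exact and far cheaper than a rank filter
    size = 2 * r + 1
    frac = ndimage.uniform_filter(
        mask.data.astype(np.float32), size=size, mode="constant", cval=0.0
    )
    filtered = frac * size**3 > (size**3 // 2) + 0.5  # count >= (N+1)/2, N odd
    prov = dict(mask.provenance)
    prov["filters"] = list(prov.get("filters", [])) + [
        {"median_mm": distance_mm, "half_width_vox": r}
    ]
    return TissueMask(filtered, mask.edge_um, prov)
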
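"""Vascular lumen segmentation of FMA stacks.

The quantification rests on counting microsphere-positive voxels, so the
positivity criterion must be explicit and recorded: every mask carries a
provenance log of the threshold method, its value and every filter applied.
Default method is Otsu on the green channel, with a fixed-threshold escape
hatch; artifact clumps are removed by a conservative minimum component size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import VoxelGeometry
from .stack import ImageStack

logger = logging.getLogger(__name__)

#: Default minimum surviving component size, voxels (≈ one 3×3×3 bead clump).
DEFAULT_MIN_VOXELS = 27

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class VesselMask:
    """Binary 3D lumen mask with geometry and a processing provenance trail."""

    mask: np.ndarray
    geometry: VoxelGeometry
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.mask.shape}")
        self.mask = self.mask.astype(bool, copy=False)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    def with_step(self, mask: np.ndarray, record: dict) -> "VesselMask":
        return VesselMask(mask=mask, geometry=self.geometry,
                          provenance=[*self.provenance, record])


@dataclass
class LabeledComponents:
    """Connected components of a vessel mask (0 = background)."""

    labels: np.ndarray
    n_components: int
    voxel_counts: np.ndarray  # counts[i] = size of component i+1
    connectivity: int
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        if self.n_components != len(self.voxel_counts):
            raise ValueError("voxel_counts length must equal n_components")


def segment_vessels(
    stack: ImageStack,
    channel: str = "green",
    method: str = "otsu",
    manual_threshold: float | None = None,
) -> VesselMask:
    """Threshold an intensity channel into a binary lumen mask.

    ``method='otsu'`` derives the threshold from the channel histogram;
    ``method='fixed'`` uses ``manual_threshold``. A voxel is positive when its
    intensity is strictly greater than the threshold. The resolved threshold
    is recorded in the mask provenance.
    """
    img = stack.channel(channel)
    if method == "otsu":
        lo, hi = img.min(), img.max()
        if lo == hi:
            raise ValueError(
                "cannot Otsu-threshold a constant image; use method='fixed' "
                "with an explicit manual_threshold"
            )
        threshold = float(threshold_otsu(np.asarray(img)))
    elif method == "fixed":
        if manual_threshold is None:
            raise ValueError("method='fixed' requires manual_threshold")
        info_max = (np.iinfo(img.dtype).max
                    if np.issubdtype(img.dtype, np.integer) else float(img.max()))
        if not 0 <= manual_threshold <= info_max:
            raise ValueError(
                f"manual_threshold {manual_threshold} outside the dynamic "
                f"range [0, {info_max}]"
            )
        threshold = float(manual_threshold)
    else:
        raise ValueError(f"unknown method {method!r}; use 'otsu' or 'fixed'")
    mask = np.asarray(img) > threshold
    record = {"step": "segment", "channel": channel, "method": method,
              "threshold": threshold, "positive_voxels": int(mask.sum())}
    logger.info("segment_vessels: %s", record)
    return VesselMask(mask=mask, geometry=stack.geometry, provenance=[record])


def label_components(mask: VesselMask, connectivity: int = 26) -> LabeledComponents:
    """3D connected-component labelling at 6/18/26 lattice connectivity."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(mask.mask, structure=structure)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return LabeledComponents(labels=labels, n_components=int(n),
                             voxel_counts=counts, connectivity=connectivity,
                             geometry=mask.geometry)


def filter_small_components(
    labeled: LabeledComponents, min_voxels: int = DEFAULT_MIN_VOXELS
) -> VesselMask:
    """Drop components smaller than ``min_voxels`` (bead-clump artifacts)."""
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    keep = np.flatnonzero(labeled.voxel_counts >= min_voxels) + 1
    mask = np.isin(labeled.labels, keep) if len(keep) else np.zeros_like(
        labeled.labels, dtype=bool
    )
    removed = int(labeled.n_components - len(keep))
    record = {"step": "filter_small_components", "min_voxels": int(min_voxels),
              "removed_components": removed,
              "removed_voxels": int(labeled.voxel_counts.sum() - mask.sum())}
    logger.info("filter_small_components: %s", record)
    if labeled.n_components > 0 and len(keep) == 0:
        warnings.warn(
            f"min_voxels={min_voxels} removed every component", stacklevel=2
        )
    return VesselMask(mask=mask, geometry=labeled.geometry, provenance=[record])


def exclude_region(mask: VesselMask, roi_mask: np.ndarray) -> VesselMask:
    """Remove an ROI from the vessel mask (the 'negative pen tool' step).

    Output voxels = mask AND NOT roi; the excluded voxel count is recorded.
    Used to strip glomerular tufts before peritubular quantification.
    """
    roi = np.asarray(roi_mask).astype(bool)
    if roi.shape != mask.mask.shape:
        raise ValueError(
            f"ROI shape {roi.shape} does not match mask shape {mask.mask.shape}"
        )
    out = mask.mask & ~roi
    record = {"step": "exclude_region",
              "excluded_voxels": int(mask.voxel_count - np.count_nonzero(out))}
    logger.info("exclude_region: %s", record)
    return mask.with_step(out, record)


def clean_mask(
    stack: ImageStack,
    channel: str = "green",
    method: str = "otsu",
    manual_threshold: float | None = None,
    connectivity: int = 26,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> VesselMask:
    """Segment + despeckle in one call; provenance accumulates both steps."""
    raw = segment_vessels(stack, channel=channel, method=method,
                          manual_threshold=manual_threshold)
    if min_voxels > 0 and raw.voxel_count > 0:
        labeled = label_components(raw, connectivity=connectivity)
        cleaned = filter_small_components(labeled, min_voxels=min_voxels)
        return VesselMask(mask=cleaned.mask, geometry=raw.geometry,
                          provenance=[*raw.provenance, *cleaned.provenance])
    return raw


def rasterize_polygon_rois(
    polygons: list[dict], shape: tuple[int, int, int]
) -> np.ndarray:
    """Rasterise per-slice polygon ROIs into a 3D mask.

    Each entry is ``{"z": int, "vertices": [[x, y], ...]}``. Pixel centres are
    tested with the even-odd rule, half-open convention (a pixel on the lower/
    left boundary is inside, on the upper/right boundary outside).
    """
    from skimage.draw import polygon as draw_polygon

    mask = np.zeros(shape, dtype=bool)
    for entry in polygons:
        z = int(entry["z"])
        if not 0 <= z < shape[0]:
            raise ValueError(f"polygon z={z} outside stack of depth {shape[0]}")
        verts = np.asarray(entry["vertices"], dtype=float)
        rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=shape[1:])
        mask[z, rr, cc] = True
    return mask
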
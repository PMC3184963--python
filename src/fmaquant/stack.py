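"""Image-stack container and TIFF I/O with explicit voxel geometry.

A stack is one or more named channels ("green" for microsphere fluorescence,
"red" for tubular autofluorescence), each a 3D array in (z, y, x) order.
Geometry is never guessed: it comes from a JSON sidecar written next to the
TIFF, or from an explicit override at read time. On conflict the sidecar wins
and a warning is logged — TIFF z-spacing tags are unreliable across dialects,
so the sidecar is the primary record.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .geometry import VoxelGeometry

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("green", "red")


@dataclass
class ImageStack:
    """Multi-channel 3D intensity stack with physical voxel geometry.

    ``channels`` maps channel name -> (z, y, x) array; all channels share one
    shape and one geometry. ``provenance`` is a free-form record of how the
    stack was produced (source path, generator parameters, ...).
    """

    channels: dict[str, np.ndarray]
    geometry: VoxelGeometry
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must have at least one channel")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} is not 3D (shape {arr.shape})")
            if np.issubdtype(arr.dtype, np.floating) and np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            )
        return self.channels[name]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _channel_path(path: Path, name: str, multi: bool) -> Path:
    if not multi:
        return path
    return path.with_name(path.stem + f"_{name}" + path.suffix)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF(s) plus a JSON geometry sidecar.

    Multi-channel stacks are written one file per channel with ``_<name>``
    suffixes; the sidecar records the channel-file mapping, the geometry and
    the provenance. Round-trips bit-exactly through :func:`read_stack`.
    Returns the sidecar path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    multi = len(stack.channels) > 1
    channel_files = {}
    for name, arr in stack.channels.items():
        cpath = _channel_path(path, name, multi)
        tifffile.imwrite(cpath, np.asarray(arr), photometric="minisblack")
        channel_files[name] = cpath.name
    sidecar = {
        **stack.geometry.to_dict(),
        "channels": list(stack.channels),
        "channel_files": channel_files,
        "provenance": _jsonable(stack.provenance),
    }
    spath = _sidecar_path(path)
    spath.write_text(json.dumps(sidecar, indent=2))
    return spath


def read_stack(
    path: str | Path,
    geometry_override: VoxelGeometry | None = None,
) -> ImageStack:
    """Read a stack written by :func:`write_stack` (or any multi-page TIFF).

    Geometry resolution order: JSON sidecar, then ``geometry_override``.
    A bare TIFF with no sidecar and no override is a hard error — the pipeline
    never assumes a pixel size. Axis order is normalised to (z, y, x).
    """
    path = Path(path)
    spath = _sidecar_path(path)
    sidecar = None
    if spath.exists():
        sidecar = json.loads(spath.read_text())

    if sidecar is not None and {"dx", "dy", "dz"} <= set(sidecar):
        geometry = VoxelGeometry.from_dict(sidecar)
        if geometry_override is not None and geometry_override != geometry:
            warnings.warn(
                f"geometry override {geometry_override} conflicts with sidecar "
                f"{geometry}; sidecar wins", stacklevel=2,
            )
        logger.info("geometry for %s resolved from sidecar %s", path, spath)
    elif geometry_override is not None:
        geometry = geometry_override
        logger.info("geometry for %s resolved from explicit override", path)
    else:
        raise ValueError(
            f"no voxel geometry for {path}: missing sidecar fields dx/dy/dz "
            "and no geometry_override given; pixel sizes are never assumed"
        )

    channels: dict[str, np.ndarray] = {}
    if sidecar is not None and "channel_files" in sidecar:
        for name, fname in sidecar["channel_files"].items():
            channels[name] = _read_pages(path.parent / fname)
        provenance = sidecar.get("provenance", {})
    else:
        channels["green"] = _read_pages(path)
        provenance = {}
    provenance = dict(provenance)
    provenance.setdefault("source", str(path))
    return ImageStack(channels=channels, geometry=geometry, provenance=provenance)


def _read_pages(path: Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a z-stack of 2D pages, got shape {arr.shape}")
    return arr


def _jsonable(obj):
    """Best-effort conversion of provenance records to JSON-serialisable form."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj
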
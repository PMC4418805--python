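"""Reading and writing multichannel 3D(+time) image stacks.

The in-memory container is :class:`ImageStack`: a 5D voxel grid in canonical
``(t, c, z, y, x)`` order together with the physical voxel size in micrometers
and ordered channel names.  All downstream modules assume this layout, so axis
normalization happens once, at read time.

Stacks are exchanged as (OME-)TIFF.  On write the voxel size is recorded in
OME pixel-size metadata; on read it is recovered from OME metadata when
present, from TIFF resolution tags otherwise, and an explicit override wins
over both.  A stack without any voxel-size source raises
:class:`~fiberwrap.errors.CalibrationError` — physical calibration is not
optional in this pipeline.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import CalibrationError

__all__ = ["ImageStack", "read_stack", "write_stack"]

_CANONICAL_AXES = "TCZYX"


@dataclasses.dataclass
class ImageStack:
    """A calibrated multichannel voxel grid.

    Parameters
    ----------
    voxels
        Array of shape ``(t, c, z, y, x)`` with finite, non-negative
        intensities.  Lower-dimensional arrays are promoted with singleton
        axes: 3D input is treated as a single-channel single-frame volume,
        4D input as ``(c, z, y, x)``.
    voxel_size
        ``(dz, dy, dx)`` in micrometers, all strictly positive.
    channel_names
        One label per channel, e.g. ``("fiber", "actin", "nuclei")``.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim < 2 or v.ndim > 5:
            raise ValueError(f"expected 2D-5D voxel array, got {v.ndim}D")
        while v.ndim < 5:
            v = v[np.newaxis]
        self.voxels = v
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != v.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {v.shape[1]} channels"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("voxel intensities must be finite")
        if v.size and v.min() < 0:
            raise ValueError("voxel intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """(z, y, x) extent in voxels."""
        return self.voxels.shape[2:]

    def channel(self, name: str, frame: int = 0) -> np.ndarray:
        """Return the 3D ``(z, y, x)`` volume of a named channel at one frame."""
        if name not in self.channel_names:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}")
        return self.voxels[frame, self.channel_names.index(name)]


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/promote a tifffile series to canonical (t, c, z, y, x)."""
    axes = axes.upper().replace("S", "C")  # RGB samples behave as channels
    # tifffile labels unidentifiable dimensions Q or I; assign them to the
    # canonical axes still missing, outermost first.
    missing = [a for a in _CANONICAL_AXES if a not in axes]
    fixed = []
    for a in axes:
        if a in _CANONICAL_AXES and a not in fixed:
            fixed.append(a)
        elif missing:
            fixed.append(missing.pop(0))
        else:
            raise ValueError(f"cannot map TIFF axes {axes!r} onto {_CANONICAL_AXES}")
    axes = "".join(fixed)
    for a in [a for a in _CANONICAL_AXES if a not in axes]:
        data = data[np.newaxis]
        axes = a + axes
    order = [axes.index(a) for a in _CANONICAL_AXES]
    return np.transpose(data, order)


def _voxel_size_from_ome(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tf.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tf.ome_metadata)
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        pixels = image["Pixels"]
        return (
            float(pixels["PhysicalSizeZ"]),
            float(pixels["PhysicalSizeY"]),
            float(pixels["PhysicalSizeX"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def _voxel_size_from_tags(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Fall back to resolution tags (x/y) + ImageJ 'spacing' (z)."""
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    # rationals: pixels per resolution unit
    def _per_unit(r):
        num, den = (r if isinstance(r, tuple) else (r, 1))
        return num / den if den else 0.0

    xppu, yppu = _per_unit(xres), _per_unit(yres)
    if xppu <= 0 or yppu <= 0:
        return None
    unit = page.tags.get("ResolutionUnit")
    scale = 1.0  # assume μm when unit is missing/none
    if unit is not None and getattr(unit.value, "value", unit.value) == 3:  # cm
        scale = 1e4
    dx, dy = scale / xppu, scale / yppu
    dz = None
    if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
        dz = float(tf.imagej_metadata["spacing"])
    if dz is None:
        return None
    return (dz, dy, dx)


def _channel_names_from_meta(tf: tifffile.TiffFile, n: int) -> tuple[str, ...]:
    if tf.ome_metadata:
        try:
            meta = tifffile.xml2dict(tf.ome_metadata)
            image = meta["OME"]["Image"]
            if isinstance(image, list):
                image = image[0]
            channels = image["Pixels"]["Channel"]
            if not isinstance(channels, list):
                channels = [channels]
            names = [c.get("Name") for c in channels]
            if len(names) == n and all(names):
                return tuple(names)
        except (KeyError, TypeError):
            pass
    return tuple(f"ch{i}" for i in range(n))


def read_stack(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a (OME-)TIFF stack into canonical form.

    Voxel size is taken from ``voxel_size_override`` when given, else OME
    metadata, else TIFF resolution tags (with ImageJ z-spacing); if none is
    available a :class:`CalibrationError` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        voxels = _normalize_axes(data, series.axes)
        if voxel_size_override is not None:
            voxel_size = tuple(float(s) for s in voxel_size_override)
        else:
            voxel_size = _voxel_size_from_ome(tf) or _voxel_size_from_tags(tf)
            if voxel_size is None:
                raise CalibrationError(
                    f"{path}: no voxel size in metadata; pass voxel_size_override"
                )
        if channel_names is None:
            channel_names = _channel_names_from_meta(tf, voxels.shape[1])
    return ImageStack(voxels.astype(np.float64, copy=False) if voxels.dtype.kind == "f"
                      else voxels, voxel_size, tuple(channel_names))


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with voxel size and channel names recorded.

    Integer input round-trips bit-exactly; float input is stored as float32.
    """
    path = Path(path)
    dz, dy, dx = stack.voxel_size
    data = stack.voxels
    if data.dtype.kind == "f":
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": _CANONICAL_AXES,
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )
    return path
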
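"""Stack and ROI input/output.

Image stacks are held in :class:`MultiChannelVolume`: one 3D voxel grid per
named channel, all congruent, with a physical voxel spacing given as
``(z, y, x)`` in micrometres.  The canonical on-disk format is OME-TIFF with
axes ``CZYX``; pixel sizes and channel names round-trip through the OME
metadata.  Regions of interest are boolean grids (:class:`RoiMask`) read
either from raster mask images (TIFF/PNG; single-plane masks are broadcast
across z) or from JSON polygon files rasterized with a voxel-centre-inside
rule.

Coordinate conventions
----------------------
All arrays are indexed ``(z, y, x)``, 0-based.  The centre of voxel ``i``
lies at physical coordinate ``i * spacing`` — detection centroids and scene
ground truth use this convention.  Polygon ROIs instead live in continuous
pixel coordinates where voxel ``i`` spans ``[i, i + 1)``; a voxel belongs to
the polygon iff its centre ``i + 0.5`` falls strictly inside.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
import tifffile

from ._errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["MultiChannelVolume", "RoiMask", "read_stack", "write_stack",
           "read_roi", "polygon_mask", "write_table"]


@dataclass
class MultiChannelVolume:
    """A multi-channel 3D image with physical voxel spacing.

    Parameters
    ----------
    channels
        Mapping of channel name to a 3D ``(z, y, x)`` intensity grid.  All
        grids must share one shape; intensities must be finite and >= 0.
    spacing
        Voxel size ``(z, y, x)`` in micrometres; strictly positive.
    metadata
        Free-form key/value pairs (bit depth, saturation level, ...).
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("volume must have at least one channel")
        self.channels = {name: np.asarray(grid) for name, grid in self.channels.items()}
        shapes = {g.shape for g in self.channels.values()}
        if len(shapes) != 1:
            raise ValidationError(f"channels differ in shape: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 3:
            raise ValidationError(f"channel grids must be 3D (z, y, x), got shape {shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive numbers, got {self.spacing}")
        for name, grid in self.channels.items():
            if not np.all(np.isfinite(grid)):
                raise ValidationError(f"channel {name!r} contains non-finite values")
            if np.any(grid < 0):
                raise ValidationError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"no channel {name!r}; available: {self.channel_names}") from None

    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiChannelVolume):
            return NotImplemented
        return (self.channel_names == other.channel_names
                and np.allclose(self.spacing, other.spacing)
                and all(np.array_equal(self.channels[n], other.channels[n])
                        for n in self.channels))


@dataclass
class RoiMask:
    """A named boolean region congruent with a volume's voxel grid."""

    voxels: np.ndarray
    name: str = "ROI"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValidationError(f"ROI mask must be 3D, got {self.voxels.ndim}D")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def require_nonempty(self) -> "RoiMask":
        if self.n_voxels == 0:
            raise ValidationError(f"ROI {self.name!r} contains no voxels")
        return self

    def complement(self, name: str | None = None) -> "RoiMask":
        return RoiMask(~self.voxels, name or f"non-{self.name}")


# ---------------------------------------------------------------------------
# OME-TIFF stacks
# ---------------------------------------------------------------------------

def write_stack(volume: MultiChannelVolume, path: str | Path) -> Path:
    """Write a volume to OME-TIFF, preserving spacing and channel names.

    Integer-typed channels round-trip bit-exactly.  Channels with mixed
    dtypes are promoted to a common dtype before writing.
    """
    path = Path(path)
    names = volume.channel_names
    dtype = np.result_type(*(g.dtype for g in volume.channels.values()))
    data = np.stack([np.asarray(volume.channels[n], dtype=dtype) for n in names])
    sz, sy, sx = volume.spacing
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeZ": sz, "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": sy, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": sx, "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_ome(xml: str) -> tuple[tuple[float, float, float] | None, list[str]]:
    """Extract (spacing, channel names) from OME-XML; missing sizes -> None."""
    root = ET.fromstring(xml)
    spacing = None
    names: list[str] = []
    for elem in root.iter():
        if _strip_ns(elem.tag) == "Pixels":
            sz = elem.get("PhysicalSizeZ")
            sy = elem.get("PhysicalSizeY")
            sx = elem.get("PhysicalSizeX")
            if sy is not None and sx is not None:
                spacing = (float(sz) if sz is not None else 1.0, float(sy), float(sx))
            for child in elem:
                if _strip_ns(child.tag) == "Channel":
                    name = child.get("Name")
                    if name:
                        names.append(name)
            break
    return spacing, names


def read_stack(path: str | Path, channel_names: Sequence[str] | None = None) -> MultiChannelVolume:
    """Read a TIFF / OME-TIFF stack into a :class:`MultiChannelVolume`.

    Axes are resolved to ``(C)ZYX`` from the TIFF series metadata.  Voxel
    spacing is taken from OME ``PhysicalSize*`` attributes when present;
    otherwise it defaults to isotropic 1 µm with a logged warning.

    Parameters
    ----------
    path
        TIFF file to read.
    channel_names
        Names to assign to the channels, in order.  If omitted, names are
        taken from OME metadata, falling back to ``ch0, ch1, ...``.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes
        data = series.asarray()
        ome_spacing, ome_names = (None, [])
        if tf.ome_metadata:
            ome_spacing, ome_names = _parse_ome(tf.ome_metadata)

    # Normalize axis order to CZYX.  Accept the common degenerate layouts.
    allowed = set("CZYXQS")
    if set(axes) - allowed:
        raise FormatError(f"cannot interpret TIFF axes {axes!r} in {path}")
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[None]  # single channel, ZYX
    elif data.ndim == 4:
        # channel axis is wherever 'C' (or unknown 'Q'/'S') sits
        caxis = None
        for cand in "CQS":
            if cand in axes:
                caxis = axes.index(cand)
                break
        if caxis is None:
            raise FormatError(f"ambiguous 4D TIFF axes {axes!r} in {path}")
        data = np.moveaxis(data, caxis, 0)
    else:
        raise FormatError(f"cannot interpret {data.ndim}D TIFF with axes {axes!r} in {path}")

    n_channels = data.shape[0]
    if channel_names is not None:
        if len(channel_names) != n_channels:
            raise FormatError(
                f"{path} holds {n_channels} channel(s) but {len(channel_names)} name(s) given")
        names = list(channel_names)
    elif len(ome_names) == n_channels:
        names = ome_names
    else:
        names = [f"ch{i}" for i in range(n_channels)]

    if ome_spacing is not None:
        spacing = ome_spacing
    else:
        logger.warning("%s has no pixel-size metadata; assuming isotropic 1 µm voxels", path)
        spacing = (1.0, 1.0, 1.0)

    return MultiChannelVolume(
        channels={name: data[i] for i, name in enumerate(names)},
        spacing=spacing,
        metadata={"source": str(path), "dtype": str(data.dtype)},
    )


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------

def polygon_mask(vertices: Sequence[Sequence[float]], shape: tuple[int, int],
                 ) -> np.ndarray:
    """Rasterize one ``(y, x)`` polygon onto a 2D grid.

    A pixel is inside iff its centre ``(y + 0.5, x + 0.5)`` lies strictly
    inside the polygon (half-open convention: an axis-aligned rectangle with
    integer vertices covers exactly its area in pixels).
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValidationError("polygon must be a list of >= 3 (y, x) vertices")
    poly = shapely.Polygon(verts[:, ::-1])  # shapely wants (x, y)
    ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny) + 0.5, np.arange(nx) + 0.5, indexing="ij")
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel())
    return inside.reshape(ny, nx)


def _roi_from_json(path: Path, shape: tuple[int, int, int]) -> np.ndarray:
    spec = json.loads(path.read_text())
    if isinstance(spec, list):  # bare vertex list: one polygon on every slice
        polys = [{"z": None, "vertices": spec}]
    else:
        polys = spec.get("polygons", [])
    if not polys:
        raise ValidationError(f"no polygons found in {path}")
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    for entry in polys:
        plane = polygon_mask(entry["vertices"], (ny, nx))
        z = entry.get("z")
        if z is None:
            mask |= plane[None, :, :]
        else:
            if not 0 <= int(z) < nz:
                raise ValidationError(f"polygon z={z} outside stack of depth {nz}")
            mask[int(z)] |= plane
    return mask


def read_roi(path: str | Path, reference: MultiChannelVolume) -> RoiMask:
    """Read an ROI as a boolean grid congruent with *reference*.

    Accepts a raster mask image (nonzero = inside; a single plane is
    broadcast across all z slices) or a JSON polygon file: either a bare
    ``[[y, x], ...]`` vertex list, or ``{"polygons": [{"z": int|null,
    "vertices": [[y, x], ...]}, ...]}`` where ``z: null`` broadcasts.
    """
    path = Path(path)
    shape = reference.shape
    if path.suffix.lower() == ".json":
        mask = _roi_from_json(path, shape)
    else:
        img = np.asarray(iio.imread(path))
        if img.ndim == 3 and img.shape[-1] in (3, 4) and img.shape[0] != shape[0]:
            img = img[..., 0]  # RGB(A) plane -> first channel
        if img.ndim == 2:
            if img.shape != shape[1:]:
                raise ValidationError(
                    f"mask plane {img.shape} does not match XY dims {shape[1:]}")
            mask = np.broadcast_to(img > 0, shape).copy()
        elif img.ndim == 3:
            if img.shape != shape:
                raise ValidationError(f"mask {img.shape} does not match volume {shape}")
            mask = img > 0
        else:
            raise ValidationError(f"cannot interpret {img.ndim}D image as ROI mask")
    roi = RoiMask(mask, name=path.stem)
    return roi.require_nonempty()


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a results table as CSV, floats rounded to 6 significant digits
    so repeated runs are byte-comparable."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path
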
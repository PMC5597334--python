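"""Permeability-barrier assay quantification.

Two readouts: the mean dye-influx intensity inside an ROI (single-dye
assay), and the Pearson correlation of the 70 kDa and 40 kDa dextran
channels over ROI voxels (dual-dye assay, DDA).  With an intact barrier the
large dye is excluded from the niche, so its PSC-ROI signal decorrelates
from the small dye (low r); barrier loss lets both dyes label the same
surfaces (high r).  ``barrier_contrast`` summarises a specimen as
``r_PSC - r_nonPSC``: negative means intact.

Pearson is computed over voxels, not cells, matching ROI-pixel semantics
of standard colocalization tools; saturated voxels are included by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import DegenerateDataError, ValidationError
from .image_io import MultiChannelVolume, RoiMask

__all__ = ["DyeAssayResult", "ColocalizationResult",
           "mean_roi_intensity", "pearson_colocalization", "barrier_contrast"]


@dataclass(frozen=True)
class DyeAssayResult:
    roi_name: str
    channel: str
    mean_intensity: float
    n_voxels: int


@dataclass(frozen=True)
class ColocalizationResult:
    roi_name: str
    pearson_r: float
    n_voxels: int


def _roi_values(volume: MultiChannelVolume, channel: str, roi: RoiMask) -> np.ndarray:
    if roi.voxels.shape != volume.shape:
        raise ValidationError(
            f"ROI {roi.name!r} shape {roi.voxels.shape} does not match volume {volume.shape}")
    return np.asarray(volume.channel(channel), dtype=float)[roi.voxels]


def mean_roi_intensity(volume: MultiChannelVolume, channel: str,
                       roi: RoiMask, *, exclude_saturated: bool = False
                       ) -> DyeAssayResult:
    """Average fluorescence intensity of *channel* over the ROI voxels."""
    roi.require_nonempty()
    values = _roi_values(volume, channel, roi)
    if exclude_saturated and "saturation" in volume.metadata:
        values = values[values < volume.metadata["saturation"]]
        if values.size == 0:
            raise DegenerateDataError(f"all ROI voxels saturated in {channel!r}")
    return DyeAssayResult(roi_name=roi.name, channel=channel,
                          mean_intensity=float(values.mean()),
                          n_voxels=int(values.size))


def pearson_colocalization(volume: MultiChannelVolume, channel_a: str,
                           channel_b: str, roi: RoiMask) -> ColocalizationResult:
    """Sample Pearson correlation of two channels over ROI voxel pairs.

    Raises
    ------
    DegenerateDataError
        If either channel has zero variance inside the ROI — r is undefined
        there and is never reported as 0.
    """
    roi.require_nonempty()
    a = _roi_values(volume, channel_a, roi)
    b = _roi_values(volume, channel_b, roi)
    if a.size < 2:
        raise ValidationError("Pearson needs at least 2 ROI voxels")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        bad = channel_a if va == 0.0 else channel_b
        raise DegenerateDataError(
            f"channel {bad!r} is constant inside ROI {roi.name!r}; Pearson undefined")
    r = float(da @ db) / np.sqrt(va * vb)
    return ColocalizationResult(roi_name=roi.name, pearson_r=float(np.clip(r, -1.0, 1.0)),
                                n_voxels=int(a.size))


def barrier_contrast(result_psc: ColocalizationResult,
                     result_nonpsc: ColocalizationResult) -> float:
    """``r_PSC - r_nonPSC`` for one specimen; negative = intact barrier."""
    return result_psc.pearson_r - result_nonpsc.pearson_r
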
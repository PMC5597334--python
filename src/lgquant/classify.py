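"""Per-cell marker classification and differentiation indices.

Each detected nucleus is scored against each marker channel by averaging
the channel intensity over a search sphere of ``radius_factor`` times the
mean nuclear radius (1.5x by default) around the nucleus centroid — wide
enough to capture membrane/cytoplasmic stains that surround rather than
fill the nucleus.  Cells whose sphere mean reaches the marker threshold are
called positive; the differentiation index is then the exact ratio of
positive cells to total cells, optionally restricted to an ROI such as the
primary lobe.

Anisotropic voxel spacing is honoured when building the sphere; spheres
clipped at the image border use only in-bounds voxels (border nuclei are
kept, since totals are reported over whole lobes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import DegenerateDataError, MeasurementError, ValidationError
from .detect import NucleusDetection, ThresholdRule
from .image_io import MultiChannelVolume, RoiMask

__all__ = ["ClassificationParams", "CellClassification", "DifferentiationReport",
           "measure_marker", "classify_positive", "differentiation_index",
           "count_positive_cells", "classifications_frame"]


@dataclass(frozen=True)
class ClassificationParams:
    """Knobs of the marker-calling stage.

    ``threshold`` applies Otsu to the distribution of per-cell sphere means
    by default; quantile or absolute rules, and per-marker overrides, are
    available.  A call is positive when the mean is >= the threshold (ties
    count positive).
    """

    radius_factor: float = 1.5
    threshold: ThresholdRule = field(default_factory=ThresholdRule)
    per_marker: Mapping[str, ThresholdRule] = field(default_factory=dict)
    per_nucleus_radius: bool = False
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if not self.radius_factor > 0:
            raise ValidationError("radius_factor must be > 0")
        object.__setattr__(self, "threshold", ThresholdRule.parse(self.threshold))
        object.__setattr__(self, "per_marker",
                           {k: ThresholdRule.parse(v) for k, v in self.per_marker.items()})

    def rule_for(self, marker: str) -> ThresholdRule:
        return self.per_marker.get(marker, self.threshold)


@dataclass(frozen=True)
class CellClassification:
    """One nucleus scored against one marker channel."""

    label: int
    marker: str
    mean_intensity: float
    positive: bool


@dataclass(frozen=True)
class DifferentiationReport:
    """Counts and indices for one specimen (optionally ROI-restricted).

    ``index_exact`` holds the ratio as an exact rational; ``index`` is its
    float value.  ``index * total == positives`` holds exactly.
    """

    total_cells: int
    positives: Mapping[str, int]
    index_exact: Mapping[str, Fraction]
    roi_name: str | None = None
    thresholds: Mapping[str, float] = field(default_factory=dict)

    @property
    def index(self) -> dict[str, float]:
        return {m: float(f) for m, f in self.index_exact.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"marker": m, "total_cells": self.total_cells,
                 "positive": self.positives[m], "index": float(self.index_exact[m]),
                 "roi": self.roi_name or "",
                 "threshold": self.thresholds.get(m, math.nan)}
                for m in self.positives]
        return pd.DataFrame(rows)


def _sphere_mean(channel: np.ndarray, spacing: Sequence[float],
                 center_um: Sequence[float], radius_um: float) -> tuple[float, int]:
    """Mean intensity over voxels whose centre lies within radius of center.

    Voxel centres sit at ``index * spacing``; the sphere is anisotropic in
    index space but spherical in physical space.  Returns (mean, n_voxels).
    """
    shape = channel.shape
    los, his, axes = [], [], []
    for c, n, s in zip(center_um, shape, spacing):
        lo = max(0, int(math.ceil((c - radius_um) / s)))
        hi = min(n - 1, int(math.floor((c + radius_um) / s)))
        if lo > hi:
            return math.nan, 0
        los.append(lo)
        his.append(hi)
        axes.append(np.arange(lo, hi + 1) * s - c)
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    inside = zz ** 2 + yy ** 2 + xx ** 2 <= radius_um ** 2
    n_in = int(inside.sum())
    if n_in == 0:
        return math.nan, 0
    window = channel[los[0]:his[0] + 1, los[1]:his[1] + 1, los[2]:his[2] + 1]
    return float(window[inside].mean()), n_in


def measure_marker(detections: Sequence[NucleusDetection],
                   volume: MultiChannelVolume, marker: str,
                   mean_radius_um: float,
                   params: ClassificationParams | None = None
                   ) -> list[tuple[int, float]]:
    """Mean marker intensity in the search sphere around each nucleus.

    The sphere radius is ``radius_factor * mean_radius_um`` (or, with
    ``per_nucleus_radius``, ``radius_factor`` times each nucleus' own
    equivalent radius).  Returns ``(label, mean_intensity)`` pairs in
    detection order.

    Raises
    ------
    MeasurementError
        If a search sphere contains no voxel centres (spacing coarser than
        the radius), naming the offending nucleus.
    """
    params = params or ClassificationParams()
    if not mean_radius_um > 0:
        raise ValidationError("mean_radius_um must be > 0")
    channel = volume.channel(marker)
    out = []
    for det in detections:
        r = params.radius_factor * (
            det.equivalent_radius_um if params.per_nucleus_radius else mean_radius_um)
        mean, n_in = _sphere_mean(channel, volume.spacing, det.centroid_um, r)
        if n_in == 0:
            raise MeasurementError(
                f"search sphere of nucleus {det.label} (r={r:.3g} µm) contains no voxels")
        out.append((det.label, mean))
    return out


def classify_positive(measurements: Mapping[str, Sequence[tuple[int, float]]],
                      params: ClassificationParams | None = None
                      ) -> tuple[list[CellClassification], dict[str, float]]:
    """Call each cell positive/negative per marker.

    The threshold for each marker is computed over that marker's
    distribution of cell means (Otsu by default); a cell is positive when
    its mean is >= the threshold.  Returns the calls plus the threshold
    actually used per marker, for reporting.

    Raises
    ------
    DegenerateDataError
        If the cell means are constant under the Otsu rule (use an absolute
        threshold for such data).
    """
    params = params or ClassificationParams()
    calls: list[CellClassification] = []
    thresholds: dict[str, float] = {}
    for marker, pairs in measurements.items():
        if not pairs:
            raise ValidationError(f"no measurements for marker {marker!r}")
        means = np.array([m for _, m in pairs], dtype=float)
        thr = params.rule_for(marker).threshold(means)
        thresholds[marker] = thr
        for label, mean in pairs:
            calls.append(CellClassification(label=label, marker=marker,
                                            mean_intensity=float(mean),
                                            positive=bool(mean >= thr)))
    return calls, thresholds


def _labels_in_roi(detections: Sequence[NucleusDetection],
                   spacing: Sequence[float], roi: RoiMask) -> set[int]:
    inside = set()
    shape = roi.voxels.shape
    for det in detections:
        idx = tuple(int(round(c / s)) for c, s in zip(det.centroid_um, spacing))
        idx = tuple(min(max(i, 0), n - 1) for i, n in zip(idx, shape))
        if roi.voxels[idx]:
            inside.add(det.label)
    return inside


def differentiation_index(classifications: Sequence[CellClassification],
                          detections: Sequence[NucleusDetection],
                          *, restrict_to: RoiMask | None = None,
                          spacing: Sequence[float] | None = None,
                          thresholds: Mapping[str, float] | None = None
                          ) -> DifferentiationReport:
    """Ratio of marker-positive cells to total cells, per marker.

    With *restrict_to*, only nuclei whose centroid falls inside the ROI
    enter both numerator and denominator (e.g. restricting to the primary
    lobe).  The ratio is kept as an exact rational alongside its float.

    Raises
    ------
    DegenerateDataError
        If the restriction leaves zero cells: the index is undefined, not 0.
    """
    labels = {d.label for d in detections}
    seen = {c.label for c in classifications}
    if not labels <= seen:
        raise ValidationError(
            f"classifications missing for labels {sorted(labels - seen)[:5]}...")
    if restrict_to is not None:
        if spacing is None:
            raise ValidationError("spacing is required for ROI restriction")
        keep = _labels_in_roi(detections, spacing, restrict_to)
        roi_name = restrict_to.name
    else:
        keep = labels
        roi_name = None
    total = len(keep)
    if total == 0:
        raise DegenerateDataError(
            f"no cells fall inside ROI {roi_name!r}; differentiation index undefined")

    markers = sorted({c.marker for c in classifications})
    positives = {m: 0 for m in markers}
    for c in classifications:
        if c.positive and c.label in keep:
            positives[c.marker] += 1
    return DifferentiationReport(
        total_cells=total,
        positives=positives,
        index_exact={m: Fraction(positives[m], total) for m in markers},
        roi_name=roi_name,
        thresholds=dict(thresholds or {}))


def count_positive_cells(classifications: Sequence[CellClassification],
                         marker: str) -> int:
    """Number of positive calls for one marker (PSC size, circulating
    hemocyte subset counts, ...)."""
    markers = {c.marker for c in classifications}
    if marker not in markers:
        raise ValidationError(f"marker {marker!r} not in classifications ({sorted(markers)})")
    return sum(1 for c in classifications if c.marker == marker and c.positive)


def classifications_frame(classifications: Sequence[CellClassification]) -> pd.DataFrame:
    return pd.DataFrame([{"label": c.label, "marker": c.marker,
                          "mean_intensity": c.mean_intensity,
                          "positive": int(c.positive)} for c in classifications])
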
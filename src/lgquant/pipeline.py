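"""End-to-end analysis of one specimen: count -> measure -> classify -> index."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._errors import DegenerateDataError
from .classify import (CellClassification, ClassificationParams,
                       DifferentiationReport, classify_positive,
                       differentiation_index, measure_marker)
from .detect import (DetectionParams, NucleusDetection, detect_nuclei,
                     estimate_mean_radius)
from .image_io import MultiChannelVolume, RoiMask

__all__ = ["SpecimenResult", "analyze_specimen"]


@dataclass(frozen=True)
class SpecimenResult:
    """Everything the pipeline computed for one stack."""

    detections: tuple[NucleusDetection, ...]
    mean_radius_um: float
    classifications: tuple[CellClassification, ...]
    thresholds: Mapping[str, float]
    report: DifferentiationReport | None

    @property
    def n_cells(self) -> int:
        return len(self.detections)


def analyze_specimen(volume: MultiChannelVolume, nuclear_channel: str,
                     markers: Sequence[str],
                     detection: DetectionParams | None = None,
                     classification: ClassificationParams | None = None,
                     roi: RoiMask | None = None) -> SpecimenResult:
    """Run the full counting/classification chain on one volume.

    Detects nuclei in the nuclear channel, estimates the mean nuclear
    radius, measures each marker within the 1.5x-radius search sphere,
    thresholds the cell means, and computes the differentiation report
    (optionally restricted to *roi*).  With no markers, only detection is
    performed and the report is None.
    """
    detection = detection or DetectionParams()
    classification = classification or ClassificationParams()
    dets = detect_nuclei(volume.channel(nuclear_channel), volume.spacing, detection)
    if not dets:
        raise DegenerateDataError("no nuclei detected; cannot analyze specimen")
    mean_r = estimate_mean_radius(dets)
    if not markers:
        return SpecimenResult(tuple(dets), mean_r, (), {}, None)
    measurements = {m: measure_marker(dets, volume, m, mean_r, classification)
                    for m in markers}
    calls, thresholds = classify_positive(measurements, classification)
    report = differentiation_index(calls, dets, restrict_to=roi,
                                   spacing=volume.spacing, thresholds=thresholds)
    return SpecimenResult(tuple(dets), mean_r, tuple(calls), thresholds, report)
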
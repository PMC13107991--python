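"""Dual-filter TUNEL+ classification and per-sample quantification.

A segmented candidate is called TUNEL-positive when it passes all three of:

* **area filter** — its calibrated area lies inside [min, max] µm²
  (inclusive at both ends), excluding sub-cellular debris and fused
  clusters;
* **overlap filter** — the fraction of its pixels inside the Otsu-thresholded
  TUNEL foreground (the overlap fraction, OF) is at or above the overlap
  threshold, suppressing detections driven by background texture;
* **region restriction** — its rounded centroid lies inside the segmented
  nuclear band (ONL), the region of interest for photoreceptor death.

The same area filter and region rule are applied by the two comparator
counters (threshold-only and instances-without-overlap-gate) so that method
comparisons isolate the classification strategy, not the bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage.measure import regionprops

from .imaging import CalibratedImage, PipelineParams, SamplePair
from .preprocess import BinaryMask, otsu_threshold, percentile_normalize, rolling_ball_subtract
from .segment import LabelMap, SegmentationBackend, WatershedFallbackBackend, segment_instances, segment_onl

__all__ = [
    "CellRecord",
    "SampleResult",
    "SampleProcessing",
    "cell_features",
    "area_filter",
    "overlap_fraction",
    "classify_cells",
    "count_nuclei_in_onl",
    "count_otsu_only",
    "count_stardist_only",
    "process_sample",
    "quantify_sample",
]


@dataclass(frozen=True)
class CellRecord:
    """One segmented candidate cell with its filter verdicts.

    ``is_tunel_positive`` is, by construction, exactly
    ``passed_area and passed_overlap and in_onl``.
    """

    label_id: int
    area_um2: float
    centroid: tuple[float, float]
    overlap_fraction: float = 0.0
    in_onl: bool = False
    passed_area: bool = False
    passed_overlap: bool = False

    @property
    def is_tunel_positive(self) -> bool:
        return self.passed_area and self.passed_overlap and self.in_onl


@dataclass(frozen=True)
class SampleResult:
    """Per-image quantitative output."""

    sample_id: str
    tunel_count: int
    nuclei_count: int
    onl_area_um2: float
    nuclei_density_per_mm2: float


def cell_features(labels: LabelMap) -> list[CellRecord]:
    """Geometry of every instance: calibrated area and centroid.

    area_um2 = pixel count / pixels_per_um²; centroid is the mean pixel
    coordinate (row, col) of the instance.
    """
    um2 = 1.0 / labels.pixels_per_um**2
    return [
        CellRecord(
            label_id=int(rp.label),
            area_um2=float(rp.area) * um2,
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
        )
        for rp in regionprops(labels.labels)
    ]


def area_filter(
    records: Sequence[CellRecord], min_area_um2: float, max_area_um2: float
) -> list[CellRecord]:
    """Set ``passed_area`` on each record; bounds inclusive at both ends."""
    if not min_area_um2 < max_area_um2:
        raise ValueError("min_area_um2 must be < max_area_um2")
    return [
        replace(r, passed_area=(min_area_um2 <= r.area_um2 <= max_area_um2))
        for r in records
    ]


def overlap_fraction(label_pixels: np.ndarray, mask: BinaryMask) -> float:
    """Fraction of a cell's pixels inside the mask foreground.

    ``label_pixels`` is a boolean array of the cell's pixel set (same shape
    as the mask).
    """
    cell = np.asarray(label_pixels, dtype=bool)
    if cell.shape != mask.shape:
        raise ValueError("cell pixel set and mask shapes differ")
    n = int(cell.sum())
    if n == 0:
        raise ValueError("empty cell pixel set")
    return float(np.logical_and(cell, mask.pixels).sum()) / n


def _centroid_in_mask(centroid: tuple[float, float], mask: np.ndarray) -> bool:
    r = min(max(int(round(centroid[0])), 0), mask.shape[0] - 1)
    c = min(max(int(round(centroid[1])), 0), mask.shape[1] - 1)
    return bool(mask[r, c])


def classify_cells(
    records: Sequence[CellRecord],
    labels: LabelMap,
    otsu_mask: BinaryMask,
    onl_mask: BinaryMask,
    params: PipelineParams,
) -> list[CellRecord]:
    """Populate OF, band membership, and the final TUNEL+ verdict.

    OF is computed for all labels in one pass via per-label pixel counts;
    the overlap test is inclusive (OF >= threshold passes). Band membership
    uses the rounded-centroid rule.
    """
    if labels.shape != otsu_mask.shape or labels.shape != onl_mask.shape:
        raise ValueError("label map and masks must share one shape")
    lab = labels.labels
    n = labels.n_labels
    sizes = np.bincount(lab.ravel(), minlength=n + 1).astype(float)
    inter = np.bincount(lab[otsu_mask.pixels].ravel(), minlength=n + 1).astype(float)
    out = []
    for r in records:
        size = sizes[r.label_id]
        of = float(inter[r.label_id] / size) if size > 0 else 0.0
        out.append(
            replace(
                r,
                overlap_fraction=of,
                passed_overlap=(of >= params.overlap_threshold),
                in_onl=_centroid_in_mask(r.centroid, onl_mask.pixels),
                passed_area=(params.min_area_um2 <= r.area_um2 <= params.max_area_um2),
            )
        )
    return out


def count_nuclei_in_onl(nuclei_labels: LabelMap, onl_mask: BinaryMask) -> int:
    """Number of nucleus instances whose rounded centroid lies in the band."""
    if nuclei_labels.shape != onl_mask.shape:
        raise ValueError("label map and mask shapes differ")
    return sum(
        _centroid_in_mask(r.centroid, onl_mask.pixels)
        for r in cell_features(nuclei_labels)
    )


def count_otsu_only(
    otsu_mask: BinaryMask, onl_mask: BinaryMask, params: PipelineParams
) -> int:
    """Threshold-only comparator: 8-connected components of the Otsu mask,
    area-filtered and band-restricted exactly like the main pipeline."""
    if otsu_mask.shape != onl_mask.shape:
        raise ValueError("mask shapes differ")
    import scipy.ndimage as ndi

    lab, n = ndi.label(otsu_mask.pixels, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0
    records = cell_features(LabelMap(lab.astype(np.int32), otsu_mask.pixels_per_um))
    return sum(
        params.min_area_um2 <= r.area_um2 <= params.max_area_um2
        and _centroid_in_mask(r.centroid, onl_mask.pixels)
        for r in records
    )


def count_stardist_only(
    tunel_labels: LabelMap, onl_mask: BinaryMask, params: PipelineParams
) -> int:
    """Instances-only comparator: area filter and band restriction, but no
    overlap-fraction gate. The combined count is a subset of this one."""
    if tunel_labels.shape != onl_mask.shape:
        raise ValueError("label map and mask shapes differ")
    return sum(
        params.min_area_um2 <= r.area_um2 <= params.max_area_um2
        and _centroid_in_mask(r.centroid, onl_mask.pixels)
        for r in cell_features(tunel_labels)
    )


@dataclass
class SampleProcessing:
    """Everything produced for one sample: intermediates, records, counts."""

    sample: SamplePair
    intermediates: dict
    records: list[CellRecord]
    result: SampleResult
    otsu_only_count: int
    stardist_only_count: int


def _preprocess(img: CalibratedImage) -> CalibratedImage:
    return percentile_normalize(rolling_ball_subtract(img))


def process_sample(
    sample: SamplePair,
    params: PipelineParams,
    cell_backend: SegmentationBackend | None = None,
    onl_backend: str = "classical",
    onl_model=None,
) -> SampleProcessing:
    """Run the four pipeline stages on one image pair.

    Stage 1: band (ONL) segmentation of the preprocessed nuclear channel.
    Stage 2: rolling-ball background subtraction (folded into preprocessing
    of both channels, together with percentile normalization).
    Stage 3: instance segmentation of both channels.
    Stage 4: Otsu mask on the preprocessed TUNEL channel, then the dual
    filter (area + overlap fraction) restricted to the band.
    """
    backend = cell_backend if cell_backend is not None else WatershedFallbackBackend()
    ppm = sample.tunel_image.pixels_per_um

    nuc_pre = _preprocess(sample.nuclei_image)
    tun_pre = _preprocess(sample.tunel_image)
    onl_mask = segment_onl(nuc_pre, backend=onl_backend, model=onl_model)

    try:
        otsu_thr, otsu_mask = otsu_threshold(tun_pre)
    except ValueError:  # constant (blank) TUNEL channel: zero foreground
        otsu_thr, otsu_mask = float("nan"), BinaryMask(
            np.zeros(tun_pre.shape, dtype=bool), ppm
        )

    tunel_labels = segment_instances(tun_pre, backend, params.tunel_prob_threshold)
    nuclei_labels = segment_instances(nuc_pre, backend, params.nuclei_prob_threshold)

    records = classify_cells(
        cell_features(tunel_labels), tunel_labels, otsu_mask, onl_mask, params
    )
    tunel_count = sum(r.is_tunel_positive for r in records)
    nuclei_count = count_nuclei_in_onl(nuclei_labels, onl_mask)
    onl_area_um2 = onl_mask.area_um2()
    if onl_area_um2 == 0.0:
        tunel_count = nuclei_count = 0
        density = 0.0
    else:
        density = nuclei_count / (onl_area_um2 / 1e6)

    result = SampleResult(
        sample_id=sample.sample_id,
        tunel_count=tunel_count,
        nuclei_count=nuclei_count,
        onl_area_um2=onl_area_um2,
        nuclei_density_per_mm2=density,
    )
    intermediates = {
        "nuclei_preprocessed": nuc_pre,
        "tunel_preprocessed": tun_pre,
        "onl_mask": onl_mask,
        "otsu_threshold": otsu_thr,
        "otsu_mask": otsu_mask,
        "tunel_labels": tunel_labels,
        "nuclei_labels": nuclei_labels,
    }
    return SampleProcessing(
        sample=sample,
        intermediates=intermediates,
        records=records,
        result=result,
        otsu_only_count=count_otsu_only(otsu_mask, onl_mask, params),
        stardist_only_count=count_stardist_only(tunel_labels, onl_mask, params),
    )


def quantify_sample(
    sample: SamplePair,
    params: PipelineParams,
    cell_backend: SegmentationBackend | None = None,
    onl_backend: str = "classical",
) -> SampleResult:
    """Convenience wrapper returning only the per-sample result."""
    return process_sample(
        sample, params, cell_backend=cell_backend, onl_backend=onl_backend
    ).result
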
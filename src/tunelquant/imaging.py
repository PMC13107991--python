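"""Calibrated image I/O, pipeline parameters, and result/visualization writers.

Images are single-channel grayscale TIFFs (8- or 16-bit), one directory per
channel (nuclear counterstain and TUNEL), with pairs matched by filename stem.
All physical thresholds in the pipeline are expressed in micrometers, so every
image carries its own spatial calibration (pixels per micrometer). The
calibration is always supplied by the user, never read from TIFF metadata.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "CalibratedImage",
    "PipelineParams",
    "SamplePair",
    "PROFILES",
    "discover_pairs",
    "read_calibrated",
    "write_results_csv",
    "write_cell_records_csv",
    "write_visualizations",
]

#: Header of Results/results.csv, in output order.
RESULTS_COLUMNS = (
    "sample_id",
    "tunel_count",
    "nuclei_count",
    "onl_area_um2",
    "nuclei_density_per_mm2",
)


@dataclass(frozen=True)
class CalibratedImage:
    """A single-channel image together with its spatial calibration.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities. Raw reads are integer
        (preserved bit-exactly); processed stages may hold floats.
    pixels_per_um
        Spatial calibration in pixels per micrometer (> 0).
    source_path
        Identifier for provenance; empty string for in-memory images.
    """

    pixels: np.ndarray
    pixels_per_um: float
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not self.pixels_per_um > 0:
            raise ValueError("pixels_per_um must be > 0")
        if np.issubdtype(px.dtype, np.integer) and px.size and px.min() < 0:
            raise ValueError("raw intensities must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Same calibration and provenance, new pixel data."""
        return CalibratedImage(pixels, self.pixels_per_um, self.source_path)

    @property
    def um2_per_px(self) -> float:
        return 1.0 / self.pixels_per_um**2


@dataclass(frozen=True)
class PipelineParams:
    """The eight user-facing pipeline parameters plus a seed.

    The two bundled profiles mirror the published calibrations: ``primary``
    (mouse retinal detachment, typical TUNEL+ soma 10-60 µm²) and
    ``small-cell`` (cohorts with smaller TUNEL+ cell bodies, 4-15 µm² with
    tighter probability and overlap gates).
    """

    nuclei_dir: Path | None = None
    tunel_dir: Path | None = None
    pixels_per_um: float = 1.5
    min_area_um2: float = 10.0
    max_area_um2: float = 60.0
    nuclei_prob_threshold: float = 0.01
    tunel_prob_threshold: float = 0.5
    overlap_threshold: float = 0.6
    seed: int | None = None

    def __post_init__(self) -> None:
        errors = []
        if not self.pixels_per_um > 0:
            errors.append("pixels_per_um must be > 0")
        if not self.min_area_um2 > 0:
            errors.append("min_area_um2 must be > 0")
        if not self.min_area_um2 < self.max_area_um2:
            errors.append("min_area_um2 must be < max_area_um2")
        for name in ("nuclei_prob_threshold", "tunel_prob_threshold", "overlap_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must lie in [0, 1]")
        if errors:
            raise ValueError("invalid pipeline parameters: " + "; ".join(errors))

    def replace(self, **kwargs) -> "PipelineParams":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_profile(cls, name: str, **overrides) -> "PipelineParams":
        try:
            base = PROFILES[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter profile {name!r}; available: {sorted(PROFILES)}"
            ) from None
        return cls(**{**base, **overrides})


#: Published parameter calibrations.
PROFILES: dict[str, dict] = {
    "primary": dict(
        min_area_um2=10.0,
        max_area_um2=60.0,
        nuclei_prob_threshold=0.01,
        tunel_prob_threshold=0.5,
        overlap_threshold=0.6,
    ),
    "small-cell": dict(
        min_area_um2=4.0,
        max_area_um2=15.0,
        nuclei_prob_threshold=0.01,
        tunel_prob_threshold=0.65,
        overlap_threshold=0.65,
    ),
}


@dataclass(frozen=True)
class SamplePair:
    """A filename-matched (nuclear stain, TUNEL) image pair."""

    sample_id: str
    nuclei_image: CalibratedImage
    tunel_image: CalibratedImage

    def __post_init__(self) -> None:
        if self.nuclei_image.shape != self.tunel_image.shape:
            raise ValueError(
                f"sample {self.sample_id!r}: nuclei image shape "
                f"{self.nuclei_image.shape} != TUNEL image shape {self.tunel_image.shape}"
            )


@dataclass(frozen=True)
class PairPaths:
    """Lightweight descriptor from :func:`discover_pairs` (images not loaded)."""

    sample_id: str
    nuclei_path: Path
    tunel_path: Path


_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


def _stems(directory: Path) -> dict[str, Path]:
    out: dict[str, Path] = {}
    for p in sorted(directory.iterdir()):
        if not p.is_file() or p.suffix.lower() not in _IMAGE_SUFFIXES:
            continue
        if p.stem in out:
            raise ValueError(
                f"duplicate filename stem {p.stem!r} in {directory} "
                f"({out[p.stem].name} vs {p.name})"
            )
        out[p.stem] = p
    return out


def discover_pairs(nuclei_dir: Path | str, tunel_dir: Path | str) -> list[PairPaths]:
    """Match image files across the two channel directories by filename stem.

    Matching is exact and case-sensitive on the stem (name minus extension).
    Unmatched files on either side are reported via :class:`UserWarning`;
    an empty intersection raises.
    """
    nuclei_dir, tunel_dir = Path(nuclei_dir), Path(tunel_dir)
    for d in (nuclei_dir, tunel_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"not a directory: {d}")
    nuc, tun = _stems(nuclei_dir), _stems(tunel_dir)
    common = sorted(set(nuc) & set(tun))
    for stem in sorted(set(nuc) - set(tun)):
        warnings.warn(f"nuclei image {stem!r} has no TUNEL partner", UserWarning, stacklevel=2)
    for stem in sorted(set(tun) - set(nuc)):
        warnings.warn(f"TUNEL image {stem!r} has no nuclei partner", UserWarning, stacklevel=2)
    if not common:
        raise ValueError(f"no pairs: {nuclei_dir} and {tunel_dir} share no filename stems")
    return [PairPaths(s, nuc[s], tun[s]) for s in common]


def read_calibrated(path: Path | str, pixels_per_um: float) -> CalibratedImage:
    """Read a single-channel grayscale image and attach the calibration.

    Integer intensities are preserved bit-exactly. Multi-channel (RGB/RGBA)
    input is rejected; extract the relevant channel upstream.
    """
    path = Path(path)
    px = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else None
    if px is None:
        import imageio.v3 as iio

        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3:
        raise ValueError(
            f"{path}: image has {px.shape[-1]} channels; this pipeline takes "
            "single-channel grayscale input — extract the channel of interest first"
        )
    if px.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {px.shape}")
    return CalibratedImage(px, pixels_per_um, str(path))


def load_pair(pp: PairPaths, pixels_per_um: float) -> SamplePair:
    return SamplePair(
        pp.sample_id,
        read_calibrated(pp.nuclei_path, pixels_per_um),
        read_calibrated(pp.tunel_path, pixels_per_um),
    )


def write_results_csv(results: Sequence, out_dir: Path | str) -> Path:
    """Write per-sample quantification to ``<out_dir>/Results/results.csv``.

    One row per sample in input order; columns are exactly
    ``sample_id, tunel_count, nuclei_count, onl_area_um2, nuclei_density_per_mm2``.
    """
    import pandas as pd

    results_dir = Path(out_dir) / "Results"
    results_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "sample_id": r.sample_id,
            "tunel_count": r.tunel_count,
            "nuclei_count": r.nuclei_count,
            "onl_area_um2": r.onl_area_um2,
            "nuclei_density_per_mm2": r.nuclei_density_per_mm2,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=list(RESULTS_COLUMNS))
    out = results_dir / "results.csv"
    df.to_csv(out, index=False, float_format="%.10g")
    return out


def write_cell_records_csv(sample_id: str, records: Sequence, out_dir: Path | str) -> Path:
    """Optional audit export: one row per segmented candidate."""
    import pandas as pd

    results_dir = Path(out_dir) / "Results"
    results_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "label_id": r.label_id,
                "area_um2": r.area_um2,
                "overlap_fraction": r.overlap_fraction,
                "in_onl": r.in_onl,
                "passed_area": r.passed_area,
                "passed_overlap": r.passed_overlap,
                "is_tunel_positive": r.is_tunel_positive,
            }
            for r in records
        ]
    )
    out = results_dir / f"{sample_id}_cells.csv"
    df.to_csv(out, index=False, float_format="%.10g")
    return out


def _imshow(ax, img, title, cmap="gray"):
    ax.imshow(img, cmap=cmap, interpolation="nearest")
    ax.set_title(title, fontsize=8)
    ax.set_axis_off()


def write_visualizations(
    sample: SamplePair,
    intermediates: dict,
    records: Sequence,
    out_dir: Path | str,
) -> list[Path]:
    """Write the per-sample quality-control images.

    Seven individual PNGs — raw nuclei, raw TUNEL, band-mask overlay,
    preprocessed TUNEL, Otsu mask, candidate label map, final TUNEL+ overlay
    annotated with the count — plus one combined 2x3 panel of the last six
    (the two raw channels carry no pipeline information beyond the overlay
    stages, so the panel shows raw TUNEL through final overlay).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    viz = Path(out_dir) / "Visualizations"
    viz.mkdir(parents=True, exist_ok=True)
    sid = sample.sample_id

    nuc = sample.nuclei_image.pixels
    tun = sample.tunel_image.pixels
    onl = intermediates["onl_mask"].pixels
    pre = intermediates["tunel_preprocessed"].pixels
    otsu = intermediates["otsu_mask"].pixels
    labels = intermediates["tunel_labels"].labels
    positives = [r for r in records if r.is_tunel_positive]

    def overlay_mask(base):
        rgb = np.stack([base] * 3, axis=-1).astype(float)
        rgb /= max(rgb.max(), 1e-12)
        rgb[onl, 1] = 0.5 * rgb[onl, 1] + 0.5
        return rgb

    def final_overlay():
        rgb = np.stack([tun] * 3, axis=-1).astype(float)
        rgb /= max(rgb.max(), 1e-12)
        for r in positives:
            rr, cc = int(round(r.centroid[0])), int(round(r.centroid[1]))
            rgb[max(0, rr - 3) : rr + 4, max(0, cc - 3) : cc + 4, 0] = 1.0
        return rgb

    panels = [
        ("raw_nuclei", nuc, "gray", f"{sid}: nuclei"),
        ("raw_tunel", tun, "gray", f"{sid}: TUNEL"),
        ("onl_overlay", overlay_mask(nuc), None, "ONL mask"),
        ("tunel_preprocessed", pre, "gray", "preprocessed TUNEL"),
        ("otsu_mask", otsu, "gray", "Otsu mask"),
        ("labels", np.where(labels > 0, labels, np.nan), "nipy_spectral", "candidates"),
        ("final_overlay", final_overlay(), None, f"TUNEL+ = {len(positives)}"),
    ]

    paths = []
    for key, img, cmap, title in panels:
        fig, ax = plt.subplots(figsize=(4, 3), dpi=72)
        _imshow(ax, img, title, cmap=cmap or "viridis")
        p = viz / f"{sid}_{key}.png"
        fig.savefig(p, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)

    fig, axes = plt.subplots(2, 3, figsize=(9, 5), dpi=72)
    for ax, (key, img, cmap, title) in zip(axes.ravel(), panels[1:]):
        _imshow(ax, img, title, cmap=cmap or "viridis")
    p = viz / f"{sid}_panel.png"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
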
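"""Synthetic two-channel retinal micrographs with exact ground truth.

Each sample emulates a cryosection acquisition: a dense, gently curved band
of nuclei (the photoreceptor outer nuclear layer) on a darker surround in
the nuclear-stain channel, and sparse bright apoptotic cells of known area
inside that band in the TUNEL channel, together with the stressors the
pipeline must survive — sub-threshold debris, super-threshold clusters,
an additive illumination ramp, Poisson shot noise and Gaussian read noise,
16-bit quantization.

Planted objects are rendered as flat-top disks with a soft Gaussian edge.
This profile has a threshold-stable pixel area (the area above any cut
between ~20% and ~80% of peak height is close to the plateau area), so a
planted cell has a well-defined size in µm²: the generator measures each
object's area on its own noiseless rendering at half maximum and calibrates
the disk radius until that measurement is within 2% of the requested area.
Ground truth therefore records what an idealized observer would measure,
independent of any downstream threshold choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi

from .imaging import CalibratedImage, SamplePair
from .preprocess import BinaryMask

__all__ = [
    "SyntheticSpec",
    "PlantedObject",
    "GroundTruth",
    "generate_sample",
    "generate_panel",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic sample.

    Defaults mirror the acquisition regime of the modeled experiments:
    ~1.5 px/µm calibration, a sinuous nuclear band ~40 µm thick occupying
    roughly an eighth of the frame, TUNEL+ somata of 12-50 µm², and debris
    deliberately planted on both sides of the 10-60 µm² area filter.
    """

    shape: tuple[int, int] = (512, 672)
    pixels_per_um: float = 1.5
    band_thickness_um: float = 40.0
    band_wave_amplitude_um: float = 16.0
    band_cycles: float = 1.25
    n_onl_nuclei: int = 180
    n_outside_nuclei: int = 30
    n_tunel_pos: int = 12
    tunel_area_range_um2: tuple[float, float] = (12.0, 50.0)
    nucleus_area_um2: float = 15.0
    n_debris_small: int = 6
    n_debris_large: int = 3
    debris_small_area_um2: tuple[float, float] = (0.8, 2.5)
    debris_large_area_um2: tuple[float, float] = (75.0, 130.0)
    illum_gradient: float = 0.15
    noise_sd: float = 150.0
    poisson: bool = True
    poisson_gain: float = 20.0
    background_offset: float = 800.0
    nuclei_amplitude: float = 12000.0
    tunel_amplitude: float = 20000.0
    amplitude_jitter: float = 0.15
    edge_sigma_px: float = 0.4
    sample_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tunel_area_range_um2
        if not (0 < lo < hi):
            raise ValueError("tunel_area_range_um2 must satisfy 0 < lo < hi")
        for name in ("n_onl_nuclei", "n_outside_nuclei", "n_tunel_pos",
                     "n_debris_small", "n_debris_large"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.pixels_per_um > 0:
            raise ValueError("pixels_per_um must be > 0")


@dataclass(frozen=True)
class PlantedObject:
    """One planted blob: center (row, col), measured area, and kind."""

    center: tuple[float, float]
    radius_px: float
    area_um2: float
    kind: str  # "tunel", "nucleus", "debris_small", "debris_large"
    in_band: bool


@dataclass(frozen=True)
class GroundTruth:
    """Exact generative truth for one sample."""

    band_mask: BinaryMask
    nuclei: list[PlantedObject]
    tunel_pos: list[PlantedObject]
    debris: list[PlantedObject]

    @property
    def expected_counts(self) -> tuple[int, int]:
        """(TUNEL+ cells, nuclei inside the band)."""
        return len(self.tunel_pos), sum(o.in_band for o in self.nuclei)


def _render_blob(
    radius_px: float, edge_sigma_px: float, offset: tuple[float, float] = (0.0, 0.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-peak flat-top blob patch and its half-maximum mask.

    Radial profile ``Phi((r - d)/sigma)`` — a disk with an erf-shaped soft
    edge whose half-maximum contour sits at radius r. ``offset`` is the
    subpixel position of the blob center within its central pixel.
    """
    from scipy.special import erf

    half = int(np.ceil(radius_px + 4 * edge_sigma_px)) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    d = np.hypot(yy - offset[0], xx - offset[1])
    patch = 0.5 * (1.0 + erf((radius_px - d) / (edge_sigma_px * np.sqrt(2.0))))
    peak = patch.max()
    if peak <= 0:
        raise ValueError("degenerate blob rendering")
    mask = patch >= 0.5 * peak
    return patch / peak, mask


def _calibrated_blob(
    area_um2: float, ppm: float, edge_sigma_px: float, offset: tuple[float, float] = (0.0, 0.0)
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Blob whose half-maximum pixel area best matches the target.

    Proportional iteration followed by a fine local radius scan; pixel-grid
    quantization limits the match to ~1 px of area, i.e. well within the
    generator's ±10% planted-area contract for areas of a few µm² and up.
    """
    target_px = area_um2 * ppm * ppm
    r = max(0.6, np.sqrt(target_px / np.pi))
    for _ in range(8):
        _, mask = _render_blob(r, edge_sigma_px, offset)
        measured = float(mask.sum())
        if measured > 0 and abs(measured - target_px) / target_px <= 0.02:
            break
        r = max(0.5, r * np.sqrt(target_px / max(measured, 1.0)))
    best = None
    for dr in np.arange(-0.5, 0.51, 0.1):
        cand = r + dr
        if cand < 0.4:
            continue
        patch, mask = _render_blob(cand, edge_sigma_px, offset)
        err = abs(float(mask.sum()) - target_px)
        if best is None or err < best[0]:
            best = (err, patch, mask, cand)
    _, patch, mask, r = best
    measured_um2 = float(mask.sum()) / (ppm * ppm)
    return patch, mask, r, measured_um2


def _stamp(canvas: np.ndarray, patch: np.ndarray, center: tuple[int, int], amplitude: float):
    half = patch.shape[0] // 2
    r0, c0 = center
    rs, re = r0 - half, r0 + half + 1
    cs, ce = c0 - half, c0 + half + 1
    pr0, pc0 = max(0, -rs), max(0, -cs)
    rs, cs = max(rs, 0), max(cs, 0)
    re, ce = min(re, canvas.shape[0]), min(ce, canvas.shape[1])
    canvas[rs:re, cs:ce] += amplitude * patch[pr0 : pr0 + (re - rs), pc0 : pc0 + (ce - cs)]


class _Placer:
    """Sequential hard-disk placement with a minimum edge-to-edge gap.

    The default half-pixel gap keeps planted half-maximum masks strictly
    disjoint while letting neighboring cells sit nearly adjacent, as nuclei
    do in the packed outer nuclear layer; close pairs are exactly the cases
    that fuse under plain threshold-and-count analysis.
    """

    def __init__(self, rng: np.random.Generator, gap_px: float = 0.5, max_tries: int = 2000):
        self.rng = rng
        self.gap = gap_px
        self.max_tries = max_tries
        self.centers: list[tuple[float, float]] = []
        self.radii: list[float] = []

    def place(self, radius_px: float, region_sampler) -> tuple[float, float]:
        centers = np.array(self.centers) if self.centers else np.empty((0, 2))
        radii = np.array(self.radii)
        for _ in range(self.max_tries):
            r, c = region_sampler()
            if centers.size:
                d = np.hypot(centers[:, 0] - r, centers[:, 1] - c)
                if np.any(d < radii + radius_px + self.gap):
                    continue
            self.centers.append((r, c))
            self.radii.append(radius_px)
            return float(r), float(c)
        raise RuntimeError(
            "infeasible packing: could not place an object after "
            f"{self.max_tries} tries (too many/too large objects for the band)"
        )


def _band_geometry(spec: SyntheticSpec, rng: np.random.Generator):
    rows, cols = spec.shape
    ppm = spec.pixels_per_um
    half_px = spec.band_thickness_um * ppm / 2.0
    amp_px = spec.band_wave_amplitude_um * ppm
    phase = rng.uniform(0, 2 * np.pi)
    x = np.arange(cols)
    center = rows / 2.0 + amp_px * np.sin(2 * np.pi * spec.band_cycles * x / cols + phase)
    band = np.abs(np.arange(rows)[:, None] - center[None, :]) <= half_px
    return band, center, half_px


def generate_sample(spec: SyntheticSpec) -> tuple[SamplePair, GroundTruth]:
    """Render one calibrated (nuclear, TUNEL) image pair plus ground truth.

    Deterministic for a fixed spec (including its seed). Raises if the
    requested object load cannot be packed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    ppm = spec.pixels_per_um
    band, band_center, band_half = _band_geometry(spec, rng)

    nuc_canvas = np.zeros(spec.shape)
    tun_canvas = np.zeros(spec.shape)
    nuclei: list[PlantedObject] = []
    tunel_pos: list[PlantedObject] = []
    debris: list[PlantedObject] = []

    def in_band_sampler(margin_px: float):
        def sample():
            c = rng.uniform(margin_px, cols - margin_px)
            half = band_half - margin_px
            r = band_center[int(c)] + rng.uniform(-half, half)
            return r, c

        return sample

    def outside_sampler(margin_px: float):
        def sample():
            for _ in range(100):
                r = rng.uniform(margin_px, rows - margin_px)
                c = rng.uniform(margin_px, cols - margin_px)
                if abs(r - band_center[int(c)]) > band_half + margin_px:
                    return r, c
            return rng.uniform(0, rows), rng.uniform(0, cols)

        return sample

    def jittered(amplitude: float) -> float:
        return amplitude * (1.0 + rng.uniform(-spec.amplitude_jitter, spec.amplitude_jitter))

    def plant(canvas, placer, target_area_um2, sampler_margin_extra, amplitude, sampler_kind):
        """Place, calibrate at the subpixel offset, stamp; return the object geometry."""
        r0 = max(0.6, np.sqrt(target_area_um2 * ppm * ppm / np.pi))
        sampler = (
            in_band_sampler(r0 + sampler_margin_extra)
            if sampler_kind == "band"
            else outside_sampler(r0 + sampler_margin_extra)
        )
        r_f, c_f = placer.place(r0, sampler)
        ri, ci = int(round(r_f)), int(round(c_f))
        offset = (r_f - ri, c_f - ci)
        patch, _, r_px, area_meas = _calibrated_blob(
            target_area_um2, ppm, spec.edge_sigma_px, offset
        )
        _stamp(canvas, patch, (ri, ci), amplitude)
        return (r_f, c_f), r_px, area_meas

    # --- TUNEL channel objects (positives + debris share one exclusion set)
    tun_placer = _Placer(rng)
    for _ in range(spec.n_tunel_pos):
        area = rng.uniform(*spec.tunel_area_range_um2)
        center, r_px, area_meas = plant(
            tun_canvas, tun_placer, area, 3.0, jittered(spec.tunel_amplitude), "band"
        )
        tunel_pos.append(PlantedObject(center, r_px, area_meas, "tunel", True))
    for kind, n, area_range in (
        ("debris_small", spec.n_debris_small, spec.debris_small_area_um2),
        ("debris_large", spec.n_debris_large, spec.debris_large_area_um2),
    ):
        for _ in range(n):
            area = rng.uniform(*area_range)
            center, r_px, area_meas = plant(
                tun_canvas, tun_placer, area, 3.0, jittered(spec.tunel_amplitude), "band"
            )
            debris.append(PlantedObject(center, r_px, area_meas, kind, True))

    # --- nuclear channel objects (band nuclei, outside nuclei, dying nuclei
    #     co-located with the TUNEL+ blobs)
    nuc_placer = _Placer(rng)
    for o in tunel_pos:
        ri, ci = int(round(o.center[0])), int(round(o.center[1]))
        offset = (o.center[0] - ri, o.center[1] - ci)
        patch, _, nuc_r, nuc_area = _calibrated_blob(
            spec.nucleus_area_um2, ppm, spec.edge_sigma_px, offset
        )
        nuc_placer.centers.append(o.center)
        nuc_placer.radii.append(nuc_r)
        _stamp(nuc_canvas, patch, (ri, ci), jittered(spec.nuclei_amplitude))
        nuclei.append(PlantedObject(o.center, nuc_r, nuc_area, "nucleus", True))
    for i in range(spec.n_onl_nuclei + spec.n_outside_nuclei):
        in_band = i < spec.n_onl_nuclei
        center, nuc_r, nuc_area = plant(
            nuc_canvas,
            nuc_placer,
            spec.nucleus_area_um2,
            2.0,
            jittered(spec.nuclei_amplitude),
            "band" if in_band else "outside",
        )
        nuclei.append(PlantedObject(center, nuc_r, nuc_area, "nucleus", in_band))

    # --- illumination, noise, quantization
    ramp_unit = (np.arange(rows)[:, None] + np.arange(cols)[None, :]) / (rows + cols - 2)

    def finish(canvas: np.ndarray, amplitude: float) -> np.ndarray:
        img = canvas + spec.background_offset + spec.illum_gradient * amplitude * ramp_unit
        if spec.poisson:
            img = rng.poisson(np.clip(img, 0, None) / spec.poisson_gain) * spec.poisson_gain
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)

    pair = SamplePair(
        spec.sample_id,
        CalibratedImage(finish(nuc_canvas, spec.nuclei_amplitude), ppm, f"{spec.sample_id}:nuclei"),
        CalibratedImage(finish(tun_canvas, spec.tunel_amplitude), ppm, f"{spec.sample_id}:tunel"),
    )
    truth = GroundTruth(
        band_mask=BinaryMask(band, ppm),
        nuclei=nuclei,
        tunel_pos=tunel_pos,
        debris=debris,
    )
    return pair, truth


def generate_panel(
    n_samples: int,
    count_range: tuple[int, int] = (5, 60),
    seed: int = 0,
    out_dir: Path | str | None = None,
    base_spec: SyntheticSpec = SyntheticSpec(),
) -> list[tuple[SamplePair, GroundTruth]]:
    """Generate a cohort of samples with planted counts drawn uniformly.

    Stands in for a 30-50 image validation cohort. When ``out_dir`` is
    given, TIFF pairs are written under ``nuclei/`` and ``tunel/`` and the
    per-sample truth under ``truth.csv`` (sample_id, true_tunel,
    true_nuclei_in_band), so the panel can be consumed by the CLI exactly
    like real data.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lo, hi = count_range
    if not (0 <= lo <= hi):
        raise ValueError("invalid count_range")
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_samples):
        n_pos = int(rng.integers(lo, hi + 1))
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base_spec, n_tunel_pos=n_pos, seed=child_seed, sample_id=f"sample_{i:03d}"
        )
        panel.append(generate_sample(spec))

    if out_dir is not None:
        import pandas as pd
        import tifffile

        out_dir = Path(out_dir)
        (out_dir / "nuclei").mkdir(parents=True, exist_ok=True)
        (out_dir / "tunel").mkdir(parents=True, exist_ok=True)
        rows = []
        for pair, truth in panel:
            tifffile.imwrite(out_dir / "nuclei" / f"{pair.sample_id}.tif", pair.nuclei_image.pixels)
            tifffile.imwrite(out_dir / "tunel" / f"{pair.sample_id}.tif", pair.tunel_image.pixels)
            tun, nuc = truth.expected_counts
            rows.append(
                {"sample_id": pair.sample_id, "true_tunel": tun, "true_nuclei_in_band": nuc}
            )
        pd.DataFrame(rows).to_csv(out_dir / "truth.csv", index=False)
    return panel
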
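"""Tubule ring detection and doublet assembly from cross-section images.

The detector assumes one pre-cropped axoneme per grayscale image, dark
tubule walls on a light background.  Rings are found with annular
matched filters (mean wall darkness on a circle minus the interior disk
mean) evaluated over a radius band, followed by non-maximum suppression
and sub-pixel peak refinement.  Candidates are paired into doublets by
mutual nearest neighbor at the expected A–B center spacing; within a
pair the complete ring (higher perimeter completeness) is the A-tubule,
the C-shaped ring the B-tubule.

Image coordinates (origin top-left, y down) are converted to the
mathematical frame (y up, origin at the canvas center) before any
geometry, matching the convention of :mod:`axosym.synthetic`.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import map_coordinates
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max

from axosym.defects import DEFAULT_ARM_MIN, call_section_defects
from axosym.geometry import (
    DEFAULT_ECCENTRICITY_CAP,
    DEFAULT_KAPPA,
    CrossSection,
    DoubletObservation,
    assess_section,
    assessment_report,
)

__all__ = [
    "TubuleCandidate",
    "DetectionConfig",
    "detect_tubules",
    "assemble_section",
    "analyze_image",
]


@dataclass(frozen=True)
class TubuleCandidate:
    """One putative microtubule ring (math-frame center, pixels)."""

    center: tuple[float, float]
    radius: float
    completeness: float  # fraction of perimeter with wall signal, [0, 1]
    contrast: float  # mean wall darkness along the ring


@dataclass(frozen=True)
class DetectionConfig:
    """All detection/scoring thresholds in one place.

    Lengths in pixels; defaults assume the 2 nm/px rendering scale of the
    synthetic generator (A-tubule radius 12 px, B-tubule 14 px).
    """

    pixel_size_nm: float = 2.0
    r_min: float = 7.0
    r_max: float = 16.0
    r_step: float = 1.0
    wall_px: float = 4.0
    completeness_min: float = 0.65
    r_a: float = 12.0
    r_b: float = 14.0
    kappa: float = DEFAULT_KAPPA
    arm_min: int = DEFAULT_ARM_MIN
    pairing_tol: float = 0.3
    completeness_tie: float = 0.05
    min_separation_factor: float = 1.2
    peak_threshold_frac: float = 0.2
    central_frac: float = 0.5
    fit_kind: str = "auto"
    eccentricity_cap: float = DEFAULT_ECCENTRICITY_CAP

    @classmethod
    def from_yaml(cls, path) -> "DetectionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _ring_kernel(r: float, wall: float) -> np.ndarray:
    half = int(math.ceil(r + wall / 2)) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    dist = np.hypot(xx, yy)
    k = (np.abs(dist - r) <= wall / 2).astype(float)
    return k / k.sum()


def _disk_kernel(r: float) -> np.ndarray:
    half = max(int(math.ceil(r)), 1)
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    k = (np.hypot(xx, yy) <= r).astype(float)
    return k / k.sum()


def _subpixel(values: np.ndarray, axis_idx: int) -> float:
    """Quadratic 1-D peak interpolation offset in [-0.5, 0.5]."""
    f0, f1, f2 = values
    denom = f0 - 2 * f1 + f2
    if denom >= -1e-12:
        return 0.0
    return float(np.clip(0.5 * (f0 - f2) / denom, -0.5, 0.5))


def _ring_profile(darkness: np.ndarray, row: float, col: float, radius: float) -> np.ndarray:
    ang = np.linspace(0.0, 2 * math.pi, 72, endpoint=False)
    rr = row + radius * np.sin(ang)
    cc = col + radius * np.cos(ang)
    return map_coordinates(darkness, np.vstack([rr, cc]), order=1, mode="nearest")


def detect_tubules(image: np.ndarray, config: DetectionConfig = DetectionConfig()) -> list[TubuleCandidate]:
    """Find candidate tubule rings, sorted by descending contrast.

    A flat or empty image yields an empty list, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        return []
    bg = float(np.median(img))
    darkness = np.clip(bg - img, 0.0, None)
    contrast_scale = float(np.percentile(darkness, 99.5))
    threshold = max(config.peak_threshold_frac * contrast_scale, 0.02)

    radii = np.arange(config.r_min, config.r_max + 1e-9, config.r_step)
    stack = np.empty((len(radii),) + img.shape)
    for i, r in enumerate(radii):
        ring = fftconvolve(darkness, _ring_kernel(r, config.wall_px), mode="same")
        inner = fftconvolve(darkness, _disk_kernel(max(r - config.wall_px, 1.0)), mode="same")
        stack[i] = ring - inner
    resp = stack.max(axis=0)
    best_r = radii[stack.argmax(axis=0)]

    min_dist = max(int(round(config.min_separation_factor * config.r_min)), 1)
    peaks = peak_local_max(
        resp, min_distance=min_dist, threshold_abs=threshold, exclude_border=False
    )
    h, w = img.shape
    out: list[TubuleCandidate] = []
    for row, col in peaks:
        drow = dcol = 0.0
        if 0 < row < h - 1:
            drow = _subpixel(resp[row - 1 : row + 2, col], 0)
        if 0 < col < w - 1:
            dcol = _subpixel(resp[row, col - 1 : col + 2], 1)
        radius = float(best_r[row, col])
        prof = _ring_profile(darkness, row + drow, col + dcol, radius)
        wall_level = float(np.percentile(prof, 80))
        completeness = (
            float(np.mean(prof > 0.5 * wall_level)) if wall_level > 0.25 * threshold else 0.0
        )
        if completeness < config.completeness_min:
            continue  # arc fragments (arm hooks, wall slivers), not rings
        x = col + dcol - w / 2.0
        y = h / 2.0 - (row + drow)
        out.append(
            TubuleCandidate(
                center=(x, y),
                radius=radius,
                completeness=completeness,
                contrast=float(prof.mean()),
            )
        )
    out.sort(key=lambda c: -c.contrast)
    return out


def _mutual_pairs(
    centers: np.ndarray, lo: float, hi: float
) -> tuple[list[tuple[int, int]], list[int]]:
    """Mutual-nearest-neighbor pairing restricted to a distance band."""
    n = len(centers)
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    d[(d < lo) | (d > hi)] = np.inf
    nn = d.argmin(axis=1)
    pairs, used = [], set()
    for i in range(n):
        j = int(nn[i])
        if i in used or j in used:
            continue
        if np.isfinite(d[i, j]) and nn[j] == i and i < j:
            pairs.append((i, j))
            used.update((i, j))
    unpaired = [i for i in range(n) if i not in used]
    return pairs, unpaired


def assemble_section(
    candidates: list[TubuleCandidate],
    config: DetectionConfig = DetectionConfig(),
    section_id: str = "image",
) -> CrossSection:
    """Assemble ring candidates into a cross-section.

    Candidates near the centroid become the central-pair count; the rest
    are paired into doublets at the expected A–B spacing.  Within a pair
    the more complete ring is the A-tubule; when completeness scores tie
    (within ``completeness_tie``) the member farther from the provisional
    center is taken as B.  The section is flagged disorganized when the
    peripheral pair count differs from 9 or more than one peripheral
    candidate stays unpaired — downstream assessment then refuses it
    rather than silently fitting a wrong circumference.
    """
    if len(candidates) < 12:
        return CrossSection(
            section_id=section_id,
            doublets=[],
            central_pair_count=0,
            disorganized=False,
            notes=f"not-assessable: only {len(candidates)} ring candidates",
        )
    centers = np.array([c.center for c in candidates])
    centroid = centers.mean(axis=0)
    dists = np.linalg.norm(centers - centroid, axis=1)
    med = float(np.median(dists))
    is_central = dists < config.central_frac * med
    central_count = int(is_central.sum())
    peri_idx = np.flatnonzero(~is_central)

    spacing = config.r_a + config.r_b
    lo, hi = spacing * (1 - config.pairing_tol), spacing * (1 + config.pairing_tol)
    pairs, unpaired = _mutual_pairs(centers[peri_idx], lo, hi)

    doublets = []
    for k, (pi, pj) in enumerate(pairs):
        ci, cj = candidates[peri_idx[pi]], candidates[peri_idx[pj]]
        if abs(ci.completeness - cj.completeness) >= config.completeness_tie:
            a, b = (ci, cj) if ci.completeness > cj.completeness else (cj, ci)
        else:  # tie-break: B sits farther out than A
            di = np.linalg.norm(np.array(ci.center) - centroid)
            dj = np.linalg.norm(np.array(cj.center) - centroid)
            a, b = (ci, cj) if di < dj else (cj, ci)
        doublets.append(
            DoubletObservation(
                index=k + 1,  # provisional; re-indexed below
                a_center=a.center,
                b_center=b.center,
                r_a=a.radius,
                r_b=b.radius,
            )
        )

    # angular order: index 1 nearest 12 o'clock, then clockwise on the image
    if doublets:
        ax = np.array([d.a_center for d in doublets])
        ang = np.arctan2(ax[:, 1] - centroid[1], ax[:, 0] - centroid[0])
        start = int(np.argmin(np.abs(np.angle(np.exp(1j * (ang - math.pi / 2))))))
        # clockwise walk from the start doublet: sort by CW angle from it
        cw = (-np.angle(np.exp(1j * (ang - ang[start])))) % (2 * math.pi)
        cw[start] = -1.0
        order = np.argsort(cw)
        ordered = []
        for rank, oi in enumerate(order):
            d = doublets[oi]
            ordered.append(
                DoubletObservation(
                    index=rank + 1,
                    a_center=d.a_center,
                    b_center=d.b_center,
                    r_a=d.r_a,
                    r_b=d.r_b,
                )
            )
        doublets = ordered

    disorganized = len(pairs) != 9 or len(unpaired) > 1
    return CrossSection(
        section_id=section_id,
        doublets=doublets,
        central_pair_count=central_count,
        disorganized=disorganized,
        notes="" if not disorganized else "pairing inconsistent with 9+2 geometry",
    )


def analyze_image(
    image: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
    section_id: str = "image",
) -> dict:
    """Full per-image pipeline: detect → assemble → fit → calls → defects.

    Returns the JSON-serializable section report; failures in any stage
    are reported under ``error`` tagged with the stage name.
    """
    report: dict = {"section_id": section_id}
    try:
        candidates = detect_tubules(image, config)
    except Exception as exc:  # pragma: no cover - defensive
        report["error"] = f"detect: {exc}"
        return report
    report["n_candidates"] = len(candidates)
    try:
        section = assemble_section(candidates, config, section_id)
    except Exception as exc:
        report["error"] = f"assemble: {exc}"
        return report
    try:
        assessment = assess_section(
            section,
            kind=config.fit_kind,  # type: ignore[arg-type]
            kappa=config.kappa,
            eccentricity_cap=config.eccentricity_cap,
        )
    except Exception as exc:
        report["error"] = f"geometry: {exc}"
        return report
    report.update(assessment_report(assessment))
    try:
        call = call_section_defects(
            section, arm_min=config.arm_min, symmetry_break=assessment.symmetry_break
        )
    except Exception as exc:
        report["error"] = f"defects: {exc}"
        return report
    report["defects"] = {
        "oda_absent": call.oda_absent,
        "ida_absent": call.ida_absent,
        "central_defect": call.central_defect,
        "disorganized": call.disorganized,
    }
    report["central_pair_count"] = section.central_pair_count
    return report


def load_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG as float in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.max() > 1.0:
        arr = arr / (255.0 if arr.max() <= 255 else 65535.0)
    return arr
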
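"""Synthetic 9+2 axoneme cross-sections with ground truth.

The generator emulates the geometry scored on TEM micrographs of
respiratory cilia: nine peripheral doublets spaced nominally 40 degrees
apart on an elliptical circumference, each doublet an A-tubule (complete
ring) and a B-tubule (incomplete, C-shaped ring) whose axis normally lies
along the local tangent.  *Rotated* doublets have their axis swung
outward by a tilt angle drawn from a separate distribution, carrying the
B-tubule outside the circumference.  Section-level defects (dynein-arm
absence, central-pair loss, microtubular disorganization) are sampled
independently per section.

Everything is reproducible from the scene seed; images are rendered with
dark tubule walls on a light background (positive TEM contrast), Gaussian
blur and additive Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy.ndimage import gaussian_filter

from axosym.geometry import CrossSection, DoubletObservation
from axosym.io import write_sections

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "break_probability",
    "dist_with_break_probability",
    "generate_section_coords",
    "simulate_patient",
    "render_section_image",
    "generate_cohort",
]

DEFAULT_SEED = 20220106


@dataclass(frozen=True)
class SceneSpec:
    """Generator parameters for synthetic sections and images.

    Lengths are in pixels at ``pixel_size`` nm/px (default 2 nm/px, the
    scale of a ~x530,000 print); intensities are on a [0, 1] grayscale.
    ``n_rotated_dist`` is the probability of generating exactly k rotated
    doublets per section, k = 0..9.
    """

    n_sections: int = 50
    ring_radius_mean: float = 105.0
    ring_radius_sd: float = 5.0
    ellipse_aspect_range: tuple[float, float] = (0.88, 1.0)
    a_center_jitter_sd: float = 1.0
    r_a: float = 12.0
    r_b: float = 14.0
    doublet_spacing_jitter_deg: float = 2.0
    tilt_deg_rotated: tuple[float, float, float, float] = (35.0, 8.0, 15.0, 75.0)
    tilt_deg_aligned_sd: float = 4.0
    n_rotated_dist: tuple[float, ...] = (
        0.55, 0.20, 0.10, 0.05, 0.04, 0.03, 0.02, 0.01, 0.0, 0.0,
    )
    p_oda_absent: float = 0.0
    p_ida_absent: float = 0.0
    p_central_defect: float = 0.0
    p_disorganized: float = 0.0
    pixel_size: float = 2.0
    psf_sigma: float = 2.0
    noise_sd: float = 0.05
    canvas_px: int = 384
    wall_px: float = 4.0
    central_radius: float = 8.0
    central_sep: float = 20.0
    background: float = 0.85
    wall_intensity: float = 0.15
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        probs = np.asarray(self.n_rotated_dist, float)
        if len(probs) != 10 or probs.min() < 0 or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("n_rotated_dist must be 10 probabilities summing to 1")
        for name in ("p_oda_absent", "p_ida_absent", "p_central_defect", "p_disorganized"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("ring_radius_mean", "r_a", "r_b", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.ellipse_aspect_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("ellipse_aspect_range must be within (0, 1]")

    def replace(self, **kw) -> "SceneSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Generator-side truth for one section."""

    section_id: str
    ellipse: tuple[float, float, float, float, float]  # xc, yc, a, b, theta
    rotated: list[bool]
    tilt_deg: list[float]
    n_rotated: int
    symmetry_break: bool
    a_centers: list[tuple[float, float]]
    b_centers: list[tuple[float, float]]
    central_centers: list[tuple[float, float]]
    oda_absent: bool
    ida_absent: bool
    central_defect: bool
    disorganized: bool

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ellipse"] = list(self.ellipse)
        return d


def break_probability(dist: tuple[float, ...]) -> float:
    """P(symmetry break) = P(n_rotated >= 4) under a per-section count law."""
    return float(sum(dist[4:]))


def dist_with_break_probability(p_break: float) -> tuple[float, ...]:
    """A simple count law with the requested break probability: counts are
    uniform on {0..3} with mass 1-p and uniform on {4..6} with mass p."""
    if not 0.0 <= p_break <= 1.0:
        raise ValueError("p_break must be in [0, 1]")
    lo = (1.0 - p_break) / 4.0
    hi = p_break / 3.0
    return (lo, lo, lo, lo, hi, hi, hi, 0.0, 0.0, 0.0)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def generate_section_coords(
    spec: SceneSpec, rng: np.random.Generator, section_id: str = "S0"
) -> tuple[CrossSection, GroundTruth]:
    """Sample one synthetic cross-section (coordinate level) plus truth.

    Nine A-centers are placed at jittered 40-degree spacing on a sampled
    ellipse; a rotated-doublet count is drawn from ``n_rotated_dist`` and
    that many doublets get tilts from the rotated distribution (axis swung
    outward about the A-center), the rest from the aligned distribution.
    ``b_center = a_center + (r_a + r_b) * axis``.
    """
    a_semi = max(rng.normal(spec.ring_radius_mean, spec.ring_radius_sd), 5 * spec.r_a)
    aspect = rng.uniform(*spec.ellipse_aspect_range)
    b_semi = a_semi * aspect
    theta = rng.uniform(0.0, math.pi)

    n_rot = int(rng.choice(10, p=np.asarray(spec.n_rotated_dist, float)))
    rotated_idx = set(rng.choice(9, size=n_rot, replace=False).tolist())

    mean_t, sd_t, lo_t, hi_t = spec.tilt_deg_rotated
    ct, st = math.cos(theta), math.sin(theta)
    doublets: list[DoubletObservation] = []
    rot_flags: list[bool] = []
    tilts: list[float] = []
    a_pts: list[tuple[float, float]] = []
    b_pts: list[tuple[float, float]] = []

    oda_absent = bool(rng.random() < spec.p_oda_absent)
    ida_absent = bool(rng.random() < spec.p_ida_absent)
    central_defect = bool(rng.random() < spec.p_central_defect)
    disorganized = bool(rng.random() < spec.p_disorganized)

    for i in range(9):
        # index 1 starts near 12 o'clock; subsequent doublets step clockwise
        t = math.radians(90.0 - 40.0 * i + rng.normal(0.0, spec.doublet_spacing_jitter_deg))
        ex, ey = a_semi * math.cos(t), b_semi * math.sin(t)
        ax = ct * ex - st * ey + rng.normal(0.0, spec.a_center_jitter_sd)
        ay = st * ex + ct * ey + rng.normal(0.0, spec.a_center_jitter_sd)

        tang = np.array([-a_semi * math.sin(t), b_semi * math.cos(t)])
        tang /= np.linalg.norm(tang)
        norm = np.array([b_semi * math.cos(t), a_semi * math.sin(t)])
        norm /= np.linalg.norm(norm)
        # rotate both into the world frame
        tang = np.array([ct * tang[0] - st * tang[1], st * tang[0] + ct * tang[1]])
        norm = np.array([ct * norm[0] - st * norm[1], st * norm[0] + ct * norm[1]])

        is_rot = i in rotated_idx
        tilt = (
            _truncnorm(rng, mean_t, sd_t, lo_t, hi_t)
            if is_rot
            else min(abs(rng.normal(0.0, spec.tilt_deg_aligned_sd)), 90.0)
        )
        axis = math.cos(math.radians(tilt)) * tang + math.sin(math.radians(tilt)) * norm
        bx, by = ax + (spec.r_a + spec.r_b) * axis[0], ay + (spec.r_a + spec.r_b) * axis[1]

        doublets.append(
            DoubletObservation(
                index=i + 1,
                a_center=(float(ax), float(ay)),
                b_center=(float(bx), float(by)),
                r_a=spec.r_a,
                r_b=spec.r_b,
                oda_present=not oda_absent,
                ida_present=not ida_absent,
            )
        )
        rot_flags.append(is_rot)
        tilts.append(float(tilt))
        a_pts.append((float(ax), float(ay)))
        b_pts.append((float(bx), float(by)))

    n_central = 0 if central_defect else 2
    central = []
    if n_central == 2:
        # the renderer anchors the pair on the A-center centroid; mirror that
        half = spec.central_sep / 2.0
        cx0 = float(np.mean([p[0] for p in a_pts]))
        cy0 = float(np.mean([p[1] for p in a_pts]))
        central = [(cx0 - half, cy0), (cx0 + half, cy0)]

    section = CrossSection(
        section_id=section_id,
        doublets=doublets,
        central_pair_count=n_central,
        disorganized=disorganized,
    )
    truth = GroundTruth(
        section_id=section_id,
        ellipse=(0.0, 0.0, a_semi, b_semi, theta),
        rotated=rot_flags,
        tilt_deg=tilts,
        n_rotated=n_rot,
        symmetry_break=n_rot >= 4,
        a_centers=a_pts,
        b_centers=b_pts,
        central_centers=central,
        oda_absent=oda_absent,
        ida_absent=ida_absent,
        central_defect=central_defect,
        disorganized=disorganized,
    )
    return section, truth


def simulate_patient(
    spec: SceneSpec,
    n_sections: int | None = None,
    rng: np.random.Generator | None = None,
    patient_id: str = "P0",
) -> tuple[list[CrossSection], list[GroundTruth]]:
    """Generate all sections of one synthetic patient."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_sections if n_sections is None else n_sections
    out = [
        generate_section_coords(spec, rng, section_id=f"{patient_id}_s{i:03d}")
        for i in range(n)
    ]
    return [s for s, _ in out], [t for _, t in out]


# ---------------------------------------------------------------------------
# rendering


def _paint_ring(
    canvas: np.ndarray,
    cx: float,
    cy: float,
    radius: float,
    wall: float,
    level: float,
    opening_dir: float | None = None,
    opening_half_deg: float = 55.0,
    sector_dir: float | None = None,
    sector_half_deg: float | None = None,
) -> None:
    """Darken an annulus on the canvas (image coordinates, row/col).

    ``opening_dir`` (radians, math frame) cuts a C-shaped gap around that
    direction; ``sector_dir`` instead keeps only a sector (used for arm
    hooks).  (cx, cy) are in the math frame centered on the canvas.
    """
    n = canvas.shape[0]
    col_c = n / 2.0 + cx
    row_c = n / 2.0 - cy
    r_out = radius + wall / 2.0
    lo_r = max(int(row_c - r_out - 1), 0)
    hi_r = min(int(row_c + r_out + 2), n)
    lo_c = max(int(col_c - r_out - 1), 0)
    hi_c = min(int(col_c + r_out + 2), n)
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    rows, cols = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dx = cols - col_c
    dy = row_c - rows  # back to y-up
    dist = np.hypot(dx, dy)
    mask = np.abs(dist - radius) <= wall / 2.0
    if opening_dir is not None:
        ang = np.arctan2(dy, dx)
        dang = np.angle(np.exp(1j * (ang - opening_dir)))
        mask &= np.abs(dang) > math.radians(opening_half_deg)
    if sector_dir is not None and sector_half_deg is not None:
        ang = np.arctan2(dy, dx)
        dang = np.angle(np.exp(1j * (ang - sector_dir)))
        mask &= np.abs(dang) <= math.radians(sector_half_deg)
    canvas[lo_r:hi_r, lo_c:hi_c][mask] = np.minimum(
        canvas[lo_r:hi_r, lo_c:hi_c][mask], level
    )


def render_section_image(
    section: CrossSection,
    spec: SceneSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a section to a float grayscale image in [0, 1].

    A-tubules are complete dark annuli, B-tubules C-shaped annuli opening
    toward their A-tubule, dynein arms small hook sectors on the A-tubule
    (ODA outward, IDA inward), and the central microtubules complete
    annuli near the section centroid.  Gaussian blur (``psf_sigma``) and
    additive Gaussian noise (``noise_sd``) are applied last.

    Raises a sizing error when the section does not fit on the canvas.
    """
    n = spec.canvas_px
    half = n / 2.0
    all_pts = [d.a_center for d in section.doublets] + [d.b_center for d in section.doublets]
    if all_pts:
        margin = max(spec.r_a, spec.r_b) + spec.wall_px + 3 * spec.psf_sigma + 2
        extent = max(max(abs(x), abs(y)) for x, y in all_pts) + margin
        if extent > half:
            raise ValueError(
                f"section {section.section_id} does not fit: needs canvas "
                f">= {int(2 * extent) + 1} px, have {n}"
            )
    canvas = np.full((n, n), spec.background, dtype=float)

    centroid = (
        np.mean([d.a_center for d in section.doublets], axis=0)
        if section.doublets
        else np.zeros(2)
    )
    for d in section.doublets:
        ax, ay = d.a_center
        bx, by = d.b_center
        _paint_ring(canvas, ax, ay, d.r_a, spec.wall_px, spec.wall_intensity)
        opening = math.atan2(ay - by, ax - bx)  # B opens toward its A-tubule
        _paint_ring(
            canvas, bx, by, d.r_b, spec.wall_px, spec.wall_intensity, opening_dir=opening
        )
        out_dir = math.atan2(ay - centroid[1], ax - centroid[0])
        if d.oda_present:
            _paint_ring(
                canvas, ax, ay, d.r_a + spec.wall_px, spec.wall_px,
                spec.wall_intensity, sector_dir=out_dir, sector_half_deg=30.0,
            )
        if d.ida_present:
            _paint_ring(
                canvas, ax, ay, d.r_a + spec.wall_px, spec.wall_px,
                spec.wall_intensity, sector_dir=out_dir + math.pi, sector_half_deg=20.0,
            )

    if section.central_pair_count > 0:
        half_sep = spec.central_sep / 2.0
        for k in range(section.central_pair_count):
            off = (2 * (k % 2) - 1) * half_sep
            _paint_ring(
                canvas,
                centroid[0] + off,
                centroid[1],
                spec.central_radius,
                spec.wall_px,
                spec.wall_intensity,
            )

    if spec.psf_sigma > 0:
        canvas = gaussian_filter(canvas, spec.psf_sigma)
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    return np.clip(canvas, 0.0, 1.0)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    spec_pcd: SceneSpec,
    spec_ctrl: SceneSpec,
    n_patients_per_arm: int,
    sections_per_patient: int,
    out_dir,
    write_images: bool = False,
) -> dict:
    """Write a two-arm synthetic cohort to disk and return the manifest.

    Layout: ``<out>/manifest.yaml`` plus, per patient,
    ``patients/<id>/doublets.csv``, ``sections.csv``, ``truth.json`` and
    optionally an ``images/`` stack of 16-bit grayscale TIFFs.  Patient
    RNG streams are spawned from each arm's spec seed, so the dataset is
    fully reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "arms": {},
        "sections_per_patient": sections_per_patient,
        "patients": [],
    }
    for arm, spec in (("PCD", spec_pcd), ("control", spec_ctrl)):
        manifest["arms"][arm] = {
            "seed": spec.seed,
            "expected_break_prob": break_probability(spec.n_rotated_dist),
        }
        streams = np.random.SeedSequence(spec.seed).spawn(max(n_patients_per_arm, 1))
        for i in range(n_patients_per_arm):
            pid = f"{arm.lower()}_{i + 1:03d}"
            rng = np.random.default_rng(streams[i])
            sections, truths = simulate_patient(
                spec, sections_per_patient, rng, patient_id=pid
            )
            pdir = out / "patients" / pid
            pdir.mkdir(parents=True, exist_ok=True)
            write_sections(sections, pdir / "doublets.csv", pdir / "sections.csv")
            (pdir / "truth.json").write_text(
                json.dumps([t.to_dict() for t in truths], indent=1)
            )
            if write_images:
                img_dir = pdir / "images"
                img_dir.mkdir(exist_ok=True)
                for s in sections:
                    img = render_section_image(s, spec, rng)
                    tifffile.imwrite(
                        img_dir / f"{s.section_id}.tiff",
                        (img * 65535).astype(np.uint16),
                    )
            manifest["patients"].append(
                {
                    "id": pid,
                    "group": arm,
                    "n_sections": sections_per_patient,
                    "true_aa_pct": 100.0
                    * sum(t.symmetry_break for t in truths)
                    / max(len(truths), 1)
                    if truths
                    else None,
                }
            )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
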
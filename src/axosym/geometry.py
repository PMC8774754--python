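"""Circumference fitting and rotated-doublet calls for 9+2 axoneme sections.

The axonemal circumference is the closed curve (circle or oval) joining
the centers of the nine A-tubules of a transverse ciliary section.  A
peripheral doublet is *rotated* when its B-tubule center protrudes beyond
that curve by at least ``kappa * r_b`` (default ``kappa = 0.5``, i.e. half
the B-tubule outside).  A section with more than three rotated doublets
carries an axonemal *symmetry break*.

All geometry lives in a mathematical frame (y up, angles CCW from +x);
conversion from image coordinates (y down) is the caller's concern — see
:mod:`axosym.detection` which performs it when reading pixel data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from skimage.measure import EllipseModel

__all__ = [
    "ConfigurationError",
    "FitDegeneracyError",
    "DoubletObservation",
    "CrossSection",
    "CircumferenceFit",
    "RotationCall",
    "SectionAssessment",
    "DEFAULT_KAPPA",
    "MIN_LOCALIZED_DOUBLETS",
    "fit_circumference",
    "radial_clearance",
    "tilt_angle",
    "is_rotated",
    "rotation_calls",
    "count_rotated",
    "has_symmetry_break",
    "assess_section",
]

#: Default protrusion threshold: B-tubule center must clear the fitted
#: curve by at least this fraction of the B-tubule radius to be "rotated".
DEFAULT_KAPPA = 0.5

#: Minimum number of doublets with both tubule centers localized for a
#: section to be assessable for symmetry break.
MIN_LOCALIZED_DOUBLETS = 8

#: Eccentricity above which an automatic ellipse fit is rejected as
#: degenerate and a circle is fitted instead.
DEFAULT_ECCENTRICITY_CAP = 0.8


class FitDegeneracyError(ValueError):
    """Raised when the point configuration does not determine a fit."""


class ConfigurationError(ValueError):
    """Raised for invalid analysis parameters (e.g. negative kappa)."""


@dataclass(frozen=True)
class DoubletObservation:
    """One peripheral microtubule doublet in a cross-section.

    Coordinates and radii are in pixels.  ``oda_present`` / ``ida_present``
    are ``True``/``False`` when the dynein arm was scored and ``None`` when
    it could not be evaluated.
    """

    index: int
    a_center: tuple[float, float]
    b_center: tuple[float, float]
    r_a: float
    r_b: float
    oda_present: bool | None = None
    ida_present: bool | None = None

    def __post_init__(self) -> None:
        if not (self.r_a > 0 and self.r_b > 0):
            raise ValueError(f"doublet {self.index}: tubule radii must be positive")
        if tuple(self.a_center) == tuple(self.b_center):
            raise ValueError(f"doublet {self.index}: A and B centers coincide")


@dataclass
class CrossSection:
    """One axoneme transverse section (up to 9 doublets plus central pair)."""

    section_id: str
    doublets: list[DoubletObservation] = field(default_factory=list)
    central_pair_count: int = 2
    disorganized: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        idx = [d.index for d in self.doublets]
        if len(idx) != len(set(idx)):
            raise ValueError(f"section {self.section_id}: duplicate doublet indices")
        if self.central_pair_count < 0:
            raise ValueError(f"section {self.section_id}: negative central pair count")


@dataclass(frozen=True)
class CircumferenceFit:
    """Fitted axonemal circumference: a circle or an ellipse.

    ``orientation`` is the CCW angle of the semi-major axis from +x, in
    radians; for a circle it is 0 and the two semi-axes are equal.
    ``rms_residual`` is the root-mean-square orthogonal distance of the
    fitted A-tubule centers from the curve.
    """

    kind: Literal["circle", "ellipse"]
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float
    rms_residual: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        if self.kind == "circle" and not (
            self.semi_major == self.semi_minor and self.orientation == 0.0
        ):
            raise ValueError("circle fit must have equal axes and zero orientation")

    @property
    def eccentricity(self) -> float:
        return math.sqrt(1.0 - (self.semi_minor / self.semi_major) ** 2)


@dataclass(frozen=True)
class RotationCall:
    """Per-doublet rotation decision.

    ``clearance`` is the signed orthogonal distance of the B-tubule center
    from the fitted curve (positive = outside); ``tilt_angle`` the unsigned
    angle in degrees between the doublet axis (A→B) and the local tangent.
    """

    doublet_index: int
    clearance: float
    tilt_angle: float
    rotated: bool


@dataclass
class SectionAssessment:
    """Full symmetry-break assessment of one section."""

    section_id: str
    assessable: bool
    reason: str
    fit: CircumferenceFit | None
    calls: list[RotationCall]
    count_rotated: int | None
    symmetry_break: bool | None


# ---------------------------------------------------------------------------
# circumference fitting


def _fit_circle(pts: np.ndarray) -> tuple[float, float, float, float]:
    """Geometric circle fit (Kasa algebraic seed + orthogonal refinement).

    Returns (xc, yc, r, rms).
    """
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    xc, yc = sol[0], sol[1]
    r = math.sqrt(max(sol[2] + xc**2 + yc**2, 1e-300))

    def resid(p: np.ndarray) -> np.ndarray:
        return np.hypot(x - p[0], y - p[1]) - p[2]

    fit = least_squares(resid, x0=[xc, yc, r], xtol=1e-15, ftol=1e-15, gtol=1e-15)
    xc, yc, r = fit.x
    rms = float(np.sqrt(np.mean(resid(fit.x) ** 2)))
    return float(xc), float(yc), float(r), rms


_SCAN_T = np.linspace(0.0, 2 * math.pi, 128, endpoint=False)
_SCAN_COS = np.cos(_SCAN_T)
_SCAN_SIN = np.sin(_SCAN_T)


def _ellipse_nearest_t_many(a: float, b: float, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Parameters t of the points on (a cos t, b sin t) nearest to (xs, ys).

    Dense angular scan for a global seed, then (vectorized) Newton on the
    stationarity condition of the squared distance.  Robust for interior
    points and on the axes (where the projection may be non-unique; any
    minimizer is returned).
    """
    d2 = (a * _SCAN_COS[:, None] - xs[None, :]) ** 2 + (
        b * _SCAN_SIN[:, None] - ys[None, :]
    ) ** 2
    t = _SCAN_T[np.argmin(d2, axis=0)].copy()
    for _ in range(40):
        ct, st = np.cos(t), np.sin(t)
        dx, dy = a * ct - xs, b * st - ys
        g = -a * st * dx + b * ct * dy  # D'(t)/2
        h = a * a * st * st - a * ct * dx + b * b * ct * ct - b * st * dy  # D''(t)/2
        step = np.where(h > 0, g / np.maximum(h, 1e-300), 0.0)
        t -= step
        if np.max(np.abs(step)) < 1e-15:
            break
    return t


def _ellipse_nearest_t(a: float, b: float, x: float, y: float) -> float:
    return float(
        _ellipse_nearest_t_many(a, b, np.array([x], float), np.array([y], float))[0]
    )


def _to_canonical(fit: CircumferenceFit, p: Sequence[float]) -> tuple[float, float]:
    """World point -> ellipse-aligned frame centered on the fit."""
    c, s = math.cos(fit.orientation), math.sin(fit.orientation)
    dx, dy = p[0] - fit.center[0], p[1] - fit.center[1]
    return c * dx + s * dy, -s * dx + c * dy


def _orthogonal_distances(
    params: np.ndarray, pts: np.ndarray
) -> np.ndarray:
    """Signed orthogonal distances of pts from ellipse (xc, yc, a, b, theta)."""
    xc, yc, a, b, th = params
    c, s = math.cos(th), math.sin(th)
    dx, dy = pts[:, 0] - xc, pts[:, 1] - yc
    u, v = c * dx + s * dy, -s * dx + c * dy
    t = _ellipse_nearest_t_many(a, b, u, v)
    d = np.hypot(a * np.cos(t) - u, b * np.sin(t) - v)
    inside = (u / a) ** 2 + (v / b) ** 2 < 1.0
    return np.where(inside, -d, d)


def _fit_ellipse(pts: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Geometric ellipse fit: algebraic (Halir–Flusser) seed, then
    Levenberg–Marquardt refinement of the orthogonal residuals.

    Returns (xc, yc, a, b, theta, rms) with a >= b and theta in [0, pi).
    """
    try:
        if hasattr(EllipseModel, "from_estimate"):
            model = EllipseModel.from_estimate(pts)
            if not model:
                raise FitDegeneracyError("algebraic ellipse fit failed (degenerate points)")
            (xc, yc), (a, b), th = model.center, model.axis_lengths, model.theta
        else:  # scikit-image < 0.26
            model = EllipseModel()
            if not model.estimate(pts):
                raise FitDegeneracyError("algebraic ellipse fit failed (degenerate points)")
            xc, yc, a, b, th = model.params
        if not np.all(np.isfinite([xc, yc, a, b, th])) or a <= 0 or b <= 0:
            raise FitDegeneracyError("algebraic ellipse fit failed (bad parameters)")
    except (TypeError, ValueError, np.linalg.LinAlgError):
        # near-circular data can defeat the conic solver; seed from a circle
        xc, yc, r, _ = _fit_circle(pts)
        a, b, th = r, 0.999 * r, 0.0
    if a < b:
        a, b = b, a
        th += math.pi / 2

    def resid(p: np.ndarray) -> np.ndarray:
        if p[2] <= 0 or p[3] <= 0:
            return np.full(len(pts), 1e6)
        return _orthogonal_distances(p, pts)

    sol = least_squares(
        resid, x0=[xc, yc, a, b, th], xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    xc, yc, a, b, th = sol.x
    if a < b:
        a, b = b, a
        th += math.pi / 2
    th = th % math.pi
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return float(xc), float(yc), float(a), float(b), float(th), rms


def _collinear(pts: np.ndarray) -> bool:
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    scale = max(sv[0], 1e-12)
    return sv[-1] / scale < 1e-9


def fit_circumference(
    a_centers: Sequence[Sequence[float]],
    kind: Literal["circle", "ellipse", "auto"] = "auto",
    *,
    eccentricity_cap: float = DEFAULT_ECCENTRICITY_CAP,
    section_id: str = "",
) -> CircumferenceFit:
    """Fit the axonemal circumference through the A-tubule centers.

    Least-squares in the *geometric* sense: the summed squared orthogonal
    (radial) distances from the points to the curve are minimized, not an
    algebraic conic residual.  ``kind="auto"`` fits an ellipse when at
    least 6 points are available and the result is non-degenerate
    (eccentricity <= ``eccentricity_cap``), otherwise falls back to a
    circle.

    Raises
    ------
    FitDegeneracyError
        Fewer points than the model needs (3 for circle, 5 for ellipse),
        collinear or otherwise degenerate configurations.
    """
    pts = np.asarray(a_centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("a_centers must be an (n, 2) array of points")
    tag = f" (section {section_id})" if section_id else ""
    n = len(pts)
    min_needed = 3 if kind == "circle" else 5
    if n < min_needed:
        raise FitDegeneracyError(
            f"{n} points given but {min_needed} required for {kind} fit{tag}"
        )
    if len(np.unique(pts, axis=0)) < min_needed or _collinear(pts):
        raise FitDegeneracyError(f"degenerate point configuration{tag}")

    if kind == "circle":
        xc, yc, r, rms = _fit_circle(pts)
        return CircumferenceFit("circle", (xc, yc), r, r, 0.0, rms)

    if kind == "ellipse":
        xc, yc, a, b, th, rms = _fit_ellipse(pts)
        return CircumferenceFit("ellipse", (xc, yc), a, b, th, rms)

    # auto
    if n >= 6:
        try:
            xc, yc, a, b, th, rms = _fit_ellipse(pts)
        except FitDegeneracyError:
            pass
        else:
            ecc = math.sqrt(1.0 - (b / a) ** 2)
            if ecc <= eccentricity_cap:
                return CircumferenceFit("ellipse", (xc, yc), a, b, th, rms)
    xc, yc, r, rms = _fit_circle(pts)
    return CircumferenceFit("circle", (xc, yc), r, r, 0.0, rms)


# ---------------------------------------------------------------------------
# per-point geometry


def radial_clearance(fit: CircumferenceFit, p: Sequence[float]) -> float:
    """Signed orthogonal distance from ``p`` to the fitted curve.

    Positive outside the closed curve, negative inside, zero on it.
    """
    if fit.kind == "circle":
        return float(
            math.hypot(p[0] - fit.center[0], p[1] - fit.center[1]) - fit.semi_major
        )
    u, v = _to_canonical(fit, p)
    a, b = fit.semi_major, fit.semi_minor
    t = _ellipse_nearest_t(a, b, u, v)
    d = math.hypot(a * math.cos(t) - u, b * math.sin(t) - v)
    inside = (u / a) ** 2 + (v / b) ** 2 < 1.0
    return float(-d if inside else d)


def _tangent_at_projection(fit: CircumferenceFit, p: Sequence[float]) -> np.ndarray:
    """Unit tangent of the fitted curve at the orthogonal projection of p."""
    u, v = _to_canonical(fit, p)
    a, b = fit.semi_major, fit.semi_minor
    t = _ellipse_nearest_t(a, b, u, v)
    tan = np.array([-a * math.sin(t), b * math.cos(t)])
    tan /= np.linalg.norm(tan)
    c, s = math.cos(fit.orientation), math.sin(fit.orientation)
    return np.array([c * tan[0] - s * tan[1], s * tan[0] + c * tan[1]])


def tilt_angle(fit: CircumferenceFit, d: DoubletObservation) -> float:
    """Unsigned angle (degrees, in [0, 90]) between the doublet axis A→B
    and the tangent of the fitted curve at the projection of the A-center.

    0 means the doublet lies flat along the circumference.
    """
    axis = np.array(d.b_center, float) - np.array(d.a_center, float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError(f"doublet {d.index}: degenerate axis (A = B)")
    tan = _tangent_at_projection(fit, d.a_center)
    cosang = abs(float(np.dot(axis / norm, tan)))
    return math.degrees(math.acos(min(1.0, cosang)))


def is_rotated(
    fit: CircumferenceFit, d: DoubletObservation, kappa: float = DEFAULT_KAPPA
) -> RotationCall:
    """Call one doublet rotated/aligned.

    Rotated iff the B-tubule center clears the fitted curve *outward* by at
    least ``kappa * r_b``; equality counts as rotated.  Inward displacement
    is recorded in ``clearance`` but never counts.
    """
    if kappa < 0:
        raise ConfigurationError(f"kappa must be >= 0, got {kappa}")
    clearance = radial_clearance(fit, d.b_center)
    return RotationCall(
        doublet_index=d.index,
        clearance=clearance,
        tilt_angle=tilt_angle(fit, d),
        rotated=clearance >= kappa * d.r_b,
    )


def rotation_calls(
    fit: CircumferenceFit,
    doublets: Sequence[DoubletObservation],
    kappa: float = DEFAULT_KAPPA,
) -> list[RotationCall]:
    return [is_rotated(fit, d, kappa) for d in doublets]


def count_rotated(
    section: CrossSection, fit: CircumferenceFit, kappa: float = DEFAULT_KAPPA
) -> int | None:
    """Number of rotated doublets, or ``None`` when the section is not
    assessable (disorganized, or fewer than 8 localized doublets)."""
    if section.disorganized or len(section.doublets) < MIN_LOCALIZED_DOUBLETS:
        return None
    return sum(c.rotated for c in rotation_calls(fit, section.doublets, kappa))


def has_symmetry_break(
    section: CrossSection, fit: CircumferenceFit, kappa: float = DEFAULT_KAPPA
) -> bool | None:
    """Symmetry break: strictly more than 3 rotated doublets (i.e. >= 4).

    ``None`` when the section is not assessable.
    """
    n = count_rotated(section, fit, kappa)
    return None if n is None else n > 3


def assess_section(
    section: CrossSection,
    kind: Literal["circle", "ellipse", "auto"] = "auto",
    kappa: float = DEFAULT_KAPPA,
    *,
    eccentricity_cap: float = DEFAULT_ECCENTRICITY_CAP,
) -> SectionAssessment:
    """Full assessment pipeline for one section: fit, per-doublet calls,
    rotated count and break flag, with not-assessable handling."""
    if section.disorganized:
        return SectionAssessment(
            section.section_id, False, "microtubular disorganization", None, [], None, None
        )
    if len(section.doublets) < MIN_LOCALIZED_DOUBLETS:
        return SectionAssessment(
            section.section_id,
            False,
            f"only {len(section.doublets)} localized doublets "
            f"(need {MIN_LOCALIZED_DOUBLETS})",
            None,
            [],
            None,
            None,
        )
    try:
        fit = fit_circumference(
            [d.a_center for d in section.doublets],
            kind,
            eccentricity_cap=eccentricity_cap,
            section_id=section.section_id,
        )
    except FitDegeneracyError as exc:
        return SectionAssessment(
            section.section_id, False, f"fit degeneracy: {exc}", None, [], None, None
        )
    calls = rotation_calls(fit, section.doublets, kappa)
    n_rot = sum(c.rotated for c in calls)
    return SectionAssessment(
        section.section_id, True, "", fit, calls, n_rot, n_rot > 3
    )


def assessment_report(assessment: SectionAssessment) -> dict:
    """JSON-serializable per-section report."""
    fit = assessment.fit
    return {
        "section_id": assessment.section_id,
        "assessable": assessment.assessable,
        "reason": assessment.reason,
        "fit": None
        if fit is None
        else {
            "kind": fit.kind,
            "center": list(fit.center),
            "semi_major": fit.semi_major,
            "semi_minor": fit.semi_minor,
            "orientation_rad": fit.orientation,
            "rms_residual": fit.rms_residual,
        },
        "doublets": [
            {
                "index": c.doublet_index,
                "clearance_px": c.clearance,
                "tilt_deg": c.tilt_angle,
                "rotated": c.rotated,
            }
            for c in assessment.calls
        ],
        "count_rotated": assessment.count_rotated,
        "symmetry_break": assessment.symmetry_break,
    }
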
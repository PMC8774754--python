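"""Circumference fitting, clearances, tilt angles and rotation calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axosym.geometry import (
    CircumferenceFit,
    ConfigurationError,
    CrossSection,
    DoubletObservation,
    FitDegeneracyError,
    assess_section,
    count_rotated,
    fit_circumference,
    has_symmetry_break,
    is_rotated,
    radial_clearance,
    tilt_angle,
)
from axosym.synthetic import generate_section_coords

from conftest import make_well_separated_spec


def ellipse_points(a, b, theta, n=9, center=(0.0, 0.0)):
    t = np.radians(np.arange(n) * 360.0 / n)
    c, s = math.cos(theta), math.sin(theta)
    x = a * np.cos(t)
    y = b * np.sin(t)
    return np.column_stack([center[0] + c * x - s * y, center[1] + s * x + c * y])


# ---------------------------------------------------------------------------
# fitting


def test_circle_fit_recovers_noiseless_circle():
    pts = ellipse_points(100.0, 100.0, 0.0)
    fit = fit_circumference(pts, "circle")
    assert fit.kind == "circle"
    assert np.allclose(fit.center, (0.0, 0.0), atol=1e-9)
    assert fit.semi_major == pytest.approx(100.0, abs=1e-9)
    assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)


def test_ellipse_fit_recovers_noiseless_ellipse():
    pts = ellipse_points(120.0, 90.0, math.radians(30.0), center=(7.0, -3.0))
    fit = fit_circumference(pts, "ellipse")
    assert fit.kind == "ellipse"
    assert np.allclose(fit.center, (7.0, -3.0), rtol=1e-6, atol=1e-6)
    assert fit.semi_major == pytest.approx(120.0, rel=1e-6)
    assert fit.semi_minor == pytest.approx(90.0, rel=1e-6)
    assert fit.orientation == pytest.approx(math.radians(30.0), rel=1e-6)


def test_auto_fit_prefers_ellipse_with_enough_points():
    pts = ellipse_points(120.0, 90.0, 0.3)
    assert fit_circumference(pts, "auto").kind == "ellipse"
    # 5 points: ellipse would be exactly determined; auto must fall back
    assert fit_circumference(ellipse_points(100, 100, 0, n=5), "auto").kind == "circle"


@pytest.mark.parametrize(
    "pts,kind",
    [
        (ellipse_points(100, 100, 0, n=2), "circle"),
        (ellipse_points(120, 90, 0, n=4), "ellipse"),
        (np.column_stack([np.arange(9.0), 2 * np.arange(9.0)]), "auto"),  # collinear
    ],
)
def test_degenerate_inputs_raise(pts, kind):
    with pytest.raises(FitDegeneracyError):
        fit_circumference(pts, kind)


def _polyline_objective(params, pts, n_poly=2048):
    """Independent geometric objective: summed squared min distance to a
    dense polygonal sampling of the candidate ellipse."""
    xc, yc, a, b, th = params
    t = np.linspace(0, 2 * math.pi, n_poly, endpoint=False)
    c, s = math.cos(th), math.sin(th)
    px = xc + c * a * np.cos(t) - s * b * np.sin(t)
    py = yc + s * a * np.cos(t) + c * b * np.sin(t)
    d2 = (pts[:, 0, None] - px) ** 2 + (pts[:, 1, None] - py) ** 2
    return float(d2.min(axis=1).sum())


def test_noisy_fit_matches_brute_force_minimizer():
    """On jittered points the geometric fit must reach (or beat) a
    derivative-free minimizer of the independent polyline objective."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(42)
    truth = (5.0, -2.0, 110.0, 88.0, 0.7)
    pts = ellipse_points(truth[2], truth[3], truth[4], center=truth[:2])
    pts = pts + rng.normal(0, 2.0, pts.shape)
    fit = fit_circumference(pts, "ellipse")
    ours = (fit.center[0], fit.center[1], fit.semi_major, fit.semi_minor, fit.orientation)
    res = minimize(
        _polyline_objective, x0=np.array(truth), args=(pts,), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    # both objectives carry a chord-discretization bias of order (pi*a/N)^2
    grid_tol = len(pts) * (math.pi * truth[2] / 2048) ** 2
    assert _polyline_objective(np.array(ours), pts) <= res.fun + grid_tol
    assert np.allclose(ours[:4], res.x[:4], atol=0.5)


# ---------------------------------------------------------------------------
# clearances and tilt


CIRCLE = CircumferenceFit("circle", (0.0, 0.0), 100.0, 100.0, 0.0, 0.0)
ELLIPSE = CircumferenceFit("ellipse", (0.0, 0.0), 120.0, 90.0, 0.0, 0.0)


@pytest.mark.parametrize(
    "fit,p,expected",
    [
        (CIRCLE, (100.0, 0.0), 0.0),
        (CIRCLE, (130.0, 0.0), 30.0),
        (CIRCLE, (50.0, 0.0), -50.0),
        (ELLIPSE, (0.0, 100.0), 10.0),
        (ELLIPSE, (120.0, 0.0), 0.0),
    ],
)
def test_radial_clearance_reference_points(fit, p, expected):
    assert radial_clearance(fit, p) == pytest.approx(expected, abs=1e-9)


def test_clearance_sign_agrees_with_implicit_equation():
    rng = np.random.default_rng(7)
    a, b, th = 120.0, 80.0, 0.5
    fit = CircumferenceFit("ellipse", (3.0, -4.0), a, b, th, 0.0)
    pts = rng.uniform(-250, 250, size=(10_000, 2))
    c, s = math.cos(th), math.sin(th)
    u = c * (pts[:, 0] - 3.0) + s * (pts[:, 1] + 4.0)
    v = -s * (pts[:, 0] - 3.0) + c * (pts[:, 1] + 4.0)
    implicit = (u / a) ** 2 + (v / b) ** 2 - 1.0
    clear = np.array([radial_clearance(fit, p) for p in pts])
    # exclude points numerically on the curve
    mask = np.abs(implicit) > 1e-9
    assert np.all(np.sign(clear[mask]) == np.sign(implicit[mask]))


def _doublet(a, b, **kw):
    kw.setdefault("index", 1)
    kw.setdefault("r_a", 12.0)
    kw.setdefault("r_b", 14.0)
    return DoubletObservation(a_center=tuple(a), b_center=tuple(b), **kw)


def test_tilt_angle_parallel_and_normal():
    d_par = _doublet((100.0, 0.0), (100.0, 26.0))  # along tangent at (100, 0)
    d_norm = _doublet((100.0, 0.0), (126.0, 0.0))  # along outward normal
    assert tilt_angle(CIRCLE, d_par) == pytest.approx(0.0, abs=1e-9)
    assert tilt_angle(CIRCLE, d_norm) == pytest.approx(90.0, abs=1e-9)


def test_tilt_angle_matches_finite_difference_tangent():
    from axosym.geometry import _ellipse_nearest_t, _to_canonical

    rng = np.random.default_rng(3)
    fit = CircumferenceFit("ellipse", (5.0, 1.0), 130.0, 95.0, 0.9, 0.0)
    for _ in range(50):
        a_pt = rng.uniform(-150, 150, 2)
        b_pt = a_pt + rng.uniform(-30, 30, 2)
        if np.allclose(a_pt, b_pt):
            continue
        d = _doublet(a_pt, b_pt)
        u, v = _to_canonical(fit, a_pt)
        t = _ellipse_nearest_t(fit.semi_major, fit.semi_minor, u, v)
        h = 1e-6
        c, s = math.cos(fit.orientation), math.sin(fit.orientation)

        def world(tt):
            x, y = fit.semi_major * math.cos(tt), fit.semi_minor * math.sin(tt)
            return np.array([c * x - s * y, s * x + c * y])

        tang = (world(t + h) - world(t - h)) / (2 * h)
        tang /= np.linalg.norm(tang)
        axis = (b_pt - a_pt) / np.linalg.norm(b_pt - a_pt)
        expected = math.degrees(math.acos(min(1.0, abs(float(np.dot(axis, tang))))))
        assert tilt_angle(fit, d) == pytest.approx(expected, abs=1e-6)


def test_degenerate_doublet_rejected():
    with pytest.raises(ValueError):
        _doublet((1.0, 1.0), (1.0, 1.0))


# ---------------------------------------------------------------------------
# rotation calls


def test_rotation_call_boundary_rule():
    on_curve = _doublet((100.0, 0.0), (100.0, 26.0))
    b_on = _doublet((74.0, 0.0), (100.0, 0.0))
    far_out = _doublet((100.0, 0.0), (128.0 + 2 * 14.0, 0.0))
    exact = _doublet((93.0, 0.0), (107.0, 0.0))  # clearance exactly 0.5 * r_b
    assert not is_rotated(CIRCLE, b_on).rotated
    assert not is_rotated(CIRCLE, on_curve).rotated
    assert is_rotated(CIRCLE, far_out).rotated
    assert is_rotated(CIRCLE, exact).rotated  # boundary equality counts
    assert is_rotated(CIRCLE, exact, kappa=0.5001).rotated is False


def test_inward_displacement_never_counts():
    inward = _doublet((100.0, 0.0), (50.0, 0.0))
    call = is_rotated(CIRCLE, inward)
    assert call.clearance < 0 and not call.rotated


def test_negative_kappa_rejected():
    with pytest.raises(ConfigurationError):
        is_rotated(CIRCLE, _doublet((100.0, 0.0), (130.0, 0.0)), kappa=-0.1)


def _section_from_spec(k, seed=0):
    spec = make_well_separated_spec(k, seed=seed)
    rng = np.random.default_rng(seed)
    return generate_section_coords(spec, rng)


@pytest.mark.parametrize("k,expect_break", [(0, False), (3, False), (4, True), (5, True)])
def test_count_and_break_from_generated_sections(k, expect_break):
    section, truth = _section_from_spec(k)
    fit = fit_circumference([d.a_center for d in section.doublets])
    assert count_rotated(section, fit) == k
    assert has_symmetry_break(section, fit) is expect_break


def test_disorganized_and_incomplete_sections_not_assessable():
    section, _ = _section_from_spec(5)
    fit = fit_circumference([d.a_center for d in section.doublets])
    disorganized = CrossSection("d", section.doublets, 2, disorganized=True)
    assert count_rotated(disorganized, fit) is None
    assert has_symmetry_break(disorganized, fit) is None
    partial = CrossSection("p", section.doublets[:7], 2)
    assert count_rotated(partial, fit) is None
    a = assess_section(partial)
    assert not a.assessable and a.symmetry_break is None


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    angle=st.floats(0, 2 * math.pi),
    scale=st.floats(0.2, 5.0),
    tx=st.floats(-500, 500),
    ty=st.floats(-500, 500),
    k=st.integers(0, 9),
)
def test_similarity_invariance_of_calls(angle, scale, tx, ty, k):
    """Rotation calls and the break flag are invariant under rigid motion
    plus uniform scaling of all coordinates (radii scaled along)."""
    section, _ = _section_from_spec(k, seed=k)
    c, s = math.cos(angle), math.sin(angle)

    def tf(p):
        return (
            scale * (c * p[0] - s * p[1]) + tx,
            scale * (s * p[0] + c * p[1]) + ty,
        )

    moved = CrossSection(
        "t",
        [
            DoubletObservation(
                d.index, tf(d.a_center), tf(d.b_center), scale * d.r_a, scale * d.r_b
            )
            for d in section.doublets
        ],
        section.central_pair_count,
    )
    a0 = assess_section(section)
    a1 = assess_section(moved)
    assert [c0.rotated for c0 in a0.calls] == [c1.rotated for c1 in a1.calls]
    assert a0.symmetry_break == a1.symmetry_break


def test_outward_motion_is_monotone():
    """Pushing one B-tubule outward along the normal at its projection never
    un-rotates it, and the rotated count never decreases."""
    section, _ = _section_from_spec(2, seed=5)
    fit = fit_circumference([d.a_center for d in section.doublets])
    target = section.doublets[0]
    base_count = count_rotated(section, fit)
    a, b = fit.semi_major, fit.semi_minor
    from axosym.geometry import _ellipse_nearest_t, _to_canonical

    u, v = _to_canonical(fit, target.b_center)
    t = _ellipse_nearest_t(a, b, u, v)
    # outward normal at the projection (canonical frame), back to world
    nrm = np.array([b * math.cos(t), a * math.sin(t)])
    nrm /= np.linalg.norm(nrm)
    c, s = math.cos(fit.orientation), math.sin(fit.orientation)
    nrm = np.array([c * nrm[0] - s * nrm[1], s * nrm[0] + c * nrm[1]])
    prev_rotated = False
    prev_count = base_count
    for delta in np.linspace(0.0, 60.0, 13):
        moved_b = (target.b_center[0] + delta * nrm[0], target.b_center[1] + delta * nrm[1])
        moved = CrossSection(
            "m",
            [
                DoubletObservation(d.index, d.a_center, moved_b if d.index == target.index else d.b_center, d.r_a, d.r_b)
                for d in section.doublets
            ],
            2,
        )
        call = is_rotated(fit, moved.doublets[0])
        count = count_rotated(moved, fit)
        assert call.rotated or not prev_rotated
        assert count >= prev_count
        prev_rotated, prev_count = call.rotated, count
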
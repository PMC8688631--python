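"""Measurement of the nine morphometric parameters on planar contours."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import LineString, Polygon

from tibmorph.errors import (
    AmbiguousSectionError,
    InsufficientArcError,
    NoCircleError,
)
from tibmorph.mesh_resection import PlanarContour
from tibmorph.morphometry import (
    PARAMETER_NAMES,
    chord_at,
    fit_circle,
    measure_all,
    measure_anterior_radius,
    measure_ap,
    measure_cm_cl,
    measure_condyle,
    measure_ml,
)
from tibmorph.synthetic import ParameterVector, make_contour

from conftest import ellipse_contour


class TestMlAp:
    def test_square(self, square_contour):
        ml, x_min, x_max = measure_ml(square_contour)
        assert (ml, x_min, x_max) == (10.0, -5.0, 5.0)
        ap, x_mid = measure_ap(square_contour)
        assert ap == pytest.approx(10.0)
        assert x_mid == 0.0

    def test_translation_invariance(self, square_contour):
        shifted = PlanarContour(points=square_contour.points + [5.0, -3.0])
        assert measure_ml(shifted)[0] == measure_ml(square_contour)[0]
        assert measure_ap(shifted)[0] == pytest.approx(
            measure_ap(square_contour)[0]
        )

    def test_ellipse_ap(self):
        ap, _ = measure_ap(ellipse_contour(36.26, 23.18))
        assert ap == pytest.approx(46.36, abs=1e-9)

    def test_four_crossings_rejected(self):
        # sideways-U polygon: the ML midline crosses the boundary 4 times
        pts = np.array(
            [(-5, -5), (5, -5), (5, -3), (-3, -3), (-3, 3), (5, 3), (5, 5),
             (-5, 5)], dtype=float,
        )
        with pytest.raises(AmbiguousSectionError):
            measure_ap(PlanarContour(points=pts))


class TestCondyle:
    def test_symmetric_contour_equal_widths(self):
        p = ParameterVector(ml=72, ap=46, map=49, lap=49, cm=14, cl=14,
                            mar=24, lar=24)
        c = make_contour(p)
        _, x_mid = measure_ap(c)
        wm, xm = measure_condyle(c, "medial", x_mid)
        wl, xl = measure_condyle(c, "lateral", x_mid)
        assert wm == pytest.approx(wl, abs=1e-6)
        assert abs(xm - x_mid) == pytest.approx(abs(xl - x_mid), abs=1e-6)

    def test_pooled_mean_condyle(self, pooled_params):
        c = make_contour(pooled_params)
        _, x_mid = measure_ap(c)
        width, x_line = measure_condyle(c, "medial", x_mid)
        assert width == pytest.approx(49.22, rel=0.01)
        assert abs(x_line - x_mid) == pytest.approx(14.29, rel=0.01)

    def test_width_matches_shapely_chord(self, male_contour):
        # independent oracle: intersect the polygon with the vertical line
        poly = Polygon(male_contour.points)
        _, x_mid = measure_ap(male_contour)
        for side in ("medial", "lateral"):
            width, x_line = measure_condyle(male_contour, side, x_mid)
            lo, hi = poly.bounds[1] - 1, poly.bounds[3] + 1
            seg = poly.intersection(LineString([(x_line, lo), (x_line, hi)]))
            ys = np.array([y for _, y in
                           (seg.coords if hasattr(seg, "coords") else
                            [pt for g in seg.geoms for pt in g.coords])])
            assert width == pytest.approx(ys.max() - ys.min(), abs=1e-9)

    def test_cm_cl(self):
        assert measure_cm_cl(0.0, -14.29, 15.28) == (14.29, 15.28)
        assert measure_cm_cl(3.0, 3.0, 3.0) == (0.0, 0.0)

    def test_mirrored_contour_swaps_cm_cl(self, male_contour):
        _, x_mid = measure_ap(male_contour)
        _, xm = measure_condyle(male_contour, "medial", x_mid)
        _, xl = measure_condyle(male_contour, "lateral", x_mid)
        mirrored = PlanarContour(points=(male_contour.points * [-1, 1])[::-1])
        _, x_mid2 = measure_ap(mirrored)
        _, xm2 = measure_condyle(mirrored, "medial", x_mid2)
        _, xl2 = measure_condyle(mirrored, "lateral", x_mid2)
        cm, cl = measure_cm_cl(x_mid, xm, xl)
        cm2, cl2 = measure_cm_cl(x_mid2, xm2, xl2)
        assert (cm2, cl2) == pytest.approx((cl, cm), abs=1e-9)


def _grid_search_circle(pts, steps=80, levels=4):
    """Coarse-to-fine 2D grid search over the center; r = mean distance."""
    cx, cy = pts.mean(axis=0)
    span = 2.0 * np.ptp(pts, axis=0).max()  # covers any plausible center
    best = None
    for _ in range(levels):
        xs = np.linspace(cx - span, cx + span, steps)
        ys = np.linspace(cy - span, cy + span, steps)
        gx, gy = np.meshgrid(xs, ys)
        d = np.hypot(pts[:, 0] - gx[..., None], pts[:, 1] - gy[..., None])
        r = d.mean(axis=-1)
        sse = ((d - r[..., None]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(sse.argmin(), sse.shape)
        if best is None or sse[i, j] < best[0]:
            best = (sse[i, j], gx[i, j], gy[i, j], r[i, j])
        _, cx, cy, _ = best
        span *= 4.0 / steps
    return best[3]


class TestFitCircle:
    def test_exact_circle(self):
        th = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pts = np.column_stack([3 + 24.43 * np.cos(th), -2 + 24.43 * np.sin(th)])
        fit = fit_circle(pts)
        assert fit.radius == pytest.approx(24.43, abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_circumcircle_of_three_points(self):
        fit = fit_circle(np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0]]))
        np.testing.assert_allclose(fit.center, [1.0, 0.0], atol=1e-9)
        assert fit.radius == pytest.approx(1.0, abs=1e-9)

    def test_collinear_points(self):
        with pytest.raises(NoCircleError):
            fit_circle(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))

    @pytest.mark.parametrize("span_deg", [20, 60, 180, 350])
    def test_noiseless_arc_exact_regardless_of_span(self, span_deg):
        th = np.linspace(0, np.deg2rad(span_deg), 40)
        pts = np.column_stack([10 + 26 * np.cos(th), 5 + 26 * np.sin(th)])
        assert fit_circle(pts).radius == pytest.approx(26.0, abs=1e-9)

    def test_noisy_arc_matches_grid_search(self):
        rng = np.random.default_rng(11)
        th = np.linspace(0.3, 2.0, 40)
        r0 = 24.0
        pts = np.column_stack([r0 * np.cos(th), r0 * np.sin(th)])
        pts += rng.normal(0, 0.1, pts.shape)
        fit = fit_circle(pts)
        oracle_r = _grid_search_circle(pts)
        assert fit.radius == pytest.approx(oracle_r, abs=0.05)


class TestAnteriorRadius:
    def test_symmetric_radii(self):
        p = ParameterVector(ml=72, ap=46, map=49, lap=49, cm=14, cl=14,
                            mar=24, lar=24)
        c = make_contour(p)
        rec = measure_all(c)
        assert rec.mar == pytest.approx(rec.lar, abs=1e-6)
        assert rec.mar == pytest.approx(24.0, rel=0.01)

    def test_male_mean_mar(self, male_contour):
        ml, _, _ = measure_ml(male_contour)
        _, x_mid = measure_ap(male_contour)
        w, x_line = measure_condyle(male_contour, "medial", x_mid)
        r = measure_anterior_radius(male_contour, "medial", ml, x_mid, w, x_line)
        assert r == pytest.approx(26.00, rel=0.01)

    def test_too_few_points(self, square_contour):
        with pytest.raises(InsufficientArcError):
            measure_anterior_radius(square_contour, "medial", 10.0, 0.0,
                                    10.0, -5.0)


class TestMeasureAll:
    def test_male_mean_roundtrip(self, male_contour, male_params):
        rec = measure_all(male_contour)
        for name, target in male_params.as_dict().items():
            assert getattr(rec, name) == pytest.approx(target, rel=0.01), name
        assert rec.ar == pytest.approx(77.52 / 49.26, abs=0.01)

    def test_circle_contour(self):
        rec = measure_all(ellipse_contour(25.0, 25.0, n=720))
        assert rec.ml == pytest.approx(50.0, abs=1e-6)
        assert rec.ap == pytest.approx(50.0, rel=1e-4)
        assert rec.ar == pytest.approx(1.0, rel=1e-4)
        assert rec.mar == pytest.approx(25.0, rel=1e-3)

    def test_ar_identity(self, male_contour):
        rec = measure_all(male_contour)
        assert abs(rec.ar * rec.ap - rec.ml) <= 1e-9 * rec.ml

    @given(dx=st.floats(-50, 50), dy=st.floats(-50, 50))
    def test_translation_invariance_all(self, male_contour, dx, dy):
        rec0 = measure_all(male_contour)
        rec1 = measure_all(
            PlanarContour(points=male_contour.points + [dx, dy])
        )
        for name in PARAMETER_NAMES:
            assert getattr(rec1, name) == pytest.approx(
                getattr(rec0, name), abs=1e-6
            ), name

    def test_resampling_stability(self, male_contour):
        rec0 = measure_all(male_contour)
        pts = np.vstack([male_contour.points, male_contour.points[:1]])
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        total = s[-1]
        targets = np.arange(0.0, total, 0.37)
        resampled = np.column_stack([
            np.interp(targets, s, pts[:, 0]), np.interp(targets, s, pts[:, 1])
        ])
        rec1 = measure_all(PlanarContour(points=resampled))
        for name in PARAMETER_NAMES:
            if name in ("cm", "cl"):
                # the condylar line sits on a resampled vertex, so its
                # position is only known to about half the vertex spacing
                assert getattr(rec1, name) == pytest.approx(
                    getattr(rec0, name), abs=0.25
                ), name
            else:
                assert getattr(rec1, name) == pytest.approx(
                    getattr(rec0, name), rel=0.005
                ), name


def test_chord_merges_tangencies(square_contour):
    # the contour vertex at a queried x must count once, not twice
    ys = chord_at(square_contour, 5.0)
    assert len(ys) == 2
    np.testing.assert_allclose(ys, [-5.0, 5.0])
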
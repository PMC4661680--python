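"""Raytracer oracles: Snell law, quadratic intersection, paraxial blur."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retisim.chart import ChartSpec, build_chart, sample_source
from retisim.eye import (
    OpticalSurface,
    build_schematic_eye,
    induce_myopia,
    paraxial_image_height,
    paraxial_trace_ray,
)
from retisim.raytrace import (
    LANDED,
    VIGNETTED,
    MapSpec,
    Ray,
    RetinalROI,
    TotalInternalReflectionError,
    _sample_pupil,
    intersect,
    refract,
    roi_from_region,
    simulate_image,
    total_flux,
    trace,
    trace_batch,
)


def random_unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestRefract:
    def test_normal_incidence_unchanged(self):
        d = np.array([0.0, 0.0, 1.0])
        n = np.array([0.0, 0.0, -1.0])
        out = refract(d, n, 1.0, 1.5)
        assert np.allclose(out, d, atol=1e-14)

    def test_30_degrees_closed_form(self):
        th1 = math.radians(30.0)
        d = np.array([math.sin(th1), 0.0, math.cos(th1)])
        n = np.array([0.0, 0.0, -1.0])
        out = refract(d, n, 1.0, 1.5)
        th2 = math.degrees(math.asin(out[0]))
        assert th2 == pytest.approx(19.471, abs=1e-3)

    def test_snell_residual_fuzzing(self, rng):
        # 1e4 random incidences: vector law must satisfy the scalar law
        worst = 0.0
        for _ in range(100):
            d = random_unit(rng, 100)
            nrm = random_unit(rng, 100)
            n1 = rng.uniform(1.0, 2.0, 100)
            n2 = rng.uniform(1.0, 2.0, 100)
            for i in range(100):
                cos1 = abs(float(d[i] @ nrm[i]))
                sin1 = math.sqrt(max(0.0, 1.0 - cos1 * cos1))
                if n1[i] * sin1 / n2[i] > 1.0 - 1e-9:
                    continue
                out = refract(d[i], nrm[i], n1[i], n2[i])
                cos2 = abs(float(out @ nrm[i]))
                sin2 = math.sqrt(max(0.0, 1.0 - cos2 * cos2))
                worst = max(worst, abs(n1[i] * sin1 - n2[i] * sin2))
        assert worst < 1e-12

    def test_tangential_component_direction_preserved(self, rng):
        d = random_unit(rng)[0]
        if d[2] < 0:
            d = -d
        n = np.array([0.0, 0.0, -1.0])
        out = refract(d, n, 1.0, 1.4)
        t_in = d - (d @ n) * n
        t_out = out - (out @ n) * n
        if np.linalg.norm(t_in) > 1e-12:
            cosang = (t_in @ t_out) / (np.linalg.norm(t_in) * np.linalg.norm(t_out))
            assert cosang == pytest.approx(1.0, abs=1e-12)

    def test_total_internal_reflection_raises(self):
        th1 = math.radians(80.0)
        d = np.array([math.sin(th1), 0.0, math.cos(th1)])
        n = np.array([0.0, 0.0, -1.0])
        with pytest.raises(TotalInternalReflectionError):
            refract(d, n, 1.5, 1.0)

    @given(
        theta=st.floats(0.0, 1.4),
        phi=st.floats(0.0, 6.28),
        n1=st.floats(1.0, 2.0),
        n2=st.floats(1.0, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_snell_property(self, theta, phi, n1, n2):
        d = np.array(
            [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta)]
        )
        n = np.array([0.0, 0.0, -1.0])
        sin1 = math.sin(theta)
        if n1 * sin1 / n2 >= 1.0 - 1e-9:
            return
        out = refract(d, n, n1, n2)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)
        sin2 = math.sqrt(out[0] ** 2 + out[1] ** 2)
        assert n1 * sin1 == pytest.approx(n2 * sin2, abs=1e-12)


class TestIntersect:
    def test_axial_ray_hits_vertex(self):
        s = OpticalSurface(vertex_z=10.0, radius=7.8, semi_aperture=5.0, n_after=1.4)
        ray = Ray(origin=[0.0, 0.0, 0.0], direction=[0.0, 0.0, 1.0])
        hit = intersect(ray, s)
        assert hit is not None
        assert np.allclose(hit, [0.0, 0.0, 10.0], atol=1e-12)

    def test_beyond_semi_aperture_misses(self):
        s = OpticalSurface(vertex_z=10.0, radius=7.8, semi_aperture=2.0, n_after=1.4)
        ray = Ray(origin=[3.0, 0.0, 0.0], direction=[0.0, 0.0, 1.0])
        assert intersect(ray, s) is None

    def test_flat_surface(self):
        s = OpticalSurface(vertex_z=5.0, radius=0.0, semi_aperture=4.0, n_after=1.4)
        ray = Ray(origin=[1.0, 1.0, 0.0], direction=[0.0, 0.0, 1.0])
        hit = intersect(ray, s)
        assert np.allclose(hit, [1.0, 1.0, 5.0])

    def test_against_quadratic_root_oracle(self, rng):
        # 1e4 random oblique rays vs an independent np.roots-based solver
        n_cases = 10_000
        s = OpticalSurface(vertex_z=8.0, radius=6.5, semi_aperture=5.0, n_after=1.4)
        cz = s.vertex_z + s.radius
        worst = 0.0
        checked = 0
        for _ in range(n_cases):
            o = np.array([rng.uniform(-3, 3), rng.uniform(-3, 3), rng.uniform(-3, 1)])
            d = np.array([rng.normal(0, 0.15), rng.normal(0, 0.15), 1.0])
            d /= np.linalg.norm(d)
            ray = Ray(origin=o, direction=d)
            hit = intersect(ray, s)
            # oracle: roots of |o + t d - c|^2 = R^2, nearest forward
            # vertex-side solution
            oc = o - np.array([0.0, 0.0, cz])
            coeffs = [1.0, 2.0 * (d @ oc), oc @ oc - s.radius**2]
            roots = np.roots(coeffs)
            roots = sorted(
                t.real
                for t in roots
                if abs(t.imag) < 1e-12
                and t.real > 1e-9
                and (o + t.real * d)[2] <= cz
            )
            if hit is None:
                if roots:
                    p = o + roots[0] * d
                    assert math.hypot(p[0], p[1]) > s.semi_aperture
                continue
            assert roots, "tracer found a hit the oracle missed"
            p = o + roots[0] * d
            worst = max(worst, float(np.linalg.norm(hit - p)))
            checked += 1
        assert checked > n_cases // 2
        assert worst < 1e-10


class TestTrace:
    def test_on_axis_ray_lands_at_origin(self, default_eye):
        ray = Ray(origin=[0.0, 0.0, -6096.0], direction=[0.0, 0.0, 1.0])
        out = trace(default_eye, ray)
        assert out.status == "landed"
        assert math.hypot(out.origin[0], out.origin[1]) < 1e-9

    def test_ray_outside_pupil_vignetted(self, default_eye):
        # aimed at the iris outside the pupil opening
        target = np.array([default_eye.stop_semi * 2.0, 0.0, default_eye.stop_z])
        origin = np.array([0.0, 0.0, -6096.0])
        d = target - origin
        ray = Ray(origin=origin, direction=d / np.linalg.norm(d))
        out = trace(default_eye, ray)
        assert out.status == "vignetted"

    def test_blur_radius_matches_paraxial_defocus_oracle(self):
        # small pupil so third-order aberration stays well below the 5%
        # tolerance; the pencil aims uniformly at the stop disc and the
        # oracle is the paraxially traced stop-edge-aimed marginal ray
        eye = induce_myopia(build_schematic_eye(stop_semi=0.75), 5.0)
        dist = 6096.0
        u0 = eye.stop_semi / (dist + eye.stop_z)
        y, u = paraxial_trace_ray(eye.surfaces, u0 * dist, u0, 0.0, 1.0)
        blur_radius = abs(y + u * (eye.retina_z - eye.surfaces[-1].vertex_z))
        rms_pred = blur_radius / math.sqrt(2.0)  # uniform disc

        n = 10_000
        rng = np.random.default_rng(5)
        origins = np.tile([0.0, 0.0, -dist], (n, 1))
        targets = _sample_pupil(eye, n, rng)
        d = targets - origins
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        status, land = trace_batch(eye, origins, d)
        land = land[status == LANDED]
        rms = math.sqrt(float((land**2).sum(axis=1).mean()))
        assert rms == pytest.approx(rms_pred, rel=0.05)

    def test_blur_monotone_in_myopia(self):
        base = build_schematic_eye()
        dist = 6096.0
        rng = np.random.default_rng(9)
        n = 5_000
        origins = np.tile([0.0, 0.0, -dist], (n, 1))
        rms_values = []
        for d_myo in range(0, 11):
            eye = induce_myopia(base, float(d_myo))
            targets = _sample_pupil(eye, n, np.random.default_rng(9))
            d = targets - origins
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            status, land = trace_batch(eye, origins, d)
            land = land[status == LANDED]
            rms_values.append(math.sqrt(float((land**2).sum(axis=1).mean())))
        assert all(a <= b for a, b in zip(rms_values, rms_values[1:]))


@pytest.fixture(scope="module")
def source(default_chart):
    return sample_source(default_chart, 20_000, seed=2)


class TestSimulateImage:
    def test_same_seed_identical_maps(self, default_eye, source):
        a = simulate_image(default_eye, source, seed=5)
        b = simulate_image(default_eye, source, seed=5)
        assert np.array_equal(a.bins, b.bins)
        assert a.landed == b.landed

    def test_power_conservation(self, default_eye, source):
        m = simulate_image(default_eye, source, seed=5)
        total = m.landed + m.vignetted + m.absorbed
        assert total == pytest.approx(m.launched, rel=1e-9)
        assert np.all(m.bins >= 0)

    def test_full_window_roi_equals_landed_in_window(self, default_eye, source):
        m = simulate_image(default_eye, source, seed=5)
        roi = RetinalROI(rects=(m.window,))
        assert total_flux(m, roi) == pytest.approx(m.landed_in_window, rel=1e-12)

    def test_empty_roi_zero(self, default_eye, source):
        m = simulate_image(default_eye, source, seed=5)
        roi = RetinalROI(rects=((100.0, 101.0, 100.0, 101.0),))
        assert total_flux(m, roi) == 0.0

    def test_quadrant_partition_sums_to_window_total(self, default_eye, source):
        m = simulate_image(default_eye, source, seed=5)
        x0, x1, y0, y1 = m.window
        xm, ym = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        # quadrants split between bin centers, so each center lands in
        # exactly one quadrant
        eps = 1e-9
        quads = [
            (x0, xm, y0, ym),
            (xm + eps, x1, y0, ym),
            (x0, xm, ym + eps, y1),
            (xm + eps, x1, ym + eps, y1),
        ]
        total = sum(total_flux(m, RetinalROI(rects=(q,))) for q in quads)
        assert total == pytest.approx(m.landed_in_window, rel=1e-9)

    def test_myopia_reduces_roi_flux(self, default_eye, default_chart):
        source = sample_source(default_chart, 200_000, seed=1)
        roi = roi_from_region(default_eye, default_chart, "whole")
        plano = simulate_image(default_eye, source, seed=1)
        myopic = simulate_image(induce_myopia(default_eye, 10.0), source, seed=1)
        assert total_flux(myopic, roi) < total_flux(plano, roi)

    def test_point_source_centroid_matches_paraxial_image_height(self, default_eye):
        # field angle 1 degree (<= 2 degrees)
        dist = 6096.0
        h = dist * math.tan(math.radians(1.0))
        n = 20_000
        origins = np.tile([0.0, h, -dist], (n, 1))
        targets = _sample_pupil(default_eye, n, np.random.default_rng(3))
        d = targets - origins
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        status, land = trace_batch(default_eye, origins, d)
        land = land[status == LANDED]
        centroid_y = float(land[:, 1].mean())
        y_pred = paraxial_image_height(default_eye, h, -dist)
        # one default bin of the whole-chart window
        chart_img_half = 0.53
        bin_size = 2 * chart_img_half * 1.2 / 256
        assert abs(centroid_y - y_pred) < bin_size

    def test_map_spec_window_override(self, default_eye, source):
        spec = MapSpec(n_bins=32, window=(-1.0, 1.0, -1.0, 1.0))
        m = simulate_image(default_eye, source, map_spec=spec, seed=5)
        assert m.bins.shape == (32, 32)
        assert m.window == (-1.0, 1.0, -1.0, 1.0)
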
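"""TIMAMP: lattice, density anchoring, Heun integration, spline styling."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from migflow.field import AzimuthalEquidistant
from migflow.records import AltitudeBand, RadarSite, ValidationError
from migflow.synth import FlowSpec, generate_case
from migflow.timamp import (
    Anchor,
    GridVolume,
    TimampConfig,
    build_lattice,
    cardinal_spline,
    compute_migrants,
    draw_anchors,
    heun_step,
    integrate_pathline,
    run_timamp,
    smooth_and_style,
    strata_bands,
    volume_migrants,
)
from tests.conftest import AnalyticField

T0 = datetime(2013, 4, 5, 18, 0, tzinfo=timezone.utc)
WINDOW = dict(window_start=T0 + timedelta(hours=1), duration_hours=2, strata_count=2)
ONE_SITE = [RadarSite("r1", "solo", 5.0, 51.0)]


def cfg(**kw):
    args = dict(WINDOW)
    args.update(kw)
    return TimampConfig(**args)


class TestConfig:
    @pytest.mark.parametrize("bad", [0, 9, -1])
    def test_duration_menu_enforced(self, bad):
        with pytest.raises(ValidationError):
            cfg(duration_hours=bad)

    def test_strata_menu_enforced(self):
        with pytest.raises(ValidationError):
            cfg(strata_count=7)

    def test_migrants_per_path_positive(self):
        with pytest.raises(ValidationError):
            cfg(migrants_per_path=0)

    def test_strata_partition_is_even(self):
        bands = strata_bands(5, 4000.0)
        assert len(bands) == 5
        assert bands[0] == AltitudeBand(0.0, 800.0)
        assert bands[-1] == AltitudeBand(3200.0, 4000.0)


class TestLattice:
    def test_centers_within_radius(self):
        vols = build_lattice(ONE_SITE, cfg(), strata_bands(2, 4000.0))
        proj = AzimuthalEquidistant.for_sites(ONE_SITE)
        site = proj.project_site(ONE_SITE[0])
        for v in vols:
            assert np.hypot(*(v.center - site)) <= 75.0 + 1e-9

    def test_cell_count_matches_disk_area(self):
        vols = build_lattice(ONE_SITE, cfg(), [AltitudeBand(0.0, 4000.0)])
        expected = np.pi * 75.0**2 / 10.0**2
        assert len(vols) == pytest.approx(expected, rel=0.04)

    def test_two_distant_radars_give_disjoint_disks(self):
        sites = [RadarSite("a", "a", 0.0, 0.0), RadarSite("b", "b", 2.7, 0.0)]  # ~300 km
        vols = build_lattice(sites, cfg(), [AltitudeBand(0.0, 4000.0)])
        proj = AzimuthalEquidistant.for_sites(sites)
        xa = proj.project_site(sites[0])
        xb = proj.project_site(sites[1])
        near_a = [v for v in vols if np.hypot(*(v.center - xa)) <= 75.0]
        near_b = [v for v in vols if np.hypot(*(v.center - xb)) <= 75.0]
        assert len(near_a) + len(near_b) == len(vols)
        assert abs(len(near_a) - len(near_b)) <= 2  # same disk, discretized


def uniform_density_field(rho):
    f = AnalyticField(lambda xy, t: (0.0, 0.0), t0=T0, n_intervals=100)
    f._density = rho
    return f


class TestVolumeMigrants:
    def volume(self, depth_km=0.8):
        return GridVolume(0, 0, AltitudeBand(0.0, 800.0), 0,
                          np.array([0.0, 0.0]), 10.0, depth_km)

    def test_uniform_density_times_volume(self):
        v = self.volume()
        assert volume_migrants(v, uniform_density_field(100.0), cfg()) == pytest.approx(8000.0)

    def test_zero_density_zero_migrants(self):
        v = self.volume()
        assert volume_migrants(v, uniform_density_field(0.0), cfg()) == 0.0

    def test_time_varying_density_uses_window_mean(self):
        f = AnalyticField(lambda xy, t: (0.0, 0.0), t0=T0, n_intervals=100)
        f.density = lambda p, t, band=0: 50.0 if t < T0 + timedelta(hours=2) else 150.0
        v = self.volume()
        got = volume_migrants(v, f, cfg())  # window = hours 1..3: half 50, half 150
        assert got == pytest.approx(100.0 * v.volume_km3)


class TestAnchors:
    def make_volume(self, migrants):
        v = GridVolume(2, 3, AltitudeBand(0.0, 2000.0), 0,
                       np.array([20.0, 30.0]), 10.0, 2.0)
        v.expected_migrants = migrants
        return v

    def test_zero_expectation_no_anchors(self, rng):
        assert draw_anchors([self.make_volume(0.0)], cfg(), rng) == []

    def test_integer_lambda_is_deterministic(self, rng):
        # 3 paths expected in a single-step window: exactly 3, no randomness in count
        c = cfg(duration_hours=1, step_minutes=60, migrants_per_path=10_000)
        anchors = draw_anchors([self.make_volume(30_000.0)], c, rng)
        assert len(anchors) == 3
        for a in anchors:
            assert (20.0 <= a.point[0] <= 30.0) and (30.0 <= a.point[1] <= 40.0)

    def test_monte_carlo_mean_matches_expectation(self):
        vols = [self.make_volume(m) for m in (4_200.0, 17_500.0, 33_300.0, 8_000.0)]
        c = cfg(migrants_per_path=10_000)
        lam = sum(v.expected_migrants for v in vols) / c.migrants_per_path
        rng = np.random.default_rng(99)
        counts = np.array([len(draw_anchors(vols, c, rng)) for _ in range(2000)])
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - lam) < 3 * se + 1e-9


class TestHeun:
    def test_constant_field_exact(self):
        f = AnalyticField(lambda xy, t: (10.0, 0.0))
        out = heun_step(np.array([0.0, 0.0]), T0, 1200.0, f, 0)
        np.testing.assert_allclose(out, [12.0, 0.0])

    def test_forward_then_backward_returns(self):
        f = AnalyticField(lambda xy, t: (7.0, -3.0))
        p = np.array([5.0, 5.0])
        q = heun_step(heun_step(p, T0, 1200.0, f, 0), T0 + timedelta(seconds=1200), -1200.0, f, 0)
        np.testing.assert_allclose(q, p, atol=1e-12)

    def test_linear_shear_is_exact(self):
        # u = a*y with y constant along the flow: Heun reproduces it exactly
        a = 0.05  # (m/s) per km
        f = AnalyticField(lambda xy, t: (a * xy[1], 0.0))
        p0 = np.array([0.0, 40.0])
        p1 = heun_step(p0, T0, 1200.0, f, 0)
        np.testing.assert_allclose(p1, [a * 40.0 * 1200.0 / 1000.0, 40.0], atol=1e-12)

    def test_rotation_error_shrinks_quadratically(self):
        omega = 2 * np.pi / (4 * 3600.0)  # rad/s, 4 h revolution
        f = AnalyticField(lambda xy, t: (-omega * xy[1] * 1000.0, omega * xy[0] * 1000.0))
        start = np.array([80.0, 0.0])
        total = 4 * 3600.0

        def final_error(h):
            p, t = start.copy(), T0
            for _ in range(int(total / h)):
                p = heun_step(p, t, h, f, 0)
                t += timedelta(seconds=h)
            return np.hypot(*(p - start))  # analytic: back to start

        e1, e2 = final_error(1200.0), final_error(600.0)
        order = np.log2(e1 / e2)
        assert 1.7 < order < 2.3


class TestIntegratePathline:
    def anchor(self, point=(0.0, 0.0), step=2):
        return Anchor(np.asarray(point, float), 0, AltitudeBand(0.0, 2000.0), step)

    def test_constant_field_straight_72km_centrally_anchored(self):
        f = AnalyticField(lambda xy, t: (10.0, 0.0), t0=T0 - timedelta(hours=6), n_intervals=72)
        pl = integrate_pathline(self.anchor(), f, cfg())
        assert pl.vertices.shape == (7, 2)
        chord = pl.vertices[-1] - pl.vertices[0]
        np.testing.assert_allclose(chord, [72.0, 0.0], atol=1e-9)
        assert pl.anchor_index == 3
        np.testing.assert_allclose(pl.vertices[pl.anchor_index], [0.0, 0.0])
        assert not pl.truncated_backward and not pl.truncated_forward

    def test_zero_field_collapses_to_a_point(self):
        f = AnalyticField(lambda xy, t: (0.0, 0.0), t0=T0 - timedelta(hours=6), n_intervals=72)
        pl = integrate_pathline(self.anchor(), f, cfg())
        assert np.ptp(pl.vertices, axis=0).max() == 0.0

    def test_rotation_vertices_stay_on_circle(self):
        omega = 2 * np.pi / (24 * 3600.0)  # slow: h*omega << 1
        f = AnalyticField(lambda xy, t: (-omega * xy[1] * 1000.0, omega * xy[0] * 1000.0),
                          t0=T0 - timedelta(hours=6), n_intervals=72)
        pl = integrate_pathline(self.anchor(point=(60.0, 0.0)), f, cfg())
        radii = np.hypot(pl.vertices[:, 0], pl.vertices[:, 1])
        assert np.max(np.abs(radii - 60.0) / 60.0) < 1e-3

    def test_vertices_strictly_time_ordered(self):
        f = AnalyticField(lambda xy, t: (10.0, 5.0), t0=T0 - timedelta(hours=6), n_intervals=72)
        pl = integrate_pathline(self.anchor(), f, cfg())
        assert all(a < b for a, b in zip(pl.times, pl.times[1:]))


class TestSpline:
    def test_collinear_vertices_stay_collinear(self):
        pts = np.stack([np.linspace(0, 10, 5), np.linspace(0, 20, 5)], axis=1)
        curve = cardinal_spline(pts, tension=0.5)
        cross = curve[:, 0] * 2.0 - curve[:, 1]  # on the line y = 2x
        np.testing.assert_allclose(cross, 0.0, atol=1e-9)

    @pytest.mark.parametrize("tension", [0.0, 0.3, 0.5, 1.0])
    def test_passes_through_every_control_vertex(self, tension, rng):
        pts = rng.uniform(-50, 50, (6, 2))
        curve = cardinal_spline(pts, tension=tension, samples_per_segment=8)
        for i, p in enumerate(pts):
            np.testing.assert_allclose(curve[i * 8], p, atol=1e-12)

    def test_catmull_rom_limit_matches_basis_oracle(self, rng):
        # explicit Catmull-Rom basis-matrix evaluation, independent route
        pts = rng.uniform(-100, 100, (5, 2))

        def catmull_rom(p0, p1, p2, p3, t):
            t2, t3 = t * t, t * t * t
            return 0.5 * (
                2 * p1 + (-p0 + p2) * t
                + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t2
                + (-p0 + 3 * p1 - 3 * p2 + p3) * t3
            )

        spp = 10
        curve = cardinal_spline(pts, tension=1.0, samples_per_segment=spp)
        for seg in (1, 2):  # interior segments, where CR tangents apply
            for j, t in enumerate(np.linspace(0, 1, spp + 1)):
                expected = catmull_rom(pts[seg - 1], pts[seg], pts[seg + 1],
                                       pts[min(seg + 2, 4)], t)
                got = curve[seg * spp + j]
                np.testing.assert_allclose(got, expected, atol=1e-9)


class TestSmoothAndStyle:
    def make_pathline(self, verts, dens):
        from migflow.timamp import Pathline
        verts = np.asarray(verts, float)
        return Pathline(
            anchor=Anchor(verts[0].copy(), 0, AltitudeBand(0, 800), 0),
            anchor_time=T0,
            vertices=verts,
            times=[T0 + timedelta(minutes=20 * i) for i in range(len(verts))],
            densities=np.asarray(dens, float),
            anchor_index=0,
        )

    def test_thickness_maps_density_and_clips(self):
        pl = self.make_pathline([[0, 0], [10, 0], [20, 0]], [0.0, 250.0, 1e6])
        sp = smooth_and_style(pl, cfg(), samples_per_segment=1)
        assert sp.thickness[0] == pytest.approx(0.5)  # thickness_min
        assert sp.thickness[1] == pytest.approx(0.5 + (6.0 - 0.5) * 0.5)
        assert sp.thickness[-1] == pytest.approx(6.0)  # clipped at max

    def test_single_point_pathline_is_dot_only(self):
        pl = self.make_pathline([[3, 4], [3, 4]], [10.0, 10.0])
        sp = smooth_and_style(pl, cfg())
        assert sp.curve.shape == (1, 2)
        np.testing.assert_allclose(sp.endpoint, [3.0, 4.0])


class TestEndToEnd:
    def test_uniform_flow_mean_bearing_is_41_degrees(self, uniform_case):
        c = cfg(window_start=T0 + timedelta(hours=1), duration_hours=2,
                strata_count=2, migrants_per_path=500_000, seed=5)
        res = run_timamp(uniform_case, c)
        assert len(res.pathlines) > 10
        bearings = []
        for sp in res.pathlines:
            v = sp.pathline.vertices
            d = v[-1] - v[0]
            if np.hypot(*d) > 1.0:
                bearings.append(np.degrees(np.arctan2(d[0], d[1])) % 360.0)
        assert np.allclose(bearings, 41.0, atol=1.0)

    def test_anchor_distribution_tracks_density_north_south(self):
        # two radars 800 km apart straddling the equator-line of the layout;
        # the northern half carries 4x the bird density
        sites = [RadarSite("n", "north", 5.0, 54.6), RadarSite("s", "south", 5.0, 47.4)]
        case = generate_case(
            layout=sites,
            flow=FlowSpec(kind="uniform", speed=10.0, bearing_deg=41.0, north_south_ratio=4.0),
            start=T0, hours=3.0, seed=21,
        )
        c = cfg(window_start=T0 + timedelta(hours=1), duration_hours=1,
                strata_count=1, migrants_per_path=100_000, seed=3)
        res = run_timamp(case, c)
        lam_n = sum(v.expected_migrants for v in res.volumes if v.center[1] > 0)
        lam_s = sum(v.expected_migrants for v in res.volumes if v.center[1] < 0)
        assert lam_n / lam_s == pytest.approx(4.0, rel=0.15)
        n_count = sum(1 for a in res.anchors if a.point[1] > 0)
        s_count = sum(1 for a in res.anchors if a.point[1] < 0)
        assert s_count > 30
        assert n_count / s_count == pytest.approx(lam_n / lam_s, rel=0.25)

    def test_pathline_final_positions_converge_quadratically(self):
        # halving the integration step changes endpoints by O(h^2)
        omega = 2 * np.pi / (12 * 3600.0)
        f = AnalyticField(lambda xy, t: (-omega * xy[1] * 1000.0, omega * xy[0] * 1000.0),
                          t0=T0 - timedelta(hours=12), n_intervals=144, interval_minutes=20)
        anchor = Anchor(np.array([70.0, 0.0]), 0, AltitudeBand(0, 4000), 2)

        def endpoint(step_minutes):
            c = cfg(duration_hours=2, step_minutes=step_minutes)
            return integrate_pathline(anchor, f, c).vertices[-1]

        e20 = endpoint(20)
        e10 = endpoint(10)
        e5 = endpoint(5)
        d1 = np.hypot(*(e20 - e10))
        d2 = np.hypot(*(e10 - e5))
        assert d1 / d2 == pytest.approx(4.0, rel=0.35)
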
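"""Projection and inverse-distance-weighted field reconstruction."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from migflow.field import (
    AzimuthalEquidistant,
    FieldUndefinedError,
    SampleSet,
    TimeRangeError,
    VectorField,
    field_at,
    idw_interpolate,
    interpolate_scalar,
    interpolate_vector,
)
from migflow.preprocess import PreprocessConfig
from migflow.records import AggregatedRecord, AltitudeBand, RadarSite
from migflow.synth import EU5_SITES

T = datetime(2013, 4, 6, 1, 0, tzinfo=timezone.utc)
BAND = AltitudeBand(200.0, 1600.0)


class TestProjection:
    def test_centroid_maps_to_origin(self):
        proj = AzimuthalEquidistant.for_sites(list(EU5_SITES))
        x, y = proj.forward(proj.lon0, proj.lat0)
        assert abs(float(x)) < 1e-9 and abs(float(y)) < 1e-9

    def test_one_degree_north_is_111km(self):
        proj = AzimuthalEquidistant(5.0, 51.0)
        x, y = proj.forward(5.0, 52.0)
        assert float(y) == pytest.approx(111.195, abs=0.05)
        assert abs(float(x)) < 1e-9

    def test_round_trip_under_one_metre(self, rng):
        proj = AzimuthalEquidistant(5.0, 51.0)
        lon = rng.uniform(-3.0, 13.0, 100)
        lat = rng.uniform(44.0, 58.0, 100)
        x, y = proj.forward(lon, lat)
        lon2, lat2 = proj.inverse(x, y)
        x2, y2 = proj.forward(lon2, lat2)
        err_km = np.hypot(np.asarray(x) - x2, np.asarray(y) - y2)
        assert err_km.max() < 1e-3

    def test_distance_from_origin_preserved(self):
        # the projection is azimuthal equidistant: range rings are exact
        proj = AzimuthalEquidistant(5.0, 51.0)
        x, y = proj.forward(5.0, 53.0)
        assert np.hypot(x, y) == pytest.approx(2 * 111.195, rel=1e-3)


def brute_idw(query, xy, values, k, p=2.0):
    """Independent IDW oracle: full sort, explicit weight normalization."""
    d = np.sqrt(((np.asarray(xy) - query) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    if d[order[0]] == 0.0:
        return np.asarray(values)[order[0]]
    w = 1.0 / d[order] ** p
    return (w[:, None] * np.asarray(values)[order]).sum(axis=0) / w.sum()


def sample_set(xy, uv=None, rho=None):
    xy = np.asarray(xy, float)
    n = len(xy)
    uv = np.zeros((n, 2)) if uv is None else np.asarray(uv, float)
    rho_arr = np.zeros(n) if rho is None else np.asarray(rho, float)
    return SampleSet(
        xy=xy,
        uv=uv,
        rho=rho_arr,
        has_vector=np.ones(n, bool),
        has_density=np.ones(n, bool) if rho is not None else np.zeros(n, bool),
    )


class TestIDW:
    def test_constant_vector_everywhere(self, rng):
        s = sample_set(rng.uniform(-100, 100, (6, 2)), uv=np.tile([3.0, -1.0], (6, 1)))
        for _ in range(10):
            q = rng.uniform(-150, 150, 2)
            np.testing.assert_allclose(interpolate_vector(q, s), [3.0, -1.0])

    def test_midpoint_of_two_equidistant_samples(self):
        s = sample_set([[0.0, 0.0], [10.0, 0.0]], uv=[[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(interpolate_vector(np.array([5.0, 0.0]), s), [0.5, 0.5])

    def test_matches_brute_force_on_six_radars(self, rng):
        for _ in range(100):
            xy = rng.uniform(-200, 200, (6, 2))
            uv = rng.normal(0, 10, (6, 2))
            rho = rng.uniform(0, 300, 6)
            q = rng.uniform(-250, 250, 2)
            got = interpolate_vector(q, sample_set(xy, uv=uv), k=5)
            np.testing.assert_allclose(got, brute_idw(q, xy, uv, 5), rtol=1e-12)
            got_r = interpolate_scalar(q, sample_set(xy, rho=rho), k=5)
            assert got_r == pytest.approx(brute_idw(q, xy, rho[:, None], 5)[0], rel=1e-12)

    def test_exact_hit_returns_sample(self, rng):
        xy = rng.uniform(-50, 50, (5, 2))
        rho = rng.uniform(0, 10, 5)
        s = sample_set(xy, rho=rho)
        assert interpolate_scalar(xy[3].copy(), s) == rho[3]

    def test_uniform_scalar(self):
        s = sample_set([[0, 0], [10, 0], [0, 10]], rho=[7.0, 7.0, 7.0])
        assert interpolate_scalar(np.array([3.0, 3.0]), s) == pytest.approx(7.0)

    def test_k_geq_n_equals_global_idw(self, rng):
        xy = rng.uniform(-100, 100, (4, 2))
        rho = rng.uniform(0, 100, 4)
        q = np.array([7.0, -13.0])
        s = sample_set(xy, rho=rho)
        assert interpolate_scalar(q, s, k=10) == pytest.approx(
            brute_idw(q, xy, rho[:, None], 4)[0], rel=1e-12
        )

    def test_no_samples_is_field_undefined(self):
        with pytest.raises(FieldUndefinedError):
            idw_interpolate(np.zeros(2), np.zeros((0, 2)), np.zeros(0))

    def test_continuity_of_nearby_probes(self, rng):
        xy = rng.uniform(-100, 100, (6, 2))
        uv = rng.normal(0, 10, (6, 2))
        s = sample_set(xy, uv=uv)
        q = np.array([150.0, 150.0])  # away from samples, no k-switch
        a = interpolate_vector(q, s, k=6)
        b = interpolate_vector(q + [0.001, 0.0], s, k=6)
        assert np.hypot(*(a - b)) < 0.1


@settings(max_examples=50, deadline=None)
@given(st.data())
def test_idw_value_in_convex_hull_and_exact_at_samples(data):
    """IDW with positive weights is a convex combination of sample values."""
    n = data.draw(st.integers(2, 8))
    coords = data.draw(
        st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=n, max_size=n, unique=True,
        )
    )
    vals = data.draw(st.lists(st.floats(-50, 50), min_size=n, max_size=n))
    xy = np.asarray(coords, float)
    v = np.asarray(vals, float)
    q = np.array([
        data.draw(st.floats(-120, 120)),
        data.draw(st.floats(-120, 120)),
    ])
    got = idw_interpolate(q, xy, v, k=5)
    assert v.min() - 1e-9 <= got <= v.max() + 1e-9
    i = data.draw(st.integers(0, n - 1))
    assert idw_interpolate(xy[i].copy(), xy, v, k=5) == v[i]


def make_field(records, sites=None, **kw):
    sites = sites or list(EU5_SITES)
    return VectorField.from_aggregates(sites, records, config=PreprocessConfig(), **kw)


class TestVectorField:
    def records(self):
        out = []
        for i, s in enumerate(EU5_SITES):
            for j in range(3):  # three 20-min intervals
                out.append(AggregatedRecord(
                    s.radar_id, T + timedelta(minutes=20 * j), BAND,
                    density=50.0 + i, u=5.0 + j, v=1.0,
                ))
        return out

    def test_snapshot_piecewise_constant(self):
        f = make_field(self.records())
        q = np.array([10.0, 20.0])
        v0 = field_at(f, T, 0).velocity(q)
        v19 = field_at(f, T + timedelta(minutes=19), 0).velocity(q)
        np.testing.assert_array_equal(v0, v19)
        v20 = field_at(f, T + timedelta(minutes=20), 0).velocity(q)
        assert v20[0] == pytest.approx(6.0)

    def test_outside_range_raises(self):
        f = make_field(self.records())
        with pytest.raises(TimeRangeError):
            f.at(T + timedelta(hours=1), 0)
        with pytest.raises(TimeRangeError):
            f.at(T - timedelta(minutes=1), 0)

    def test_exact_at_radar_sites(self):
        f = make_field(self.records())
        xy = f.projection.project_site(EU5_SITES[2])
        np.testing.assert_allclose(f.velocity(xy, T, 0), [5.0, 1.0])
        assert f.density(xy, T, 0) == pytest.approx(52.0)

    def test_zero_convention_participates_missing_excluded(self):
        recs = [
            AggregatedRecord("eu01", T, BAND, density=10.0, u=0.0, v=0.0,
                             velocity_is_zero_convention=True),
            AggregatedRecord("eu02", T, BAND, density=10.0, u=None, v=None),
            AggregatedRecord("eu03", T, BAND, density=10.0, u=8.0, v=0.0),
        ]
        f = make_field(recs)
        a = f.projection.project_site(EU5_SITES[0])
        b = f.projection.project_site(EU5_SITES[1])
        # the zero-convention radar pins the field to rest at its site
        np.testing.assert_array_equal(f.velocity(a, T, 0), [0.0, 0.0])
        # the missing-velocity radar does not: field there blends the others
        v = f.velocity(b, T, 0)
        assert 0.0 < v[0] < 8.0

    def test_time_blend_interpolates_between_intervals(self):
        f = make_field(self.records(), time_blend=True)
        q = np.array([0.0, 0.0])
        v = f.velocity(q, T + timedelta(minutes=10), 0)
        assert v[0] == pytest.approx(5.5)
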
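"""TAWSS/OSI definitions, area-weighted summaries and low-shear areas."""
import numpy as np
import pytest

from aneushear import (
    InvalidParameterError,
    TriSurfaceField,
    low_shear_areas,
    pointwise_tawss_osi,
    region_summary,
)
from conftest import random_wss_field


def simple_field(values_fn, n_times=30, period=1.0):
    """Four-point, two-triangle field (one dome, one parent triangle)."""
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
    tris = np.array([[0, 1, 2], [1, 3, 2]])
    region = np.array([1, 1, 2, 2])
    times = np.linspace(0, period, n_times)
    wss = np.stack([values_fn(t) for t in times])
    return TriSurfaceField(points=pts, triangles=tris, region=region, times=times, wss=wss)


def oracle_tawss_osi(field, refine=10):
    """Brute-force oracle: resample the sampled series (the magnitude series
    for the TAWSS integrand, the component series for the vector integral)
    on a refine-x denser grid and trapezoid-integrate there."""
    t = field.times
    fine = np.unique(np.concatenate(
        [np.linspace(t[i], t[i + 1], refine + 1) for i in range(t.size - 1)]
    ))
    period = t[-1] - t[0]
    mag = np.linalg.norm(field.wss, axis=2)  # (K, N) sampled magnitudes
    n = field.n_points
    int_mag = np.array(
        [np.trapezoid(np.interp(fine, t, mag[:, p]), fine) for p in range(n)]
    )
    int_vec = np.array(
        [
            [np.trapezoid(np.interp(fine, t, field.wss[:, p, c]), fine) for c in range(3)]
            for p in range(n)
        ]
    )
    tawss = int_mag / period
    with np.errstate(invalid="ignore"):
        osi = 0.5 * (1 - np.where(int_mag > 0, np.linalg.norm(int_vec, axis=1) / int_mag, 1.0))
    return tawss, osi


class TestPointwise:
    def test_constant_vector(self):
        f = simple_field(lambda t: np.tile([3.0, 4.0, 0.0], (4, 1)))
        tawss, osi = pointwise_tawss_osi(f)
        assert tawss == pytest.approx(np.full(4, 5.0))
        assert osi == pytest.approx(np.zeros(4))

    def test_fully_reversing_sinusoid(self):
        v = 7.0
        f = simple_field(
            lambda t: np.tile([v * np.sin(2 * np.pi * t), 0.0, 0.0], (4, 1)),
            n_times=4001,
        )
        tawss, osi = pointwise_tawss_osi(f)
        assert osi == pytest.approx(np.full(4, 0.5), abs=1e-12)
        assert tawss == pytest.approx(np.full(4, 2 * v / np.pi), rel=1e-5)

    def test_zero_field_defines_osi_zero(self):
        f = simple_field(lambda t: np.zeros((4, 3)))
        tawss, osi = pointwise_tawss_osi(f)
        assert np.all(tawss == 0) and np.all(osi == 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_refined_trapezoid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f = random_wss_field(rng)
        tawss, osi = pointwise_tawss_osi(f)
        tawss_o, osi_o = oracle_tawss_osi(f)
        np.testing.assert_allclose(tawss, tawss_o, rtol=1e-6)
        np.testing.assert_allclose(osi, osi_o, rtol=0, atol=1e-6)

    def test_osi_bounds_hold(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            f = random_wss_field(rng)
            _, osi = pointwise_tawss_osi(f)
            assert np.all(osi >= 0) and np.all(osi <= 0.5)

    def test_nonfinite_vector_named(self):
        def fn(t):
            v = np.ones((4, 3))
            v[2, 1] = np.nan
            return v
        with pytest.raises(InvalidParameterError, match="point 2"):
            pointwise_tawss_osi(simple_field(fn))


class TestRegionSummary:
    def test_uniform_field(self):
        f = simple_field(lambda t: np.tile([2.0, 0.0, 0.0], (4, 1)))
        tawss, osi = pointwise_tawss_osi(f)
        s = region_summary(f, tawss, osi)
        for v in (s.dome_mean_tawss, s.dome_min_tawss, s.dome_max_tawss,
                  s.parent_mean_tawss, s.parent_min_tawss, s.parent_max_tawss):
            assert v == pytest.approx(2.0)

    def test_area_weighted_mean_two_triangles(self):
        # two dome triangles with areas 0.5 and 1.5, uniform vertex values 10 and 20
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                        [3, 0, 1], [3, 1, 1], [0, 0, 1], [10, 0, 0], [11, 0, 0], [10, 1, 0]],
                       dtype=float)
        tris = np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        region = np.array([1, 1, 1, 1, 1, 1, 2, 2, 2])
        times = np.array([0.0, 1.0])
        vals = np.array([10, 10, 10, 20, 20, 20, 5, 5, 5], dtype=float)
        wss = np.tile(vals[None, :, None] * np.array([1.0, 0, 0]), (2, 1, 1))
        f = TriSurfaceField(points=pts, triangles=tris, region=region, times=times, wss=wss)
        tawss, osi = pointwise_tawss_osi(f)
        s = region_summary(f, tawss, osi)
        assert s.dome_mean_tawss == pytest.approx((10 * 0.5 + 20 * 1.5) / 2.0)  # 17.5

    def test_matches_generator_ground_truth(self, coarse_patient):
        field, gt = coarse_patient
        tawss, osi = pointwise_tawss_osi(field)
        s = region_summary(field, tawss, osi)
        assert s.parent_mean_tawss == pytest.approx(gt.parent_mean_tawss, rel=1e-10)
        assert s.dome_mean_tawss == pytest.approx(gt.dome_mean_tawss, rel=1e-10)
        assert s.dome_area == pytest.approx(gt.dome_area, rel=1e-10)
        assert s.mtlsa[70] == pytest.approx(gt.mtlsa[70], rel=1e-10)
        assert s.lsa == pytest.approx(gt.lsa, rel=1e-10)
        assert s.dome_max_osi == pytest.approx(gt.dome_osi, rel=1e-10)

    def test_invariant_under_reordering_and_rigid_motion(self, coarse_patient):
        field, _ = coarse_patient
        rng = np.random.default_rng(0)
        perm = rng.permutation(field.n_points)
        inv = np.argsort(perm)
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shifted = TriSurfaceField(
            points=field.points[perm] @ q.T + np.array([1.0, -2.0, 3.0]),
            triangles=inv[field.triangles],
            region=field.region[perm],
            times=field.times,
            wss=field.wss[:, perm, :] @ q.T,
        )
        t1, o1 = pointwise_tawss_osi(field)
        t2, o2 = pointwise_tawss_osi(shifted)
        s1 = region_summary(field, t1, o1)
        s2 = region_summary(shifted, t2, o2)
        for a, b in zip(s1.to_dict().values(), s2.to_dict().values()):
            if isinstance(a, dict):
                for k in a:
                    assert a[k] == pytest.approx(b[k], rel=1e-9)
            else:
                assert a == pytest.approx(b, rel=1e-9)


class TestLowShearAreas:
    def _patient_summary(self, field):
        tawss, osi = pointwise_tawss_osi(field)
        return tawss, region_summary(field, tawss, osi)

    def test_dome_at_parent_mean_has_zero_mtlsa(self):
        f = simple_field(lambda t: np.tile([2.0, 0.0, 0.0], (4, 1)))
        tawss, s = self._patient_summary(f)
        assert all(v == 0.0 for v in s.mtlsa.values())

    def test_zero_dome_shear_fills_all_thresholds(self):
        # separated dome/parent triangles so each is purely one region
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 0, 0], [6, 0, 0], [5, 1, 0]],
                       dtype=float)
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        region = np.array([1, 1, 1, 2, 2, 2])
        vals = np.array([0, 0, 0, 2, 2, 2], dtype=float)
        wss = np.tile(vals[None, :, None] * np.array([1.0, 0, 0]), (2, 1, 1))
        f2 = TriSurfaceField(points=pts, triangles=tris, region=region,
                             times=np.array([0.0, 1.0]), wss=wss)
        t2, o2 = pointwise_tawss_osi(f2)
        s = region_summary(f2, t2, o2)
        assert all(v == 100.0 for v in s.mtlsa.values())
        assert s.lsa == 100.0  # parent SD is 0 here, threshold = mean > 0

    def test_mtlsa_monotone_in_threshold(self, coarse_patient):
        field, _ = coarse_patient
        tawss, osi = pointwise_tawss_osi(field)
        s = region_summary(field, tawss, osi, mtlsa_percents=(10, 30, 50, 70, 90, 99))
        vals = [s.mtlsa[x] for x in sorted(s.mtlsa)]
        assert vals == sorted(vals)
        assert all(0 <= v <= 100 for v in vals)
        assert 0 <= s.lsa <= 100

    def test_refinement_stability(self):
        from aneushear import FluidProperties, SyntheticPatientSpec, make_patient
        vals = {}
        for edge in (0.06, 0.03):
            spec = SyntheticPatientSpec(mesh_edge_size=edge, n_time_samples=8, seed=1)
            field, _ = make_patient(spec, FluidProperties())
            tawss, osi = pointwise_tawss_osi(field)
            vals[edge] = region_summary(field, tawss, osi)
        for attr in ("dome_mean_tawss", "parent_mean_tawss", "lsa"):
            a, b = getattr(vals[0.06], attr), getattr(vals[0.03], attr)
            assert a == pytest.approx(b, rel=0.01)
        for x in (50, 70, 90):
            assert vals[0.06].mtlsa[x] == pytest.approx(vals[0.03].mtlsa[x], rel=0.01)
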
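"""Ripley's K, O-ring, CSR envelopes and departure intervals."""
import numpy as np
import pytest

from mistlemap import (
    EnvelopeResult,
    HabitatRegion,
    PPConfig,
    csr_envelope,
    departure_intervals,
    o_ring,
    ripleys_k,
)
from mistlemap import point_pattern as pp


class TestRipleysK:
    def test_two_point_hand_count(self):
        region = HabitatRegion.from_rectangle(10.0, 10.0)  # |A| = 100
        pts = np.array([[2.0, 2.0], [5.0, 6.0]])  # distance 5
        r = np.array([1.0, 4.9, 5.0, 8.0])
        k = ripleys_k(pts, region, r)
        np.testing.assert_allclose(k, [0.0, 0.0, 100.0, 100.0])

    def test_monotone_nondecreasing(self, km_square, rng):
        pts = km_square.sample_uniform(100, rng)
        k = ripleys_k(pts, km_square, np.linspace(10, 500, 30))
        assert np.all(np.diff(k) >= 0)

    def test_point_outside_region_named(self, km_square):
        pts = np.array([[10.0, 10.0], [2000.0, 50.0]])
        with pytest.raises(ValueError, match="point 1"):
            ripleys_k(pts, km_square, [100.0])

    def test_uncorrected_matches_square_window_closed_form(self, km_square):
        """E[K̂_uncorr(r)] = πr² − 8r³/(3L) + r⁴/(2L²) exactly for CSR in a
        square of side L (no edge correction): check by simulation."""
        vals = []
        for s in range(50):
            pts = km_square.sample_uniform(500, np.random.default_rng(s))
            vals.append(ripleys_k(pts, km_square, [100.0])[0])
        exact = np.pi * 100**2 - 8 * 100**3 / (3 * 1000) + 100**4 / (2 * 1000**2)
        assert np.mean(vals) == pytest.approx(exact, rel=0.03)

    def test_translation_correction_unbiased(self, km_square):
        vals = []
        for s in range(50):
            pts = km_square.sample_uniform(500, np.random.default_rng(s))
            vals.append(ripleys_k(pts, km_square, [100.0], correction="translation")[0])
        assert np.mean(vals) == pytest.approx(np.pi * 100**2, rel=0.03)

    def test_translation_requires_rectangle(self, rng):
        tri = HabitatRegion.from_vertices([(0, 0), (100, 0), (0, 100)])
        pts = tri.sample_uniform(10, rng)
        with pytest.raises(ValueError, match="rectangle"):
            ripleys_k(pts, tri, [10.0], correction="translation")


class TestORing:
    def test_annulus_area_estimate_interior(self, km_square):
        """Grid-counted annulus area ≈ 2πrw for an annulus fully inside."""
        pts = np.array([[500.0, 500.0]])
        r = np.array([100.0])
        w, cell = 20.0, 2.0
        grid = pp.region_grid_points(km_square, cell)
        from scipy.spatial import cKDTree

        gtree = cKDTree(grid)
        n_in = gtree.query_ball_point([500.0, 500.0], r[0] + w / 2, return_length=True)
        n_lo = gtree.query_ball_point([500.0, 500.0], r[0] - w / 2, return_length=True)
        est_area = (n_in - n_lo) * cell**2
        assert est_area == pytest.approx(2 * np.pi * 100.0 * 20.0, rel=0.02)

    def test_single_point_zero_everywhere(self, km_square):
        o = o_ring(np.array([[500.0, 500.0]]), km_square, [50.0, 100.0], 20.0, 5.0)
        np.testing.assert_array_equal(o, [0.0, 0.0])

    def test_cell_larger_than_ring_rejected(self, km_square, rng):
        pts = km_square.sample_uniform(10, rng)
        with pytest.raises(ValueError, match="cell_size"):
            o_ring(pts, km_square, [100.0], ring_width=10.0, cell_size=20.0)

    def test_csr_oring_near_intensity(self, km_square):
        """Under CSR Ô(r) ≈ λ at all r (mean over simulations)."""
        r = np.array([100.0, 200.0, 300.0])
        vals = []
        for s in range(40):
            pts = km_square.sample_uniform(500, np.random.default_rng(s))
            vals.append(o_ring(pts, km_square, r, 20.0, 10.0))
        np.testing.assert_allclose(np.mean(vals, axis=0), 500 / 1e6, rtol=0.05)

    def test_k_oring_consistency_under_csr(self, km_square):
        """dK/dr ≈ 2πr·Ô(r)/λ at mid-range r under CSR (sim. average).

        Uses the edge-corrected K, whose derivative is comparable to the
        edge-corrected O-ring; the uncorrected K's boundary deficit grows
        with r and breaks the identity by construction.
        """
        r = np.linspace(50, 350, 13)
        dks, os_ = [], []
        for s in range(30):
            pts = km_square.sample_uniform(400, np.random.default_rng(s))
            k = ripleys_k(pts, km_square, r, correction="translation")
            dks.append(np.gradient(k, r))
            os_.append(o_ring(pts, km_square, r, 25.0, 10.0))
        lam = 400 / 1e6
        mid = slice(3, 9)
        np.testing.assert_allclose(
            np.mean(dks, axis=0)[mid],
            (2 * np.pi * r * np.mean(os_, axis=0) / lam)[mid],
            rtol=0.10,
        )


class TestCsrEnvelope:
    def test_nominal_level_arithmetic(self):
        assert PPConfig(n_sim=199, rank=5).nominal_level == pytest.approx(0.05)

    def test_same_estimator_code_path(self, km_square, rng):
        pts = km_square.sample_uniform(50, rng)
        cfg = PPConfig(r_grid=np.linspace(20, 200, 5), n_sim=19, rank=1,
                       ring_width=20.0, cell_size=10.0)
        env_k = csr_envelope(pts, km_square, "K", cfg, rng)
        assert env_k.statistic_fn is pp.ripleys_k
        env_o = csr_envelope(pts, km_square, "oring", cfg, rng)
        assert env_o.statistic_fn is pp.o_ring

    def test_envelope_reproducible_and_ordered(self, km_square, rng):
        pts = km_square.sample_uniform(60, rng)
        cfg = PPConfig(r_grid=np.linspace(20, 200, 6), n_sim=19, rank=1)
        a = csr_envelope(pts, km_square, "K", cfg, 11)
        b = csr_envelope(pts, km_square, "K", cfg, 11)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)
        assert np.all(a.lower <= a.upper)

    def test_csr_input_mostly_inside(self, km_square):
        inside = 0
        total = 0
        for s in range(10):
            pts = km_square.sample_uniform(150, np.random.default_rng(s))
            cfg = PPConfig(r_grid=np.linspace(30, 300, 10), n_sim=39, rank=1)
            env = csr_envelope(pts, km_square, "K", cfg, s)
            inside += int(np.sum(env.verdicts == "inside"))
            total += len(env.verdicts)
        assert inside / total >= 0.90

    def test_simulated_points_respect_region(self, rng):
        tri = HabitatRegion.from_vertices([(0, 0), (500, 0), (0, 500)])
        sampled = tri.sample_uniform(500, rng)
        assert tri.contains_xy(sampled[:, 0], sampled[:, 1]).all()


class TestDepartureIntervals:
    def _env(self, r, obs, lower, upper):
        obs, lower, upper = (np.asarray(a, float) for a in (obs, lower, upper))
        verd = np.where(obs > upper, "above", np.where(obs < lower, "below", "inside"))
        return EnvelopeResult(np.asarray(r, float), np.asarray(obs, float),
                              np.asarray(lower, float), np.asarray(upper, float),
                              verd, "K", 19, 1, 0.1)

    def test_single_above_interval_interpolated(self):
        env = self._env([10, 20, 30], [1, 5, 9], [0, 0, 0], [2, 6, 8])
        deps = departure_intervals(env)
        assert len(deps) == 1
        start, end, direction = deps[0]
        assert direction == "above"
        assert 20 < start < 30
        assert start == pytest.approx(25.0)  # linear crossing of obs-upper
        assert end == 30.0

    def test_all_inside_empty(self):
        env = self._env([10, 20], [1, 1], [0, 0], [2, 2])
        assert departure_intervals(env) == []

    def test_below_at_tail_only(self):
        env = self._env([10, 20, 30], [1, 1, -5], [0, 0, 0], [2, 2, 2])
        deps = departure_intervals(env)
        assert len(deps) == 1
        assert deps[0][2] == "below"
        assert deps[0][1] == 30.0
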
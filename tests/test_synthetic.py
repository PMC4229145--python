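"""Synthetic-data generator: determinism, CSR/GRF validity, calibrations."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mistlemap import (
    DispersalMixture,
    HabitatRegion,
    SimulationConfig,
    SphericalModel,
    ThomasParams,
    clump_volume,
    decompose_volume_to_clumps,
    gen_dispersal,
    gen_female_volume,
    gen_logvolume_marks,
    gen_region,
    gen_territories,
    gen_trees,
    simulate_dataset,
    total_tree_volume,
)
from mistlemap.territory_geometry import mcp


class TestGenRegion:
    def test_rectangle_area(self):
        region = gen_region({"rectangle": (2646.0, 2646.0)})
        assert region.area == pytest.approx(7_001_316.0)

    def test_unit_square(self):
        region = gen_region({"vertices": [(0, 0), (1, 0), (1, 1), (0, 1)]})
        assert region.area == pytest.approx(1.0)

    def test_triangle_shoelace(self):
        region = gen_region({"vertices": [(0, 0), (2, 0), (0, 2)]})
        assert region.area == pytest.approx(2.0)

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            gen_region({"vertices": [(0, 0), (1, 1), (1, 0), (0, 1)]})


class TestGenTrees:
    def test_csr_count_and_containment(self, unit_square, rng):
        pts = gen_trees(unit_square, "csr", None, 1000, rng)
        assert pts.shape == (1000, 2)
        assert np.all(unit_square.contains_xy(pts[:, 0], pts[:, 1]))

    def test_determinism(self, km_square):
        a = gen_trees(km_square, "thomas", ThomasParams(), 200, 7)
        b = gen_trees(km_square, "thomas", ThomasParams(), 200, 7)
        np.testing.assert_array_equal(a, b)

    def test_csr_multinomial_quadrat_counts(self, km_square):
        """Counts in equal-area quadrats are multinomial under CSR.

        Chi-square goodness-of-fit aggregated over 50 seeds should not
        reject at alpha = 0.01.
        """
        stat = 0.0
        dof = 0
        for s in range(50):
            pts = gen_trees(km_square, "csr", None, 400, s)
            counts, _, _ = np.histogram2d(
                pts[:, 0], pts[:, 1], bins=4, range=[[0, 1000], [0, 1000]]
            )
            expected = 400 / 16.0
            stat += float(((counts - expected) ** 2 / expected).sum())
            dof += 15
        assert stats.chi2.sf(stat, dof) > 0.01

    def test_thomas_params_validated(self):
        with pytest.raises(ValueError):
            ThomasParams(parent_intensity=0.0)


class TestLogVolumeMarks:
    def test_pure_nugget_iid_variance(self, km_square):
        """With c = 0 marks are iid with variance c0 (within 3 SE, 50 reps)."""
        model = SphericalModel(nugget=2.0, partial_sill=0.0, range_m=100.0)
        variances = []
        for s in range(50):
            rng = np.random.default_rng(s)
            pts = km_square.sample_uniform(200, rng)
            z = gen_logvolume_marks(pts, model, mean=5.0, rng=rng)
            variances.append(np.var(z, ddof=1))
        mean_var = np.mean(variances)
        # Var(s²) = 2σ⁴/(n-1) per rep; SE of the mean over 50 reps
        se = math.sqrt(2 * 2.0**2 / 199 / 50)
        assert abs(mean_var - 2.0) < 3 * se

    def test_zero_covariance_beyond_range(self):
        model = SphericalModel(nugget=0.1, partial_sill=1.0, range_m=50.0)
        assert model.structured_covariance(50.0) == 0.0
        assert model.structured_covariance(120.0) == 0.0
        assert model.structured_covariance(0.0) == pytest.approx(1.0)

    def test_duplicate_coordinates_allowed(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0]])
        model = SphericalModel(nugget=0.5, partial_sill=1.0, range_m=50.0)
        z = gen_logvolume_marks(pts, model, rng=0)
        assert np.all(np.isfinite(z))

    def test_mean_respected(self, km_square):
        model = SphericalModel(nugget=1.0, partial_sill=0.5, range_m=100.0)
        zs = [
            np.mean(gen_logvolume_marks(km_square.sample_uniform(300, np.random.default_rng(s)), model, mean=10.0, rng=s))
            for s in range(30)
        ]
        assert np.mean(zs) == pytest.approx(10.0, abs=0.2)


class TestDecompose:
    def test_zero(self):
        assert all(v == 0 for v in decompose_volume_to_clumps(0.0).values())

    def test_exact_category_fit(self):
        counts = decompose_volume_to_clumps(clump_volume(5))
        assert counts[5] == 1
        assert sum(v for c, v in counts.items() if c != 5) == 0

    def test_greedy_trace(self):
        v = 2 * clump_volume(1) + clump_volume(3)
        counts = decompose_volume_to_clumps(v)
        assert counts == {1: 2, 2: 0, 3: 1, 4: 0, 5: 0, 6: 0}

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            decompose_volume_to_clumps(-1.0)

    @given(st.floats(min_value=0.0, max_value=1e8, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_roundtrip_within_one_smallest_clump(self, volume):
        counts = decompose_volume_to_clumps(volume)
        recomposed = total_tree_volume(counts)
        assert recomposed <= volume * (1 + 1e-9) + 1e-6
        assert volume - recomposed < clump_volume(1) * (1 + 1e-9)


class TestFemaleVolume:
    def test_noise_free_perfect_correlation(self, rng):
        total = np.exp(rng.normal(10, 1.5, 45))
        female = gen_female_volume(total, 0.6, 0.0, rng)
        assert np.corrcoef(female, total)[0, 1] == pytest.approx(1.0)

    def test_zero_total_gives_zero_female(self, rng):
        female = gen_female_volume(np.zeros(10), 0.5, 1000.0, rng)
        assert np.all(female == 0.0)

    def test_default_calibration_r_near_09(self):
        """Sample r ≈ 0.9 at n = 45 under the default slope/noise settings."""
        cfg = SimulationConfig()
        rs = []
        for s in range(100):
            rg = np.random.default_rng(s)
            total = np.exp(
                cfg.mean_log_volume
                + math.sqrt(cfg.grf_model.sill) * rg.standard_normal(45)
            )
            female = gen_female_volume(total, cfg.female_slope, cfg.female_noise_sd, rg)
            rs.append(np.corrcoef(female, total)[0, 1])
        assert 0.85 < np.mean(rs) < 0.95


class TestTerritories:
    def test_single_territory_mcp_computable(self, km_square, rng):
        df = gen_territories(km_square, 1, 5, 10.0, rng, radius=50.0)
        assert df["territory_id"].nunique() == 1
        _, area = mcp(df[["x_m", "y_m"]].to_numpy())
        assert area > 0

    def test_infeasible_spacing_errors(self, km_square, rng):
        with pytest.raises(RuntimeError, match="could not place"):
            gen_territories(km_square, 2, 3, 5000.0, rng, radius=50.0, max_tries=50)

    def test_spacing_respected_and_inside(self, km_square, rng):
        df = gen_territories(km_square, 5, 10, 200.0, rng, radius=80.0)
        centers = df.groupby("territory_id")[["x_m", "y_m"]].mean().to_numpy()
        from scipy.spatial.distance import pdist

        # cluster means sit close to true centers; allow slack of the scatter
        assert pdist(centers).min() > 200.0 - 2 * 80.0
        assert km_square.contains_xy(df["x_m"], df["y_m"]).all()

    def test_mean_mcp_area_calibration(self):
        """Default geometry yields mean MCP area within 2x of 41,663 m²."""
        region = HabitatRegion.from_rectangle(2646.0, 2646.0)
        areas = []
        for s in range(5):
            df = gen_territories(region, 10, 15, 250.0, np.random.default_rng(s))
            for _, grp in df.groupby("territory_id"):
                areas.append(mcp(grp[["x_m", "y_m"]].to_numpy())[1])
        mean = np.mean(areas)
        assert 41663 / 2 < mean < 41663 * 2


class TestDispersal:
    def test_degenerate_short_mixture(self, rng):
        mix = DispersalMixture(short_fraction=1.0, short_scale_m=1e-9, long_scale_m=1.0)
        d = gen_dispersal(50, mix, rng)
        assert np.all(d["distance_m"] < 1e-6)

    def test_stored_distance_consistent_with_coordinates(self, rng):
        d = gen_dispersal(200, DispersalMixture(), rng)
        recomputed = np.hypot(
            d["breeding_x_m"] - d["natal_x_m"], d["breeding_y_m"] - d["natal_y_m"]
        )
        np.testing.assert_allclose(recomputed, d["distance_m"], rtol=1e-9)

    def test_default_calibration_fraction_below_250(self):
        fracs = [
            np.mean(gen_dispersal(500, DispersalMixture(), s)["distance_m"] < 250)
            for s in range(40)
        ]
        assert 0.55 < np.mean(fracs) < 0.60


class TestSimulateDataset:
    def test_determinism_and_schema(self):
        cfg = SimulationConfig(
            n_trees=120,
            region_spec={"rectangle": (800.0, 800.0)},
            n_territories=3,
            points_per_territory=6,
            territory_spacing=150.0,
            territory_radius=60.0,
            n_dispersal=20,
            seed=42,
        )
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a["trees"].equals(b["trees"])
        assert a["territories"].equals(b["territories"])
        assert a["dispersal"].equals(b["dispersal"])
        for col in ("tree_id", "x_m", "y_m", "n_cat1", "n_elongate",
                    "total_volume_cm3", "female_volume_cm3", "log_volume"):
            assert col in a["trees"].columns
        assert np.allclose(
            a["trees"]["log_volume"], np.log(a["trees"]["total_volume_cm3"])
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_trees=1)
        with pytest.raises(ValueError):
            SimulationConfig(pattern="grid")
        with pytest.raises(ValueError):
            SimulationConfig(female_slope=1.5)
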
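"""Scenario lattice, sensitivity curves, two-sector surfaces and the
attainment search (with brute-force oracles on the surrogate truth)."""

import numpy as np
import pytest

from aqemu import health as h
from aqemu import scenarios as sc
from aqemu import synthetic as syn
from aqemu.synthetic import SECTORS


class TestBuildGrid:
    def test_default_lattice_size(self):
        grid = sc.build_grid()
        assert grid.levels.size == 8
        assert np.allclose(grid.levels, np.arange(0, 1.5, 0.2))
        assert grid.n_scenarios == 32_768

    @pytest.mark.parametrize("n_sectors,step,expected", [(1, 0.2, 8), (2, 0.5, 9)])
    def test_small_lattices(self, n_sectors, step, expected):
        grid = sc.build_grid(step=step, n_sectors=n_sectors)
        assert grid.n_scenarios == expected

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            sc.build_grid(step=2.0)


@pytest.fixture(scope="module")
def truth_grid(linear_simulator, domain):
    grid = sc.build_grid()
    return sc.evaluate_grid(linear_simulator, grid, None, domain, pollutants=("PM2.5",))


class TestEvaluateGrid:
    def test_single_point_matches_population_weighting(self, simulator, domain):
        grid = sc.ScenarioGrid(levels=np.array([1.0]), X=np.ones((1, 5)))
        out = sc.evaluate_grid(simulator, grid, None, domain)
        pm, o3 = syn.simulate(simulator, np.ones(5))
        assert out.table["exposure_PM2.5_national"].iloc[0] == pytest.approx(
            np.average(pm, weights=domain.population)
        )
        assert out.table["exposure_O3_national"].iloc[0] == pytest.approx(
            np.average(o3, weights=domain.population)
        )

    def test_exposure_monotone_along_single_sector_slices(self, truth_grid):
        t = truth_grid.table
        others = [s for s in SECTORS if s != "IND"]
        baseline_mask = np.all(
            [np.isclose(t[s], 1.0) for s in others], axis=0
        )
        # no lattice level is exactly 1.0 under the chosen offsets; use 0.8
        slice_mask = np.all([np.isclose(t[s], 0.8) for s in others], axis=0)
        slc = t[slice_mask].sort_values("IND")
        assert (np.diff(slc["exposure_PM2.5_national"]) >= -1e-9).all()

    def test_permuted_scenario_order_identical(self, linear_simulator, domain):
        grid = sc.build_grid(step=0.5)  # 243 scenarios
        rng = np.random.default_rng(0)
        perm = rng.permutation(grid.n_scenarios)
        shuffled = sc.ScenarioGrid(levels=grid.levels, X=grid.X[perm])
        a = sc.evaluate_grid(linear_simulator, grid, None, domain, ("PM2.5",))
        b = sc.evaluate_grid(linear_simulator, shuffled, None, domain, ("PM2.5",))
        assert np.allclose(
            a.table["exposure_PM2.5_national"].to_numpy()[perm],
            b.table["exposure_PM2.5_national"].to_numpy(),
        )


class TestSectorCurve:
    def test_baseline_level_has_zero_relative_change(self, simulator, domain):
        curve = sc.sector_curve(
            simulator, "IND", np.array([0.0, 0.5, 1.0]), None, domain
        )
        at_1 = curve[np.isclose(curve.scaling, 1.0)]
        assert at_1["rel_exposure_PM2.5"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_full_removal_drop_matches_configured_share(self, simulator, domain):
        curve = sc.sector_curve(simulator, "IND", np.array([0.0]), None, domain)
        assert curve["rel_exposure_PM2.5"].iloc[0] == pytest.approx(-0.28, abs=0.02)

    def test_mortality_drop_smaller_than_exposure_drop(
        self, simulator, domain, baseline_rates
    ):
        """Concave exposure–response at high exposure: the fractional
        burden reduction lags the fractional exposure reduction."""
        curve = sc.sector_curve(
            simulator,
            "IND",
            np.array([0.0]),
            None,
            domain,
            gemm=h.load_gemm_params(),
            rates=baseline_rates,
        )
        rel_exp = curve["rel_exposure_PM2.5"].iloc[0]
        rel_mort = curve["rel_MORT_PM2.5"].iloc[0]
        assert rel_exp < 0 and rel_mort < 0
        assert abs(rel_mort) < abs(rel_exp)

    def test_unknown_sector_rejected(self, simulator, domain):
        with pytest.raises(ValueError):
            sc.sector_curve(simulator, "XXX", [1.0], None, domain)


class TestPairSurface:
    def test_corner_baseline_and_joint_removal(self, simulator, domain):
        surf = sc.pair_surface(
            simulator, "RES", "IND", np.array([0.0, 1.0]), None, domain
        )
        pm, _ = syn.simulate(simulator, np.ones(5))
        base = np.average(pm, weights=domain.population)
        at_11 = surf[(surf.RES == 1.0) & (surf.IND == 1.0)]["exposure_PM2.5"].iloc[0]
        at_00 = surf[(surf.RES == 0.0) & (surf.IND == 0.0)]["exposure_PM2.5"].iloc[0]
        assert at_11 == pytest.approx(base)
        # joint removal drop ~ sum of the configured shares (0.28 + 0.21)
        assert (base - at_00) / base == pytest.approx(0.49, abs=0.03)

    def test_monotone_along_each_axis(self, simulator, domain):
        levels = np.array([0.0, 0.5, 1.0, 1.4])
        surf = sc.pair_surface(simulator, "RES", "IND", levels, None, domain)
        for _, grp in surf.groupby("RES"):
            assert (np.diff(grp.sort_values("IND")["exposure_PM2.5"]) >= -1e-9).all()

    def test_identical_sectors_rejected(self, simulator, domain):
        with pytest.raises(ValueError):
            sc.pair_surface(simulator, "IND", "IND", [0.0, 1.0], None, domain)


class TestAttainment:
    def test_trivial_thresholds(self, truth_grid):
        hi = sc.attainment(truth_grid, 1e6)
        assert hi.count == truth_grid.n_scenarios
        # mean reduction over the full lattice = 1 - mean(levels)
        expected = (1.0 - truth_grid.levels.mean()) * 100
        for s in SECTORS:
            assert hi.mean_reduction_pct[s] == pytest.approx(expected)
        lo = sc.attainment(truth_grid, -1.0)
        assert lo.count == 0
        assert np.isnan(lo.mean_reduction_pct["IND"])

    def test_count_matches_closed_form_enumeration(
        self, truth_grid, linear_simulator, domain
    ):
        """Brute-force oracle: count attaining configurations by direct
        surrogate evaluation over the full 8^5 lattice."""
        pm, _ = syn.simulate_many(linear_simulator, truth_grid.X)
        exposure = np.average(pm, weights=domain.population, axis=0)
        threshold = 35.0
        expected = int((exposure <= threshold).sum())
        rep = sc.attainment(truth_grid, threshold)
        assert rep.count == expected
        assert np.array_equal(rep.attaining_index, np.flatnonzero(exposure <= threshold))

    def test_attaining_sets_nested_in_threshold(self, truth_grid):
        r15 = sc.attainment(truth_grid, 15.0)
        r25 = sc.attainment(truth_grid, 25.0)
        r35 = sc.attainment(truth_grid, 35.0)
        assert set(r15.attaining_index) <= set(r25.attaining_index)
        assert set(r25.attaining_index) <= set(r35.attaining_index)

    def test_monotone_closure_of_attaining_set(self, truth_grid):
        """If s attains and s' <= s componentwise, s' attains too."""
        rep = sc.attainment(truth_grid, 35.0)
        attain = np.zeros(truth_grid.n_scenarios, dtype=bool)
        attain[rep.attaining_index] = True
        X = truth_grid.X
        rng = np.random.default_rng(1)
        idx = rng.choice(rep.attaining_index, size=min(200, rep.count), replace=False)
        for i in idx:
            smaller = X[i].copy()
            k = rng.integers(0, 5)
            if smaller[k] >= 0.2:
                smaller[k] -= 0.2
                j = np.flatnonzero(np.all(np.isclose(X, smaller), axis=1))[0]
                assert attain[j]

    def test_unpopulated_grid_rejected(self):
        with pytest.raises(ValueError):
            sc.attainment(sc.build_grid(step=0.5), 35.0)

    def test_summary_mentions_count_and_sectors(self, truth_grid):
        rep = sc.attainment(truth_grid, 35.0, target_name="NAQT")
        s = rep.summary()
        assert "NAQT" in s and str(rep.count) in s and "IND" in s
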
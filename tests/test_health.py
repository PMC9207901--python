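"""Exposure–response and burden equations: closed-form worked examples,
bounds, additivity and bound-evaluation uncertainty propagation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aqemu import health as h
from aqemu import synthetic as syn

FIXTURE = dict(theta=0.1430, alpha=1.6, mu=15.5, nu=36.8)


class TestExposureResponse:
    def test_excess_exposure_worked_examples(self):
        assert h.excess_exposure(47.4, h.PM_COUNTERFACTUAL) == pytest.approx(45.0)
        assert h.excess_exposure(43.8, h.O3_COUNTERFACTUAL) == pytest.approx(8.1)
        assert h.excess_exposure(2.0, 2.4) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            h.excess_exposure(-1.0, 2.4)

    def test_rr_is_one_at_zero_exposure(self):
        assert h.gemm_rr(0.0, **FIXTURE) == 1.0

    def test_rr_closed_form_worked_example(self):
        # independent high-precision evaluation of
        # exp(θ ln(1+z/α) / (1+exp((μ−z)/ν))) at z=45
        assert h.gemm_rr(45.0, **FIXTURE) == pytest.approx(1.3949, abs=2e-4)

    def test_rr_vanishing_theta_limit(self):
        assert h.gemm_rr(100.0, 1e-12, 1.6, 15.5, 36.8) == pytest.approx(1.0)

    def test_rr_monotone_and_continuous_over_range(self):
        z = np.linspace(0, 200, 4001)
        gemm = h.load_gemm_params()
        for age, prm in gemm.iterrows():
            rr = h.gemm_rr(z, prm["theta"], prm["alpha"], prm["mu"], prm["nu"])
            assert (np.diff(rr) >= -1e-12).all()
            assert (rr >= 1).all()
            assert np.abs(np.diff(rr)).max() < 0.01  # no jumps

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            h.gemm_rr(1.0, 0.1, -1.0, 15.5, 36.8)


class TestPAF:
    def test_pm_worked_examples(self):
        assert h.paf_pm(1.0, 1000) == 0.0
        assert h.paf_pm(2.0, 1000) == pytest.approx(500.0)
        rr = h.gemm_rr(45.0, **FIXTURE)
        assert h.paf_pm(rr, 100_000) == pytest.approx(28_310, abs=10)

    def test_pm_rr_below_one_rejected(self):
        with pytest.raises(ValueError):
            h.paf_pm(0.99, 100)

    def test_o3_worked_examples(self):
        p = h.O3RiskParams()
        assert h.paf_o3(0.0, p, 100_000) == 0.0
        # z = 10 is the reference increment: PAF = P(1 − 1/HR) exactly
        assert h.paf_o3(10.0, p, 100_000) == pytest.approx(
            100_000 * (1 - 1 / 1.06), abs=1e-6
        )
        # independent closed-form evaluation at the national excess exposure
        assert h.paf_o3(8.1, p, 100_000) == pytest.approx(4610.13, abs=0.1)

    @settings(deadline=None, max_examples=100)
    @given(
        z=st.floats(0, 150),
        pop=st.floats(0, 1e7),
        theta=st.floats(0.01, 0.3),
    )
    def test_paf_bounded_by_population(self, z, pop, theta):
        rr = h.gemm_rr(z, theta, 1.6, 15.5, 36.8)
        assert 0.0 <= h.paf_pm(rr, pop) <= pop
        assert 0.0 <= h.paf_o3(z, h.O3RiskParams(), pop) <= pop

    def test_o3_increasing_in_z_and_hr(self):
        p_lo = h.O3RiskParams()
        assert h.paf_o3(20.0, p_lo, 1e5) > h.paf_o3(10.0, p_lo, 1e5)
        assert h.paf_o3(10.0, p_lo, 1e5, "upper") > h.paf_o3(10.0, p_lo, 1e5, "lower")


class TestBurden:
    def test_products_and_linearity(self):
        m, l, d = h.burden(500.0, 0.01, 0.2, 0.05)
        assert (m, l, d) == (5.0, 100.0, 25.0)
        m2, l2, d2 = h.burden(1000.0, 0.01, 0.2, 0.05)
        assert (m2, l2, d2) == (2 * m, 2 * l, 2 * d)
        assert h.burden(0.0, 0.01, 0.2, 0.05) == (0.0, 0.0, 0.0)

    def test_dalys_sum_and_aggregation_commute(self):
        assert h.dalys(3.0, 1.0) == 4.0
        yll = np.array([1.0, 2.0, 3.0])
        yld = np.array([0.5, 0.5, 0.5])
        assert h.dalys(yll, yld).sum() == h.dalys(yll.sum(), yld.sum())

    def test_rates_per_100k(self):
        assert h.rates_per_100k(42_190.0, 1_000_000.0) == pytest.approx(4219.0)
        assert h.rates_per_100k(0.0, 1e6) == 0.0
        # invariant to splitting and recombining cells
        parts = h.rates_per_100k(np.array([10.0, 32.0]), np.array([1e5, 1e5]))
        whole = h.rates_per_100k(42.0, 2e5)
        assert np.average(parts, weights=[1e5, 1e5]) == pytest.approx(whole)


@pytest.fixture(scope="module")
def inputs(domain, simulator, baseline_rates):
    pm, o3 = syn.simulate(simulator, np.ones(5))
    return dict(
        domain=domain,
        pm_values=pm,
        o3_values=o3,
        gemm=h.load_gemm_params(),
        o3_params=h.O3RiskParams(),
        rates=baseline_rates,
    )


class TestAssessBurden:
    def test_regional_sums_match_national(self, inputs):
        df = h.assess_burden(**inputs)
        for pollutant in ("PM2.5", "O3"):
            for measure in h.MEASURES:
                sub = df[(df.pollutant == pollutant) & (df.measure == measure)]
                nat = sub[sub.level == "national"]["value"].iloc[0]
                reg = sub[sub.level == "region"]["value"].sum()
                assert reg == pytest.approx(nat, rel=1e-9)

    def test_dalys_equal_yll_plus_yld(self, inputs):
        df = h.assess_burden(**inputs).set_index(["level", "unit", "pollutant", "measure"])
        for key in {(l, u, p) for l, u, p, _ in df.index}:
            assert df.loc[(*key, "DALYs"), "value"] == pytest.approx(
                df.loc[(*key, "YLL"), "value"] + df.loc[(*key, "YLD"), "value"]
            )

    def test_burden_monotone_in_exposure(self, inputs):
        lower = dict(inputs, pm_values=inputs["pm_values"] * 0.5)
        a = h.assess_burden(**lower)
        b = h.assess_burden(**inputs)
        mask = a.pollutant == "PM2.5"
        assert (a[mask]["value"].to_numpy() <= b[mask]["value"].to_numpy() + 1e-9).all()

    def test_propagate_ui_matches_bound_reruns(self, inputs):
        """Oracle: the interval bounds equal two independent full-pipeline
        evaluations at the bound parameters."""
        res = h.propagate_ui(**inputs)
        for variant in ("lower", "upper"):
            direct = h.assess_burden(**inputs, variant=variant)
            merged = res.data.merge(
                direct,
                on=["level", "unit", "pollutant", "measure"],
                suffixes=("", "_direct"),
            )
            assert np.allclose(merged[variant], merged["value"])

    def test_ui_ordered_and_degenerate_case(self, inputs):
        res = h.propagate_ui(**inputs)
        assert (res.data["lower"] <= res.data["central"]).all()
        assert (res.data["central"] <= res.data["upper"]).all()
        # degenerate rates: collapse the triples -> degenerate interval
        rates = inputs["rates"].copy()
        rates["lower"] = rates["central"]
        rates["upper"] = rates["central"]
        gemm = inputs["gemm"].copy()
        gemm["theta_lower"] = gemm["theta"]
        gemm["theta_upper"] = gemm["theta"]
        o3p = h.O3RiskParams(hr=1.06, hr_lower=1.06, hr_upper=1.06)
        res2 = h.propagate_ui(
            inputs["domain"], inputs["pm_values"], inputs["o3_values"], gemm, o3p, rates
        )
        assert np.allclose(res2.data["lower"], res2.data["upper"])

    def test_widening_theta_widens_mort_interval(self, inputs):
        gemm_wide = inputs["gemm"].copy()
        gemm_wide["theta_lower"] -= 0.02
        gemm_wide["theta_upper"] += 0.02
        a = h.propagate_ui(**inputs)
        b = h.propagate_ui(**{**inputs, "gemm": gemm_wide})
        lo_a, _, hi_a = a.national("PM2.5", "MORT")
        lo_b, _, hi_b = b.national("PM2.5", "MORT")
        assert hi_b - lo_b > hi_a - lo_a


class TestTotalBurden:
    def _frame(self, mort):
        return pd.DataFrame(
            [{"level": "national", "unit": "all", "measure": "MORT", "value": mort}]
        )

    def test_reported_aggregate_and_share(self):
        tot = h.total_burden(self._frame(2_143_700.0), self._frame(46_000.0))
        assert tot["value"].iloc[0] == pytest.approx(2_189_700.0)
        assert round(100 * tot["share_pm"].iloc[0]) == 98

    def test_zero_second_pollutant(self):
        tot = h.total_burden(self._frame(100.0), self._frame(0.0))
        assert tot["value"].iloc[0] == 100.0
        assert tot["share_pm"].iloc[0] == 1.0

    def test_mismatched_levels_rejected(self):
        other = pd.DataFrame(
            [{"level": "region", "unit": 0, "measure": "MORT", "value": 1.0}]
        )
        with pytest.raises(ValueError):
            h.total_burden(self._frame(1.0), other)
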
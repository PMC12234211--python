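"""Currency safety, IPW weighting, micro-costing aggregation."""

import numpy as np
import pandas as pd
import pytest

from cadcea import schema
from cadcea.costing import (
    CostingConfig,
    CurrencyError,
    Money,
    PropensityWeighter,
    adjust_inflation,
    aggregate_perspective,
    convert_currency,
    fit_propensity,
    ipw_cost_summaries,
    participant_oope_usd,
    productivity_cost,
    weighted_cost_mean,
)
from cadcea.synth import CohortSpec, generate_cohort


class TestMoney:
    def test_mixed_currency_addition_raises(self):
        with pytest.raises(CurrencyError):
            Money(1.0, "KHR") + Money(1.0, "USD")
        assert (Money(1.0, "USD") + Money(2.0, "USD")).amount == 3.0

    @pytest.mark.parametrize("amount,cpi_s,cpi_t,expected", [
        (100.0, 100.0, 110.0, 110.0),
        (100.0, 95.0, 95.0, 100.0),
        (0.0, 80.0, 120.0, 0.0),
    ])
    def test_inflation_ratio(self, amount, cpi_s, cpi_t, expected):
        out = adjust_inflation(Money(amount, "KHR"), cpi_s, cpi_t)
        assert out.amount == pytest.approx(expected)
        assert out.currency == "KHR"

    def test_nonpositive_cpi_rejected(self):
        with pytest.raises(ValueError):
            adjust_inflation(Money(1.0, "KHR"), 0.0, 100.0)

    @pytest.mark.parametrize("khr,usd", [
        (400_000, 96.0), (0, 0.0), (100_000, 24.0),
    ])
    def test_exchange_rate(self, khr, usd):
        out = convert_currency(Money(khr, "KHR"))
        assert out.amount == pytest.approx(usd)
        assert out.currency == "USD"

    def test_no_double_conversion(self):
        with pytest.raises(CurrencyError, match="already USD"):
            convert_currency(Money(5.0, "USD"))


class TestPropensity:
    def test_intercept_only_weights_are_one(self, small_wide):
        ipw = fit_propensity(small_wide, covariates=[])
        assert np.allclose(ipw.stabilized, 1.0)

    def test_extreme_scores_clipped(self, rng):
        n = 300
        x = np.r_[np.zeros(n), np.ones(n)]          # near-perfect separation
        df = pd.DataFrame({"arm": np.r_[["MMD"] * n, ["CAD"] * n],
                           "sep": x + 0.001 * rng.random(2 * n)})
        ipw = fit_propensity(df, covariates=["sep"])
        assert ipw.propensity.min() >= 0.01
        assert ipw.propensity.max() <= 0.95

    def test_truncation_alters_at_most_one_percent(self, small_wide):
        w = PropensityWeighter().fit(small_wide)
        raw_mean_capped = (w.weights_ == w.truncation_cap_).mean()
        assert raw_mean_capped <= 0.02
        assert w.weights_.max() <= w.truncation_cap_

    def test_stabilized_weights_mean_near_one(self, small_wide):
        w = PropensityWeighter().fit(small_wide)
        for arm in schema.ARMS:
            mask = (small_wide["arm"] == arm).to_numpy()
            assert w.weights_[mask].mean() == pytest.approx(1.0, abs=0.15)

    def test_single_arm_rejected(self, small_wide):
        with pytest.raises(ValueError, match="both arms"):
            PropensityWeighter().fit(small_wide[small_wide["arm"] == "MMD"])

    def test_weighting_improves_balance(self):
        """On deliberately imbalanced cohorts the weighted standardized mean
        difference of imbalanced covariates is below the unweighted one."""
        improved = 0
        reps = 5
        for rep in range(reps):
            cohort = generate_cohort(CohortSpec(
                n_control=400, n_intervention=400, seed=500 + rep))
            wide = schema.to_wide(cohort.records)
            w = PropensityWeighter().fit(wide).weights_
            cad = (wide["arm"] == "CAD").to_numpy()
            x = (wide["site_setting"] == "urban").to_numpy(float)

            def smd(weights):
                m1 = np.average(x[cad], weights=weights[cad])
                m0 = np.average(x[~cad], weights=weights[~cad])
                s = np.sqrt(0.5 * (np.var(x[cad]) + np.var(x[~cad])))
                return abs(m1 - m0) / s

            improved += smd(w) < smd(np.ones_like(w))
        assert improved >= reps - 1


class TestWeightedMean:
    def test_unit_weights_arithmetic_mean(self, rng):
        c = rng.random(50)
        mean, _ = weighted_cost_mean(c, np.ones(50))
        assert mean == pytest.approx(c.mean())

    def test_hand_example(self):
        mean, _ = weighted_cost_mean([10.0, 20.0], [1.0, 3.0])
        assert mean == pytest.approx(17.5)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="zero total weight"):
            weighted_cost_mean([1.0], [0.0])


class TestAggregation:
    def test_health_system_perspective(self, published_ledger):
        cad = aggregate_perspective(published_ledger, "CAD", "health_system", 2040)
        assert cad.total == pytest.approx(250_322.40)
        assert cad.mean_per_participant == pytest.approx(122.71, abs=0.005)
        mmd = aggregate_perspective(published_ledger, "MMD", "health_system", 2049)
        assert mmd.total == pytest.approx(4_733.30)
        assert mmd.mean_per_participant == pytest.approx(2.31, abs=0.005)

    def test_societal_excludes_community_worker_items(self, published_ledger):
        cad = aggregate_perspective(published_ledger, "CAD", "societal", 2040)
        assert cad.total == pytest.approx(319_339.03, abs=0.01)
        assert not any("CAW (CAD)" in k for k in cad.components
                       if "OOPE CAW" in k or "Productivity CAW" in k)
        mmd = aggregate_perspective(published_ledger, "MMD", "societal", 2049)
        assert mmd.total == pytest.approx(85_407.96, abs=0.01)

    def test_empty_ledger_zero(self):
        empty = pd.DataFrame(columns=schema.LEDGER_COLUMNS)
        s = aggregate_perspective(empty, "CAD", "health_system", 100)
        assert s.total == 0.0 and s.mean_per_participant == 0.0

    def test_unknown_payer_rejected(self, published_ledger):
        bad = published_ledger.copy()
        bad.loc[0, "payer"] = "mystery"
        with pytest.raises(ValueError, match="payer"):
            aggregate_perspective(bad, "CAD", "health_system", 2040)

    def test_khr_ledger_rows_converted(self):
        ledger = pd.DataFrame([{
            "label": "local item", "perspective": "health_system", "arm": "MMD",
            "payer": "programme", "amount": 100_000.0, "currency": "KHR",
            "cpi_source": 100.0, "cpi_target": 110.0}])
        s = aggregate_perspective(ledger, "MMD", "health_system", 100)
        assert s.total == pytest.approx(100_000 * 1.1 * 0.00024)

    def test_additive_over_ledger_partitions(self, published_ledger):
        whole = aggregate_perspective(published_ledger, "CAD", "societal", 2040)
        top = aggregate_perspective(published_ledger.iloc[:5], "CAD", "societal", 2040)
        bottom = aggregate_perspective(published_ledger.iloc[5:], "CAD", "societal", 2040)
        assert whole.total == pytest.approx(top.total + bottom.total)


class TestProductivity:
    def test_zero_visits_zero_cost(self):
        assert productivity_cost(np.zeros(3), np.ones(3), np.ones(3), 2.0).sum() == 0.0

    def test_hand_example(self):
        # 5 trips x (2*0.5 + 1.0 = 2 h) x 1.5 USD/h = 15 USD
        out = productivity_cost(np.array([5.0]), np.array([0.5]),
                                np.array([1.0]), 1.5)
        assert out[0] == pytest.approx(15.0)

    def test_caregiver_doubles_time_value(self):
        solo = productivity_cost(np.array([4.0]), np.array([1.0]),
                                 np.array([1.0]), 1.0, caregiver=np.array([0.0]))
        pair = productivity_cost(np.array([4.0]), np.array([1.0]),
                                 np.array([1.0]), 1.0, caregiver=np.array([1.0]))
        assert pair[0] == pytest.approx(2 * solo[0])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            productivity_cost(np.array([1.0]), np.array([-1.0]),
                              np.array([0.0]), 1.0)


class TestPooledCosting:
    def test_full_path(self, imputed_small, small_cohort):
        pooled = ipw_cost_summaries(imputed_small.datasets_, small_cohort.ledger)
        for persp in ("health_system", "societal"):
            for arm in schema.ARMS:
                s = pooled.summaries[(arm, persp)]
                assert s.total >= 0
                assert s.mean_per_participant == pytest.approx(s.total / 250)
        # societal adds participant costs on top of programme costs
        assert (pooled.summaries[("MMD", "societal")].total
                > pooled.summaries[("MMD", "health_system")].total)
        assert pooled.incremental_cost("health_system") == pytest.approx(
            pooled.summaries[("CAD", "health_system")].mean_per_participant
            - pooled.summaries[("MMD", "health_system")].mean_per_participant)

    def test_oope_inflation_then_conversion_order(self, imputed_small):
        df = imputed_small.datasets_[0]
        base = participant_oope_usd(df, CostingConfig())
        doubled_cpi = participant_oope_usd(
            df, CostingConfig(cpi_source=100.0, cpi_target=200.0))
        assert np.allclose(doubled_cpi, 2 * base)
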
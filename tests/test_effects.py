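"""Rubin pooling, logistic DiD models, marginal standardization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cadcea.effects import (
    DEFAULT_COVARIATES,
    OutcomeModelSpec,
    PooledDidModel,
    PooledEstimate,
    did_estimate,
    did_from_fit,
    fit_outcome_model,
    marginal_predict,
    pool_rubin,
    select_model,
)


class TestPoolRubin:
    def test_no_between_variance(self):
        est = pool_rubin([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert (est.qbar, est.B, est.T, est.lam) == (2.0, 0.0, 1.0, 0.0)

    def test_hand_arithmetic_m2(self):
        est = pool_rubin([1.0, 3.0], [1.0, 1.0])
        assert est.qbar == 2.0
        assert est.W == 1.0
        assert est.B == 2.0
        assert est.T == pytest.approx(1.0 + 1.5 * 2.0)

    def test_permutation_invariance(self, rng):
        q = rng.normal(size=6).tolist()
        v = rng.random(6).tolist()
        a = pool_rubin(q, v)
        perm = rng.permutation(6)
        b = pool_rubin([q[i] for i in perm], [v[i] for i in perm])
        assert a.qbar == pytest.approx(b.qbar)
        assert a.T == pytest.approx(b.T)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
           st.lists(st.floats(0, 10), min_size=8, max_size=8))
    def test_total_variance_dominates_within(self, estimates, variances):
        variances = variances[: len(estimates)]
        est = pool_rubin(estimates, variances)
        assert est.T >= est.W - 1e-12
        assert est.T == pytest.approx(est.W + (1 + 1 / len(estimates)) * est.B)
        assert 0.0 <= est.lam <= 1.0
        assert 0.0 <= est.fmi <= 1.0
        assert est.ci_low <= est.qbar <= est.ci_high

    def test_fmi_vanishes_as_between_shrinks(self):
        big = pool_rubin([0.0, 1.0], [1.0, 1.0], n_obs=1000, k_params=2)
        small = pool_rubin([0.0, 1e-6], [1.0, 1.0], n_obs=1000, k_params=2)
        assert small.fmi < big.fmi
        assert small.fmi < 0.01

    def test_requires_two_imputations(self):
        with pytest.raises(ValueError, match="m >= 2"):
            pool_rubin([1.0], [1.0])


def _cell_frame(counts):
    """Long table from {(arm, wave): (n_success, n_failure)}."""
    rows = []
    pid = 0
    for (arm, wave), (s, f) in counts.items():
        for y in [1.0] * s + [0.0] * f:
            rows.append({"participant_id": pid, "arm": arm, "wave": wave,
                         "adherent": y})
            pid += 1
    return pd.DataFrame(rows)


SATURATED_COUNTS = {
    ("MMD", "baseline"): (30, 70), ("MMD", "endline"): (45, 55),
    ("CAD", "baseline"): (40, 60), ("CAD", "endline"): (35, 65),
}


class TestOutcomeModel:
    def test_saturated_interaction_equals_cross_ratio(self):
        df = _cell_frame(SATURATED_COUNTS)
        fit = fit_outcome_model(df, OutcomeModelSpec("adherent"))
        odds = {k: s / f for k, (s, f) in SATURATED_COUNTS.items()}
        cross_ratio = ((odds[("CAD", "endline")] / odds[("CAD", "baseline")])
                       / (odds[("MMD", "endline")] / odds[("MMD", "baseline")]))
        assert math.exp(fit.interaction_log_or) == pytest.approx(cross_ratio, rel=1e-6)

    def test_saturated_marginal_equals_raw_proportions(self):
        df = _cell_frame(SATURATED_COUNTS)
        fit = fit_outcome_model(df, OutcomeModelSpec("adherent"))
        for (arm, wave), (s, f) in SATURATED_COUNTS.items():
            mean, var = marginal_predict(fit, df, arm, wave)
            assert mean == pytest.approx(s / (s + f), abs=1e-6)
            assert var >= 0

    def test_null_interaction_covered(self, rng):
        n = 400
        df = pd.DataFrame({
            "participant_id": np.arange(2 * n),
            "arm": np.repeat(["MMD", "CAD"], n),
            "wave": np.tile(np.repeat(["baseline", "endline"], n // 2), 2),
            "adherent": (rng.random(2 * n) < 0.7).astype(float),
        })
        fit = fit_outcome_model(df, OutcomeModelSpec("adherent"))
        z = fit.interaction_log_or / np.sqrt(fit.interaction_var)
        assert abs(z) < 3

    def test_separation_detected(self):
        df = _cell_frame({("MMD", "baseline"): (20, 0), ("MMD", "endline"): (0, 20),
                          ("CAD", "baseline"): (20, 0), ("CAD", "endline"): (0, 20)})
        with pytest.raises(Exception, match="separation|binary"):
            fit_outcome_model(df, OutcomeModelSpec("adherent"))


class TestSelectModel:
    def test_identical_candidate_lrt_zero(self, imputed_small_long):
        df = imputed_small_long[0]
        full = OutcomeModelSpec("adherent", ("site_setting", "comorbidity"))
        chosen, table = select_model(df, full, [full])
        assert table.loc[0, "lrt"] == pytest.approx(0.0, abs=1e-8)
        assert table.loc[0, "p"] == 1.0
        assert chosen == full

    def test_lrt_matches_longhand_loglik(self, imputed_small_long):
        from scipy.special import expit
        df = imputed_small_long[0]
        full = OutcomeModelSpec("adherent", ("site_setting", "comorbidity"))
        nested = OutcomeModelSpec("adherent", ("site_setting",))
        _, table = select_model(df, full, [nested])

        def longhand_llf(spec):
            fit = fit_outcome_model(df, spec)
            from cadcea.effects import _long_design
            data = df.dropna(subset=["adherent"])
            y, X, _ = _long_design(data, spec, columns=fit.design_columns)
            p = expit(X @ fit.params.to_numpy())
            return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))

        expected = 2 * (longhand_llf(full) - longhand_llf(nested))
        assert table.loc[0, "lrt"] == pytest.approx(expected, abs=1e-6)

    def test_null_covariate_dropped(self):
        """A covariate with no true effect is pruned in most replicates."""
        accepted = 0
        reps = 20
        for rep in range(reps):
            rg = np.random.default_rng(300 + rep)
            n = 300
            arm = np.repeat(["MMD", "CAD"], n)
            wave = np.tile(["baseline", "endline"], n)
            noise_cov = rg.integers(0, 2, 2 * n).astype(float)
            p = 0.6 + 0.1 * (arm == "CAD")
            df = pd.DataFrame({
                "participant_id": np.arange(2 * n), "arm": arm, "wave": wave,
                "comorbidity": noise_cov,
                "adherent": (rg.random(2 * n) < p).astype(float),
            })
            full = OutcomeModelSpec("adherent", ("comorbidity",))
            chosen, _ = select_model(df, full, [OutcomeModelSpec("adherent")])
            accepted += chosen.covariates == ()
        assert accepted >= int(0.8 * reps)

    def test_non_nested_candidate_rejected(self, imputed_small_long):
        full = OutcomeModelSpec("adherent", ("site_setting",))
        other = OutcomeModelSpec("adherent", ("comorbidity",))
        with pytest.raises(ValueError, match="nested"):
            select_model(imputed_small_long[0], full, [other])


def _pe(q, t=1e-4, m=3):
    half = 1.96 * np.sqrt(t)
    return PooledEstimate(q, t, 0.0, t, 0.0, 0.0, np.inf, q - half, q + half, m)


class TestDidEstimate:
    def test_published_stratum_arithmetic(self):
        """0.91->0.81 control and 0.87->0.82 intervention give A=-0.10,
        B=-0.05, DiD=0.05."""
        strata = {("MMD", "baseline"): _pe(0.91), ("MMD", "endline"): _pe(0.81),
                  ("CAD", "baseline"): _pe(0.87), ("CAD", "endline"): _pe(0.82)}
        res = did_estimate(strata)
        assert res.diff_control == pytest.approx(-0.10)
        assert res.diff_int == pytest.approx(-0.05)
        assert res.did == pytest.approx(0.05)

    def test_identical_trajectories_null(self):
        strata = {("MMD", "baseline"): _pe(0.8), ("MMD", "endline"): _pe(0.7),
                  ("CAD", "baseline"): _pe(0.8), ("CAD", "endline"): _pe(0.7)}
        assert did_estimate(strata).did == pytest.approx(0.0)

    def test_linearity_in_stratum_means(self, rng):
        vals = rng.random(4)
        strata = {k: _pe(v) for k, v in zip(
            [("MMD", "baseline"), ("MMD", "endline"),
             ("CAD", "baseline"), ("CAD", "endline")], vals)}
        res = did_estimate(strata)
        assert res.did == pytest.approx((vals[3] - vals[2]) - (vals[1] - vals[0]))

    def test_probability_bounds_enforced(self):
        strata = {("MMD", "baseline"): _pe(1.2), ("MMD", "endline"): _pe(0.5),
                  ("CAD", "baseline"): _pe(0.5), ("CAD", "endline"): _pe(0.5)}
        with pytest.raises(ValueError, match="outside"):
            did_estimate(strata)


class TestPooledDidModel:
    def test_fit_attributes(self, imputed_small_long):
        model = PooledDidModel("adherent").fit(imputed_small_long)
        assert len(model.fits_) == 3
        assert model.interaction_.m == 3
        d = model.did_
        for est in (d.p_control_base, d.p_control_end, d.p_int_base, d.p_int_end):
            assert 0.0 <= est.qbar <= 1.0
        assert d.did == pytest.approx(d.diff_int - d.diff_control)
        assert "arm:wave" in model.pooled_params_.index

    def test_did_consistent_between_pooling_paths(self, imputed_small_long):
        """Point estimate is identical whether the DiD is pooled within
        imputations or assembled from pooled strata (it is linear)."""
        a = PooledDidModel("adherent", pool_did_within=True).fit(imputed_small_long)
        b = PooledDidModel("adherent", pool_did_within=False).fit(imputed_small_long)
        assert a.did_.did == pytest.approx(b.did_.did, abs=1e-10)
        # the independence approximation is the conservative one
        assert b.did_.se >= a.did_.se * 0.5

    def test_default_covariates_used(self, imputed_small_long):
        model = PooledDidModel("good_physical").fit(imputed_small_long)
        assert model.spec_.covariates == tuple(DEFAULT_COVARIATES["good_physical"])

    def test_within_imputation_did_matches_manual(self, imputed_small_long):
        df = imputed_small_long[0]
        fit = fit_outcome_model(df, OutcomeModelSpec(
            "adherent", tuple(DEFAULT_COVARIATES["adherent"])))
        strata, did, var = did_from_fit(fit, df)
        manual = (strata[("CAD", "endline")][0] - strata[("CAD", "baseline")][0]
                  - strata[("MMD", "endline")][0] + strata[("MMD", "baseline")][0])
        assert did == pytest.approx(manual)
        assert var > 0
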
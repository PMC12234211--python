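"""Pooled logistic outcome models and difference-in-differences estimation.

Each binary outcome (ART adherence, good physical health, good mental
health) is modelled on the stacked baseline + endline rows with a single
logistic regression::

    logit P(Y=1) = b0 + b1*CAD + b2*endline + b3*CAD*endline + covariates

The arm-by-wave interaction odds ratio ``exp(b3)`` is the adjusted
intervention effect.  The model is fitted in every imputed dataset;
coefficients, marginally standardized stratum probabilities, and the DiD
are pooled across imputations with Rubin's rules (Barnard-Rubin
small-sample degrees of freedom).

Marginal standardization: for a stratum (arm, wave), every row of that arm
has its arm/wave indicators set to the stratum, covariates kept as
observed, and the predicted probabilities are averaged.  The DiD is
``(CAD endline - CAD baseline) - (MMD endline - MMD baseline)``; by
default it is computed within each imputation (propagating the covariance
between strata) and the m DiD values are pooled.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from . import schema

#: default adjustment covariates per outcome
DEFAULT_COVARIATES: dict[str, list[str]] = {
    "adherent": ["site_setting", "age_group", "employment", "duration_art"],
    "good_physical": ["gender", "age_group", "education", "employment",
                      "travel_time", "income_usd", "comorbidity"],
    "good_mental": ["site_setting", "gender", "education", "employment",
                    "family_size", "travel_time", "income_usd",
                    "duration_art", "comorbidity"],
}


class SeparationError(RuntimeError):
    """Perfect separation or non-convergence in a logistic fit."""


@dataclasses.dataclass(frozen=True)
class OutcomeModelSpec:
    """A logistic outcome model: outcome, adjustment covariates, interaction."""

    outcome: str
    covariates: tuple[str, ...] = ()
    includes_interaction: bool = True

    def __post_init__(self):
        if self.outcome not in schema.OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        base = ("arm", "wave", "arm:wave") if self.includes_interaction else ("arm", "wave")
        return base + self.covariates

    def is_nested_in(self, other: "OutcomeModelSpec") -> bool:
        return (self.outcome == other.outcome
                and set(self.terms) <= set(other.terms))


@dataclasses.dataclass
class ModelFit:
    """A fitted logistic model with everything pooling and prediction need."""

    spec: OutcomeModelSpec
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n_obs: int
    k_params: int
    design_columns: list[str]
    converged: bool

    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.llf

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.n_obs) - 2 * self.llf

    @property
    def interaction_log_or(self) -> float:
        return float(self.params["arm:wave"])

    @property
    def interaction_var(self) -> float:
        return float(self.cov.loc["arm:wave", "arm:wave"])


@dataclasses.dataclass
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and variances."""

    qbar: float
    W: float
    B: float
    T: float
    fmi: float
    lam: float
    df: float
    ci_low: float
    ci_high: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.T))


@dataclasses.dataclass
class DidResult:
    """DiD of marginally standardized predicted probabilities."""

    p_control_base: PooledEstimate
    p_control_end: PooledEstimate
    p_int_base: PooledEstimate
    p_int_end: PooledEstimate
    diff_control: float            # A
    diff_int: float                # B
    did: float                     # B - A
    se: float
    pooled_did: PooledEstimate


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def pool_rubin(estimates: Sequence[float], variances: Sequence[float],
               n_obs: int | None = None, k_params: int = 1,
               alpha: float = 0.05) -> PooledEstimate:
    """Combine m completed-data estimates.

    qbar = mean, W = mean within-imputation variance, B = between-imputation
    sample variance, T = W + (1 + 1/m) B; lambda = (1+1/m)B/T; fmi per the
    standard adjusted definition; degrees of freedom follow Barnard-Rubin
    when ``n_obs`` is given, else the classic large-sample form.
    """
    q = np.asarray(estimates, float)
    v = np.asarray(variances, float)
    if q.shape != v.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-D")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 imputations")
    if (v < 0).any():
        raise ValueError("variances must be non-negative")
    qbar = float(q.mean())
    W = float(v.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if T <= 0:
        return PooledEstimate(qbar, W, B, T, 0.0, 0.0, np.inf, qbar, qbar, m)
    lam = (1.0 + 1.0 / m) * B / T
    lam_c = min(max(lam, 1e-12), 1 - 1e-12)
    df_old = (m - 1) / lam_c**2
    if n_obs is not None:
        nu_com = max(n_obs - k_params, 1)
        nu_obs = nu_com * (nu_com + 1) / (nu_com + 3) * (1.0 - lam_c)
        df = 1.0 / (1.0 / df_old + 1.0 / nu_obs)
    else:
        df = df_old
    fmi = (2.0 / (df + 3.0) + lam) / (lam + 1.0) if np.isfinite(df) else lam
    tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    half = tcrit * np.sqrt(T)
    return PooledEstimate(qbar, W, B, T, float(fmi), float(lam), float(df),
                          qbar - half, qbar + half, m)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _long_design(df: pd.DataFrame, spec: OutcomeModelSpec,
                 columns: list[str] | None = None
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix for the stacked-wave logistic model.

    When ``columns`` (from a previous fit) is given, the matrix is aligned
    to it, filling absent dummy levels with zeros.
    """
    y = df[spec.outcome].to_numpy(float)
    cols: list[str] = ["const", "arm", "wave"]
    arm = (df["arm"] == "CAD").to_numpy(float)
    wave = (df["wave"] == "endline").to_numpy(float)
    parts = [np.ones_like(arm), arm, wave]
    if spec.includes_interaction:
        parts.append(arm * wave)
        cols.append("arm:wave")
    for cov in spec.covariates:
        s = df[cov]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            x = s.to_numpy(float)
            if cov == "income_usd":         # heavy right tail: model on log scale
                x = np.log(np.clip(x, 1e-9, None))
            parts.append(x)
            cols.append(cov)
        else:
            d = pd.get_dummies(s.astype(str), prefix=cov, drop_first=True, dtype=float)
            for c in d.columns:
                parts.append(d[c].to_numpy())
                cols.append(c)
    frame = pd.DataFrame(np.column_stack(parts), columns=cols)
    if columns is not None:
        extra = [c for c in cols if c not in columns]
        if extra:
            raise RuntimeError(f"prediction data has unseen levels: {extra}")
        frame = frame.reindex(columns=columns, fill_value=0.0)
        cols = list(columns)
    return y, frame.to_numpy(), cols


def fit_outcome_model(df_long: pd.DataFrame, spec: OutcomeModelSpec) -> ModelFit:
    """ML logistic fit on the stacked two-wave rows of one imputed dataset."""
    data = df_long.dropna(subset=[spec.outcome])
    y, X, cols = _long_design(data, spec)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome!r} is not binary 0/1")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        fit = model.fit(maxiter=200)
    params = np.asarray(fit.params)
    if not np.all(np.isfinite(params)):
        raise SeparationError(f"non-finite coefficients in {spec.outcome} model")
    core = {"const", "arm", "wave", "arm:wave"}
    big = [c for c, b in zip(cols, params) if abs(b) > 15]
    big_core = [c for c in big if c in core]
    if big_core:
        raise SeparationError(f"probable separation on term(s): {', '.join(big_core)}")
    if big:        # quasi-separated nuisance dummy (sparse level): keep, warn
        import warnings
        warnings.warn(f"{spec.outcome}: extreme coefficient on {', '.join(big)}; "
                      "sparse covariate level")
    return ModelFit(
        spec=spec,
        params=pd.Series(params, index=cols),
        cov=pd.DataFrame(np.asarray(fit.cov_params()), index=cols, columns=cols),
        llf=float(fit.llf), n_obs=len(y), k_params=X.shape[1],
        design_columns=cols, converged=bool(fit.converged),
    )


def select_model(df_long: pd.DataFrame, full_spec: OutcomeModelSpec,
                 candidates: Sequence[OutcomeModelSpec],
                 alpha: float = 0.05) -> tuple[OutcomeModelSpec, pd.DataFrame]:
    """Likelihood-ratio-based selection among models nested in ``full_spec``.

    Chooses the smallest candidate not significantly worse than the full
    model (LRT p > alpha), breaking ties by lower BIC (parsimony first).
    """
    full = fit_outcome_model(df_long, full_spec)
    rows = []
    fits = {}
    for cand in candidates:
        if not cand.is_nested_in(full_spec):
            raise ValueError(f"candidate {cand} is not nested in the full model")
        fit = fit_outcome_model(df_long, cand)
        fits[cand] = fit
        lrt = 2.0 * (full.llf - fit.llf)
        df_diff = full.k_params - fit.k_params
        p = 1.0 if df_diff == 0 else float(stats.chi2.sf(max(lrt, 0.0), df_diff))
        rows.append({"covariates": ",".join(cand.covariates) or "(none)",
                     "k": fit.k_params, "lrt": max(lrt, 0.0), "df": df_diff,
                     "p": p, "aic": fit.aic, "bic": fit.bic})
    table = pd.DataFrame(rows)
    ok = [(c, fits[c]) for c, r in zip(candidates, rows) if r["p"] > alpha]
    if ok:
        chosen = min(ok, key=lambda cf: (cf[1].k_params, cf[1].bic))[0]
    else:
        chosen = full_spec
    return chosen, table


# ---------------------------------------------------------------------------
# Marginal standardization and DiD
# ---------------------------------------------------------------------------

_STRATA = (("MMD", "baseline"), ("MMD", "endline"),
           ("CAD", "baseline"), ("CAD", "endline"))


def _stratum_design(df_long: pd.DataFrame, fit: ModelFit, arm: str, wave: str
                    ) -> np.ndarray:
    sub = df_long[df_long["arm"] == arm]
    if sub.empty:
        raise ValueError(f"empty stratum: arm={arm}")
    counter = sub.copy()
    counter["arm"] = arm
    counter["wave"] = wave
    _, X, _ = _long_design(counter.assign(**{fit.spec.outcome: 0.0}), fit.spec,
                           columns=fit.design_columns)
    return X


def marginal_predict(fit: ModelFit, df_long: pd.DataFrame, arm: str, wave: str
                     ) -> tuple[float, float]:
    """Mean predicted probability for a counterfactual (arm, wave) stratum.

    Returns ``(mean, delta-method variance)`` of the average over all rows
    of that arm with indicators set to the stratum and covariates observed.
    """
    X = _stratum_design(df_long, fit, arm, wave)
    beta = fit.params.to_numpy()
    p = expit(X @ beta)
    grad = (p * (1 - p))[:, None] * X
    g = grad.mean(axis=0)
    var = float(g @ fit.cov.to_numpy() @ g)
    return float(p.mean()), var


def did_from_fit(fit: ModelFit, df_long: pd.DataFrame
                 ) -> tuple[dict[tuple[str, str], tuple[float, float]], float, float]:
    """Within-imputation stratum means, DiD and its delta-method variance."""
    strata = {}
    grads = {}
    beta = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    for arm, wave in _STRATA:
        X = _stratum_design(df_long, fit, arm, wave)
        p = expit(X @ beta)
        g = ((p * (1 - p))[:, None] * X).mean(axis=0)
        strata[(arm, wave)] = (float(p.mean()), float(g @ cov @ g))
        grads[(arm, wave)] = g
    did = (strata[("CAD", "endline")][0] - strata[("CAD", "baseline")][0]
           - strata[("MMD", "endline")][0] + strata[("MMD", "baseline")][0])
    g_did = (grads[("CAD", "endline")] - grads[("CAD", "baseline")]
             - grads[("MMD", "endline")] + grads[("MMD", "baseline")])
    var_did = float(g_did @ cov @ g_did)
    return strata, did, var_did


def did_estimate(strata: dict[tuple[str, str], PooledEstimate],
                 pooled_did: PooledEstimate | None = None) -> DidResult:
    """Assemble a :class:`DidResult` from pooled stratum probabilities.

    When ``pooled_did`` (the within-imputation DiD pooled over m) is given
    its SE is used; otherwise the SE treats the four strata as independent
    (conservative).
    """
    for key, est in strata.items():
        if not 0.0 <= est.qbar <= 1.0:
            raise ValueError(f"stratum probability outside [0,1]: {key} -> {est.qbar}")
    a = strata[("MMD", "endline")].qbar - strata[("MMD", "baseline")].qbar
    b = strata[("CAD", "endline")].qbar - strata[("CAD", "baseline")].qbar
    did = b - a
    if pooled_did is not None:
        se = pooled_did.se
    else:
        se = float(np.sqrt(sum(est.T for est in strata.values())))
        pooled_did = PooledEstimate(
            did, se**2, 0.0, se**2, 0.0, 0.0, np.inf,
            did - 1.96 * se, did + 1.96 * se, strata[("MMD", "baseline")].m)
    return DidResult(
        p_control_base=strata[("MMD", "baseline")],
        p_control_end=strata[("MMD", "endline")],
        p_int_base=strata[("CAD", "baseline")],
        p_int_end=strata[("CAD", "endline")],
        diff_control=a, diff_int=b, did=did, se=se, pooled_did=pooled_did,
    )


# ---------------------------------------------------------------------------
# Estimator over imputed datasets
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator  # noqa: E402  (keep dataclasses above)


class PooledDidModel(BaseEstimator):
    """Fit one outcome model per imputed dataset and pool with Rubin's rules.

    Parameters
    ----------
    outcome : one of ``adherent`` / ``good_physical`` / ``good_mental``.
    covariates : adjustment covariates; per-outcome defaults when None.
    pool_did_within : pool the within-imputation DiD values (default) or
        combine pooled stratum estimates under independence.

    Attributes
    ----------
    fits_ : the m :class:`ModelFit` objects.
    pooled_params_ : Rubin-pooled coefficient table (log-odds scale).
    interaction_ : :class:`PooledEstimate` of the arm-by-wave log-OR.
    did_ : :class:`DidResult`.
    """

    def __init__(self, outcome: str = "adherent",
                 covariates: Sequence[str] | None = None,
                 pool_did_within: bool = True, alpha: float = 0.05):
        self.outcome = outcome
        self.covariates = covariates
        self.pool_did_within = pool_did_within
        self.alpha = alpha

    def fit(self, datasets: Sequence[pd.DataFrame], y=None) -> "PooledDidModel":
        """``datasets``: m imputed long-format tables."""
        covs = (tuple(self.covariates) if self.covariates is not None
                else tuple(DEFAULT_COVARIATES[self.outcome]))
        spec = OutcomeModelSpec(self.outcome, covs)
        fits, stratum_vals, did_vals, did_vars = [], {s: [] for s in _STRATA}, [], []
        stratum_vars = {s: [] for s in _STRATA}
        for df in datasets:
            fit = fit_outcome_model(df, spec)
            fits.append(fit)
            strata, did, var_did = did_from_fit(fit, df)
            for s in _STRATA:
                stratum_vals[s].append(strata[s][0])
                stratum_vars[s].append(strata[s][1])
            did_vals.append(did)
            did_vars.append(var_did)
        n_obs = fits[0].n_obs
        k = fits[0].k_params
        self.fits_ = fits
        self.spec_ = spec
        rows = []
        for term in fits[0].design_columns:
            est = pool_rubin([f.params[term] for f in fits],
                             [f.cov.loc[term, term] for f in fits],
                             n_obs=n_obs, k_params=k, alpha=self.alpha)
            rows.append({"term": term, "estimate": est.qbar, "se": est.se,
                         "or": float(np.exp(est.qbar)),
                         "or_low": float(np.exp(est.ci_low)),
                         "or_high": float(np.exp(est.ci_high)),
                         "fmi": est.fmi, "lambda": est.lam, "df": est.df,
                         "p": float(2 * stats.t.sf(abs(est.qbar / est.se), est.df))
                              if est.se > 0 else 0.0})
        self.pooled_params_ = pd.DataFrame(rows).set_index("term")
        self.interaction_ = pool_rubin(
            [f.interaction_log_or for f in fits],
            [f.interaction_var for f in fits],
            n_obs=n_obs, k_params=k, alpha=self.alpha)
        pooled_strata = {
            s: pool_rubin(stratum_vals[s], stratum_vars[s],
                          n_obs=n_obs, k_params=k, alpha=self.alpha)
            for s in _STRATA
        }
        pooled_did = (pool_rubin(did_vals, did_vars, n_obs=n_obs, k_params=k,
                                 alpha=self.alpha)
                      if self.pool_did_within else None)
        self.did_ = did_estimate(pooled_strata, pooled_did)
        return self
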
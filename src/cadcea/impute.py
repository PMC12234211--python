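"""Multiple imputation by chained equations (fully conditional specification).

Endline outcomes, itemized costs and facility-visit counts are missing for
participants lost to follow-up.  Under a missing-at-random assumption each
variable with missingness is imputed from its own conditional model,
sweeping through variables (ascending missingness fraction) for a fixed
number of iterations, independently in each of ``m`` chains — one chain
per completed dataset.

Method dispatch by variable type:

* ``pmm`` — predictive mean matching for continuous variables: Bayesian
  linear-model parameter draw, then each missing row receives the observed
  value of one of the *k* donors nearest in predicted mean.  Imputations
  are always members of the observed support, so semicontinuous costs keep
  their point mass at zero.
* ``logistic`` — binary variables: GLM fit with a normal-approximation
  parameter draw, imputation by Bernoulli draw from predicted probability.
* ``proportional_odds`` — ordinal variables, sampling from predicted
  category probabilities.
* ``multinomial`` — unordered multi-level categoricals, likewise.

Visit counts are imputed from socio-demographic predictors only;
socio-demographics of LTFU participants are carried forward from baseline
unchanged (they are assumed stable over the study window).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator

from . import schema

METHODS = ("pmm", "logistic", "proportional_odds", "multinomial")

#: endline variables imputed by default (derived binaries recomputed after)
DEFAULT_IMPUTED = (
    ["adherent_end", "pcs_end", "mcs_end"]
    + [f"{c}_end" for c in schema.COST_ITEMS]
    + ["caregiver_end", "visits"]
)


class StepError(RuntimeError):
    """A conditional-model step failed (singular fit, separation, ...)."""


class ImputationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    m: int = Field(default=10, ge=2)
    iterations: int = Field(default=50, ge=1)
    method_map: dict[str, str] = Field(default_factory=dict)
    predictor_matrix: dict[str, list[str]] = Field(default_factory=dict)
    donor_pool_k: int = Field(default=5, ge=1)
    seed: int = Field(default=0, ge=0)

    def validated(self) -> "ImputationConfig":
        for var, method in self.method_map.items():
            if method not in METHODS:
                raise ValueError(f"unknown method {method!r} for {var!r}")
            preds = self.predictor_matrix.get(var, [])
            if not preds:
                raise ValueError(f"variable {var!r} has no predictors")
        return self


@dataclasses.dataclass
class ImputationResult:
    datasets: list[pd.DataFrame]
    chain_stats: pd.DataFrame       # chain, iteration, variable, mean, sd
    config: ImputationConfig

    def __post_init__(self) -> None:
        if len(self.datasets) != self.config.m:
            raise ValueError("len(datasets) != m")


# ---------------------------------------------------------------------------
# Conditional-model steps
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    """Intercept + dummy-coded design matrix from mixed-type predictors."""
    parts = [np.ones((len(df), 1))]
    for c in cols:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.to_numpy(float).reshape(-1, 1))
        else:
            d = pd.get_dummies(s.astype(str), drop_first=True, dtype=float)
            parts.append(d.to_numpy())
    return np.hstack(parts)


def pmm_step(y: pd.Series, X: np.ndarray, donor_pool_k: int,
             rng: np.random.Generator, return_donors: bool = False):
    """Predictive-mean-matching imputation for the missing entries of ``y``.

    Returns imputed values aligned with ``y[y.isna()]``.  Type-1 matching:
    observed predictions use the ML estimate, missing-row predictions use a
    Bayesian parameter draw, and each missing row copies the observed value
    of one of the ``donor_pool_k`` nearest donors chosen uniformly.
    """
    obs = y.notna().to_numpy()
    mis = ~obs
    if not mis.any():
        return (np.empty(0), {}) if return_donors else np.empty(0)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise StepError(f"no observed donors for {y.name!r}")
    k = donor_pool_k
    if n_obs < k:
        warnings.warn(f"{y.name}: only {n_obs} donors, shrinking k from {k}")
        k = n_obs
    X_obs, X_mis = X[obs], X[mis]
    y_obs = y.to_numpy(float)[obs]

    beta_hat, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    df_resid = max(n_obs - rank, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(df_resid, random_state=rng)
    xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
    cov = sigma2 * xtx_inv
    cov = (cov + cov.T) / 2.0
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        beta_draw = beta_hat + L @ rng.standard_normal(len(beta_hat))
    except np.linalg.LinAlgError:
        beta_draw = beta_hat

    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_draw
    dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
    kk = min(k, n_obs)
    nearest = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
    choice = rng.integers(0, kk, size=len(yhat_mis))
    donors = nearest[np.arange(len(yhat_mis)), choice]
    if return_donors:
        donor_sets = {i: set(nearest[i].tolist()) for i in range(len(yhat_mis))}
        return y_obs[donors], {"donor_sets": donor_sets, "yhat_obs": yhat_obs,
                               "yhat_mis": yhat_mis}
    return y_obs[donors]


def logistic_step(y: pd.Series, X: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Bayesian-draw logistic imputation for a binary variable."""
    obs = y.notna().to_numpy()
    mis = ~obs
    if not mis.any():
        return np.empty(0)
    y_obs = y.to_numpy(float)[obs]
    levels = np.unique(y_obs)
    if len(levels) == 1:            # degenerate: observed part is constant
        return np.full(int(mis.sum()), levels[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y_obs, X[obs], family=sm.families.Binomial()).fit()
            beta = np.asarray(fit.params)
            cov = np.asarray(fit.cov_params())
            if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(cov)):
                raise StepError("non-finite logistic fit (separation?)")
        except Exception as exc:   # noqa: BLE001 - any fit failure falls through
            raise StepError(f"logistic step failed for {y.name!r}: {exc}") from exc
    cov = (cov + cov.T) / 2.0
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        beta_draw = beta + L @ rng.standard_normal(len(beta))
    except np.linalg.LinAlgError:
        beta_draw = beta
    p = expit(X[mis] @ beta_draw)
    return (rng.random(len(p)) < p).astype(float)


def _categorical_step(y: pd.Series, X: np.ndarray, rng: np.random.Generator,
                      ordered: bool) -> np.ndarray:
    """Proportional-odds (ordered) or multinomial sampling step."""
    obs = y.notna().to_numpy()
    mis = ~obs
    if not mis.any():
        return np.empty(0)
    y_cat = pd.Categorical(y[obs], ordered=ordered)
    levels = list(y_cat.categories)
    if len(levels) == 1:
        return np.full(int(mis.sum()), levels[0], dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if ordered:
                from statsmodels.miscmodels.ordinal_model import OrderedModel
                model = OrderedModel(y_cat.codes.astype(float), X[obs][:, 1:],
                                     distr="logit")
                fit = model.fit(method="bfgs", disp=False, maxiter=200)
                params = np.asarray(fit.params)
                cov = np.asarray(fit.cov_params())
                draw = _mvn_draw(params, cov, rng)
                probs = model.model_predict(draw, exog=X[mis][:, 1:], which="prob")
            else:
                model = sm.MNLogit(y_cat.codes.astype(float), X[obs])
                fit = model.fit(disp=False, maxiter=200)
                params = np.asarray(fit.params)
                cov = np.asarray(fit.cov_params())
                draw = _mvn_draw(params.ravel(order="F"), cov, rng)
                draw = draw.reshape(params.shape, order="F")
                probs = model.predict(draw, exog=X[mis])
            probs = np.clip(np.asarray(probs), 0.0, None)
            probs /= probs.sum(axis=1, keepdims=True)
        except Exception as exc:   # noqa: BLE001
            raise StepError(f"categorical step failed for {y.name!r}: {exc}") from exc
    cum = probs.cumsum(axis=1)
    u = rng.random(len(cum))
    codes = (u[:, None] > cum).sum(axis=1)
    return np.asarray(levels, dtype=object)[codes]


def _mvn_draw(mean: np.ndarray, cov: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        return mean + L @ rng.standard_normal(len(mean))
    except np.linalg.LinAlgError:
        return mean


def proportional_odds_step(y, X, rng):
    return _categorical_step(y, X, rng, ordered=True)


def multinomial_step(y, X, rng):
    return _categorical_step(y, X, rng, ordered=False)


# ---------------------------------------------------------------------------
# Configuration builder
# ---------------------------------------------------------------------------

def infer_method(series: pd.Series) -> str:
    """Assign the conditional-model family from the variable's type."""
    non_null = series.dropna()
    if isinstance(series.dtype, pd.CategoricalDtype):
        return "proportional_odds" if series.dtype.ordered else "multinomial"
    if pd.api.types.is_numeric_dtype(series):
        uniq = non_null.unique()
        if len(uniq) <= 2 and set(np.asarray(uniq, float)) <= {0.0, 1.0}:
            return "logistic"
        return "pmm"
    n_levels = non_null.nunique()
    if n_levels == 2:
        return "logistic"
    if n_levels == 0:
        raise ValueError(f"cannot type all-missing variable {series.name!r}")
    return "multinomial"


def build_default_config(wide_df: pd.DataFrame, m: int = 10,
                         iterations: int = 50, donor_pool_k: int = 5,
                         seed: int = 0) -> ImputationConfig:
    """Default method dispatch and predictor matrix for the wide table.

    Predictors for every imputed variable are the socio-demographic
    covariates plus the baseline outcome/cost variables plus the *other*
    imputed endline variables; the visit count uses socio-demographics
    only.  Derived binaries (``good_physical_end``/``good_mental_end``)
    are recomputed from imputed scores, not imputed directly.
    """
    sociodemo = ["arm"] + [c for c in schema.SOCIODEMO if c in wide_df.columns]
    baseline = [c for c in wide_df.columns
                if c.endswith("_base") and pd.api.types.is_numeric_dtype(wide_df[c])
                and not wide_df[c].isna().any()]
    candidates = [c for c in DEFAULT_IMPUTED if c in wide_df.columns]
    imputed = [c for c in candidates if wide_df[c].isna().any()]
    method_map, predictors = {}, {}
    for var in imputed:
        method_map[var] = infer_method(wide_df[var])
        if var == "visits":
            predictors[var] = list(sociodemo)
        else:
            others = [v for v in imputed if v not in (var, "visits")]
            predictors[var] = sociodemo + baseline + others
    return ImputationConfig(m=m, iterations=iterations, method_map=method_map,
                            predictor_matrix=predictors,
                            donor_pool_k=donor_pool_k, seed=seed).validated()


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

_STEP_FN = {
    "pmm": lambda y, X, k, rng: pmm_step(y, X, k, rng),
    "logistic": lambda y, X, k, rng: logistic_step(y, X, rng),
    "proportional_odds": lambda y, X, k, rng: proportional_odds_step(y, X, rng),
    "multinomial": lambda y, X, k, rng: multinomial_step(y, X, rng),
}


class MICEImputer(BaseEstimator):
    """Chained-equations multiple imputer (scikit-learn estimator style).

    ``fit(X)`` runs ``m`` independent chains on the wide participant table
    and stores the completed datasets and per-sweep chain statistics.

    Parameters
    ----------
    m : number of imputed datasets (one chain each).
    iterations : sweeps per chain.
    method_map, predictor_matrix : per-variable model dispatch; built with
        :func:`build_default_config` when omitted.
    donor_pool_k : PMM donor-pool size.
    random_state : master seed; chains use spawned child streams.

    Attributes
    ----------
    datasets_ : list of ``m`` completed copies of the input.
    chain_stats_ : per chain/iteration/variable mean and SD of imputations.
    config_ : the resolved :class:`ImputationConfig`.
    """

    def __init__(self, m: int = 10, iterations: int = 50,
                 method_map: dict[str, str] | None = None,
                 predictor_matrix: dict[str, list[str]] | None = None,
                 donor_pool_k: int = 5, random_state: int = 0):
        self.m = m
        self.iterations = iterations
        self.method_map = method_map
        self.predictor_matrix = predictor_matrix
        self.donor_pool_k = donor_pool_k
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "MICEImputer":
        if self.method_map is None or self.predictor_matrix is None:
            config = build_default_config(
                X, m=self.m, iterations=self.iterations,
                donor_pool_k=self.donor_pool_k, seed=self.random_state)
        else:
            config = ImputationConfig(
                m=self.m, iterations=self.iterations,
                method_map=self.method_map,
                predictor_matrix=self.predictor_matrix,
                donor_pool_k=self.donor_pool_k, seed=self.random_state,
            ).validated()
        result = fcs_impute(X, config)
        self.datasets_ = result.datasets
        self.chain_stats_ = result.chain_stats
        self.config_ = result.config
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame | None = None) -> list[pd.DataFrame]:
        """Return the ``m`` completed datasets from :meth:`fit`."""
        if not hasattr(self, "datasets_"):
            raise RuntimeError("MICEImputer is not fitted")
        return self.datasets_

    def fit_transform(self, X: pd.DataFrame, y=None) -> list[pd.DataFrame]:
        return self.fit(X).transform()

    @property
    def result_(self) -> ImputationResult:
        return ImputationResult(self.datasets_, self.chain_stats_, self.config_)


def fcs_impute(wide_df: pd.DataFrame, config: ImputationConfig) -> ImputationResult:
    """Run the chained-equations engine; see :class:`MICEImputer`."""
    config = config.validated()
    variables = [v for v in config.method_map if wide_df[v].isna().any()]
    if not variables:
        datasets = [wide_df.copy() for _ in range(config.m)]
        stats_df = pd.DataFrame(columns=["chain", "iteration", "variable", "mean", "sd"])
        return ImputationResult(datasets, stats_df, config)

    # sweep order: ascending missingness fraction, ties by name
    miss_frac = {v: wide_df[v].isna().mean() for v in variables}
    order = sorted(variables, key=lambda v: (miss_frac[v], v))

    seeds = np.random.SeedSequence(config.seed).spawn(config.m)
    datasets, stat_rows = [], []
    for chain, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        working = wide_df.copy()
        for var in order:                       # init: draws from observed marginals
            mis = working[var].isna()
            donors = working.loc[~mis, var].to_numpy()
            working.loc[mis, var] = rng.choice(donors, size=int(mis.sum()))
        for it in range(config.iterations):
            for var in order:
                mis_mask = wide_df[var].isna()
                X = _design(working, config.predictor_matrix[var])
                y = wide_df[var]                # original missingness pattern
                try:
                    imputed = _STEP_FN[config.method_map[var]](
                        y, X, config.donor_pool_k, rng)
                except StepError as exc:
                    warnings.warn(f"sweep {it} {var}: {exc}; marginal draw fallback")
                    donors = y.dropna().to_numpy()
                    imputed = rng.choice(donors, size=int(mis_mask.sum()))
                working.loc[mis_mask, var] = imputed
                vals = pd.to_numeric(working.loc[mis_mask, var], errors="coerce")
                stat_rows.append({"chain": chain, "iteration": it, "variable": var,
                                  "mean": float(vals.mean()),
                                  "sd": float(vals.std(ddof=0))})
        _rederive(working)
        datasets.append(working)
    stats_df = pd.DataFrame(stat_rows)
    return ImputationResult(datasets, stats_df, config)


def _rederive(working: pd.DataFrame) -> None:
    """Recompute score-derived binaries after imputation."""
    if "pcs_end" in working and "good_physical_end" in working:
        working["good_physical_end"] = (
            working["pcs_end"].astype(float) >= 50.0).astype(float)
    if "mcs_end" in working and "good_mental_end" in working:
        working["good_mental_end"] = (
            working["mcs_end"].astype(float) >= 42.0).astype(float)


def convergence_report(result: ImputationResult, window: int = 10,
                       threshold: float = 1.2) -> pd.DataFrame:
    """Chain-mixing diagnostics per imputed variable.

    Over the final ``window`` sweeps computes the between-chain variance of
    chain means, the within-chain variance of the mean trajectory, and a
    potential-scale-reduction-style mixing ratio; flags variables whose
    ratio exceeds ``threshold``.
    """
    cs = result.chain_stats
    if cs.empty:
        return pd.DataFrame(columns=["variable", "between", "within",
                                     "mixing_ratio", "passed"])
    iters = int(cs["iteration"].max()) + 1
    if iters < window:
        warnings.warn(f"only {iters} sweeps available; diagnostics use all of them")
    lo = max(iters - window, 0)
    rows = []
    for var, sub in cs.groupby("variable"):
        pivot = (sub[sub["iteration"] >= lo]
                 .pivot(index="chain", columns="iteration", values="mean"))
        seq = pivot.to_numpy(float)          # chains x sweeps
        n_sweeps = seq.shape[1]
        chain_means = seq.mean(axis=1)
        within = float(seq.var(axis=1, ddof=1).mean()) if n_sweeps > 1 else 0.0
        between = float(chain_means.var(ddof=1)) if len(chain_means) > 1 else 0.0
        if within > 0:
            var_plus = (n_sweeps - 1) / n_sweeps * within + between
            ratio = float(np.sqrt(var_plus / within))
        else:
            scale = max(abs(float(chain_means.mean())), 1.0)
            ratio = 1.0 if between <= 1e-12 * scale**2 else np.inf
        rows.append({"variable": var, "between": between, "within": within,
                     "mixing_ratio": ratio, "passed": ratio <= threshold})
    return pd.DataFrame(rows)
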
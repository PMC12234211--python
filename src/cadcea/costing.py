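"""Micro-costing: inflation/currency adjustment, IPW-balanced participant
costs, and per-perspective aggregation.

Health-system costs are the fixed programme items (community-worker
salaries, training, meetings/communication).  Societal costs add the
out-of-pocket expenditure (OOPE) and productivity losses of participants
and their caregivers — but exclude community-worker OOPE and productivity,
since community-worker salary, transport and communication are already
covered by the health system.

All arithmetic is currency-safe: mixing Riel (KHR) and USD raises.
Adjustment order is fixed: inflate in the original currency (CPI ratio to
the target price date), then convert KHR to USD at 0.00024 USD/Riel.

Participant OOPE and productivity costs are covariate-balanced with a
stabilized, truncated inverse-probability weight: a logistic propensity of
assignment to the intervention arm from baseline socio-demographics,
clipped to [0.01, 0.95]; stabilized weight = marginal arm probability /
conditional probability; truncated at the empirical 99th percentile within
each imputed dataset.  Weighted means are pooled across imputations with
Rubin's rules.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from . import schema
from .effects import PooledEstimate, pool_rubin

KHR_PER_USD_RATE = 0.00024      # 1 Riel = 0.00024 USD

#: travel-time category -> one-way hours (midpoint-style valuation)
TRAVEL_HOURS = {"short": 0.25, "medium": 1.25, "long": 5.0, "very_long": 10.0}

#: hourly value of participant/caregiver time.  Median household income
#: (~216 USD/month) over ~30 days x 8 h is ~0.9 USD/h per household; with
#: roughly two earning adults per household the per-person rate is ~0.45.
DEFAULT_WAGE_USD_PER_HOUR = 0.45

#: default propensity covariates: the socio-demographic set
DEFAULT_PROPENSITY_COVARIATES = (
    schema.SOCIODEMO_CATEGORICAL + ["comorbidity", "waiting_hours", "income_usd"]
)


class CurrencyError(ValueError):
    """Mixed-currency arithmetic or an invalid conversion."""


@dataclasses.dataclass(frozen=True)
class Money:
    """An amount tagged with its currency (KHR or USD)."""

    amount: float
    currency: str

    def __post_init__(self):
        if self.currency not in ("KHR", "USD"):
            raise CurrencyError(f"unknown currency {self.currency!r}")
        if not np.isfinite(self.amount):
            raise CurrencyError("non-finite amount")

    def __add__(self, other: "Money") -> "Money":
        if not isinstance(other, Money):
            raise CurrencyError("can only add Money to Money")
        if other.currency != self.currency:
            raise CurrencyError(
                f"cannot add {other.currency} to {self.currency}")
        return Money(self.amount + other.amount, self.currency)

    def __mul__(self, factor: float) -> "Money":
        return Money(self.amount * float(factor), self.currency)

    __rmul__ = __mul__


def adjust_inflation(amount: Money, cpi_source: float, cpi_target: float) -> Money:
    """Re-express ``amount`` at the target price date: x * CPI_t / CPI_s."""
    if cpi_source <= 0 or cpi_target <= 0:
        raise ValueError("CPI values must be positive")
    return Money(amount.amount * cpi_target / cpi_source, amount.currency)


def convert_currency(amount: Money, rate: float = KHR_PER_USD_RATE) -> Money:
    """Convert Riel to USD; refuses to double-convert USD."""
    if amount.currency == "USD":
        raise CurrencyError("amount is already USD; refusing to convert again")
    return Money(amount.amount * rate, "USD")


# ---------------------------------------------------------------------------
# Propensity weights
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IpwWeights:
    propensity: np.ndarray          # clipped P(arm = CAD | covariates)
    stabilized: np.ndarray
    truncation_cap: float


class PropensityWeighter(BaseEstimator):
    """Stabilized, truncated inverse-probability weights for arm assignment.

    ``fit(df)`` takes a wide table (one row per participant) with ``arm``
    and baseline covariates.

    Attributes
    ----------
    propensity_ : clipped propensity scores P(CAD | x).
    weights_ : stabilized truncated weights aligned with the input rows.
    truncation_cap_ : the 99th-percentile cap that was applied.
    """

    def __init__(self, covariates: Sequence[str] | None = None,
                 clip_bounds: tuple[float, float] = (0.01, 0.95),
                 truncate_percentile: float = 99.0):
        self.covariates = covariates
        self.clip_bounds = clip_bounds
        self.truncate_percentile = truncate_percentile

    def fit(self, df: pd.DataFrame, y=None) -> "PropensityWeighter":
        arms = df["arm"].unique()
        if len(arms) < 2:
            raise ValueError("both arms must be present to fit a propensity model")
        chosen = (DEFAULT_PROPENSITY_COVARIATES if self.covariates is None
                  else self.covariates)
        covs = [c for c in chosen if c in df.columns]
        z = (df["arm"] == "CAD").to_numpy(float)
        parts = [np.ones((len(df), 1))]
        for c in covs:
            s = df[c]
            if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
                x = s.to_numpy(float)
                if c in ("income_usd", "waiting_hours"):
                    x = np.log(np.clip(x, 1e-9, None))
                parts.append(x.reshape(-1, 1))
            else:
                parts.append(pd.get_dummies(s.astype(str), drop_first=True,
                                            dtype=float).to_numpy())
        X = np.hstack(parts)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(z, X, family=sm.families.Binomial()).fit(maxiter=100)
        lo, hi = self.clip_bounds
        e = np.clip(np.asarray(fit.fittedvalues), lo, hi)
        p_marg = z.mean()
        w = np.where(z == 1.0, p_marg / e, (1.0 - p_marg) / (1.0 - e))
        cap = float(np.percentile(w, self.truncate_percentile))
        self.propensity_ = e
        self.weights_ = np.minimum(w, cap)
        self.truncation_cap_ = cap
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, df: pd.DataFrame | None = None) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("PropensityWeighter is not fitted")
        return self.weights_

    @property
    def ipw_(self) -> IpwWeights:
        return IpwWeights(self.propensity_, self.weights_, self.truncation_cap_)


def fit_propensity(df: pd.DataFrame, covariates: Sequence[str] | None = None,
                   clip_bounds: tuple[float, float] = (0.01, 0.95),
                   truncate_percentile: float = 99.0) -> IpwWeights:
    """Functional wrapper over :class:`PropensityWeighter`."""
    return PropensityWeighter(covariates, clip_bounds,
                              truncate_percentile).fit(df).ipw_


def weighted_cost_mean(costs: np.ndarray, weights: np.ndarray
                       ) -> tuple[float, float]:
    """Weighted mean cost and its (within-dataset) variance estimate.

    Mean = sum(w c) / sum(w); variance by the linearized ratio estimator
    sum(w_i^2 (c_i - mean)^2) / (sum w)^2.
    """
    costs = np.asarray(costs, float)
    weights = np.asarray(weights, float)
    sw = weights.sum()
    if sw <= 0:
        raise ValueError("zero total weight")
    mean = float((weights * costs).sum() / sw)
    var = float((weights**2 * (costs - mean) ** 2).sum() / sw**2)
    return mean, var


# ---------------------------------------------------------------------------
# Participant-level cost construction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CostingConfig:
    """Valuation parameters for participant costs."""

    exchange_rate: float = KHR_PER_USD_RATE
    cpi_source: float = 1.0                 # CPI at the survey price date
    cpi_target: float = 1.0                 # CPI at the reporting date
    wage_usd_per_hour: float = DEFAULT_WAGE_USD_PER_HOUR  # human-capital rate
    travel_hours: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(TRAVEL_HOURS))
    propensity_covariates: tuple[str, ...] | None = None
    clip_bounds: tuple[float, float] = (0.01, 0.95)
    truncate_percentile: float = 99.0


def per_trip_oope_khr(wide_df: pd.DataFrame) -> np.ndarray:
    """Itemized per-trip OOPE in Riel, averaged over the two waves."""
    base = sum(wide_df[f"{c}_base"].to_numpy(float) for c in schema.COST_ITEMS)
    end = sum(wide_df[f"{c}_end"].to_numpy(float) for c in schema.COST_ITEMS)
    return 0.5 * (base + end)


def participant_oope_usd(wide_df: pd.DataFrame, config: CostingConfig) -> np.ndarray:
    """Per-participant OOPE over the study period, USD at the target date.

    Per-trip itemized OOPE (Riel) x number of facility trips, inflated in
    Riel, then converted to USD.
    """
    per_trip = per_trip_oope_khr(wide_df)
    visits = wide_df["visits"].to_numpy(float)
    total_khr = per_trip * visits
    inflated = total_khr * (config.cpi_target / config.cpi_source)
    return inflated * config.exchange_rate


def productivity_cost(visits: np.ndarray, travel_hours: np.ndarray,
                      waiting_hours: np.ndarray, wage_usd_per_hour: float,
                      caregiver: np.ndarray | None = None) -> np.ndarray:
    """Human-capital time valuation of facility trips, USD.

    trips x (round-trip travel + waiting hours) x hourly wage; the time of
    an accompanying caregiver is valued at the same wage when the caregiver
    flag is set.
    """
    travel_hours = np.asarray(travel_hours, float)
    waiting_hours = np.asarray(waiting_hours, float)
    if (travel_hours < 0).any() or (waiting_hours < 0).any():
        raise ValueError("negative travel or waiting time")
    hours = 2.0 * travel_hours + waiting_hours
    cost = np.asarray(visits, float) * hours * wage_usd_per_hour
    if caregiver is not None:
        cost = cost * (1.0 + np.asarray(caregiver, float))
    return cost


def participant_productivity_usd(wide_df: pd.DataFrame,
                                 config: CostingConfig) -> np.ndarray:
    travel = wide_df["travel_time"].map(config.travel_hours).to_numpy(float)
    caregiver = wide_df["caregiver_end"].to_numpy(float)
    return productivity_cost(
        wide_df["visits"].to_numpy(float), travel,
        wide_df["waiting_hours"].to_numpy(float),
        config.wage_usd_per_hour, caregiver=caregiver,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CostSummary:
    """Per-arm, per-perspective cost totals (USD at the target date)."""

    arm: str
    perspective: str
    total: float
    mean_per_participant: float
    variance: float = 0.0           # imputation-propagated, mean scale
    components: dict[str, float] = dataclasses.field(default_factory=dict)


def _ledger_total_usd(ledger: pd.DataFrame, arm: str,
                      payers: set[str] | None = None) -> tuple[float, dict[str, float]]:
    rows = ledger[ledger["arm"].isin([arm, "shared"])]
    if payers is not None:
        rows = rows[rows["payer"].isin(payers)]
    total = 0.0
    components: dict[str, float] = {}
    for _, r in rows.iterrows():
        m = Money(float(r["amount"]), str(r["currency"]))
        m = adjust_inflation(m, float(r.get("cpi_source", 1.0)),
                             float(r.get("cpi_target", 1.0)))
        if m.currency == "KHR":
            m = convert_currency(m)
        share = 0.5 if r["arm"] == "shared" else 1.0
        components[str(r["label"])] = m.amount * share
        total += m.amount * share
    return total, components


def aggregate_perspective(ledger: pd.DataFrame, arm: str, perspective: str,
                          arm_size: int,
                          participant_totals: dict[str, tuple[float, float]] | None = None,
                          ) -> CostSummary:
    """Aggregate the cost ledger (plus participant costs) for one arm.

    ``health_system``: programme-payer ledger items only.  ``societal``:
    health-system total + participant/caregiver OOPE + participant
    productivity (``participant_totals`` maps component name to
    ``(total_usd, variance_of_mean)``), excluding any community-worker
    (``caw``-payer) ledger items.
    """
    if perspective not in ("health_system", "societal"):
        raise ValueError(f"unknown perspective {perspective!r}")
    unknown = set(ledger["payer"]) - {"programme", "participant", "caregiver", "caw"}
    if unknown:
        raise ValueError(f"unknown payer(s) in ledger: {sorted(unknown)}")
    hs_total, components = _ledger_total_usd(ledger, arm, payers={"programme"})
    total = hs_total
    variance = 0.0
    if perspective == "societal":
        non_prog, extra = _ledger_total_usd(
            ledger, arm, payers={"participant", "caregiver"})
        total += non_prog
        components.update(extra)
        for name, (part_total, var_of_mean) in (participant_totals or {}).items():
            components[name] = part_total
            total += part_total
            variance += var_of_mean
    mean = total / arm_size
    return CostSummary(arm=arm, perspective=perspective, total=total,
                       mean_per_participant=mean, variance=variance,
                       components=components)


@dataclasses.dataclass
class PooledCosts:
    """IPW-weighted, Rubin-pooled cost summaries per arm and perspective."""

    summaries: dict[tuple[str, str], CostSummary]     # (arm, perspective)
    oope_mean: dict[str, PooledEstimate]              # per arm, weighted mean
    productivity_mean: dict[str, PooledEstimate]
    weight_diagnostics: pd.DataFrame

    def incremental_cost(self, perspective: str) -> float:
        return (self.summaries[("CAD", perspective)].mean_per_participant
                - self.summaries[("MMD", perspective)].mean_per_participant)


def ipw_cost_summaries(datasets: Sequence[pd.DataFrame], ledger: pd.DataFrame,
                       config: CostingConfig | None = None,
                       arm_sizes: dict[str, int] | None = None) -> PooledCosts:
    """Full costing path over m imputed wide datasets.

    Within each dataset: fit the propensity model, weight each arm's OOPE
    and productivity costs, take weighted means; pool the m means per arm
    with Rubin's rules; scale to totals by the intention-to-treat arm size;
    aggregate with the programme ledger per perspective.
    """
    config = config or CostingConfig()
    first = datasets[0]
    arm_sizes = arm_sizes or {a: int((first["arm"] == a).sum()) for a in schema.ARMS}
    oope = {a: ([], []) for a in schema.ARMS}          # means, variances
    prod = {a: ([], []) for a in schema.ARMS}
    diag_rows = []
    for i, df in enumerate(datasets):
        weighter = PropensityWeighter(
            covariates=config.propensity_covariates,
            clip_bounds=config.clip_bounds,
            truncate_percentile=config.truncate_percentile).fit(df)
        w = weighter.weights_
        oope_usd = participant_oope_usd(df, config)
        prod_usd = participant_productivity_usd(df, config)
        for arm in schema.ARMS:
            mask = (df["arm"] == arm).to_numpy()
            m_o, v_o = weighted_cost_mean(oope_usd[mask], w[mask])
            m_p, v_p = weighted_cost_mean(prod_usd[mask], w[mask])
            oope[arm][0].append(m_o)
            oope[arm][1].append(v_o)
            prod[arm][0].append(m_p)
            prod[arm][1].append(v_p)
            diag_rows.append({"dataset": i, "arm": arm,
                              "mean_weight": float(w[mask].mean()),
                              "max_weight": float(w[mask].max()),
                              "cap": weighter.truncation_cap_})
    n_obs = len(first)
    oope_pooled = {a: pool_rubin(*oope[a], n_obs=n_obs) for a in schema.ARMS}
    prod_pooled = {a: pool_rubin(*prod[a], n_obs=n_obs) for a in schema.ARMS}
    summaries = {}
    for arm in schema.ARMS:
        n = arm_sizes[arm]
        participant_totals = {
            "OOPE (participants and caregivers)":
                (oope_pooled[arm].qbar * n, oope_pooled[arm].T),
            "Productivity cost (participants)":
                (prod_pooled[arm].qbar * n, prod_pooled[arm].T),
        }
        for persp in ("health_system", "societal"):
            summaries[(arm, persp)] = aggregate_perspective(
                ledger, arm, persp, n,
                participant_totals if persp == "societal" else None)
    return PooledCosts(summaries=summaries, oope_mean=oope_pooled,
                       productivity_mean=prod_pooled,
                       weight_diagnostics=pd.DataFrame(diag_rows))
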
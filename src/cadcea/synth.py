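"""Synthetic two-arm quasi-experimental cohort generator.

Emulates the structure of a community ART delivery (CAD, intervention)
versus multi-month dispensing (MMD, control) cohort of clinically stable
people living with HIV: socio-demographic covariates with arm imbalance,
binary outcomes (ART adherence, good physical/mental health) generated on
a latent log-odds scale with a shared participant random intercept,
arm-specific outcome decline between baseline and endline, semicontinuous
out-of-pocket cost items (point mass at zero + log-normal, in Riel),
Poisson facility-visit counts, and missing-at-random loss to follow-up
whose marginal rates are calibrated per arm by bisection.

Default parameters reproduce the observed study margins: arm sizes
2049/2040, baseline/endline outcome prevalences, LTFU rates 29.67%/20.29%,
mean visit counts 5.25/4.72, and the programme cost ledger (CAW salaries,
training, meetings).  Covariate-outcome and LTFU coefficient magnitudes
are free parameters of the generator (the study reports none); defaults
are modest log-odds effects documented in the methods note.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit, logit
from scipy.stats import truncnorm

from . import schema
from .measures import derive_outcomes

# ---------------------------------------------------------------------------
# Defaults: observed study margins
# ---------------------------------------------------------------------------

#: covariate level probabilities per arm (MMD, CAD)
COVARIATE_MARGINALS: dict[str, dict[str, tuple[float, float]]] = {
    "site_setting": {"urban": (0.7711, 0.6142), "rural": (0.2289, 0.3858)},
    "age_group": {
        "15-24": (0.0522, 0.0657), "25-49": (0.5681, 0.5127),
        "50-64": (0.3455, 0.3877), "65+": (0.0342, 0.0338),
    },
    "gender": {
        "male": (0.3875, 0.3828), "female": (0.5583, 0.6044),
        "lgbtqia": (0.0542, 0.0127),
    },
    "marital": {"single": (0.4212, 0.3975), "married": (0.5788, 0.6025)},
    "education": {
        "none": (0.1674, 0.1863), "primary": (0.4558, 0.5098),
        "secondary": (0.2162, 0.1980), "tertiary": (0.1147, 0.0740),
        "university": (0.0459, 0.0319),
    },
    "employment": {
        "unemployed": (0.1737, 0.2015), "farmer_fisherman": (0.2445, 0.2799),
        "driver": (0.0288, 0.0319), "self_employed": (0.2089, 0.1657),
        "government": (0.0498, 0.0338), "private": (0.0878, 0.0725),
        "construction_factory": (0.1420, 0.1593), "other": (0.0644, 0.0554),
    },
    "family_size": {
        "alone": (0.0220, 0.0265), "small": (0.6935, 0.7328),
        "medium": (0.2513, 0.2167), "large": (0.0332, 0.0240),
    },
    "children": {
        "none": (0.4241, 0.4157), "one": (0.3128, 0.3333),
        "two": (0.1869, 0.1676), "three_plus": (0.0761, 0.0833),
    },
    "duration_hiv": {
        "1-5": (0.1942, 0.1074), "6-10": (0.1913, 0.1593),
        "11-15": (0.2572, 0.3211), "16-20": (0.2689, 0.3162),
        "21+": (0.0883, 0.0961),
    },
    "duration_art": {
        "0-5": (0.2172, 0.1358), "6-10": (0.2172, 0.1995),
        "11-15": (0.3050, 0.3549), "16-20": (0.2289, 0.2725),
        "21+": (0.0317, 0.0373),
    },
    "transport_mode": {
        "foot_bicycle": (0.0347, 0.0402), "motorised": (0.9273, 0.9539),
        "boat_other": (0.0381, 0.0059),
    },
    "travel_time": {
        "short": (0.4173, 0.4627), "medium": (0.4807, 0.4500),
        "long": (0.0966, 0.0784), "very_long": (0.0054, 0.0088),
    },
}

#: (baseline, endline) outcome prevalence targets per arm
OUTCOME_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    "adherent":      {"MMD": (0.8980, 0.7978), "CAD": (0.8660, 0.8234)},
    "good_physical": {"MMD": (0.6984, 0.4978), "CAD": (0.5529, 0.4641)},
    "good_mental":   {"MMD": (0.8326, 0.7833), "CAD": (0.7632, 0.7453)},
}

#: free-parameter covariate->outcome log-odds loadings
DEFAULT_LOADINGS: dict[str, dict[tuple[str, str | None], float]] = {
    "adherent": {
        ("site_setting", "urban"): 0.15, ("duration_art", "0-5"): -0.30,
        ("employment", "unemployed"): -0.20, ("age_group", "15-24"): -0.35,
    },
    "good_physical": {
        ("comorbidity", None): -0.60, ("age_group", "50-64"): -0.40,
        ("age_group", "65+"): -0.80, ("income_log", None): 0.15,
        ("travel_time", "long"): -0.20,
    },
    "good_mental": {
        ("comorbidity", None): -0.30, ("income_log", None): 0.20,
        ("family_size", "alone"): -0.40, ("gender", "lgbtqia"): -0.30,
    },
}

#: free-parameter MAR LTFU log-odds coefficients (on baseline variables)
DEFAULT_LTFU_COEF: dict[tuple[str, str | None], float] = {
    ("adherent_base", None): -0.40, ("good_mental_base", None): -0.25,
    ("site_setting", "urban"): 0.20, ("duration_art", "0-5"): 0.35,
    ("age_group", "15-24"): 0.30, ("employment", "construction_factory"): 0.25,
}


class CostItemModel(BaseModel):
    """Semicontinuous per-trip cost item: P(zero) + log-normal (KHR)."""

    model_config = ConfigDict(extra="forbid")
    p_zero: float = Field(ge=0.0, le=1.0)
    median: float | dict[str, float] = Field(description="median of the nonzero part, KHR")
    sigma: float = Field(gt=0.0)

    def median_for(self, arm: str) -> float:
        if isinstance(self.median, dict):
            return self.median[arm]
        return float(self.median)


DEFAULT_COST_MODEL: dict[str, dict[str, Any]] = {
    "cost_consultation":   {"p_zero": 0.97, "median": 20_000, "sigma": 0.8},
    "cost_diagnostic":     {"p_zero": 0.97, "median": 10_000, "sigma": 0.8},
    "cost_medicine":       {"p_zero": 0.96, "median": 10_000, "sigma": 0.9},
    "cost_other_medical":  {"p_zero": 0.97, "median": 10_000, "sigma": 1.0},
    # transport medians average the two waves (8000/10000 control, 6000/10000
    # intervention per trip)
    "cost_transport":      {"p_zero": 0.08, "median": {"MMD": 9_000, "CAD": 8_000}, "sigma": 0.9},
    "cost_food":           {"p_zero": 0.15, "median": 5_000, "sigma": 0.7},
    "cost_lodging":        {"p_zero": 0.97, "median": 15_000, "sigma": 0.8},
    "cost_other_nonmedical": {"p_zero": 0.90, "median": 8_000, "sigma": 0.9},
}

#: programme-level fixed cost ledger (USD, already inflation-adjusted)
DEFAULT_PROGRAMME_COSTS: list[dict[str, Any]] = [
    {"label": "CAW salary", "perspective": "health_system", "arm": "CAD",
     "payer": "programme", "amount": 235_260.00, "currency": "USD",
     "cpi_source": 1.0, "cpi_target": 1.0},
    {"label": "Training (CAD)", "perspective": "health_system", "arm": "CAD",
     "payer": "programme", "amount": 6_007.37, "currency": "USD",
     "cpi_source": 1.0, "cpi_target": 1.0},
    {"label": "CAW meetings and communication", "perspective": "health_system",
     "arm": "CAD", "payer": "programme", "amount": 9_055.03, "currency": "USD",
     "cpi_source": 1.0, "cpi_target": 1.0},
    {"label": "Training (MMD)", "perspective": "health_system", "arm": "MMD",
     "payer": "programme", "amount": 4_733.30, "currency": "USD",
     "cpi_source": 1.0, "cpi_target": 1.0},
]


class LtfuModel(BaseModel):
    """MAR dropout: logit(P(LTFU)) = calibrated intercept + coef·baseline."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)
    target_rates: dict[str, float] = Field(
        default={"MMD": 0.2967, "CAD": 0.2029},
        description="marginal LTFU probability per arm",
    )
    coefficients: dict[str, float] = Field(
        default_factory=lambda: {
            f"{col}={lvl}" if lvl is not None else col: v
            for (col, lvl), v in DEFAULT_LTFU_COEF.items()
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "LtfuModel":
        for arm, r in self.target_rates.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"LTFU target rate for {arm} outside [0,1): {r}")
        return self


class CohortSpec(BaseModel):
    """Generating parameters for a synthetic two-arm cohort."""

    model_config = ConfigDict(extra="forbid")

    n_control: int = Field(default=2049, gt=0)
    n_intervention: int = Field(default=2040, gt=0)
    baseline_prevalences: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            o: {a: t[0] for a, t in arms.items()} for o, arms in OUTCOME_TARGETS.items()
        }
    )
    endline_prevalences: dict[str, dict[str, float]] | None = Field(
        default_factory=lambda: {
            o: {a: t[1] for a, t in arms.items()} for o, arms in OUTCOME_TARGETS.items()
        },
        description="marginal endline targets; shift/interaction calibrated by "
                    "bisection when set",
    )
    endline_logit_shifts: dict[str, dict[str, float]] | None = Field(
        default=None,
        description="explicit {'outcome': {'time': s, 'interaction': g}} log-odds "
                    "shifts; overrides endline_prevalences when given",
    )
    covariate_marginals: dict[str, dict[str, tuple[float, float]]] = Field(
        default_factory=lambda: COVARIATE_MARGINALS
    )
    covariate_outcome_loadings: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            o: {f"{c}={lvl}" if lvl is not None else c: v for (c, lvl), v in m.items()}
            for o, m in DEFAULT_LOADINGS.items()
        }
    )
    random_intercept_sd: float = Field(default=0.8, ge=0.0)
    comorbidity_rates: dict[str, float] = Field(
        default={"MMD": 0.1718, "CAD": 0.2490}
    )
    income_median_usd: dict[str, float] = Field(default={"MMD": 216.0, "CAD": 192.0})
    income_sigma: float = Field(default=0.7, gt=0)
    waiting_median_hours: dict[str, float] = Field(default={"MMD": 1.5, "CAD": 2.0})
    waiting_sigma: float = Field(default=0.5, gt=0)
    caregiver_rates: dict[str, tuple[float, float]] = Field(
        default={"MMD": (0.0249, 0.0590), "CAD": (0.0456, 0.0560)},
        description="(baseline, endline) probability a caregiver came along",
    )
    ltfu_model: LtfuModel = Field(default_factory=LtfuModel)
    cost_model: dict[str, CostItemModel] = Field(
        default_factory=lambda: {k: CostItemModel(**v) for k, v in DEFAULT_COST_MODEL.items()}
    )
    visit_means: dict[str, float] = Field(default={"MMD": 5.25, "CAD": 4.72})
    nonadherent_item_probs: list[float] = Field(
        default=[0.55, 0.35, 0.20, 0.40, 0.15],
        description="P(item='yes') given non-adherent, per primary item",
    )
    caw_count: int = Field(default=82, gt=0)
    programme_costs: list[dict[str, Any]] = Field(
        default_factory=lambda: [dict(r) for r in DEFAULT_PROGRAMME_COSTS]
    )
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _validate(self) -> "CohortSpec":
        problems = []
        for o, arms in self.baseline_prevalences.items():
            for a, p in arms.items():
                if not 0.0 < p < 1.0:
                    problems.append(f"baseline prevalence {o}/{a}={p} outside (0,1)")
        if self.endline_prevalences is not None:
            for o, arms in self.endline_prevalences.items():
                for a, p in arms.items():
                    if not 0.0 < p < 1.0:
                        problems.append(f"endline prevalence {o}/{a}={p} outside (0,1)")
        for a, mu in self.visit_means.items():
            if mu <= 0:
                problems.append(f"visit mean for {a} must be > 0")
        if problems:
            raise ValueError("; ".join(problems))
        return self


@dataclasses.dataclass
class SyntheticCohort:
    """A generated cohort: long participant table + generating truth."""

    records: pd.DataFrame
    truth: dict[str, Any]
    ledger: pd.DataFrame

    @property
    def wide(self) -> pd.DataFrame:
        return schema.to_wide(self.records)


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------

def child_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Independent per-stage generators from one master seed.

    Child k of ``SeedSequence(seed)`` (spawned in the order of ``names``)
    drives stage ``names[k]``, so each stage is reproducible in isolation.
    """
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _coef_terms(coefficients: Mapping[str, float], df: pd.DataFrame) -> np.ndarray:
    """Linear predictor from ``"column=level"`` / ``"column"`` coefficient keys.

    Numeric keys use the column standardized in-sample; ``income_log`` is
    resolved to standardized log income.
    """
    lp = np.zeros(len(df))
    for key, coef in coefficients.items():
        if "=" in key:
            col, lvl = key.split("=", 1)
            lp += coef * (df[col].astype(str) == lvl).to_numpy(float)
        else:
            col = key
            if col == "income_log":
                x = np.log(df["income_usd"].to_numpy(float))
            else:
                x = df[col].to_numpy(float)
            sd = x.std()
            lp += coef * ((x - x.mean()) / sd if sd > 0 else 0.0)
    return lp


def calibrate_intercept(lp: np.ndarray, target: float,
                        lo: float = -20.0, hi: float = 20.0,
                        tol: float = 1e-10) -> float:
    """Bisection for c with mean(expit(c + lp)) == target."""
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target probability outside [0,1]: {target}")
    if target == 0.0:
        return -np.inf
    f = lambda c: expit(c + lp).mean() - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"target rate {target} unattainable within intercept bounds")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _draw_categorical(rng: np.random.Generator, levels: list[str],
                      probs: np.ndarray, n: int) -> np.ndarray:
    probs = np.asarray(probs, float)
    probs = probs / probs.sum()
    return rng.choice(levels, size=n, p=probs)


def _truncnorm(rng: np.random.Generator, n: int, loc: float, scale: float,
               lower: float = -np.inf, upper: float = np.inf) -> np.ndarray:
    a, b = (lower - loc) / scale, (upper - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def _scores_from_outcome(rng: np.random.Generator, good: np.ndarray,
                         threshold: float, spread: float = 5.0) -> np.ndarray:
    """Continuous SF-12 component score consistent with its dichotomization."""
    n = len(good)
    out = np.empty(n)
    g = good.astype(bool)
    out[g] = _truncnorm(rng, int(g.sum()), threshold + 4.0, spread, lower=threshold)
    out[~g] = _truncnorm(rng, int((~g).sum()), threshold - 6.0, spread,
                         upper=np.nextafter(threshold, -np.inf))
    return np.round(out, 2)


def _draw_costs(rng: np.random.Generator, item: CostItemModel, arm: str,
                n: int) -> np.ndarray:
    zero = rng.random(n) < item.p_zero
    mu = np.log(item.median_for(arm))
    vals = np.exp(rng.normal(mu, item.sigma, size=n))
    vals = np.round(vals / 100.0) * 100.0   # costs reported to the nearest 100 Riel
    vals[zero] = 0.0
    return vals


def _truncated_poisson(rng: np.random.Generator, mean: float, n: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1 (every participant visits at least once)."""
    out = rng.poisson(mean, size=n)
    while (mask := out == 0).any():
        out[mask] = rng.poisson(mean, size=int(mask.sum()))
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

_STREAMS = ["covariates", "outcomes", "scores", "items", "costs", "visits",
            "caregiver", "ltfu"]


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Generate a complete (pre-dropout) cohort from ``spec``.

    Both waves are fully observed; apply :func:`apply_mar_ltfu` to impose
    missing-at-random dropout afterwards.
    """
    spec = spec or CohortSpec()
    rngs = child_rngs(spec.seed, _STREAMS)
    n = {"MMD": spec.n_control, "CAD": spec.n_intervention}
    truth: dict[str, Any] = {"spec": spec.model_dump(), "intercepts": {},
                             "time_shifts": {}, "interactions": {}}

    # --- covariates ---
    rng = rngs["covariates"]
    frames = []
    for j, arm in enumerate(schema.ARMS):
        df = pd.DataFrame({"arm": arm}, index=range(n[arm]))
        for cov, levels in spec.covariate_marginals.items():
            names = list(levels)
            probs = np.array([levels[l][j] for l in names])
            df[cov] = _draw_categorical(rng, names, probs, n[arm])
        df["comorbidity"] = (rng.random(n[arm]) < spec.comorbidity_rates[arm]).astype(int)
        df["income_usd"] = np.round(np.exp(rng.normal(
            np.log(spec.income_median_usd[arm]), spec.income_sigma, n[arm])), 2)
        df["waiting_hours"] = np.round(np.exp(rng.normal(
            np.log(spec.waiting_median_hours[arm]), spec.waiting_sigma, n[arm])), 2)
        frames.append(df)
    cov_df = pd.concat(frames, ignore_index=True)
    cov_df.insert(0, "participant_id", np.arange(1, len(cov_df) + 1))

    # --- latent outcomes ---
    rng = rngs["outcomes"]
    outcome_latent: dict[str, dict[str, np.ndarray]] = {}
    for outcome in schema.OUTCOMES:
        loadings = spec.covariate_outcome_loadings.get(outcome, {})
        u = rng.normal(0.0, spec.random_intercept_sd, len(cov_df))
        lp_cov = _coef_terms(loadings, cov_df) + u
        base = np.empty(len(cov_df))
        end_logit = np.empty(len(cov_df))
        for arm in schema.ARMS:
            mask = (cov_df["arm"] == arm).to_numpy()
            c = calibrate_intercept(lp_cov[mask],
                                    spec.baseline_prevalences[outcome][arm])
            truth["intercepts"].setdefault(outcome, {})[arm] = c
            base[mask] = c + lp_cov[mask]
        y_base = (rng.random(len(cov_df)) < expit(base)).astype(int)

        if spec.endline_logit_shifts is not None:
            shifts = spec.endline_logit_shifts[outcome]
            s, g = float(shifts["time"]), float(shifts["interaction"])
        else:
            tgt = spec.endline_prevalences[outcome]
            ctl = (cov_df["arm"] == "MMD").to_numpy()
            s = calibrate_intercept(base[ctl], tgt["MMD"])
            intv = ~ctl
            g = calibrate_intercept(base[intv] + s, tgt["CAD"])
        truth["time_shifts"][outcome] = s
        truth["interactions"][outcome] = g
        is_cad = (cov_df["arm"] == "CAD").to_numpy(float)
        end_logit = base + s + g * is_cad
        y_end = (rng.random(len(cov_df)) < expit(end_logit)).astype(int)
        outcome_latent[outcome] = {"base": y_base, "end": y_end}

    # --- SF-12 component scores consistent with the binary outcomes ---
    rng = rngs["scores"]
    scores = {
        ("pcs", "base"): _scores_from_outcome(rng, outcome_latent["good_physical"]["base"], 50.0),
        ("pcs", "end"): _scores_from_outcome(rng, outcome_latent["good_physical"]["end"], 50.0),
        ("mcs", "base"): _scores_from_outcome(rng, outcome_latent["good_mental"]["base"], 42.0),
        ("mcs", "end"): _scores_from_outcome(rng, outcome_latent["good_mental"]["end"], 42.0),
    }

    # --- adherence items consistent with the adherent flag ---
    rng = rngs["items"]
    items: dict[tuple[str, str], np.ndarray] = {}
    p_items = np.asarray(spec.nonadherent_item_probs, float)
    for wave in ("base", "end"):
        adherent = outcome_latent["adherent"][wave].astype(bool)
        draws = rng.random((len(cov_df), 5)) < p_items
        none_yes = ~draws.any(axis=1)
        draws[none_yes, 0] = True          # non-adherent => at least one "yes"
        for k, item in enumerate(schema.ADHERENCE_ITEMS):
            col = np.where(adherent, "no", np.where(draws[:, k], "yes", "no"))
            items[(item, wave)] = col

    # --- per-trip costs, visits, caregiver ---
    rng = rngs["costs"]
    costs: dict[tuple[str, str], np.ndarray] = {}
    for wave in ("base", "end"):
        for name, model in spec.cost_model.items():
            vals = np.empty(len(cov_df))
            for arm in schema.ARMS:
                mask = (cov_df["arm"] == arm).to_numpy()
                vals[mask] = _draw_costs(rng, model, arm, int(mask.sum()))
            costs[(name, wave)] = vals

    rng = rngs["visits"]
    visits = np.empty(len(cov_df), dtype=int)
    for arm in schema.ARMS:
        mask = (cov_df["arm"] == arm).to_numpy()
        visits[mask] = _truncated_poisson(rng, spec.visit_means[arm], int(mask.sum()))

    rng = rngs["caregiver"]
    caregiver = {}
    for wi, wave in enumerate(("base", "end")):
        p = np.empty(len(cov_df))
        for arm in schema.ARMS:
            mask = (cov_df["arm"] == arm).to_numpy()
            p[mask] = spec.caregiver_rates[arm][wi]
        caregiver[wave] = (rng.random(len(cov_df)) < p).astype(int)

    # --- assemble long table ---
    rows = []
    for wave, suffix in (("baseline", "base"), ("endline", "end")):
        df = cov_df.copy()
        df.insert(2, "wave", wave)
        for item in schema.ADHERENCE_ITEMS:
            df[item] = items[(item, suffix)]
        df["pcs"] = scores[("pcs", suffix)]
        df["mcs"] = scores[("mcs", suffix)]
        for name in schema.COST_ITEMS:
            df[name] = costs[(name, suffix)]
        df["caregiver"] = caregiver[suffix]
        df["visits"] = visits if wave == "endline" else np.nan
        df["ltfu"] = 0
        rows.append(df)
    long_df = pd.concat(rows, ignore_index=True)
    long_df = derive_outcomes(long_df)
    long_df = long_df[[c for c in schema.LONG_COLUMNS if c in long_df.columns]]
    long_df = long_df.sort_values(["participant_id", "wave"], ignore_index=True)

    ledger = pd.DataFrame(spec.programme_costs)
    return SyntheticCohort(records=long_df, truth=truth, ledger=ledger)


def apply_mar_ltfu(cohort: SyntheticCohort,
                   ltfu_model: LtfuModel | None = None,
                   rng: np.random.Generator | None = None) -> SyntheticCohort:
    """Impose missing-at-random dropout: delete endline rows for selected
    participants.

    Selection probability depends only on baseline (observed) variables;
    per-arm intercepts are calibrated by bisection so the realized marginal
    LTFU rates match the targets in expectation.
    """
    spec = CohortSpec(**cohort.truth["spec"])
    model = ltfu_model or spec.ltfu_model
    if rng is None:
        rng = child_rngs(spec.seed, _STREAMS)["ltfu"]

    base = cohort.records[cohort.records["wave"] == "baseline"].reset_index(drop=True)
    feats = base.copy()
    for out in schema.OUTCOMES:
        feats[f"{out}_base"] = base[out].to_numpy(float)
    lp = _coef_terms(model.coefficients, feats)
    prob = np.empty(len(base))
    intercepts = {}
    for arm in schema.ARMS:
        mask = (base["arm"] == arm).to_numpy()
        target = model.target_rates[arm]
        if target == 0.0:
            prob[mask] = 0.0
            intercepts[arm] = -np.inf
            continue
        c = calibrate_intercept(lp[mask], target)
        intercepts[arm] = c
        prob[mask] = expit(c + lp[mask])
    dropped = rng.random(len(base)) < prob
    ltfu_ids = set(base.loc[dropped, "participant_id"])

    records = cohort.records.copy()
    records["ltfu"] = records["participant_id"].isin(ltfu_ids).astype(int)
    records = records[~((records["wave"] == "endline")
                        & records["participant_id"].isin(ltfu_ids))]
    records = records.reset_index(drop=True)
    truth = dict(cohort.truth)
    truth["ltfu"] = {"intercepts": intercepts,
                     "coefficients": dict(model.coefficients),
                     "target_rates": dict(model.target_rates)}
    return SyntheticCohort(records=records, truth=truth, ledger=cohort.ledger)


def export_cohort(cohort: SyntheticCohort, path: str | Path) -> dict[str, Path]:
    """Write ``participants.csv``, ``programme_costs.csv`` and ``truth.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "participants": path / "participants.csv",
        "ledger": path / "programme_costs.csv",
        "truth": path / "truth.json",
    }
    cohort.records.to_csv(files["participants"], index=False)
    cohort.ledger.to_csv(files["ledger"], index=False)
    files["truth"].write_text(json.dumps(cohort.truth, indent=1, default=float))
    return files


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", "arm", "wave") if c not in df.columns]
    if missing:
        raise ValueError(f"participant table missing columns: {missing}")
    return df


def read_ledger(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in schema.LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cost ledger missing columns: {missing}")
    return df


def load_cohort(path: str | Path) -> SyntheticCohort:
    """Round-trip partner of :func:`export_cohort`."""
    path = Path(path)
    records = read_participants(path / "participants.csv")
    ledger = read_ledger(path / "programme_costs.csv")
    truth = json.loads((path / "truth.json").read_text())
    return SyntheticCohort(records=records, truth=truth, ledger=ledger)
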
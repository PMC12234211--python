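"""Outcome classification and arm-comparison descriptive statistics.

Three binary analysis outcomes are derived from raw instrument responses:

* **ART adherence** — adherent iff the participant answered "no" to all
  five primary adherence questions (missed doses in the past two months,
  difficulty remembering, stopping when feeling better, missed doses in
  the past four days, stopping when feeling worse).
* **Good physical health** — SF-12 Physical Component Score (PCS) >= 50.
* **Good mental health** — SF-12 Mental Component Score (MCS) >= 42.

Thresholds are inclusive: the score tables define the analysis categories
as "PCS >= 50" / "MCS >= 42", and the boundary convention follows them.

:func:`describe_arms` compares a variable between the two arms with the
conventional test-dispatch rules: Student's t-test when both arms pass a
Shapiro-Wilk normality check (else Mann-Whitney U) for continuous
variables; Pearson chi-square, or Fisher's exact when any *expected* cell
count is below five, for categorical ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import schema

PCS_THRESHOLD = 50.0
MCS_THRESHOLD = 42.0

_YES = {"yes", "y", "1", "true"}
_NO = {"no", "n", "0", "false"}


class ClassificationError(ValueError):
    """Raised when a record cannot be classified (missing or invalid item)."""


def normalize_yes_no(value: Any) -> str | None:
    """Map a yes/no item to ``"yes"``/``"no"`` or ``None`` when missing.

    Accepts case-insensitive strings, 0/1 integers and booleans.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return "yes" if value else "no"
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return "yes" if value == 1 else "no"
    text = str(value).strip().lower()
    if text in _YES:
        return "yes"
    if text in _NO:
        return "no"
    if text == "":
        return None
    raise ClassificationError(f"unrecognized yes/no value: {value!r}")


@dataclass(frozen=True)
class AdherenceItems:
    """Responses to the five primary adherence questions."""

    missed_2mo: Any
    hard_to_remember: Any
    stop_when_better: Any
    missed_4days: Any
    stop_when_worse: Any

    def normalized(self) -> dict[str, str | None]:
        return {f: normalize_yes_no(getattr(self, f)) for f in schema.ADHERENCE_ITEMS}


def classify_adherence(items: AdherenceItems | Mapping[str, Any]) -> bool:
    """True iff every primary item is "no". Raises on any missing item."""
    if not isinstance(items, AdherenceItems):
        items = AdherenceItems(**{f: items[f] for f in schema.ADHERENCE_ITEMS})
    norm = items.normalized()
    missing = [f for f, v in norm.items() if v is None]
    if missing:
        raise ClassificationError(f"missing adherence item(s): {', '.join(missing)}")
    return all(v == "no" for v in norm.values())


def _classify_score(value: float, threshold: float, label: str) -> bool:
    value = float(value)
    if not math.isfinite(value):
        raise ClassificationError(f"non-finite {label} score: {value!r}")
    return value >= threshold


def classify_physical(pcs: float) -> bool:
    """Good physical health: PCS >= 50 (inclusive)."""
    return _classify_score(pcs, PCS_THRESHOLD, "PCS")


def classify_mental(mcs: float) -> bool:
    """Good mental health: MCS >= 42 (inclusive)."""
    return _classify_score(mcs, MCS_THRESHOLD, "MCS")


def derive_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``adherent``, ``good_physical``, ``good_mental`` columns.

    Rows where the required inputs are missing get NaN (they are the
    imputation targets downstream, not classification errors).
    """
    out = df.copy()
    items = df[schema.ADHERENCE_ITEMS].map(normalize_yes_no)
    complete = items.notna().all(axis=1)
    adherent = pd.Series(np.nan, index=df.index, dtype=float)
    adherent[complete] = (items[complete] == "no").all(axis=1).astype(float)
    out["adherent"] = adherent
    for col, score, thr in (
        ("good_physical", "pcs", PCS_THRESHOLD),
        ("good_mental", "mcs", MCS_THRESHOLD),
    ):
        vals = pd.to_numeric(df[score], errors="coerce")
        derived = pd.Series(np.nan, index=df.index, dtype=float)
        derived[vals.notna()] = (vals[vals.notna()] >= thr).astype(float)
        out[col] = derived
    return out


@dataclass
class ArmComparison:
    """Result of a two-arm comparison for one variable."""

    variable: str
    kind: str                      # "continuous" | "categorical"
    test: str                      # name of the dispatched test
    statistic: float
    pvalue: float
    summaries: dict[str, Any]      # per-arm summaries

    def as_row(self) -> dict[str, Any]:
        row = {"variable": self.variable, "test": self.test,
               "statistic": self.statistic, "p_value": self.pvalue}
        for arm, summ in self.summaries.items():
            row[arm] = summ
        return row


def _continuous_comparison(x: np.ndarray, y: np.ndarray, variable: str,
                           shapiro_alpha: float = 0.05) -> ArmComparison:
    # Shapiro-Wilk is capped at 5000 observations by scipy; subsample
    # deterministically above that (test power is ample either way).
    def _normal(v: np.ndarray) -> bool:
        if len(v) > 5000:
            v = v[:: len(v) // 5000 + 1]
        if np.ptp(v) == 0:
            return False
        return stats.shapiro(v).pvalue > shapiro_alpha

    if _normal(x) and _normal(y):
        res = stats.ttest_ind(x, y)
        test = "t-test"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        test = "mann-whitney"
    summaries = {}
    for arm, v in (("MMD", x), ("CAD", y)):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        summaries[arm] = f"{med:g} ({q3 - q1:g})"
    return ArmComparison(variable, "continuous", test,
                         float(res.statistic), float(res.pvalue), summaries)


def _categorical_comparison(table: pd.DataFrame, variable: str) -> ArmComparison:
    counts = table.to_numpy()
    if counts.shape[1] < 2 or (counts.sum(axis=0) == 0).any():
        raise ValueError(f"variable {variable!r}: needs >=2 observed levels per arm")
    if counts.shape[0] < 2:
        raise ValueError(f"variable {variable!r}: single-level categorical")
    chi2, p, _, expected = stats.chi2_contingency(counts.T, correction=False)
    test, stat = "chi-square", float(chi2)
    if (expected < 5).any():
        if counts.shape[0] == 2:
            stat, p = stats.fisher_exact(counts.T)
            test = "fisher"
        else:
            test = "chi-square (low expected counts)"
    totals = counts.sum(axis=0)
    summaries = {
        arm: "; ".join(
            f"{lvl}: {int(n)} ({100 * n / tot:.2f})"
            for lvl, n in zip(table.index, counts[:, j])
        )
        for j, (arm, tot) in enumerate(zip(table.columns, totals))
    }
    return ArmComparison(variable, "categorical", test, stat, float(p), summaries)


def describe_arms(records: pd.DataFrame, variable: str,
                  kind: str | None = None) -> ArmComparison:
    """Compare ``variable`` between arms with the dispatched test.

    Parameters
    ----------
    records : long or wide participant table with an ``arm`` column.
    variable : column to compare.
    kind : force ``"continuous"`` or ``"categorical"``; inferred from the
        dtype when omitted.
    """
    if variable not in records.columns:
        raise KeyError(f"variable {variable!r} not in table")
    sub = records[["arm", variable]].dropna()
    if sub.empty:
        raise ValueError(f"variable {variable!r} is all-missing")
    arms = [a for a in schema.ARMS if (sub["arm"] == a).any()]
    if len(arms) < 2:
        raise ValueError("both arms must be present")
    if kind is None:
        kind = ("continuous"
                if pd.api.types.is_numeric_dtype(sub[variable])
                and sub[variable].nunique() > 10 else "categorical")
    if kind == "continuous":
        x = sub.loc[sub["arm"] == "MMD", variable].to_numpy(float)
        y = sub.loc[sub["arm"] == "CAD", variable].to_numpy(float)
        if min(len(x), len(y)) < 2:
            raise ValueError("need >=2 observations per arm")
        return _continuous_comparison(x, y, variable)
    table = pd.crosstab(sub[variable], sub["arm"])[list(schema.ARMS)]
    return _categorical_comparison(table, variable)


def summary_table(records: pd.DataFrame, variables: list[tuple[str, str]],
                  ) -> pd.DataFrame:
    """Arm-comparison summary for several variables (one row each)."""
    rows = [describe_arms(records, var, kind).as_row() for var, kind in variables]
    return pd.DataFrame(rows)
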
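"""Incremental cost-effectiveness ratios and incremental net benefits.

Given the incremental mean cost per participant dC (intervention minus
control, USD) and the incremental effect dE (the difference-in-differences
of predicted outcome probabilities):

* ICER = dC / dE in the north-east quadrant (dC > 0, dE > 0): USD per
  additional participant achieving the outcome.  A cheaper-and-better
  intervention (dC < 0, dE > 0) *dominates*; costlier-and-worse
  (dC > 0, dE < 0) is *dominated*; dE = 0 leaves the ratio undefined.
* INB at a cost-effectiveness threshold: INB = CET x dE - dC; the
  intervention is cost-effective at that threshold iff INB >= 0.

Default thresholds: one-time GDP per capita (USD 1799) and an
opportunity-cost estimate (USD 304), both config-overridable.
"""

from __future__ import annotations

import dataclasses
import math

from pydantic import BaseModel, ConfigDict, Field

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"
INDETERMINATE = "indeterminate"


class ThresholdSet(BaseModel):
    """Cost-effectiveness thresholds, USD per unit of effect."""

    model_config = ConfigDict(extra="forbid")
    cet_gdp: float = Field(default=1799.0, gt=0.0,
                           description="one-time GDP per capita")
    cet_opportunity: float = Field(default=304.0, gt=0.0,
                                   description="opportunity-cost estimate")

    def as_dict(self) -> dict[str, float]:
        return {"gdp_per_capita": self.cet_gdp,
                "opportunity_cost": self.cet_opportunity}


@dataclasses.dataclass
class CeaResult:
    """ICER and per-threshold INB/verdict for one outcome and perspective."""

    outcome: str
    perspective: str
    delta_c: float
    delta_e: float
    icer: float | str
    inb_per_cet: dict[str, float]
    verdict_per_cet: dict[str, str]


def icer(delta_c: float, delta_e: float) -> float | str:
    """ICER or a dominance code; never divides by a zero effect."""
    if not (math.isfinite(delta_c) and math.isfinite(delta_e)):
        raise ValueError("non-finite incremental cost or effect")
    if delta_e == 0.0:
        return UNDEFINED if delta_c != 0.0 else INDETERMINATE
    if delta_e > 0.0:
        return DOMINANT if delta_c < 0.0 else delta_c / delta_e
    return DOMINATED if delta_c > 0.0 else delta_c / delta_e


def inb(cet: float, delta_c: float, delta_e: float) -> float:
    """Incremental net benefit: CET x dE - dC."""
    if cet <= 0:
        raise ValueError("CET must be positive")
    if not (math.isfinite(delta_c) and math.isfinite(delta_e)):
        raise ValueError("non-finite incremental cost or effect")
    return cet * delta_e - delta_c


def verdict(icer_value: float | str, inb_value: float) -> str:
    """Classification at one threshold: cost-effective iff INB >= 0."""
    if icer_value == DOMINANT:
        return "cost_effective"
    if icer_value == DOMINATED:
        return "not_cost_effective"
    if icer_value == INDETERMINATE:
        return INDETERMINATE
    return "cost_effective" if inb_value >= 0.0 else "not_cost_effective"


def evaluate(delta_c: float, delta_e: float, thresholds: ThresholdSet | None = None,
             outcome: str = "", perspective: str = "") -> CeaResult:
    """Full decision for one (outcome, perspective) pair."""
    thresholds = thresholds or ThresholdSet()
    ratio = icer(delta_c, delta_e)
    inbs, verdicts = {}, {}
    for label, cet in thresholds.as_dict().items():
        value = inb(cet, delta_c, delta_e)
        inbs[label] = value
        verdicts[label] = verdict(ratio, value)
    return CeaResult(outcome=outcome, perspective=perspective,
                     delta_c=delta_c, delta_e=delta_e, icer=ratio,
                     inb_per_cet=inbs, verdict_per_cet=verdicts)
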
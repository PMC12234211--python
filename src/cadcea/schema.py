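"""Column dictionary and reshaping helpers for the participant table.

The participant table is long: one row per participant per wave
(``baseline``, ``endline``).  Socio-demographic covariates are constant
across waves; endline rows are absent for participants lost to follow-up
(LTFU).  Costs are itemized per last clinic trip, in Cambodian Riel (KHR);
``visits`` is the number of facility trips over the study period and is
recorded on the endline row only.
"""

from __future__ import annotations

import pandas as pd

ARMS = ("MMD", "CAD")  # control, intervention
WAVES = ("baseline", "endline")

#: socio-demographic covariates (categorical unless noted)
SOCIODEMO_CATEGORICAL = [
    "site_setting",     # urban / rural
    "age_group",        # 15-24 / 25-49 / 50-64 / 65+
    "gender",           # male / female / lgbtqia
    "marital",          # single / married
    "education",        # none / primary / secondary / tertiary / university
    "employment",       # unemployed / farmer_fisherman / driver / self_employed
                        # / government / private / construction_factory / other
    "family_size",      # alone / small / medium / large
    "children",         # none / one / two / three_plus
    "duration_hiv",     # 1-5 / 6-10 / 11-15 / 16-20 / 21+
    "duration_art",     # 0-5 / 6-10 / 11-15 / 16-20 / 21+
    "transport_mode",   # foot_bicycle / motorised / boat_other
    "travel_time",      # short / medium / long / very_long
]
SOCIODEMO_CONTINUOUS = ["waiting_hours", "income_usd"]
SOCIODEMO_BINARY = ["comorbidity"]
SOCIODEMO = SOCIODEMO_CATEGORICAL + SOCIODEMO_CONTINUOUS + SOCIODEMO_BINARY

#: five primary adherence items (yes/no); adherent iff all "no"
ADHERENCE_ITEMS = [
    "missed_2mo",
    "hard_to_remember",
    "stop_when_better",
    "missed_4days",
    "stop_when_worse",
]

#: out-of-pocket cost items per last clinic trip, KHR
COST_ITEMS = [
    "cost_consultation",
    "cost_diagnostic",
    "cost_medicine",
    "cost_other_medical",
    "cost_transport",
    "cost_food",
    "cost_lodging",
    "cost_other_nonmedical",
]
MEDICAL_COST_ITEMS = COST_ITEMS[:4]
NONMEDICAL_COST_ITEMS = COST_ITEMS[4:]

#: derived binary outcomes
OUTCOMES = ["adherent", "good_physical", "good_mental"]
SCORE_COLS = ["pcs", "mcs"]

#: per-wave measured variables (besides covariates)
WAVE_COLS = ADHERENCE_ITEMS + SCORE_COLS + OUTCOMES + COST_ITEMS + ["caregiver"]

LONG_COLUMNS = (
    ["participant_id", "arm", "wave"]
    + SOCIODEMO
    + ADHERENCE_ITEMS
    + SCORE_COLS
    + OUTCOMES
    + COST_ITEMS
    + ["caregiver", "visits", "ltfu"]
)

LEDGER_COLUMNS = [
    "label", "perspective", "arm", "payer", "amount", "currency",
    "cpi_source", "cpi_target",
]


def to_wide(long_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long participant table to one row per participant.

    Wave-varying columns get ``_base`` / ``_end`` suffixes; endline columns
    are NaN for LTFU participants (their endline rows are absent).
    """
    static = ["arm"] + SOCIODEMO + ["ltfu"]
    base = long_df[long_df["wave"] == "baseline"].set_index("participant_id")
    end = long_df[long_df["wave"] == "endline"].set_index("participant_id")
    wave_cols = [c for c in WAVE_COLS if c in long_df.columns]
    wide = base[static + wave_cols].rename(
        columns={c: f"{c}_base" for c in wave_cols}
    )
    wide = wide.join(end[wave_cols].rename(columns={c: f"{c}_end" for c in wave_cols}))
    if "visits" in long_df.columns:
        wide = wide.join(end[["visits"]])
    return wide.reset_index()


def to_long(wide_df: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_wide`; emits endline rows for every participant
    (so an imputed wide table reshapes to a complete long table)."""
    static = ["participant_id", "arm"] + [c for c in SOCIODEMO if c in wide_df]
    frames = []
    for wave, suffix in (("baseline", "_base"), ("endline", "_end")):
        cols = {f"{c}{suffix}": c for c in WAVE_COLS if f"{c}{suffix}" in wide_df}
        part = wide_df[static + list(cols)].rename(columns=cols)
        part.insert(2, "wave", wave)
        if wave == "endline" and "visits" in wide_df:
            part["visits"] = wide_df["visits"].to_numpy()
        if "ltfu" in wide_df:
            part["ltfu"] = wide_df["ltfu"].to_numpy()
        frames.append(part)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "wave"], ignore_index=True)
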
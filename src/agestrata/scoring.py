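"""Deterministic recoding of raw survey answers into analysis variables.

Raw respondent records (demographics, ten binary social-activity items,
three family-participation aspects, three health measures, three
socioeconomic measures) are mapped onto the coded variables the analysis
uses: a 0-10 social-participation count, a 0/1/2 family-participation
category, ordinal 0/1/2 recodes of self-rated health, depression (CES-D)
and functional impairment (IADL), and ordinal socioeconomic codes for
hukou, education and income.

All coding operations are pure functions of their inputs; a
:class:`CodingConfig` carries the boundary conventions that the source
questionnaire leaves ambiguous (CES-D cut between the "tendency" and
"high-risk" bands, half-open income brackets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CodingError",
    "CodingConfig",
    "HOUSEWORK_LEVELS",
    "SRH_LEVELS",
    "EDU_LEVELS",
    "N_SP_ITEMS",
    "SP_ITEM_NAMES",
    "score_social_participation",
    "code_family_participation",
    "code_health",
    "code_ses",
    "standardize",
    "code_records",
]


class CodingError(ValueError):
    """Raised when a raw answer violates the questionnaire's value domain."""


#: Housework-help frequency levels, least to most frequent. Only the
#: distinction "almost_never" vs anything else enters the coding.
HOUSEWORK_LEVELS = (
    "almost_never",
    "few_times_year",
    "at_least_monthly",
    "at_least_weekly",
    "almost_every_day",
)

#: Self-rated health levels, best to worst.
SRH_LEVELS = (
    "very_healthy",
    "quite_healthy",
    "fair",
    "quite_unhealthy",
    "very_unhealthy",
)

#: Highest educational attainment, lowest to highest.
EDU_LEVELS = ("illiterate", "elementary", "middle", "high_or_above")

N_SP_ITEMS = 10

#: The ten social activities behind the 0-10 participation count.
SP_ITEM_NAMES = (
    "voting",
    "religious_gatherings",
    "senior_university",
    "tv_radio_reading",
    "singing_instrument",
    "mahjong_chess_cards",
    "square_dancing",
    "sanitation_volunteering",
    "skilled_volunteering",
    "exercise",
)


@dataclass(frozen=True)
class CodingConfig:
    """Boundary conventions for the ordinal recodes.

    Parameters
    ----------
    cesd_cuts : (int, int)
        Lower edges of the middle and top CES-D bands. The default
        ``(10, 18)`` codes totals <= 9 as 0 (no depression), 10-17 as 1
        (depressive tendency) and 18-27 as 2 (high risk), resolving the
        questionnaire's overlapping band edges into a partition.
    income_cuts : (float, float, float)
        Annual-income bracket edges in RMB; brackets are half-open
        ``[lo, hi)`` with the top bracket closed above, so 2300 falls in
        the lower-middle bracket and 10,000 in the high bracket.
    """

    cesd_cuts: tuple[int, int] = (10, 18)
    income_cuts: tuple[float, float, float] = (2300.0, 5000.0, 10000.0)


def score_social_participation(sp_items: Sequence[int]) -> int:
    """Sum the ten binary activity indicators into the 0-10 score."""
    items = list(sp_items)
    if len(items) != N_SP_ITEMS:
        raise CodingError(
            f"expected {N_SP_ITEMS} social-participation items, got {len(items)}"
        )
    for v in items:
        if v not in (0, 1):
            raise CodingError(f"social-participation items must be 0/1, got {v!r}")
    return int(sum(items))


def code_family_participation(
    parent_care_hours: float,
    grandchild_care_any: bool | int,
    housework_freq: str,
) -> int:
    """Code family participation as 0 (none), 1 (one aspect), 2 (two or more).

    An aspect counts as active when: weekly parent-care hours exceed 0;
    the respondent has ever cared for grandchildren; housework help occurs
    at any frequency other than "almost_never".
    """
    if parent_care_hours < 0:
        raise CodingError(f"parent care hours must be >= 0, got {parent_care_hours}")
    if housework_freq not in HOUSEWORK_LEVELS:
        raise CodingError(f"unknown housework frequency {housework_freq!r}")
    n_active = (
        int(parent_care_hours > 0)
        + int(bool(grandchild_care_any))
        + int(housework_freq != "almost_never")
    )
    return min(2, n_active)


def code_health(
    self_rated_health_raw: str,
    cesd_total: int,
    iadl_score: int,
    config: CodingConfig = CodingConfig(),
) -> tuple[int, int, int]:
    """Recode the three health measures to ordinal 0/1/2 (higher = worse).

    Returns ``(srh_code, dep_code, iadl_code)``: self-rated health
    (good / fair / poor), CES-D depression band, and IADL impairment band
    (0 = fully functional, 1-5 = impaired, 6-10 = significantly impaired).
    """
    if self_rated_health_raw not in SRH_LEVELS:
        raise CodingError(f"unknown self-rated health level {self_rated_health_raw!r}")
    if not 0 <= cesd_total <= 27:
        raise CodingError(f"CES-D total must be in [0, 27], got {cesd_total}")
    if not 0 <= iadl_score <= 10:
        raise CodingError(f"IADL score must be in [0, 10], got {iadl_score}")

    srh_idx = SRH_LEVELS.index(self_rated_health_raw)
    srh_code = 0 if srh_idx <= 1 else (1 if srh_idx == 2 else 2)

    lo, hi = config.cesd_cuts
    dep_code = 0 if cesd_total < lo else (1 if cesd_total < hi else 2)

    iadl_code = 0 if iadl_score == 0 else (1 if iadl_score <= 5 else 2)
    return srh_code, dep_code, iadl_code


def code_ses(
    hukou: str,
    education_raw: str,
    income_rmb: float | None,
    config: CodingConfig = CodingConfig(),
) -> tuple[int, int, int | None]:
    """Recode household registration, education and income.

    Returns ``(hukou_code, edu_code, income_code)`` with hukou 1 =
    agricultural / 2 = nonagricultural, education 1-4 from illiterate to
    high school or above, and income 1-4 over half-open RMB brackets.
    Missing income propagates as ``None``.
    """
    if hukou == "agricultural":
        hukou_code = 1
    elif hukou == "nonagricultural":
        hukou_code = 2
    else:
        raise CodingError(f"unknown hukou category {hukou!r}")

    if education_raw not in EDU_LEVELS:
        raise CodingError(f"unknown education level {education_raw!r}")
    edu_code = EDU_LEVELS.index(education_raw) + 1

    if income_rmb is None or (isinstance(income_rmb, float) and np.isnan(income_rmb)):
        income_code: int | None = None
    else:
        if income_rmb < 0:
            raise CodingError(f"income must be >= 0, got {income_rmb}")
        c1, c2, c3 = config.income_cuts
        if income_rmb < c1:
            income_code = 1
        elif income_rmb < c2:
            income_code = 2
        elif income_rmb < c3:
            income_code = 3
        else:
            income_code = 4
    return hukou_code, edu_code, income_code


def standardize(scores: Sequence[float]) -> np.ndarray:
    """z-score a vector of participation scores (sample SD, ddof = 1).

    Raises :class:`CodingError` for fewer than two observations or a
    constant vector, where the z-score is undefined.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise CodingError("standardization needs at least two scores")
    sd = x.std(ddof=1)
    if sd == 0:
        raise CodingError("cannot standardize a constant score vector")
    return (x - x.mean()) / sd


# Column order of the coded table; kept stable for downstream CSVs.
CODED_COLUMNS = [
    "id",
    "gender",
    "age",
    "married",
    "sp_score",
    "fp_category",
    "srh_code",
    "dep_code",
    "iadl_code",
    "hukou_code",
    "edu_code",
    "income_code",
]


def code_records(raw: pd.DataFrame, config: CodingConfig = CodingConfig()) -> pd.DataFrame:
    """Apply every coding rule to a raw survey table, row by row.

    `raw` must carry the canonical raw columns (see
    :func:`agestrata.pipeline.read_survey` for header remapping). Returns
    a coded table with one row per respondent in stable column order;
    ``income_code`` is a nullable integer column. ``sp_z`` is *not*
    added here — standardization is an analysis-sample decision made by
    the pipeline after listwise deletion.
    """
    item_cols = [f"sp_{name}" for name in SP_ITEM_NAMES]
    out = {c: [] for c in CODED_COLUMNS}
    for row in raw.itertuples(index=False):
        r = row._asdict()
        sp = score_social_participation([r[c] for c in item_cols])
        fp = code_family_participation(
            r["parent_care_hours"], r["grandchild_care_any"], r["housework_freq"]
        )
        srh, dep, iadl = code_health(
            r["self_rated_health_raw"], r["cesd_total"], r["iadl_score"], config
        )
        income = r["income_rmb"]
        if pd.isna(income):
            income = None
        hukou, edu, inc = code_ses(r["hukou"], r["education_raw"], income, config)
        out["id"].append(r["id"])
        out["gender"].append(r["gender"])
        out["age"].append(int(r["age"]))
        out["married"].append(int(bool(r["married"])))
        out["sp_score"].append(sp)
        out["fp_category"].append(fp)
        out["srh_code"].append(srh)
        out["dep_code"].append(dep)
        out["iadl_code"].append(iadl)
        out["hukou_code"].append(hukou)
        out["edu_code"].append(edu)
        out["income_code"].append(inc)
    coded = pd.DataFrame(out, columns=CODED_COLUMNS)
    coded["income_code"] = coded["income_code"].astype("Int64")
    return coded
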
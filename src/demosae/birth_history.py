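"""Birth-history tabulation into event/exposure and age-segment tables.

Two tabulators consume the woman/child recode tables:

* :func:`tabulate_fertility_exposure` builds the age-group x district
  table of weighted births (events) and weighted woman-years (exposure)
  over the window preceding each interview — the x_i and t_i of the
  Poisson fertility model.
* :func:`tabulate_mortality` builds the synthetic-cohort tabulation of
  weighted deaths and weighted at-risk cohort per under-five age
  segment, following the DHS boundary-cohort half-weighting rule.

Window convention: the window covers calendar months
``interview_cmc - window_months`` .. ``interview_cmc - 1``; the
interview month itself is excluded. Age-group assignment is at month
granularity (completed years = floor(months/12)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from demosae.ages import (
    AGE_GROUPS,
    N_AGE_GROUPS,
    N_SEGMENTS,
    NEONATAL_MAX_DAYS,
    SEGMENT_BOUNDS,
    SEGMENT_LABELS,
    age_group_of_months,
)

logger = logging.getLogger(__name__)


@dataclass
class ChildRecord:
    child_birth_cmc: int
    is_dead: bool = False
    age_at_death_days: int | None = None
    age_at_death_months: int | None = None

    def __post_init__(self) -> None:
        has_age = (
            self.age_at_death_days is not None
            or self.age_at_death_months is not None
        )
        if self.is_dead != has_age:
            raise ValueError("death-age fields must be present iff is_dead")


@dataclass
class WomanRecord:
    woman_id: str
    district_id: str
    psu_id: str
    weight: float
    interview_cmc: int
    birth_cmc: int
    children: list[ChildRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interview_cmc <= self.birth_cmc:
            raise ValueError("interview_cmc must exceed birth_cmc")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        for c in self.children:
            if c.child_birth_cmc > self.interview_cmc:
                raise ValueError("child born after interview")


def records_to_frames(
    records: list[WomanRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert record objects to the (women, children) frame pair."""
    wrows, crows = [], []
    for w in records:
        wrows.append(
            {
                "woman_id": w.woman_id,
                "district_id": w.district_id,
                "psu_id": w.psu_id,
                "weight": w.weight,
                "interview_cmc": w.interview_cmc,
                "birth_cmc": w.birth_cmc,
            }
        )
        for c in w.children:
            crows.append(
                {
                    "woman_id": w.woman_id,
                    "district_id": w.district_id,
                    "psu_id": w.psu_id,
                    "weight": w.weight,
                    "child_birth_cmc": c.child_birth_cmc,
                    "is_dead": int(c.is_dead),
                    "age_at_death_days": c.age_at_death_days,
                    "age_at_death_months": c.age_at_death_months,
                }
            )
    women = pd.DataFrame(wrows)
    children = pd.DataFrame(
        crows,
        columns=[
            "woman_id", "district_id", "psu_id", "weight",
            "child_birth_cmc", "is_dead",
            "age_at_death_days", "age_at_death_months",
        ],
    )
    for col in ("age_at_death_days", "age_at_death_months"):
        children[col] = children[col].astype("Int64")
    return women, children


def _empty_fertility_table(districts: list[str]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_product(
        [districts, AGE_GROUPS], names=["district_id", "age_group"]
    )
    return (
        pd.DataFrame({"events": 0.0, "exposure": 0.0}, index=idx)
        .reset_index()
    )


def tabulate_fertility_exposure(
    women: pd.DataFrame,
    children: pd.DataFrame | None = None,
    window_months: int = 36,
) -> pd.DataFrame:
    """Weighted births and woman-years by district and 5-year age group.

    Each calendar month in the window contributes ``weight / 12``
    woman-years to the age group the woman occupies that month; each
    in-window birth contributes ``weight`` events to the mother's age
    group at the birth month. Months at ages outside 15-49 are dropped.

    Returns a long table: district_id, age_group, events, exposure, with
    all seven groups present for every district.
    """
    if window_months < 1:
        raise ValueError("window_months must be >= 1")
    if women is None or len(women) == 0:
        raise ValueError("women table is empty")

    age_at_interview = (
        women["interview_cmc"].to_numpy() - women["birth_cmc"].to_numpy()
    ) // 12
    bad = (age_at_interview < 10) | (age_at_interview > 60)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} women aged outside 10-60 at interview",
            stacklevel=2,
        )

    d_codes, d_uniques = pd.factorize(women["district_id"], sort=True)
    nd = len(d_uniques)
    exposure = np.zeros((nd, N_AGE_GROUPS))
    events = np.zeros((nd, N_AGE_GROUPS))

    interview = women["interview_cmc"].to_numpy()
    wbirth = women["birth_cmc"].to_numpy()
    weight = women["weight"].to_numpy(dtype=float)
    for k in range(1, window_months + 1):
        grp = np.asarray(age_group_of_months(interview - k - wbirth))
        valid = grp >= 0
        np.add.at(
            exposure, (d_codes[valid], grp[valid]), weight[valid] / 12.0
        )

    if children is not None and len(children):
        c = children.merge(
            women[["woman_id", "interview_cmc", "birth_cmc"]].rename(
                columns={"birth_cmc": "mother_birth_cmc"}
            ),
            on="woman_id",
            how="inner",
        )
        ccmc = c["child_birth_cmc"].to_numpy()
        iv = c["interview_cmc"].to_numpy()
        in_window = (ccmc >= iv - window_months) & (ccmc <= iv - 1)
        grp = np.asarray(
            age_group_of_months(ccmc - c["mother_birth_cmc"].to_numpy())
        )
        valid = in_window & (grp >= 0)
        cd_codes = d_uniques.get_indexer(c["district_id"])
        np.add.at(
            events,
            (cd_codes[valid], grp[valid]),
            c["weight"].to_numpy(dtype=float)[valid],
        )

    out = _empty_fertility_table(list(d_uniques))
    out["events"] = events.ravel()
    out["exposure"] = exposure.ravel()
    return out


def _death_segment(
    months: np.ndarray, days: np.ndarray
) -> np.ndarray:
    """Segment index of each death; neonatal keyed on days when known.

    ``days`` may carry -1 for unknown; month-0 deaths with unknown days
    fall back to the neonatal segment (logged).
    """
    los = np.array([lo for lo, _ in SEGMENT_BOUNDS])
    seg = np.searchsorted(los, months, side="right") - 1
    known_days = days >= 0
    neonatal = known_days & (days <= NEONATAL_MAX_DAYS)
    # deaths at >= 29 days but recorded in month 0 belong to segment 1-2
    late_month0 = known_days & ~neonatal & (months == 0)
    seg = np.where(neonatal, 0, seg)
    seg = np.where(late_month0, 1, seg)
    fallback = ~known_days & (months == 0)
    if fallback.any():
        logger.info(
            "%d month-0 deaths without day detail treated as neonatal",
            int(fallback.sum()),
        )
    return seg


def tabulate_mortality(
    women: pd.DataFrame,
    children: pd.DataFrame,
    window_months: int = 60,
) -> pd.DataFrame:
    """Synthetic-cohort tabulation of deaths and at-risk cohorts.

    Children born in the window enter each age segment's cohort with
    full weight when the whole segment span is observable by the
    interview, and half weight when the interview falls inside the span
    (the DHS boundary-cohort rule). Observed deaths carry full weight
    and are assigned to the segment containing the age at death; deaths
    recorded beyond 59 months count the child as surviving the
    under-five period.

    Returns a long table: district_id, segment, deaths, cohort.
    """
    if window_months < 1:
        raise ValueError("window_months must be >= 1")
    districts = sorted(pd.unique(women["district_id"]))
    idx = pd.MultiIndex.from_product(
        [districts, SEGMENT_LABELS], names=["district_id", "segment"]
    )
    out = pd.DataFrame({"deaths": 0.0, "cohort": 0.0}, index=idx)
    if children is None or len(children) == 0:
        return out.reset_index()

    c = children.merge(
        women[["woman_id", "interview_cmc"]], on="woman_id", how="inner"
    )
    ccmc = c["child_birth_cmc"].to_numpy()
    iv = c["interview_cmc"].to_numpy()
    in_window = (ccmc >= iv - window_months) & (ccmc <= iv - 1)
    c = c.loc[in_window]
    if len(c) == 0:
        return out.reset_index()

    w = c["weight"].to_numpy(dtype=float)
    age_iv = (c["interview_cmc"] - c["child_birth_cmc"]).to_numpy()
    months = c["age_at_death_months"].fillna(-1).to_numpy(dtype=int)
    days = c["age_at_death_days"].fillna(-1).to_numpy(dtype=int)
    dead = (c["is_dead"].to_numpy(dtype=int) == 1) & (months <= 59)
    if (months > 59).any():
        logger.info(
            "%d deaths beyond 59 months counted as under-five survivors",
            int((months > 59).sum()),
        )

    death_seg = np.where(dead, _death_segment(months, days), -1)
    bad = dead & (months >= 0) & (months > age_iv)
    if bad.any():
        raise ValueError("age at death exceeds age at interview")

    dmat = np.zeros((len(districts), N_SEGMENTS))
    cmat = np.zeros((len(districts), N_SEGMENTS))
    d_index = pd.Index(districts)
    d_codes = d_index.get_indexer(c["district_id"])
    for j, (lo, hi) in enumerate(SEGMENT_BOUNDS):
        # dead children: at risk in every segment up to the death segment
        at_risk_dead = dead & (death_seg >= j)
        np.add.at(cmat, (d_codes[at_risk_dead], j), w[at_risk_dead])
        died_here = dead & (death_seg == j)
        np.add.at(dmat, (d_codes[died_here], j), w[died_here])
        # surviving children: full weight when the segment is fully
        # observable, half weight in the boundary cohort
        alive = ~dead
        full = alive & (age_iv >= hi)
        half = alive & (age_iv > lo) & (age_iv < hi)
        np.add.at(cmat, (d_codes[full], j), w[full])
        np.add.at(cmat, (d_codes[half], j), 0.5 * w[half])

    out["deaths"] = dmat.ravel()
    out["cohort"] = cmat.ravel()
    return out.reset_index()


#: Mapping from DHS individual-recode variable names to package columns,
#: for users holding licensed survey files.
DHS_COLUMN_MAP = {
    "v001": "psu_id",
    "v005": "weight_raw",      # divide by 1e6 per DHS convention
    "v008": "interview_cmc",
    "v011": "birth_cmc",
    "b3": "child_birth_cmc",
    "b5": "child_alive",       # 1 = alive
    "b6": "age_at_death_raw",  # coded units + value
    "b7": "age_at_death_months",
}
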
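"""Shared age-group and age-segment conventions.

Ages and dates follow the DHS century-month-code (CMC) convention:
months elapsed since January 1900, so CMC = 12*(year-1900) + month.
Reproductive ages span 15-49 in seven five-year groups; under-five
mortality is decomposed into the eight standard DHS age segments.
"""

from __future__ import annotations

import numpy as np

# Seven five-year reproductive age groups, 15-19 is the Poisson reference.
AGE_GROUPS: tuple[str, ...] = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
)
N_AGE_GROUPS = len(AGE_GROUPS)
REPRO_START_MONTHS = 15 * 12   # age 15 in months
REPRO_END_MONTHS = 50 * 12     # exclusive upper bound (age 50)
GROUP_WIDTH_MONTHS = 60        # five years

# Eight DHS age segments for synthetic-cohort child mortality, in months.
# Bounds are half-open [lo, hi).
SEGMENT_LABELS: tuple[str, ...] = (
    "0", "1-2", "3-5", "6-11", "12-23", "24-35", "36-47", "48-59",
)
SEGMENT_BOUNDS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 3), (3, 6), (6, 12), (12, 24), (24, 36), (36, 48), (48, 60),
)
N_SEGMENTS = len(SEGMENT_LABELS)
SEGMENT_LENGTHS = tuple(hi - lo for lo, hi in SEGMENT_BOUNDS)

NEONATAL_MAX_DAYS = 28  # deaths at < 29 days are neonatal

# Segment index sets for the three headline rates.
NMR_SEGMENTS = (0,)
IMR_SEGMENTS = (0, 1, 2, 3)
U5MR_SEGMENTS = (0, 1, 2, 3, 4, 5, 6, 7)


def age_group_of_months(age_months: np.ndarray | int) -> np.ndarray | int:
    """Map age in completed months to an age-group index (0..6), or -1
    when outside the reproductive span 15-49."""
    age_months = np.asarray(age_months)
    idx = (age_months - REPRO_START_MONTHS) // GROUP_WIDTH_MONTHS
    out = np.where(
        (age_months >= REPRO_START_MONTHS) & (age_months < REPRO_END_MONTHS),
        idx,
        -1,
    )
    return out if out.ndim else int(out)


def cmc(year: int, month: int) -> int:
    """Century month code of a calendar month (month in 1..12)."""
    return 12 * (year - 1900) + month


def monthly_hazards_to_segment_q(hazards: np.ndarray) -> np.ndarray:
    """Per-segment death probabilities q_j from per-month hazards h_j.

    A child alive at the start of segment j dies within it with
    probability q_j = 1 - (1 - h_j)**len_j.
    """
    h = np.asarray(hazards, dtype=float)
    lengths = np.asarray(SEGMENT_LENGTHS, dtype=float)
    return 1.0 - (1.0 - h) ** lengths


def segment_q_to_rates(q: np.ndarray) -> dict[str, float]:
    """Closed-form NMR/IMR/U5MR (per 1000) from segment probabilities."""
    q = np.asarray(q, dtype=float)
    surv = 1.0 - q
    return {
        "nmr": 1000.0 * (1.0 - np.prod(surv[list(NMR_SEGMENTS)])),
        "imr": 1000.0 * (1.0 - np.prod(surv[list(IMR_SEGMENTS)])),
        "u5mr": 1000.0 * (1.0 - np.prod(surv[list(U5MR_SEGMENTS)])),
    }
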
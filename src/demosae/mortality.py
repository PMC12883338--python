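"""Synthetic-cohort child mortality rates with jackknife variances.

From the age-segment tabulation (weighted deaths and at-risk cohort per
segment) each segment's component death probability is
q_j = deaths_j / cohort_j, and a rate over an age range is synthesized
by the DHS product rule

    rate = 1000 * (1 - prod_j (1 - q_j))

over the segments spanning the range: segment 0 alone for the neonatal
rate (NMR), segments 0 .. 6-11 for the infant rate (IMR), and all eight
for the under-five rate (U5MR). Design-based sampling variances come
from a delete-one-PSU jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from demosae.ages import (
    IMR_SEGMENTS,
    N_SEGMENTS,
    NMR_SEGMENTS,
    SEGMENT_LABELS,
    U5MR_SEGMENTS,
)


@dataclass
class MortalitySegmentEstimate:
    segment: str
    q: float            # death probability within the segment
    deaths: float       # weighted
    cohort: float       # weighted at-risk count
    empty: bool = False  # flagged when the cohort is empty


@dataclass
class MortalityRates:
    """Per-district rates (per 1000 live births) and their variances on
    the probability scale."""

    district_id: str
    nmr: float
    imr: float
    u5mr: float
    n_births: float
    nmr_variance: float = np.nan
    imr_variance: float = np.nan
    u5mr_variance: float = np.nan


def component_probabilities(
    tab: pd.DataFrame,
) -> list[MortalitySegmentEstimate]:
    """Per-segment q_j = deaths_j / cohort_j for one district's
    tabulation (columns: segment, deaths, cohort)."""
    t = tab.set_index("segment").reindex(list(SEGMENT_LABELS))
    if t[["deaths", "cohort"]].isna().any().any():
        raise ValueError("tabulation must contain all 8 segments")
    out = []
    for label, row in t.iterrows():
        deaths, cohort = float(row["deaths"]), float(row["cohort"])
        if deaths < 0 or cohort < 0:
            raise ValueError("negative deaths or cohort")
        if deaths > cohort + 1e-9:
            raise ValueError(
                f"segment {label}: deaths ({deaths}) exceed cohort ({cohort})"
            )
        if cohort == 0:
            out.append(MortalitySegmentEstimate(label, 0.0, 0.0, 0.0, True))
        else:
            out.append(
                MortalitySegmentEstimate(
                    label, min(deaths / cohort, 1.0), deaths, cohort
                )
            )
    return out


def _range_rate(q: np.ndarray, segments: tuple[int, ...]) -> float:
    return 1000.0 * (1.0 - float(np.prod(1.0 - q[list(segments)])))


def synthesize_rates(
    segments: list[MortalitySegmentEstimate], district_id: str = ""
) -> MortalityRates:
    """Combine the eight component probabilities into NMR/IMR/U5MR."""
    if len(segments) != N_SEGMENTS:
        raise ValueError("expected 8 segment estimates")
    q = np.array([s.q for s in segments])
    if np.any((q < 0) | (q > 1)):
        raise ValueError("component probabilities must lie in [0,1]")
    return MortalityRates(
        district_id=district_id,
        nmr=_range_rate(q, NMR_SEGMENTS),
        imr=_range_rate(q, IMR_SEGMENTS),
        u5mr=_range_rate(q, U5MR_SEGMENTS),
        n_births=segments[0].cohort,
    )


def rates_from_tabulation(tab: pd.DataFrame) -> pd.DataFrame:
    """All-district rates from a long tabulation table."""
    rows = []
    for district, t in tab.groupby("district_id", sort=True):
        r = synthesize_rates(component_probabilities(t), str(district))
        rows.append(
            {
                "district_id": r.district_id,
                "nmr": r.nmr,
                "imr": r.imr,
                "u5mr": r.u5mr,
                "n_births": r.n_births,
            }
        )
    return pd.DataFrame(rows)


Estimator = Callable[[pd.DataFrame, pd.DataFrame], float | np.ndarray]


def jackknife_variance(
    women: pd.DataFrame,
    children: pd.DataFrame,
    estimator: Estimator,
    psu_col: str = "psu_id",
) -> float | np.ndarray:
    """Delete-one-PSU jackknife variance of a survey estimator.

    ``estimator(women, children)`` may return a scalar or a vector; the
    variance is ((G-1)/G) * sum_g (theta_(g) - mean)^2 over the G PSU
    deletions. A single-PSU district cannot support the jackknife and
    returns NaN (flagged missing; downstream smoothing floors it).
    """
    psus = pd.unique(women[psu_col])
    G = len(psus)
    if G < 2:
        return np.nan
    reps = []
    child_psu = children[psu_col] if len(children) else pd.Series(dtype=object)
    for g in psus:
        w_sub = women.loc[women[psu_col] != g]
        c_sub = (
            children.loc[child_psu != g] if len(children) else children
        )
        reps.append(np.asarray(estimator(w_sub, c_sub), dtype=float))
    reps_arr = np.stack(reps)
    mean = reps_arr.mean(axis=0)
    var = (G - 1) / G * ((reps_arr - mean) ** 2).sum(axis=0)
    return var if var.ndim else float(var)


def floor_variance(rate_per_1000: float, n_births: float) -> float:
    """Probability-scale variance floor via a half-death continuity
    correction, so zero-death districts still carry finite precision."""
    if n_births <= 0:
        raise ValueError("n_births must be positive for the variance floor")
    p = max(rate_per_1000 / 1000.0, 0.5 / n_births)
    p = min(p, 1.0 - 0.5 / n_births)
    return p * (1.0 - p) / n_births
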
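"""Band classification, two-round transition tables and scatter exports.

Indicator values are classified into ordered bands (e.g. TFR < 1.6,
1.6-2.1, 2.1-2.7, above 2.7) and summarized as per-round counts with
percentages. Mortality band labels carry two-decimal gaps
("< 10" vs "10.01-20.00"), so mortality values are rounded to 2 dp
before banding and a value rounding exactly onto a cutpoint goes to the
lower band; TFR bands share endpoints and use half-open [low, high)
intervals with the lower bound inclusive.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BandScheme:
    indicator: str
    cutpoints: tuple[float, ...]
    labels: tuple[str, ...]
    rounded: bool = False  # mortality convention: round to 2 dp, ties down

    def __post_init__(self) -> None:
        if list(self.cutpoints) != sorted(set(self.cutpoints)):
            raise ValueError("cutpoints must be strictly increasing")
        if len(self.labels) != len(self.cutpoints) + 1:
            raise ValueError("need exactly one label per interval")


TFR_BANDS = BandScheme(
    "tfr", (1.6, 2.1, 2.7), ("< 1.6", "1.6-2.1", "2.1-2.7", "Above 2.7")
)
NMR_BANDS = BandScheme(
    "nmr",
    (10.0, 20.0, 30.0, 40.0),
    ("< 10", "10.01-20.00", "20.01-30.00", "30.01-40.00", "40.01 and above"),
    rounded=True,
)
IMR_BANDS = BandScheme(
    "imr",
    (15.0, 25.0, 35.0, 45.0),
    ("< 15", "15.01-25.00", "25.01-35.00", "35.01-45.00", "45.01 and above"),
    rounded=True,
)
U5MR_BANDS = BandScheme(
    "u5mr",
    (20.0, 35.0, 45.0, 55.0),
    ("< 20", "20.01-35.00", "35.01-45.00", "45.01-55.00", "55.01 and above"),
    rounded=True,
)
DEFAULT_SCHEMES = {
    "tfr": TFR_BANDS,
    "nmr": NMR_BANDS,
    "imr": IMR_BANDS,
    "u5mr": U5MR_BANDS,
}


def assign_band(value: float, scheme: BandScheme) -> str:
    """Band label of a single value; every finite value >= 0 maps to
    exactly one band."""
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"value must be finite and >= 0, got {value}")
    if scheme.rounded:
        r = round_half_up(value, 2)
        idx = bisect_left(scheme.cutpoints, r)   # ties go to the lower band
    else:
        idx = bisect_right(scheme.cutpoints, value)  # [low, high)
    return scheme.labels[idx]


def band_counts(values, scheme: BandScheme) -> pd.Series:
    """Counts per band over an iterable of values, in label order."""
    counts = pd.Series(0, index=list(scheme.labels), dtype=int)
    for v in values:
        counts[assign_band(float(v), scheme)] += 1
    return counts


def _percentages(counts: pd.Series, total: int) -> pd.Series:
    return counts.map(
        lambda n: round_half_up(100.0 * n / total, 2) if total else 0.0
    )


def transition_table(
    values_round1,
    values_round2,
    scheme: BandScheme,
) -> pd.DataFrame:
    """Two-round band table: counts and 2-dp percentages per band.

    Totals may differ across rounds (district frames may change between
    surveys). Percentages are of the round total, rounded half away
    from zero.
    """
    c1 = band_counts(values_round1, scheme)
    c2 = band_counts(values_round2, scheme)
    return transition_table_from_counts(c1, c2, scheme)


def transition_table_from_counts(
    counts_round1,
    counts_round2,
    scheme: BandScheme,
    total_round1: int | None = None,
    total_round2: int | None = None,
) -> pd.DataFrame:
    """Same table from precomputed per-band counts (label order).

    ``total_round*`` override the denominators, useful when verifying a
    published table whose printed total row is the authority.
    """
    c1 = pd.Series(np.asarray(counts_round1, dtype=int), index=list(scheme.labels))
    c2 = pd.Series(np.asarray(counts_round2, dtype=int), index=list(scheme.labels))
    t1 = int(c1.sum()) if total_round1 is None else int(total_round1)
    t2 = int(c2.sum()) if total_round2 is None else int(total_round2)
    out = pd.DataFrame(
        {
            "band": list(scheme.labels),
            "n_round1": c1.to_numpy(),
            "pct_round1": _percentages(c1, t1).to_numpy(),
            "n_round2": c2.to_numpy(),
            "pct_round2": _percentages(c2, t2).to_numpy(),
        }
    )
    total = pd.DataFrame(
        [{"band": "Total", "n_round1": t1, "pct_round1": np.nan,
          "n_round2": t2, "pct_round2": np.nan}]
    )
    return pd.concat([out, total], ignore_index=True)


def format_transition_table(table: pd.DataFrame, indicator: str) -> str:
    """Aligned-text rendering, trailing zeros trimmed as in print."""
    lines = [f"{indicator.upper():<16}{'n':>6}{'%':>8}{'n':>8}{'%':>8}"]
    for _, row in table.iterrows():
        def fmt(x):
            if pd.isna(x):
                return ""
            s = f"{x:.2f}".rstrip("0").rstrip(".")
            return s
        lines.append(
            f"{row['band']:<16}{row['n_round1']:>6}{fmt(row['pct_round1']):>8}"
            f"{row['n_round2']:>8}{fmt(row['pct_round2']):>8}"
        )
    return "\n".join(lines)


def scatter_export(
    tfr_estimates: pd.DataFrame,
    mortality_estimates: pd.DataFrame,
    scheme: BandScheme = TFR_BANDS,
    round_label: str = "",
) -> pd.DataFrame:
    """Per-district table behind the TFR-vs-mortality scatter plots.

    ``tfr_estimates`` needs (district_id, tfr); ``mortality_estimates``
    needs (district_id, nmr, imr, u5mr). Districts present on one side
    only are emitted with missing fields (and logged).
    """
    merged = tfr_estimates[["district_id", "tfr"]].merge(
        mortality_estimates[["district_id", "nmr", "imr", "u5mr"]],
        on="district_id",
        how="outer",
    )
    incomplete = merged.isna().any(axis=1)
    if incomplete.any():
        import logging

        logging.getLogger(__name__).info(
            "%d districts present for one indicator only", int(incomplete.sum())
        )
    merged["tfr_band"] = [
        assign_band(v, scheme) if pd.notna(v) else ""
        for v in merged["tfr"]
    ]
    merged["round"] = round_label
    return merged[
        ["district_id", "tfr", "tfr_band", "nmr", "imr", "u5mr", "round"]
    ]
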
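"""Poisson log-rate fertility model: district ASFRs and TFR.

Weighted birth counts x_i per five-year age group are modelled as
Poisson with mean mu_i = lambda_i * t_i, i.e. a log link with
log-exposure offset:

    log(mu_i) = log(t_i) + alpha + sum_w beta_w A_wi

with A_wi age-group dummies for 20-24 .. 45-49 and 15-19 the reference.
The model is saturated in age groups, so the fitted rate in every group
with positive exposure equals the occurrence/exposure ratio
x_i / t_i — a property :func:`tfr_direct` exploits as an independent
check. The TFR is five times the sum of the seven fitted ASFRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from demosae.ages import AGE_GROUPS, N_AGE_GROUPS

#: sentinel for the log-rate coefficient of a zero-event group
NEG_INF = -np.inf


@dataclass
class FertilityFit:
    """Fitted district fertility model.

    ``alpha`` is the log rate of the 15-19 reference group and ``beta``
    the six contrasts for 20-24 .. 45-49; ``vcov`` is the 7x7 covariance
    of (alpha, beta) with zero rows for flagged groups. ``zero_flags``
    marks groups returned with ASFR 0 because they had zero events or
    zero exposure (their coefficient is a -inf sentinel).
    """

    alpha: float
    beta: np.ndarray          # (6,)
    asfr: np.ndarray          # (7,) rates per woman-year
    tfr: float
    vcov: np.ndarray          # (7, 7)
    log_likelihood: float
    zero_flags: np.ndarray    # (7,) bool
    tfr_variance: float
    district_id: str | None = None


def _prepare_cells(cells: pd.DataFrame) -> pd.DataFrame:
    c = cells.set_index("age_group").reindex(list(AGE_GROUPS))
    if c[["events", "exposure"]].isna().any().any():
        missing = c.index[c["events"].isna()].tolist()
        raise ValueError(f"missing age groups: {missing}")
    if (c["exposure"] < 0).any() or (c["events"] < 0).any():
        raise ValueError("events and exposure must be nonnegative")
    return c


def fit_poisson_rates(
    cells: pd.DataFrame, district_id: str | None = None
) -> FertilityFit:
    """Maximum-likelihood Poisson fit with log-exposure offset.

    ``cells`` is the 7-row table (age_group, events, exposure) for one
    district. Groups with zero events or zero exposure are returned with
    ASFR 0 and flagged rather than dropped, keeping the TFR sum
    well-defined. Fitting uses IRLS to relative tolerance 1e-10
    (max 100 iterations).
    """
    c = _prepare_cells(cells)
    events = c["events"].to_numpy(dtype=float)
    exposure = c["exposure"].to_numpy(dtype=float)
    if not (exposure > 0).any():
        raise ValueError("all exposures are zero; nothing to fit")

    include = (exposure > 0) & (events > 0)
    zero_flags = ~include
    k = int(include.sum())

    coefs = np.full(N_AGE_GROUPS, NEG_INF)
    vcov_groups = np.zeros((N_AGE_GROUPS, N_AGE_GROUPS))
    llf = 0.0
    if k:
        # one indicator column per included group: coefficient = log rate;
        # the model is saturated, so statsmodels' perfect-prediction
        # warning is expected and harmless here
        X = np.eye(k)
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.GLM(
                events[include],
                X,
                family=sm.families.Poisson(),
                offset=np.log(exposure[include]),
            ).fit(
                maxiter=100,
                tol=1e-10,
                start_params=np.log(events[include] / exposure[include]),
            )
        coefs[include] = res.params
        vcov_groups[np.ix_(include, include)] = np.asarray(res.cov_params())
        llf = float(res.llf)

    asfr = np.where(include, np.exp(coefs), 0.0)
    tfr = 5.0 * float(asfr.sum())

    # delta method on the per-group log-rate scale: d TFR / d c_g = 5 lambda_g
    grad = 5.0 * asfr
    tfr_variance = float(grad @ vcov_groups @ grad)

    # map per-group log rates to (alpha, beta) with 15-19 as reference
    if include[0]:
        alpha = float(coefs[0])
        beta = np.where(include[1:], coefs[1:] - alpha, NEG_INF)
        A = np.zeros((N_AGE_GROUPS, N_AGE_GROUPS))
        A[0, 0] = 1.0
        for w in range(1, N_AGE_GROUPS):
            if include[w]:
                A[w, w] = 1.0
                A[w, 0] = -1.0
        vcov = A @ vcov_groups @ A.T
    else:
        alpha = NEG_INF
        beta = np.where(include[1:], coefs[1:], NEG_INF)
        vcov = vcov_groups.copy()

    return FertilityFit(
        alpha=alpha,
        beta=beta,
        asfr=asfr,
        tfr=tfr,
        vcov=vcov,
        log_likelihood=llf,
        zero_flags=zero_flags,
        tfr_variance=tfr_variance,
        district_id=district_id,
    )


def predict_asfr(fit: FertilityFit, age_group: str) -> float:
    """Fitted rate exp(alpha + beta_w); the reference group returns
    exp(alpha). Flagged zero groups return 0."""
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}")
    g = AGE_GROUPS.index(age_group)
    return float(fit.asfr[g])


def tfr_direct(cells: pd.DataFrame) -> float:
    """Occurrence/exposure TFR: 5 * sum of events/exposure per group,
    with 0/0 treated as 0. Independent of the GLM path."""
    if cells is None or len(cells) == 0:
        return 0.0
    events = cells["events"].to_numpy(dtype=float)
    exposure = cells["exposure"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(exposure > 0, events / np.where(exposure > 0, exposure, 1.0), 0.0)
    if ((exposure == 0) & (events > 0)).any():
        raise ValueError("events without exposure")
    return 5.0 * float(rates.sum())


def fit_all_districts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-district independent fits over a long event/exposure table.

    Returns a tidy frame: district_id, asfr_<group>..., tfr, tfr_se.
    """
    rows = []
    for district, cells in table.groupby("district_id", sort=True):
        fit = fit_poisson_rates(cells, district_id=str(district))
        row: dict[str, object] = {"district_id": district}
        for g, label in enumerate(AGE_GROUPS):
            row[f"asfr_{label}"] = fit.asfr[g]
        row["tfr"] = fit.tfr
        row["tfr_se"] = float(np.sqrt(max(fit.tfr_variance, 0.0)))
        rows.append(row)
    return pd.DataFrame(rows)
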
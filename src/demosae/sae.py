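"""Hierarchical Bayesian small-area smoothing of district estimates.

An area-level (Fay–Herriot-type) model ties each district's direct
survey estimate to census-like auxiliary covariates through a link
function. Writing y_d for the link-scale direct estimate of district d
and theta_d for the latent link-scale rate:

    y_d | theta_d, gamma_d  ~  Normal(theta_d, gamma_d)
    theta_d                 =  x_d' beta + u_d,   u_d ~ Normal(0, sigma_u^2)

with x_d the standardized auxiliaries plus intercept. The link-scale
sampling variances gamma_d are *unknown parameters*: each has an
inverse-gamma prior anchored at the design-based (jackknife) estimate
gamma_hat_d with nu_d pseudo-degrees-of-freedom, and is updated from its
posterior. The log link is used for the TFR and the logit link for
mortality probabilities (the logistic-normal mixed model).

All full conditionals are conjugate, so the model is fit by a Gibbs
sampler with burn-in and thinning (every k-th draw retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit

AUX_DEFAULT_COLUMNS = (
    "household_size",
    "pct_scheduled_caste",
    "pct_scheduled_tribe",
    "female_literacy_pct",
)


@dataclass
class PriorSpec:
    """Hyperpriors; all configurable, defaults deliberately diffuse.

    ``psi_prior_df`` of None anchors each gamma_d with
    nu_d = effective_size_d - 1 (floored at 1); a number fixes nu for
    every district.
    """

    beta_prior_variance: float = 1e6
    sigma_u_shape: float = 0.01
    sigma_u_rate: float = 0.01
    psi_prior_df: float | None = None

    def __post_init__(self) -> None:
        if min(self.beta_prior_variance, self.sigma_u_shape, self.sigma_u_rate) <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if self.psi_prior_df is not None and self.psi_prior_df <= 0:
            raise ValueError("psi_prior_df must be positive")


@dataclass
class ChainConfig:
    n_iterations: int = 10_000
    burn_in: int = 2_000
    thin_k: int = 5
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must lie in [0, n_iterations)")
        if self.thin_k < 1 or self.n_chains < 1:
            raise ValueError("thin_k and n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin_k


@dataclass
class SAEModel:
    """Assembled area-level model ready for sampling."""

    district_ids: list[str]
    y: np.ndarray            # link-scale direct estimates
    gamma_hat: np.ndarray    # link-scale design variances (anchors)
    nu: np.ndarray           # pseudo-df per district
    X: np.ndarray            # (D, p) design: intercept + standardized aux
    link: str                # "log" or "logit"
    per_1000: bool           # natural-scale values are per 1000
    priors: PriorSpec
    aux_columns: tuple[str, ...] = AUX_DEFAULT_COLUMNS
    direct_values: np.ndarray | None = None  # natural scale, for reports

    @property
    def n_districts(self) -> int:
        return len(self.y)


@dataclass
class GibbsDraws:
    """Retained draws, shaped (n_chains, n_retained, ...)."""

    beta: np.ndarray       # (C, R, p)
    sigma_u2: np.ndarray   # (C, R)
    theta: np.ndarray      # (C, R, D), link scale
    gamma: np.ndarray      # (C, R, D)
    model: SAEModel
    chain: ChainConfig


@dataclass
class PosteriorSummary:
    districts: pd.DataFrame      # natural-scale posterior per district
    beta: pd.DataFrame           # coefficient summaries
    sigma_u2: dict[str, float]
    diagnostics: dict[str, float | list[float]]


def build_model(
    direct: pd.DataFrame,
    auxiliaries: pd.DataFrame,
    link: str = "log",
    priors: PriorSpec | None = None,
    aux_columns: tuple[str, ...] = AUX_DEFAULT_COLUMNS,
    per_1000: bool | None = None,
    prob_floor: float = 1e-4,
    rate_floor: float = 1e-3,
) -> SAEModel:
    """Assemble the area-level model.

    ``direct`` needs columns district_id, value, sampling_variance and
    (optionally) effective_size. For the logit link, values are per-1000
    rates converted to probabilities (with a continuity correction near
    0 and 1) and ``sampling_variance`` is on the probability scale; for
    the log link, values and variances are on the natural rate scale.
    Link-scale observation variances come from the delta method.
    Auxiliaries are standardized (mean 0, sd 1) internally.
    """
    if priors is None:
        priors = PriorSpec()
    if link not in ("log", "logit"):
        raise ValueError("link must be 'log' or 'logit'")
    if per_1000 is None:
        per_1000 = link == "logit"

    d = direct.merge(auxiliaries, on="district_id", how="left", validate="1:1")
    missing_aux = d[list(aux_columns)].isna().any(axis=1)
    if missing_aux.any():
        bad = d.loc[missing_aux, "district_id"].tolist()
        raise ValueError(f"districts without auxiliary rows: {bad}")

    values = d["value"].to_numpy(dtype=float)
    psi = d["sampling_variance"].to_numpy(dtype=float)
    if "effective_size" in d:
        n_eff = d["effective_size"].to_numpy(dtype=float)
    else:
        n_eff = np.full(len(d), 2.0)
    if np.any(values < 0):
        raise ValueError("direct estimates must be nonnegative")
    if np.any(~np.isfinite(psi)) or np.any(psi <= 0):
        raise ValueError("sampling variances must be positive and finite "
                         "(floor them before smoothing)")

    if link == "logit":
        p = values / 1000.0 if per_1000 else values.copy()
        clipped = (p < prob_floor) | (p > 1 - prob_floor)
        p = np.clip(p, prob_floor, 1 - prob_floor)
        if clipped.any():
            import logging

            logging.getLogger(__name__).info(
                "continuity-corrected %d boundary probabilities",
                int(clipped.sum()),
            )
        y = logit(p)
        gamma_hat = psi / (p * (1 - p)) ** 2
    else:
        v = np.maximum(values, rate_floor)
        y = np.log(v)
        gamma_hat = psi / v**2

    if priors.psi_prior_df is not None:
        nu = np.full(len(d), float(priors.psi_prior_df))
    else:
        nu = np.maximum(n_eff - 1.0, 1.0)

    Z = d[list(aux_columns)].to_numpy(dtype=float)
    sd = Z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (Z - Z.mean(axis=0)) / sd
    X = np.column_stack([np.ones(len(d)), Z])

    return SAEModel(
        district_ids=d["district_id"].astype(str).tolist(),
        y=y,
        gamma_hat=gamma_hat,
        nu=nu,
        X=X,
        link=link,
        per_1000=per_1000,
        priors=priors,
        aux_columns=tuple(aux_columns),
        direct_values=values,
    )


def _sample_inverse_gamma(
    rng: np.random.Generator, shape: float | np.ndarray, rate: float | np.ndarray
) -> np.ndarray:
    return 1.0 / rng.gamma(shape, 1.0 / np.asarray(rate, dtype=float))


def _run_chain(
    model: SAEModel,
    chain: ChainConfig,
    rng: np.random.Generator,
    fixed: dict,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    y, X = model.y, model.X
    D, p = X.shape
    pr = model.priors

    beta_fixed = fixed.get("beta")
    sigma_fixed = fixed.get("sigma_u2")
    gamma_fixed = fixed.get("gamma")

    # initial state: OLS coefficients, residual variance, direct values
    beta = (
        np.asarray(beta_fixed, dtype=float)
        if beta_fixed is not None
        else np.linalg.lstsq(X, y, rcond=None)[0]
    )
    resid = y - X @ beta
    sigma_u2 = (
        float(sigma_fixed)
        if sigma_fixed is not None
        else max(float(resid.var()), 1e-4)
    )
    gamma = (
        np.asarray(gamma_fixed, dtype=float).copy()
        if gamma_fixed is not None
        else model.gamma_hat.copy()
    )
    theta = y.copy()

    R = chain.n_retained
    out_beta = np.empty((R, p))
    out_sigma = np.empty(R)
    out_theta = np.empty((R, D))
    out_gamma = np.empty((R, D))

    degenerate = sigma_fixed is not None and sigma_fixed == 0.0
    r = 0
    for it in range(chain.n_iterations):
        if degenerate:
            # sigma_u2 = 0 collapses theta onto the regression surface;
            # beta is drawn from its observation-layer conditional
            if beta_fixed is None:
                prec = X.T @ (X / gamma[:, None]) + np.eye(p) / pr.beta_prior_variance
                L = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, X.T @ (y / gamma))
                beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            theta = X @ beta
        else:
            if beta_fixed is None:
                prec = X.T @ X / sigma_u2 + np.eye(p) / pr.beta_prior_variance
                L = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, X.T @ theta / sigma_u2)
                beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            if sigma_fixed is None:
                resid = theta - X @ beta
                sigma_u2 = float(
                    _sample_inverse_gamma(
                        rng,
                        pr.sigma_u_shape + 0.5 * D,
                        pr.sigma_u_rate + 0.5 * float(resid @ resid),
                    )
                )
            prec_theta = 1.0 / gamma + 1.0 / sigma_u2
            mean_theta = (y / gamma + (X @ beta) / sigma_u2) / prec_theta
            theta = mean_theta + rng.standard_normal(D) / np.sqrt(prec_theta)

        if gamma_fixed is None:
            gamma = _sample_inverse_gamma(
                rng,
                0.5 * (model.nu + 1.0),
                0.5 * (model.nu * model.gamma_hat + (y - theta) ** 2),
            )

        if not (
            np.isfinite(beta).all()
            and np.isfinite(theta).all()
            and np.isfinite(gamma).all()
            and np.isfinite(sigma_u2)
        ):
            raise RuntimeError(
                "non-finite Gibbs state at iteration "
                f"{it}: beta={beta}, sigma_u2={sigma_u2}"
            )

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin_k == 0:
            if r < R:
                out_beta[r] = beta
                out_sigma[r] = sigma_u2
                out_theta[r] = theta
                out_gamma[r] = gamma
                r += 1
    return out_beta[:r], out_sigma[:r], out_theta[:r], out_gamma[:r]


def gibbs_sample(
    model: SAEModel,
    chain: ChainConfig,
    fixed: dict | None = None,
) -> GibbsDraws:
    """Run the Gibbs sampler; fully reproducible given ``chain.seed``.

    ``fixed`` may pin 'beta' (vector), 'sigma_u2' (scalar; 0 collapses
    the random effects) or 'gamma' (vector) for conjugate-case checks.
    """
    fixed = fixed or {}
    betas, sigmas, thetas, gammas = [], [], [], []
    for ci in range(chain.n_chains):
        rng = np.random.default_rng([chain.seed, 7, ci])
        b, s, t, g = _run_chain(model, chain, rng, fixed)
        betas.append(b)
        sigmas.append(s)
        thetas.append(t)
        gammas.append(g)
    return GibbsDraws(
        beta=np.stack(betas),
        sigma_u2=np.stack(sigmas),
        theta=np.stack(thetas),
        gamma=np.stack(gammas),
        model=model,
        chain=chain,
    )


def _inv_link(model: SAEModel, theta: np.ndarray) -> np.ndarray:
    if model.link == "logit":
        p = expit(theta)
        return 1000.0 * p if model.per_1000 else p
    return np.exp(theta)


def lag1_autocorrelation(x: np.ndarray) -> float:
    """Lag-1 autocorrelation of a 1-D draw sequence."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float(x[:-1] @ x[1:]) / denom


def _rhat(x: np.ndarray) -> float:
    """Potential scale reduction across chains (x: (chains, draws))."""
    if x.shape[0] < 2:
        return float("nan")
    r = az.rhat(az.convert_to_dataset(x[..., None]))
    return float(np.asarray(r.to_array()).ravel()[0])


def summarize(
    draws: GibbsDraws, level: float = 0.90
) -> PosteriorSummary:
    """Posterior means/medians and equal-tailed credible intervals.

    District summaries are reported on the natural scale (per 1000 for
    mortality indicators). Diagnostics: potential scale reduction for
    beta and sigma_u2 (needs >= 2 chains) and lag-1 autocorrelation of
    the retained draws.
    """
    model = draws.model
    n_total = draws.sigma_u2.size
    if n_total < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2

    theta_nat = _inv_link(model, draws.theta.reshape(-1, model.n_districts))
    districts = pd.DataFrame(
        {
            "district_id": model.district_ids,
            "direct": model.direct_values,
            "posterior_mean": theta_nat.mean(axis=0),
            "posterior_median": np.median(theta_nat, axis=0),
            "ci_low": np.quantile(theta_nat, lo_q, axis=0),
            "ci_high": np.quantile(theta_nat, hi_q, axis=0),
        }
    )

    p = draws.beta.shape[-1]
    flat_beta = draws.beta.reshape(-1, p)
    names = ["intercept"] + [f"z_{c}" for c in model.aux_columns]
    beta = pd.DataFrame(
        {
            "coefficient": names,
            "mean": flat_beta.mean(axis=0),
            "sd": flat_beta.std(axis=0, ddof=1),
            "ci_low": np.quantile(flat_beta, lo_q, axis=0),
            "ci_high": np.quantile(flat_beta, hi_q, axis=0),
            "rhat": [_rhat(draws.beta[:, :, j]) for j in range(p)],
        }
    )

    sig = draws.sigma_u2.ravel()
    sigma_u2 = {
        "mean": float(sig.mean()),
        "median": float(np.median(sig)),
        "ci_low": float(np.quantile(sig, lo_q)),
        "ci_high": float(np.quantile(sig, hi_q)),
    }
    single_chain = draws.sigma_u2.shape[0] < 2
    diagnostics = {
        "rhat_sigma_u2": _rhat(draws.sigma_u2),
        "rhat_beta_max": (
            float(np.nanmax(rb))
            if not single_chain and np.isfinite(rb := beta["rhat"].to_numpy()).any()
            else float("nan")
        ),
        "lag1_autocorr_sigma_u2": lag1_autocorrelation(draws.sigma_u2[0]),
        "lag1_autocorr_beta": [
            lag1_autocorrelation(draws.beta[0, :, j]) for j in range(p)
        ],
        "n_retained_total": int(n_total),
        "single_chain": bool(single_chain),
    }
    return PosteriorSummary(
        districts=districts, beta=beta, sigma_u2=sigma_u2, diagnostics=diagnostics
    )


def shrinkage_weights(model: SAEModel, draws: GibbsDraws) -> pd.DataFrame:
    """Diagnostic composition weight sigma_u2 / (sigma_u2 + gamma_d):
    the weight the direct estimate receives relative to the regression
    surface; near 1 means the direct estimate dominates."""
    sigma = float(draws.sigma_u2.mean())
    gamma = draws.gamma.reshape(-1, model.n_districts).mean(axis=0)
    return pd.DataFrame(
        {
            "district_id": model.district_ids,
            "gamma_posterior_mean": gamma,
            "weight_on_direct": sigma / (sigma + gamma),
        }
    )
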
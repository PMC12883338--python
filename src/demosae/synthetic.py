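"""NFHS-like synthetic microdata with known district-level truth.

The generator emulates the structure of DHS individual-recode birth
histories: one row per ever-married woman (district, PSU, sampling
weight, interview date, own birth date) and one row per live-born child
(birth date, survival status, age at death). True district-level
age-specific fertility rates (ASFRs) and age-segment mortality hazards
are drawn from a Fay–Herriot-style linear predictor on standardized
census-like auxiliary covariates, so that every downstream estimator can
be checked against known ground truth.

Column dictionary
-----------------
women.csv
    woman_id        unique identifier
    district_id     district identifier (shared with auxiliaries)
    psu_id          primary sampling unit within district
    weight          sampling weight (lognormal, mean 1)
    interview_cmc   interview month, century month code
    birth_cmc       woman's own birth month, CMC

children.csv
    woman_id, district_id, psu_id, weight   (denormalized from mother)
    child_birth_cmc      child's birth month, CMC
    is_dead              1 if the child died before the interview
    age_at_death_days    integer days, present iff is_dead
    age_at_death_months  integer completed months, present iff is_dead

auxiliaries.csv
    district_id, household_size, pct_scheduled_caste,
    pct_scheduled_tribe, female_literacy_pct, and the standardized
    scores z_* actually entering the linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from demosae.ages import (
    N_AGE_GROUPS,
    N_SEGMENTS,
    SEGMENT_LENGTHS,
    monthly_hazards_to_segment_q,
    segment_q_to_rates,
)

# Relative age pattern of fertility across the seven 5-year groups
# (peaks at 25-29, near-zero at 45-49); sums to 1.
BASE_ASFR_SHAPE = np.array([0.10, 0.24, 0.26, 0.18, 0.12, 0.07, 0.03])

# Share of all under-five deaths falling in each age segment
# (heavily front-loaded into the neonatal month); sums to 1.
SEGMENT_DEATH_SHARES = np.array(
    [0.45, 0.08, 0.08, 0.12, 0.12, 0.06, 0.05, 0.04]
)

AUXILIARY_COLUMNS = (
    "household_size",
    "pct_scheduled_caste",
    "pct_scheduled_tribe",
    "female_literacy_pct",
)
# Location/scale turning standardized scores into presentation values.
_AUX_LOC = np.array([4.8, 16.0, 9.0, 65.0])
_AUX_SCALE = np.array([0.6, 6.0, 4.0, 12.0])


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey.

    ``auxiliary_effect`` are the coefficients of the four standardized
    auxiliaries on the link scale — log TFR for fertility and logit of
    the under-five death probability for mortality — so that the small
    area model downstream is correctly specified by construction.
    """

    n_districts: int = 20
    seed: int = 0
    interview_cmc: int = 1446          # mid-2020
    n_women: int = 500
    n_psu: int = 25
    weight_dispersion: float = 0.2     # lognormal sigma; 0 => equal weights
    auxiliary_effect: np.ndarray = field(
        default_factory=lambda: np.array([0.08, 0.05, 0.04, -0.10])
    )
    auxiliary_noise_sd: float = 0.08
    base_tfr: float = 2.2              # TFR at average auxiliaries
    base_u5mr_prob: float = 0.045      # under-five death probability at average
    min_birth_spacing: int = 9         # months between consecutive births
    fixed_asfr: np.ndarray | None = None           # override: same in all districts
    fixed_segment_hazard: np.ndarray | None = None  # override: monthly hazards

    def __post_init__(self) -> None:
        self.auxiliary_effect = np.asarray(self.auxiliary_effect, dtype=float)
        if self.n_districts < 1:
            raise ConfigurationError("n_districts must be >= 1")
        if self.interview_cmc <= 12 * 70:
            raise ConfigurationError("interview_cmc must be post-1970")
        if self.weight_dispersion < 0 or self.auxiliary_noise_sd < 0:
            raise ConfigurationError("dispersion parameters must be >= 0")
        if self.auxiliary_effect.shape != (len(AUXILIARY_COLUMNS),):
            raise ConfigurationError(
                f"auxiliary_effect must have {len(AUXILIARY_COLUMNS)} entries"
            )
        if self.n_women < 1 or self.n_psu < 1:
            raise ConfigurationError("n_women and n_psu must be >= 1")
        if self.fixed_asfr is not None:
            self.fixed_asfr = np.asarray(self.fixed_asfr, dtype=float)
            if self.fixed_asfr.shape != (N_AGE_GROUPS,) or np.any(
                (self.fixed_asfr < 0) | (self.fixed_asfr > 1)
            ):
                raise ConfigurationError("fixed_asfr must be 7 rates in [0,1]")
        if self.fixed_segment_hazard is not None:
            self.fixed_segment_hazard = np.asarray(
                self.fixed_segment_hazard, dtype=float
            )
            if self.fixed_segment_hazard.shape != (N_SEGMENTS,) or np.any(
                (self.fixed_segment_hazard < 0) | (self.fixed_segment_hazard > 1)
            ):
                raise ConfigurationError(
                    "fixed_segment_hazard must be 8 probabilities in [0,1]"
                )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class TruthProfile:
    """Latent district rates the estimators are meant to recover."""

    district_id: str
    true_asfr: np.ndarray            # 7 rates per woman-year
    true_segment_hazard: np.ndarray  # 8 monthly death probabilities
    n_women: int
    n_psu: int

    def __post_init__(self) -> None:
        self.true_asfr = np.asarray(self.true_asfr, dtype=float)
        self.true_segment_hazard = np.asarray(
            self.true_segment_hazard, dtype=float
        )
        if self.true_asfr.shape != (N_AGE_GROUPS,):
            raise ConfigurationError("true_asfr must have 7 entries")
        if self.true_segment_hazard.shape != (N_SEGMENTS,):
            raise ConfigurationError("true_segment_hazard must have 8 entries")
        for arr in (self.true_asfr, self.true_segment_hazard):
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError("rates must lie in [0,1]")
        if self.n_women < 1 or self.n_psu < 1:
            raise ConfigurationError("n_women and n_psu must be >= 1")

    @property
    def true_tfr(self) -> float:
        return 5.0 * float(self.true_asfr.sum())

    def true_mortality_rates(self) -> dict[str, float]:
        """Closed-form NMR/IMR/U5MR per 1000 implied by the hazards."""
        q = monthly_hazards_to_segment_q(self.true_segment_hazard)
        return segment_q_to_rates(q)


def _district_ids(n: int) -> list[str]:
    return [f"D{i + 1:03d}" for i in range(n)]


def _standardized_auxiliaries(config: GeneratorConfig) -> np.ndarray:
    """Standardized auxiliary scores, reproducible from the seed alone."""
    rng = np.random.default_rng([config.seed, 101])
    return rng.standard_normal((config.n_districts, len(AUXILIARY_COLUMNS)))


def _shares_to_segment_q(total_prob: np.ndarray) -> np.ndarray:
    """Split an under-five death probability into per-segment conditional
    probabilities q_j so deaths follow SEGMENT_DEATH_SHARES."""
    total_prob = np.atleast_1d(np.asarray(total_prob, dtype=float))
    d = SEGMENT_DEATH_SHARES[None, :] * total_prob[:, None]  # unconditional
    surv_at_start = 1.0 - np.concatenate(
        [np.zeros((len(total_prob), 1)), np.cumsum(d, axis=1)[:, :-1]], axis=1
    )
    return d / surv_at_start


def generate_truth(config: GeneratorConfig) -> list[TruthProfile]:
    """Draw the latent district rate profiles.

    True log-TFR and logit under-five death probability are linear in the
    standardized auxiliaries with coefficients ``auxiliary_effect`` plus
    Gaussian noise of sd ``auxiliary_noise_sd``; the ASFR age pattern and
    the within-under-five death-age pattern are fixed shapes.
    """
    z = _standardized_auxiliaries(config)
    rng = np.random.default_rng([config.seed, 102])
    n = config.n_districts

    if config.fixed_asfr is not None:
        asfr = np.tile(config.fixed_asfr, (n, 1))
    else:
        log_tfr = (
            np.log(config.base_tfr)
            + z @ config.auxiliary_effect
            + rng.normal(0.0, config.auxiliary_noise_sd, n)
        )
        asfr = np.clip(
            BASE_ASFR_SHAPE[None, :] * (np.exp(log_tfr) / 5.0)[:, None], 0.0, 1.0
        )

    if config.fixed_segment_hazard is not None:
        hazard = np.tile(config.fixed_segment_hazard, (n, 1))
    else:
        logit_q5 = (
            logit(config.base_u5mr_prob)
            + z @ config.auxiliary_effect
            + rng.normal(0.0, config.auxiliary_noise_sd, n)
        )
        q = _shares_to_segment_q(expit(logit_q5))
        lengths = np.asarray(SEGMENT_LENGTHS, dtype=float)
        hazard = 1.0 - (1.0 - q) ** (1.0 / lengths[None, :])

    return [
        TruthProfile(
            district_id=d,
            true_asfr=asfr[i],
            true_segment_hazard=hazard[i],
            n_women=config.n_women,
            n_psu=config.n_psu,
        )
        for i, d in enumerate(_district_ids(n))
    ]


def generate_auxiliaries(
    truth: list[TruthProfile], config: GeneratorConfig
) -> pd.DataFrame:
    """Census-like district covariate table.

    Presentation columns are affine transforms of the standardized
    scores; percentages are clipped to [0, 100]. The ``z_*`` columns are
    the scores that actually enter the truth linear predictor.
    """
    if not truth:
        raise ConfigurationError("truth must be nonempty")
    z = _standardized_auxiliaries(config)
    if z.shape[0] != len(truth):
        raise ConfigurationError("config.n_districts does not match truth")
    raw = _AUX_LOC[None, :] + _AUX_SCALE[None, :] * z
    raw[:, 1:] = np.clip(raw[:, 1:], 0.0, 100.0)  # percentage columns
    raw[:, 0] = np.clip(raw[:, 0], 1.0, None)     # household size >= 1
    df = pd.DataFrame(raw, columns=list(AUXILIARY_COLUMNS))
    df.insert(0, "district_id", [t.district_id for t in truth])
    for j, col in enumerate(AUXILIARY_COLUMNS):
        df[f"z_{col}"] = z[:, j]
    return df


def _simulate_district(
    profile: TruthProfile, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = profile.n_women
    interview = config.interview_cmc

    age_months = rng.integers(15 * 12, 50 * 12, n)  # completed age at interview
    birth_cmc = interview - age_months
    psu = rng.integers(0, profile.n_psu, n)
    if config.weight_dispersion > 0:
        s = config.weight_dispersion
        weight = rng.lognormal(-0.5 * s * s, s, n)
    else:
        weight = np.ones(n)

    # Month-by-month fertility from age 15 to the month before interview.
    n_repro = age_months - 15 * 12
    max_months = int(n_repro.max()) if n else 0
    since_last = np.full(n, config.min_birth_spacing, dtype=np.int64)
    mother_idx: list[np.ndarray] = []
    child_cmc: list[np.ndarray] = []
    # The spacing constraint makes births a renewal process: a monthly
    # hazard p applied only in eligible months yields a stationary rate
    # p / (1 + (s-1) p) with s the minimum spacing. Invert so that the
    # *realized* rate matches the configured ASFR.
    blackout = config.min_birth_spacing - 1
    for j in range(max_months):
        group = (15 * 12 + j) // 60 - 3
        r = profile.true_asfr[group] / 12.0
        if blackout * r >= 1.0:
            raise ConfigurationError(
                "ASFR too high for the configured birth spacing"
            )
        p = r / (1.0 - blackout * r)
        eligible = (j < n_repro) & (since_last >= config.min_birth_spacing)
        gives_birth = eligible & (rng.random(n) < p)
        since_last += 1
        if gives_birth.any():
            idx = np.nonzero(gives_birth)[0]
            mother_idx.append(idx)
            child_cmc.append(birth_cmc[idx] + 15 * 12 + j)
            since_last[idx] = 0

    women = pd.DataFrame(
        {
            "woman_id": [
                f"{profile.district_id}_W{i:05d}" for i in range(n)
            ],
            "district_id": profile.district_id,
            "psu_id": [f"{profile.district_id}_P{k:03d}" for k in psu],
            "weight": weight,
            "interview_cmc": interview,
            "birth_cmc": birth_cmc,
        }
    )

    if mother_idx:
        midx = np.concatenate(mother_idx)
        ccmc = np.concatenate(child_cmc)
    else:
        midx = np.empty(0, dtype=int)
        ccmc = np.empty(0, dtype=int)
    order = np.lexsort((ccmc, midx))
    midx, ccmc = midx[order], ccmc[order]
    nc = len(midx)

    # Death month from the piecewise-constant monthly hazard, censored at
    # the interview: a simulated death after the child's current age is
    # recorded as alive.
    monthly_h = np.repeat(
        profile.true_segment_hazard, np.asarray(SEGMENT_LENGTHS)
    )
    f = monthly_h * np.concatenate([[1.0], np.cumprod(1.0 - monthly_h)[:-1]])
    cum_f = np.cumsum(f)
    death_month = np.searchsorted(cum_f, rng.random(nc))  # 60 => survives
    age_at_interview = interview - ccmc
    observed_death = death_month < np.minimum(age_at_interview, 60)

    days = np.where(
        death_month == 0,
        rng.integers(0, 29, nc),
        death_month * 30 + rng.integers(0, 30, nc),
    )
    children = pd.DataFrame(
        {
            "woman_id": women["woman_id"].to_numpy()[midx],
            "district_id": profile.district_id,
            "psu_id": women["psu_id"].to_numpy()[midx],
            "weight": weight[midx],
            "child_birth_cmc": ccmc,
            "is_dead": observed_death.astype(int),
            "age_at_death_days": np.where(observed_death, days, -1),
            "age_at_death_months": np.where(observed_death, death_month, -1),
        }
    )
    children["age_at_death_days"] = children["age_at_death_days"].where(
        children["is_dead"] == 1
    ).astype("Int64")
    children["age_at_death_months"] = children["age_at_death_months"].where(
        children["is_dead"] == 1
    ).astype("Int64")
    return women, children


def simulate_microdata(
    truth: list[TruthProfile], config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the woman and child recode tables for every district.

    Returns ``(women, children)`` DataFrames following the module column
    dictionary. Fully deterministic given ``config.seed``.
    """
    if not truth:
        raise ConfigurationError("truth must be nonempty")
    women_parts, child_parts = [], []
    for i, profile in enumerate(truth):
        rng = np.random.default_rng([config.seed, 200, i])
        w, c = _simulate_district(profile, config, rng)
        women_parts.append(w)
        child_parts.append(c)
    women = pd.concat(women_parts, ignore_index=True)
    children = pd.concat(child_parts, ignore_index=True)
    return women, children


def truth_to_frame(truth: list[TruthProfile]) -> pd.DataFrame:
    """Flatten truth profiles to a tidy table (one row per district)."""
    rows = []
    for t in truth:
        row: dict[str, object] = {"district_id": t.district_id}
        for g in range(N_AGE_GROUPS):
            row[f"asfr_{g}"] = t.true_asfr[g]
        for s in range(N_SEGMENTS):
            row[f"hazard_{s}"] = t.true_segment_hazard[s]
        row["tfr"] = t.true_tfr
        row.update(t.true_mortality_rates())
        row["n_women"] = t.n_women
        row["n_psu"] = t.n_psu
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(
    out_dir: str | Path,
    config: GeneratorConfig,
    truth: list[TruthProfile],
    women: pd.DataFrame,
    children: pd.DataFrame,
    auxiliaries: pd.DataFrame,
) -> dict[str, Path]:
    """Persist a full synthetic dataset as CSV + YAML config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": out / "config.yaml",
        "truth": out / "truth.csv",
        "women": out / "women.csv",
        "children": out / "children.csv",
        "auxiliaries": out / "auxiliaries.csv",
    }
    config.to_yaml(paths["config"])
    truth_to_frame(truth).to_csv(paths["truth"], index=False)
    women.to_csv(paths["women"], index=False)
    children.to_csv(paths["children"], index=False)
    auxiliaries.to_csv(paths["auxiliaries"], index=False)
    return paths


def read_microdata(
    women_path: str | Path, children_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    women = pd.read_csv(women_path)
    children = pd.read_csv(
        children_path,
        dtype={"age_at_death_days": "Int64", "age_at_death_months": "Int64"},
    )
    return women, children
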
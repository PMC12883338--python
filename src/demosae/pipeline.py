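"""End-to-end orchestration: generate/ingest -> tabulate -> estimate ->
smooth -> report, driven by a single YAML config.

Every stage writes a tidy CSV artifact under the output directory and
the run closes with a JSON manifest (config hash, seed, package
versions, per-stage row counts). Reruns with the same config and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from demosae import __version__
from demosae.birth_history import (
    tabulate_fertility_exposure,
    tabulate_mortality,
)
from demosae.fertility import fit_all_districts, tfr_direct
from demosae.mortality import (
    floor_variance,
    jackknife_variance,
    rates_from_tabulation,
)
from demosae.reporting import (
    DEFAULT_SCHEMES,
    format_transition_table,
    scatter_export,
    transition_table,
)
from demosae.sae import (
    ChainConfig,
    PriorSpec,
    build_model,
    gibbs_sample,
    shrinkage_weights,
    summarize,
)
from demosae.synthetic import (
    GeneratorConfig,
    generate_auxiliaries,
    generate_truth,
    read_microdata,
    simulate_microdata,
    truth_to_frame,
)

logger = logging.getLogger(__name__)

MORTALITY_INDICATORS = ("nmr", "imr", "u5mr")
ALL_INDICATORS = ("tfr",) + MORTALITY_INDICATORS


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending
    districts where applicable."""


@dataclass
class RoundSpec:
    """One survey round: either synthetic generator parameters or paths
    to existing women/children CSVs."""

    name: str
    generator: dict | None = None
    women_path: str | None = None
    children_path: str | None = None


@dataclass
class RunConfig:
    rounds: list[RoundSpec]
    indicators: tuple[str, ...] = ALL_INDICATORS
    fertility_window: int = 36
    mortality_window: int = 60
    auxiliaries_path: str | None = None
    run_sae: bool = True
    priors: PriorSpec = field(default_factory=PriorSpec)
    chain: dict = field(default_factory=dict)
    out_dir: str = "pipeline_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        rounds = [RoundSpec(**r) for r in raw.pop("rounds")]
        priors = PriorSpec(**raw.pop("priors", {}))
        return cls(rounds=rounds, priors=priors, **raw)


def validate_inputs(
    women: pd.DataFrame, children: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Exclude records with incomplete birth-history information.

    No imputation is performed; exclusions are counted by reason and
    kept + excluded always equals the input row count.
    """
    report: dict[str, int] = {
        "women_in": len(women),
        "children_in": len(children),
    }
    w_missing = (
        women[["interview_cmc", "birth_cmc", "weight"]].isna().any(axis=1)
        | (women["weight"] <= 0)
    )
    age = (women["interview_cmc"] - women["birth_cmc"]) / 12.0
    w_implausible = ~w_missing & ((age < 10) | (age > 60))
    keep_w = ~(w_missing | w_implausible)
    report["women_excluded_missing_fields"] = int(w_missing.sum())
    report["women_excluded_implausible_age"] = int(w_implausible.sum())

    women_clean = women.loc[keep_w]
    c_orphan = ~children["woman_id"].isin(women_clean["woman_id"])
    c_missing_birth = children["child_birth_cmc"].isna()
    dead = children["is_dead"].fillna(0).astype(int) == 1
    c_dead_no_age = dead & (
        children["age_at_death_days"].isna()
        & children["age_at_death_months"].isna()
    )
    drop_c = c_orphan | c_missing_birth | c_dead_no_age
    report["children_excluded_mother_excluded"] = int(c_orphan.sum())
    report["children_excluded_missing_birth_date"] = int(
        (c_missing_birth & ~c_orphan).sum()
    )
    report["children_excluded_death_without_age"] = int(
        (c_dead_no_age & ~c_orphan & ~c_missing_birth).sum()
    )
    report["women_kept"] = int(keep_w.sum())
    report["children_kept"] = int((~drop_c).sum())
    return women_clean, children.loc[~drop_c], report


def _district_tfr_estimator(window: int):
    def est(w: pd.DataFrame, c: pd.DataFrame) -> float:
        return tfr_direct(tabulate_fertility_exposure(w, c, window))

    return est


def _district_mortality_estimator(window: int):
    def est(w: pd.DataFrame, c: pd.DataFrame) -> np.ndarray:
        rates = rates_from_tabulation(tabulate_mortality(w, c, window))
        r = rates.iloc[0]
        return np.array([r["nmr"], r["imr"], r["u5mr"]]) / 1000.0

    return est


def direct_estimates(
    women: pd.DataFrame,
    children: pd.DataFrame,
    fertility_window: int = 36,
    mortality_window: int = 60,
    jackknife: bool = True,
) -> pd.DataFrame:
    """Design-based district estimates of all four indicators with
    delete-one-PSU jackknife variances (floored where degenerate).

    Returns one row per district: tfr, nmr, imr, u5mr, their variances
    (probability scale for mortality), n_psu, n_births.
    """
    exposure = tabulate_fertility_exposure(women, children, fertility_window)
    fert = fit_all_districts(exposure)
    mort_tab = tabulate_mortality(women, children, mortality_window)
    mort = rates_from_tabulation(mort_tab)
    out = fert[["district_id", "tfr", "tfr_se"]].merge(
        mort, on="district_id", how="outer"
    )
    out["tfr_variance"] = out["tfr_se"] ** 2
    out = out.drop(columns="tfr_se")

    n_psu = women.groupby("district_id")["psu_id"].nunique()
    out["n_psu"] = out["district_id"].map(n_psu).fillna(0).astype(int)

    var_cols = {k: [] for k in ("tfr", "nmr", "imr", "u5mr")}
    for district, grp in women.groupby("district_id", sort=True):
        cgrp = children.loc[children["district_id"] == district]
        if jackknife and grp["psu_id"].nunique() >= 2:
            v_tfr = jackknife_variance(
                grp, cgrp, _district_tfr_estimator(fertility_window)
            )
            v_mort = jackknife_variance(
                grp, cgrp, _district_mortality_estimator(mortality_window)
            )
        else:
            v_tfr, v_mort = np.nan, np.array([np.nan] * 3)
        var_cols["tfr"].append(v_tfr)
        for i, k in enumerate(MORTALITY_INDICATORS):
            var_cols[k].append(v_mort[i])

    districts = sorted(women["district_id"].unique())
    jk = pd.DataFrame({"district_id": districts})
    jk["tfr_jk_variance"] = var_cols["tfr"]
    for k in MORTALITY_INDICATORS:
        jk[f"{k}_variance"] = var_cols[k]
    out = out.merge(jk, on="district_id", how="left")

    # prefer the jackknife for the TFR; fall back to the delta-method
    # variance from the Poisson fit when the jackknife is unavailable
    out["tfr_variance"] = out["tfr_jk_variance"].where(
        out["tfr_jk_variance"].notna() & (out["tfr_jk_variance"] > 0),
        out["tfr_variance"],
    )
    out = out.drop(columns="tfr_jk_variance")
    for k in MORTALITY_INDICATORS:
        floored = [
            floor_variance(r, n) if not (v > 0) else v
            for r, n, v in zip(out[k], out["n_births"], out[f"{k}_variance"])
        ]
        out[f"{k}_variance"] = floored
    out["tfr_variance"] = out["tfr_variance"].clip(lower=1e-6)
    return out


def smooth_indicator(
    direct: pd.DataFrame,
    auxiliaries: pd.DataFrame,
    indicator: str,
    priors: PriorSpec,
    chain: ChainConfig,
):
    """Fay–Herriot smoothing of one indicator; returns (summary,
    shrinkage weights, model, draws)."""
    if indicator not in ALL_INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")
    link = "log" if indicator == "tfr" else "logit"
    frame = pd.DataFrame(
        {
            "district_id": direct["district_id"],
            "value": direct[indicator],
            "sampling_variance": direct[f"{indicator}_variance"],
            "effective_size": direct["n_psu"],
        }
    )
    try:
        model = build_model(frame, auxiliaries, link=link, priors=priors)
    except ValueError as e:
        raise PipelineError(f"sae/build_model[{indicator}]: {e}") from e
    draws = gibbs_sample(model, chain)
    summary = summarize(draws)
    weights = shrinkage_weights(model, draws)
    return summary, weights, model, draws


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {
            "rounds": [r.__dict__ for r in config.rounds],
            "indicators": list(config.indicators),
            "fertility_window": config.fertility_window,
            "mortality_window": config.mortality_window,
            "priors": config.priors.__dict__,
            "chain": config.chain,
            "seed": config.seed,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stage_order": ["ingest", "validate", "tabulate", "estimate", "report"],
        "stages": {},
    }
    per_round: dict[str, dict] = {}
    auxiliaries = (
        pd.read_csv(config.auxiliaries_path)
        if config.auxiliaries_path
        else None
    )

    for i, rnd in enumerate(config.rounds):
        rdir = out / rnd.name
        rdir.mkdir(exist_ok=True)
        # stage 1: generate or ingest
        if rnd.generator is not None:
            gen = GeneratorConfig(
                **{"seed": config.seed + i, **rnd.generator}
            )
            truth = generate_truth(gen)
            women, children = simulate_microdata(truth, gen)
            aux_r = generate_auxiliaries(truth, gen)
            truth_to_frame(truth).to_csv(rdir / "truth.csv", index=False)
        elif rnd.women_path and rnd.children_path:
            women, children = read_microdata(rnd.women_path, rnd.children_path)
            aux_r = auxiliaries
        else:
            raise PipelineError(
                f"ingest[{rnd.name}]: need generator params or data paths"
            )
        # stage 2: validate
        women, children, vreport = validate_inputs(women, children)
        women.to_csv(rdir / "women.csv", index=False)
        children.to_csv(rdir / "children.csv", index=False)
        # stage 3+4: tabulate and estimate
        direct = direct_estimates(
            women,
            children,
            config.fertility_window,
            config.mortality_window,
        )
        direct.to_csv(rdir / "direct_estimates.csv", index=False)
        # stage 5: smooth
        smoothed: dict[str, pd.DataFrame] = {}
        if config.run_sae:
            if aux_r is None:
                raise PipelineError(
                    f"sae[{rnd.name}]: auxiliaries required but not provided"
                )
            aux_r.to_csv(rdir / "auxiliaries.csv", index=False)
            chain = ChainConfig(
                **{"seed": config.seed + 100 + i, **config.chain}
            )
            for ind in config.indicators:
                summary, weights, _, _ = smooth_indicator(
                    direct, aux_r, ind, config.priors, chain
                )
                tab = summary.districts.merge(
                    weights[["district_id", "weight_on_direct"]],
                    on="district_id",
                )
                tab.to_csv(rdir / f"sae_{ind}.csv", index=False)
                (rdir / f"sae_{ind}_diagnostics.json").write_text(
                    json.dumps(summary.diagnostics, default=float, indent=1)
                )
                smoothed[ind] = tab
        per_round[rnd.name] = {
            "direct": direct,
            "smoothed": smoothed,
            "validation": vreport,
        }
        manifest["stages"][rnd.name] = {
            "validation": vreport,
            "districts": int(len(direct)),
            "sae_indicators": sorted(smoothed),
        }

    # stage 6: reporting
    _report(config, out, per_round, manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _estimate_series(round_data: dict, indicator: str) -> pd.Series:
    """Smoothed posterior means when available, else direct values."""
    sm = round_data["smoothed"].get(indicator)
    if sm is not None:
        return sm["posterior_mean"]
    return round_data["direct"][indicator]


def _report(config, out: Path, per_round: dict, manifest: dict) -> None:
    names = list(per_round)
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    for name, data in per_round.items():
        est = pd.DataFrame({"district_id": data["direct"]["district_id"]})
        for ind in config.indicators:
            est[ind] = _estimate_series(data, ind).to_numpy()
        if "tfr" in est and set(MORTALITY_INDICATORS) <= set(est.columns):
            scatter_export(est, est, round_label=name).to_csv(
                report_dir / f"scatter_{name}.csv", index=False
            )
    if len(names) >= 2:
        r1, r2 = per_round[names[0]], per_round[names[1]]
        for ind in config.indicators:
            table = transition_table(
                _estimate_series(r1, ind),
                _estimate_series(r2, ind),
                DEFAULT_SCHEMES[ind],
            )
            table.to_csv(report_dir / f"transition_{ind}.csv", index=False)
            (report_dir / f"transition_{ind}.txt").write_text(
                format_transition_table(table, ind)
            )
    manifest["stages"]["report"] = {"rounds": names}
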
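"""Workflow orchestration: simulate/ingest -> metrics -> prep -> fit -> report.

All artefacts are delimited UTF-8 text with header rows; the manifest
echoes the configuration and seeds so any run can be reproduced exactly
(identical config and seed give byte-identical posterior files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import AgeSexStandardizer, SEX_COVARIATES
from .estimator import SocialMortalityModel
from .metrics import build_covariates
from .records import load_individuals, load_interactions, cohort_tally
from .simulate import AbmConfig, abm_dispersal_priors

logger = logging.getLogger(__name__)

RHAT_WARN = 1.1


@dataclass
class RunConfig:
    """Paths and settings for one full pipeline run."""

    individuals: str = ""
    covariates: str | None = None  # precomputed covariate table, or
    grooming: str | None = None  # ... raw interaction inputs for the metrics stage
    agonism: str | None = None
    effort: str | None = None
    outdir: str = "socmort_out"
    alpha: dict = field(default_factory=lambda: {"F": 5.0, "M": 7.0})
    sexes: tuple = ("F", "M")
    n_chains: int = 8
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    imputation: str = "truncated_normal"  # or "linear"
    abm: AbmConfig = field(default_factory=AbmConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "abm" in raw:
            raw["abm"] = AbmConfig(**raw["abm"])
        if "sexes" in raw:
            raw["sexes"] = tuple(raw["sexes"])
        return cls(**raw)


def posterior_frame(ps) -> pd.DataFrame:
    """Flatten a PosteriorSet into one row per retained draw."""
    names = list(ps.draws)
    n_chains, n_kept = ps.draws[names[0]].shape
    rows = {"chain": np.repeat(np.arange(n_chains), n_kept),
            "iter": np.tile(np.arange(n_kept), n_chains)}
    for n in names:
        rows[n] = ps.draws[n].ravel()
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write all artefacts to ``cfg.outdir``."""
    if not cfg.covariates and not (cfg.grooming and cfg.agonism and cfg.effort):
        raise ValueError("config must provide either covariates or all of "
                         "grooming/agonism/effort")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    individuals = load_individuals(cfg.individuals)
    tally = cohort_tally(individuals)

    if cfg.covariates:
        cov = pd.read_csv(cfg.covariates, dtype={"id": str})
    elif cfg.grooming and cfg.agonism and cfg.effort:
        grooming = load_interactions(cfg.grooming, "grooming")
        agonism = load_interactions(cfg.agonism, "agonism")
        effort = pd.read_csv(cfg.effort, dtype={"id_a": str, "id_b": str})
        cov = build_covariates(grooming, agonism, individuals, effort, alpha=cfg.alpha)
        cov.to_csv(out / "covariates.csv", index=False)
    else:
        raise ValueError("config must provide either covariates or all of "
                         "grooming/agonism/effort")

    standardizer = AgeSexStandardizer()
    cov_std = standardizer.fit_transform(cov)
    cov_std.to_csv(out / "covariates_standardized.csv", index=False)

    male_priors = abm_dispersal_priors(cfg.abm)
    summaries, rhat_all = [], {}
    models = {}
    for sex in cfg.sexes:
        if not any(r.sex == sex for r in individuals):
            logger.warning("no %s individuals; skipping", sex)
            continue
        model = SocialMortalityModel(
            sex=sex, alpha=cfg.alpha[sex], n_chains=cfg.n_chains, n_iter=cfg.n_iter,
            burn_in=cfg.burn_in, thin=cfg.thin, seed=cfg.seed + (0 if sex == "F" else 1),
            imputation=cfg.imputation,
            priors=male_priors if sex == "M" else None,
        ).fit(individuals, cov_std)
        models[sex] = model
        posterior_frame(model.posterior_).to_csv(out / f"posterior_{sex}.csv", index=False)
        s = model.summary_.copy()
        s.insert(0, "sex", sex)
        summaries.append(s)
        rhat_all.update({f"{sex}:{k}": v for k, v in model.rhat_.items()})

    summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    summary.to_csv(out / "summary.csv", index=False)

    bad_rhat = {k: v for k, v in rhat_all.items() if not (v < RHAT_WARN)}
    if bad_rhat:
        logger.warning("R-hat above %.2f for: %s", RHAT_WARN, sorted(bad_rhat))
    manifest = {
        "package_version": __version__,
        "config": _jsonable(asdict(cfg)),
        "cohort_tally": _jsonable(tally),
        "rhat": {k: (None if not np.isfinite(v) else round(float(v), 5))
                 for k, v in rhat_all.items()},
        "rhat_threshold": RHAT_WARN,
        "rhat_ok": not bad_rhat,
        "covariate_labels": {s: list(SEX_COVARIATES[s]) for s in cfg.sexes},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"summary": summary, "manifest": manifest, "models": models, "outdir": str(out)}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    return obj
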
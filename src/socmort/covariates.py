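"""Per-individual life-year trajectories and age-sex standardization.

Ages inside the model are measured from maturity: x = age - alpha with
alpha = 5 years (females) or 7 years (males).  Life-year t is the integer
age class [alpha + t, alpha + t + 1), half-open, t >= 0.  An individual's
first and last observed classes may be fractional (entry between
birthdays; death or censoring mid-year).

Covariates (DSI_F, DSI_M, proportional rank) are standardized within
(sex, covariate, life-year) strata so that values represent deviations
from sex- and age-typical levels; the stratified moments (mean, sd, min,
max, count) are also what the within-sampler truncated-normal imputation
draws from.  Standard deviations use the population (n) convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import IndividualRecord

logger = logging.getLogger(__name__)

COVARIATES = ("dsi_f", "dsi_m", "prop_rank")
#: covariate columns entering each sex's hazard (males have no DSI_M)
SEX_COVARIATES = {"F": ("dsi_f", "dsi_m", "prop_rank"), "M": ("dsi_f", "prop_rank")}


def build_life_years(rec: IndividualRecord, alpha: float, birth: float | None = None):
    """Age classes intersected with the observation window.

    Returns ``[(t, fraction_of_year_observed), ...]``; empty when the
    individual exits before maturity.
    """
    if birth is None:
        birth = rec.birth_mid
    x0 = max(rec.entry - birth, alpha) - alpha
    x1 = (rec.last - birth) - alpha
    if x1 <= 0 or x1 <= x0:
        return []
    out = []
    for t in range(int(math.floor(x0)), int(math.ceil(x1))):
        frac = min(x1, t + 1) - max(x0, t)
        if frac > 0:
            out.append((t, frac))
    return out


@dataclass
class CovariateTrajectory:
    """One individual's life-year covariate values with a missingness mask."""

    id: str
    values: np.ndarray  # (T, p)
    observed: np.ndarray  # (T, p) bool

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed mask must align")


@dataclass
class AgeSexMoments:
    """Stratified moments: (sex, covariate, life_year) -> mean/sd/min/max/count.

    ``pooled`` carries the across-age fallback per (sex, covariate), used
    when a stratum has fewer than two observed values.
    """

    table: pd.DataFrame  # columns sex, covariate, life_year, mean, sd, min, max, count
    pooled: pd.DataFrame = field(default=None)  # columns sex, covariate, mean, sd, min, max, count

    def lookup(self, sex: str, covariate: str, life_year: int):
        t = self.table
        row = t[(t["sex"] == sex) & (t["covariate"] == covariate) & (t["life_year"] == life_year)]
        if len(row) and int(row["count"].iloc[0]) >= 2:
            return row.iloc[0]
        p = self.pooled
        row = p[(p["sex"] == sex) & (p["covariate"] == covariate)]
        if not len(row):
            raise KeyError(f"no observed data for ({sex}, {covariate})")
        return row.iloc[0]


def age_sex_moments(cov: pd.DataFrame, covariates=COVARIATES) -> AgeSexMoments:
    """Stratified mean/sd/min/max/count of the *observed* covariate values.

    ``cov`` is the long table ``id,sex,life_year,<covariates>`` where NaN
    marks missing.  Empty strata carry count 0 and NaN moments.
    """
    rows, pooled_rows = [], []
    for sex, sub in cov.groupby("sex"):
        for c in covariates:
            if c not in cov.columns:
                continue
            obs_all = sub[c].dropna()
            pooled_rows.append(_moment_row(obs_all, sex=sex, covariate=c))
            for t, stratum in sub.groupby("life_year"):
                rows.append(_moment_row(stratum[c].dropna(), sex=sex, covariate=c,
                                        life_year=int(t)))
    cols = ["sex", "covariate", "life_year", "mean", "sd", "min", "max", "count"]
    table = pd.DataFrame(rows, columns=cols)
    pooled = pd.DataFrame(pooled_rows, columns=[c for c in cols if c != "life_year"])
    return AgeSexMoments(table=table, pooled=pooled)


def _moment_row(values: pd.Series, **key):
    v = values.to_numpy(dtype=float)
    if len(v) == 0:
        return {**key, "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan, "count": 0}
    return {
        **key,
        "mean": float(np.mean(v)),
        "sd": float(np.std(v)),  # population convention
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "count": int(len(v)),
    }


def age_sex_standardize(cov: pd.DataFrame, moments: AgeSexMoments,
                        covariates=COVARIATES) -> pd.DataFrame:
    """(v - mean)/sd within each (sex, covariate, life_year) stratum.

    Degenerate strata (count < 2 or sd = 0) map to 0 with a warning, so a
    lone observation carries no signal rather than a spurious one.
    """
    out = cov.copy()
    key = ["sex", "life_year"]
    n_degenerate = 0
    for c in covariates:
        if c not in out.columns:
            continue
        merged = out[key].merge(
            moments.table[moments.table["covariate"] == c],
            on=key, how="left",
        )
        mean = merged["mean"].to_numpy()
        sd = merged["sd"].to_numpy()
        count = merged["count"].fillna(0).to_numpy()
        ok = (count >= 2) & (sd > 0)
        vals = out[c].to_numpy(dtype=float)
        observed = ~np.isnan(vals)
        n_degenerate += int((observed & ~ok).sum())
        with np.errstate(invalid="ignore"):
            out[c] = np.where(observed, np.where(ok, (vals - mean) / sd, 0.0), np.nan)
    if n_degenerate:
        logger.warning("%d observed values in degenerate strata standardized to 0", n_degenerate)
    return out


class AgeSexStandardizer:
    """Transformer removing sex- and age-typical covariate levels.

    sklearn-style: ``fit`` learns stratified moments from the observed
    values of the long covariate table, ``transform`` z-scores each value
    within its (sex, covariate, life-year) stratum, ``inverse_transform``
    restores the original scale (identity on observed values in
    non-degenerate strata).
    """

    def __init__(self, covariates=COVARIATES):
        self.covariates = covariates

    def get_params(self, deep=True):
        return {"covariates": self.covariates}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, cov: pd.DataFrame, y=None):
        self.moments_ = age_sex_moments(cov, self.covariates)
        return self

    def transform(self, cov: pd.DataFrame) -> pd.DataFrame:
        return age_sex_standardize(cov, self.moments_, self.covariates)

    def fit_transform(self, cov: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(cov).transform(cov)

    def inverse_transform(self, cov: pd.DataFrame) -> pd.DataFrame:
        out = cov.copy()
        key = ["sex", "life_year"]
        for c in self.covariates:
            if c not in out.columns:
                continue
            merged = out[key].merge(
                self.moments_.table[self.moments_.table["covariate"] == c],
                on=key, how="left",
            )
            mean = merged["mean"].to_numpy()
            sd = merged["sd"].to_numpy()
            count = merged["count"].fillna(0).to_numpy()
            ok = (count >= 2) & (sd > 0)
            vals = out[c].to_numpy(dtype=float)
            out[c] = np.where(ok, vals * sd + mean, vals)
        return out


def trajectories_from_table(cov: pd.DataFrame, ids, T: int,
                            covariates=COVARIATES) -> list[CovariateTrajectory]:
    """Pivot the long covariate table into dense per-individual arrays."""
    by_id = dict(tuple(cov.groupby("id")))
    out = []
    for idv in ids:
        values = np.full((T, len(covariates)), np.nan)
        sub = by_id.get(idv)
        if sub is not None:
            for row in sub.itertuples(index=False):
                t = int(row.life_year)
                if 0 <= t < T:
                    for j, c in enumerate(covariates):
                        values[t, j] = getattr(row, c)
        out.append(CovariateTrajectory(id=str(idv), values=values, observed=~np.isnan(values)))
    return out
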
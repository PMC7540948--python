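"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-sex wild-primate study population observed
over a multi-decade window: Gompertz baseline mortality modified by
proportional hazards on age-sex-standardized social covariates,
male-only permanent out-migration (Bernoulli state, gamma-distributed
departure ages by origin class), right-censoring at the study close,
birth-date brackets for immigrants, and covariates missing before an
immigrant's entry.  Default cohort sizes, maturity ages, fate structure
and effect magnitudes mirror the published composition of the Amboseli
adult baboon cohort (265 females / 277 males, alpha = 5 / 7, immigrant
males with bracketed ages, kappa for bond strength near ln 0.72).

Covariate trajectories are a deterministic age profile (bond strength
and status peak in early adulthood and decline later) plus an AR(1)
deviation.  Lifespans are drawn by inverting the model's own
discrete-step cumulative hazard (constant hazard within each life-year),
so the simulator and the likelihood share one definition of survival.

An agent-based dispersal simulator elicits the out-migration priors:
agents disperse at empirical ages and pick a destination group uniformly
at random; choosing a non-study group means leaving the study
population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import SEX_COVARIATES
from .model import IMMIGRANT, NATAL, MortalityParams, OutMigrationParams, PriorSpec
from .records import from_decimal_year


def _default_mort():
    # baselines chosen so the default cohort reproduces the published fate
    # composition (~49/51 female death/censoring, ~39% male unknown fate);
    # kappa magnitudes sit in the published effect regime (ln 0.72 etc.)
    return {
        "F": MortalityParams(a=0.013, b=0.10, kappa=np.array([-0.462, -0.371, 0.0])),
        "M": MortalityParams(a=0.0055, b=0.13, kappa=np.array([-0.33, 0.122])),
    }


def _default_outmig():
    return OutMigrationParams(gamma_prob=[0.40, 0.25], gam_shape=[3.0, 3.0],
                              gam_rate=[2.0, 0.8])


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    n_females: int = 265
    n_males: int = 277
    alpha: dict = field(default_factory=lambda: {"F": 5.0, "M": 7.0})
    mort: dict = field(default_factory=_default_mort)
    outmig: OutMigrationParams = field(default_factory=_default_outmig)
    window_start: float = 1984.0
    window_years: float = 35.0
    #: span of calendar years over which subjects enter adulthood/immigrate;
    #: defaults to the whole window (None)
    entry_span: float | None = None
    immigrant_fraction: float = 0.585  # of males
    #: probability that a death is observed (carcass found / decline seen);
    #: an unobserved male death becomes a disappearance with unknown fate
    death_detection: dict = field(default_factory=lambda: {"F": 1.0, "M": 0.6})
    bracket_width: float = 2.0  # immigrant-male birth bracket (years)
    female_uncertain_fraction: float = 0.125
    female_bracket_width: float = 1.0
    profile_peak: float = 3.0  # life-years after maturity at which covariates peak
    profile_amp: float = 0.6
    ar_rho: float = 0.6
    ar_sd: float = 0.5
    missing_rate: float = 0.10
    T_max: int = 35
    seed: int = 0

    @property
    def window_end(self) -> float:
        return self.window_start + self.window_years


def age_profile(t, peak: float, amp: float) -> np.ndarray:
    """Sex-typical covariate level by life-year: rises to a peak in early
    adulthood then declines (gamma-shaped bump, zero asymptote)."""
    t = np.asarray(t, dtype=float)
    return amp * (t / peak) * np.exp(1.0 - t / peak)


def simulate_covariate_trajectories(cfg: SimConfig, sex: str, rng,
                                    n: int | None = None) -> np.ndarray:
    """Raw covariate paths: age profile + AR(1) deviation, (n, T, p).

    The rank column is squashed through a logistic link so emitted
    proportional ranks live in [0, 1].
    """
    labels = SEX_COVARIATES[sex]
    p = len(labels)
    single = n is None
    n = 1 if single else n
    T = cfg.T_max
    dev = np.zeros((n, T, p))
    marginal_sd = cfg.ar_sd / math.sqrt(1.0 - cfg.ar_rho**2) if cfg.ar_sd > 0 else 0.0
    if cfg.ar_sd > 0:
        dev[:, 0, :] = marginal_sd * rng.standard_normal((n, p))
        for t in range(1, T):
            dev[:, t, :] = cfg.ar_rho * dev[:, t - 1, :] + cfg.ar_sd * rng.standard_normal((n, p))
    prof = age_profile(np.arange(T), cfg.profile_peak, cfg.profile_amp)
    V = prof[None, :, None] + dev
    rank_col = labels.index("prop_rank")
    V[:, :, rank_col] = 1.0 / (1.0 + np.exp(-2.0 * (V[:, :, rank_col] - cfg.profile_amp / 2)))
    return V[0] if single else V


def _cohort_standardize(V: np.ndarray) -> np.ndarray:
    """Standardize by life-year across the cohort (population sd)."""
    mean = V.mean(axis=0, keepdims=True)
    sd = V.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (V - mean) / sd


def simulate_lifespan(mort: MortalityParams, W, rng) -> float:
    """One age at death (years since maturity) by cumulative-hazard inversion.

    Accumulates the model's discrete per-life-year hazard until it
    exceeds a standard-exponential draw, then solves the crossing point
    exactly under the within-step constant hazard.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    haz = mort.a * np.exp(mort.b * np.arange(W.shape[0]) + W @ mort.kappa)
    E = rng.exponential()
    cum = 0.0
    for t, h in enumerate(haz):
        if cum + h >= E:
            return t + (E - cum) / h
        cum += h
    return float(len(haz)) + (E - cum) / haz[-1]


def _simulate_lifespans(mort: MortalityParams, U: np.ndarray, rng,
                        x_min=None, exp_draws=None) -> np.ndarray:
    """Vectorised inversion over a cohort, U of shape (n, T, p).

    ``x_min`` conditions each draw on survival to that age (immigrants
    are alive when they enter the study population).  ``exp_draws``
    substitutes the standard-exponential deviates, e.g. stratified
    draws for variance-reduced validation.
    """
    n, T, _ = U.shape
    haz = mort.a * np.exp(mort.b * np.arange(T)[None, :] + U @ mort.kappa)
    cum = np.cumsum(haz, axis=1)
    E = rng.exponential(size=n) if exp_draws is None else np.asarray(exp_draws)
    if x_min is not None:
        x_min = np.asarray(x_min, dtype=float)
        tf = np.clip(np.floor(x_min).astype(int), 0, T - 1)
        before = np.where(tf > 0, cum[np.arange(n), np.maximum(tf - 1, 0)], 0.0)
        H_min = before + (x_min - tf) * haz[np.arange(n), tf]
        E = E + H_min
    idx = (cum < E[:, None]).sum(axis=1)
    x = np.empty(n)
    inside = idx < T
    i_in = np.nonzero(inside)[0]
    before = np.where(idx[i_in] > 0, cum[i_in, np.maximum(idx[i_in] - 1, 0)], 0.0)
    x[i_in] = idx[i_in] + (E[i_in] - before) / haz[i_in, idx[i_in]]
    i_out = np.nonzero(~inside)[0]
    x[i_out] = T + (E[i_out] - cum[i_out, -1]) / haz[i_out, -1]
    return x


def simulate_population(cfg: SimConfig):
    """Generate (individuals, covariates, truth) tables.

    individuals: ``id,sex,birth_min,birth_max,entry_date,last_date,fate,origin``
    (ISO dates).  covariates: observed ``id,sex,life_year,dsi_f,dsi_m,
    prop_rank`` with NaN where missing (immigrants lack all pre-entry
    values; observed cells drop out at the configured missingness rate).
    truth: latent birth, death age, out-migration state/age and the full
    latent covariate table, for validation only.
    """
    rng = np.random.default_rng(cfg.seed)
    ind_rows, cov_rows, truth_rows, latent_rows = [], [], [], []
    for sex, n in (("F", cfg.n_females), ("M", cfg.n_males)):
        if n == 0:
            continue
        alpha = cfg.alpha[sex]
        labels = SEX_COVARIATES[sex]
        V = simulate_covariate_trajectories(cfg, sex, rng, n=n)
        U = _cohort_standardize(V)

        immigrant = np.zeros(n, dtype=bool)
        if sex == "M":
            immigrant = rng.random(n) < cfg.immigrant_fraction
        x_entry = np.zeros(n)
        x_entry[immigrant] = rng.gamma(2.0, 1.0, size=int(immigrant.sum()))
        # death conditioned on being alive at study entry (left truncation)
        x_death = _simulate_lifespans(cfg.mort[sex], U, rng, x_min=x_entry)
        # maturity/entry spread across the recruitment span
        span = min(cfg.entry_span or cfg.window_years, cfg.window_years)
        e_cal = rng.uniform(cfg.window_start, cfg.window_start + span - 0.1, size=n)
        birth = e_cal - alpha - x_entry
        x_cens = (cfg.window_end - birth) - alpha

        o = np.zeros(n, dtype=int)
        x_mig = np.full(n, np.inf)
        if sex == "M":
            j = np.where(immigrant, IMMIGRANT, NATAL)
            o = (rng.random(n) < np.asarray(cfg.outmig.gamma_prob)[j]).astype(int)
            for i in np.nonzero(o)[0]:
                shape = cfg.outmig.gam_shape[j[i]]
                rate = cfg.outmig.gam_rate[j[i]]
                z = rng.gamma(shape, 1.0 / rate)
                for _ in range(200):  # departure cannot precede entry
                    if z > x_entry[i]:
                        break
                    z = rng.gamma(shape, 1.0 / rate)
                else:
                    o[i] = 0
                    continue
                x_mig[i] = z

        x_exit = np.minimum(np.minimum(x_death, x_cens), x_mig)
        cause = np.where(x_exit == x_death, "death",
                         np.where(x_exit == x_cens, "censored", "migration"))
        fate = np.where(cause == "migration", "unknown", cause)
        # deaths missed by observers are disappearances with unknown fate
        detect = cfg.death_detection.get(sex, 1.0)
        missed = (cause == "death") & (rng.random(n) >= detect)
        fate = np.where(missed, "unknown", fate)

        for i in range(n):
            idv = f"{sex}{i:04d}"
            b = birth[i]
            bmin = bmax = b
            w = 0.0
            if sex == "M" and immigrant[i]:
                w = cfg.bracket_width
            elif sex == "F" and rng.random() < cfg.female_uncertain_fraction:
                w = cfg.female_bracket_width
            if w > 0:
                u = rng.uniform(0, w)
                bmin, bmax = b - u, b + (w - u)
                bmax = min(bmax, e_cal[i] - alpha)  # age at entry stays >= alpha
                bmax = max(bmax, b)
            last_cal = b + alpha + x_exit[i]
            ind_rows.append({
                "id": idv, "sex": sex,
                "birth_min": from_decimal_year(bmin),
                "birth_max": from_decimal_year(bmax),
                "entry_date": from_decimal_year(e_cal[i]),
                "last_date": from_decimal_year(last_cal),
                "fate": fate[i],
                "origin": "immigrant" if (sex == "M" and immigrant[i]) else "natal",
            })
            truth_rows.append({
                "id": idv, "sex": sex, "birth": b,
                "x_entry": x_entry[i], "x_exit": x_exit[i],
                "x_death": x_death[i],
                "o": int(o[i]),
                "x_mig": x_mig[i] if np.isfinite(x_mig[i]) else np.nan,
                "cause": cause[i],
                "fate": fate[i],
            })
            t_lo = int(math.floor(x_entry[i]))
            t_hi = min(int(math.floor(x_exit[i])), cfg.T_max - 1)
            # an observer bins life-years by the estimated (bracket-midpoint)
            # birth, so emitted indices shift for uncertain-age subjects
            shift = int(np.rint(b - 0.5 * (bmin + bmax)))
            for t in range(0, t_hi + 1):
                vals = {c: np.nan for c in ("dsi_f", "dsi_m", "prop_rank")}
                lat = {c: np.nan for c in ("dsi_f", "dsi_m", "prop_rank")}
                for cidx, c in enumerate(labels):
                    lat[c] = V[i, t, cidx]
                    if t >= t_lo and rng.random() >= cfg.missing_rate:
                        vals[c] = V[i, t, cidx]
                latent_rows.append({"id": idv, "sex": sex, "life_year": t, **lat})
                t_apparent = t + shift
                if (t >= t_lo and t_apparent >= 0
                        and any(not np.isnan(v) for v in vals.values())):
                    cov_rows.append({"id": idv, "sex": sex,
                                     "life_year": t_apparent, **vals})

    individuals = pd.DataFrame(ind_rows)
    covariates = pd.DataFrame(
        cov_rows, columns=["id", "sex", "life_year", "dsi_f", "dsi_m", "prop_rank"])
    truth = {
        "individuals": pd.DataFrame(truth_rows),
        "latent_covariates": pd.DataFrame(
            latent_rows, columns=["id", "sex", "life_year", "dsi_f", "dsi_m", "prop_rank"]),
        "config": cfg,
    }
    return individuals, covariates, truth


# ---------------------------------------------------------------------------
# interaction-level generator
# ---------------------------------------------------------------------------

def simulate_interactions(cfg: SimConfig, individuals: pd.DataFrame,
                          latent: pd.DataFrame, rng, n_groups: int = 2,
                          grooming_rate: float = 2.0, bond_effect: float = 1.0,
                          pair_prob: float = 0.35, steepness: float = 4.0):
    """Grooming, agonism and effort tables consistent with the latent state.

    Dyadic grooming counts are Poisson with log-rate increasing in the
    two members' latent bond values; decided agonistic outcomes are
    Bernoulli favouring the higher latent rank with the given steepness
    (a logistic contest on the rank difference).  Intended for cohorts of
    a few hundred individuals; cost grows with dyads x life-years.
    """
    from .records import to_decimal_year

    info = individuals.set_index("id")
    ids = list(individuals["id"])
    sex = info["sex"].to_dict()
    birth = {i: to_decimal_year(info.loc[i, "birth_min"]) * 0.5
             + to_decimal_year(info.loc[i, "birth_max"]) * 0.5 for i in ids}
    entry = {i: to_decimal_year(info.loc[i, "entry_date"]) for i in ids}
    last = {i: to_decimal_year(info.loc[i, "last_date"]) for i in ids}
    group = {i: f"G{rng.integers(n_groups)}" for i in ids}
    lat = {(r.id, int(r.life_year)): r for r in latent.itertuples(index=False)}

    def zval(i, t, col):
        row = lat.get((i, t))
        if row is None:
            return None
        v = getattr(row, col)
        return None if (isinstance(v, float) and math.isnan(v)) else float(v)

    groom_rows, effort_rows, agon_rows = [], [], []
    for fi in ids:
        af = cfg.alpha[sex[fi]]
        t0 = int(math.floor(max(entry[fi] - birth[fi], af) - af))
        t1 = int(math.floor((last[fi] - birth[fi]) - af))
        for t in range(max(t0, 0), min(t1, cfg.T_max - 1) + 1):
            y0 = birth[fi] + af + t
            y1 = y0 + 1.0
            zf = zval(fi, t, "dsi_f")
            if zf is None:
                continue
            for pj in ids:
                if pj == fi or group[pj] != group[fi]:
                    continue
                if sex[fi] == "M" and sex[pj] == "M":
                    continue
                ap = cfg.alpha[sex[pj]]
                lo = max(y0, entry[pj], birth[pj] + ap, entry[fi])
                hi = min(y1, last[pj], last[fi])
                overlap = hi - lo
                if overlap <= 0.05:
                    continue
                tp = int(math.floor((0.5 * (lo + hi) - birth[pj]) - ap))
                zp = zval(pj, max(tp, 0), "dsi_f")
                if zp is None:
                    zp = 0.0
                lam = grooming_rate * overlap * math.exp(bond_effect * 0.5 * (zf + zp))
                count = rng.poisson(lam)
                effort_rows.append({"id_a": fi, "id_b": pj, "life_year": t,
                                    "effort": overlap})
                for _ in range(count):
                    swap = rng.random() < 0.5
                    a, b = (fi, pj) if swap else (pj, fi)
                    groom_rows.append({"date": rng.uniform(lo, hi), "actor": a,
                                       "recipient": b, "group": group[fi]})
    # monthly agonistic contests per (group, sex)
    n_months = int(cfg.window_years * 12)
    for m in range(n_months):
        y = cfg.window_start + (m + 0.5) / 12.0
        for g in {group[i] for i in ids}:
            for sx in ("F", "M"):
                members = [i for i in ids
                           if group[i] == g and sex[i] == sx
                           and entry[i] <= y <= last[i]
                           and (y - birth[i]) >= cfg.alpha[sx]]
                for ai in range(len(members)):
                    for bi in range(ai + 1, len(members)):
                        if rng.random() >= pair_prob:
                            continue
                        i1, i2 = members[ai], members[bi]
                        t1_ = int(math.floor((y - birth[i1]) - cfg.alpha[sx]))
                        t2_ = int(math.floor((y - birth[i2]) - cfg.alpha[sx]))
                        r1 = zval(i1, t1_, "prop_rank") or 0.5
                        r2 = zval(i2, t2_, "prop_rank") or 0.5
                        p_win = 1.0 / (1.0 + math.exp(-steepness * (r1 - r2)))
                        w, l = (i1, i2) if rng.random() < p_win else (i2, i1)
                        agon_rows.append({"date": y, "winner": w, "loser": l,
                                          "group": g, "decided": True})
    from .records import from_decimal_year_array

    grooming = pd.DataFrame(groom_rows, columns=["date", "actor", "recipient", "group"])
    agonism = pd.DataFrame(agon_rows, columns=["date", "winner", "loser", "group", "decided"])
    for df in (grooming, agonism):
        if len(df):
            df["year"] = df["date"].astype(float)
            df["date"] = from_decimal_year_array(df["year"])
        else:
            df["year"] = pd.Series(dtype=float)
    effort = pd.DataFrame(effort_rows, columns=["id_a", "id_b", "life_year", "effort"])
    return grooming, agonism, effort


# ---------------------------------------------------------------------------
# agent-based dispersal simulator -> out-migration priors
# ---------------------------------------------------------------------------

def _default_natal_ages():
    # plausible ages (years) at first (natal) dispersal for male baboons
    return (7.5, 8.0, 8.3, 8.7, 9.0, 9.4, 9.8, 10.3, 11.0, 8.5, 9.1, 8.9)


def _default_higher_ages():
    # ages at second and subsequent dispersals
    return (9.5, 10.5, 11.2, 12.0, 13.0, 10.8, 12.5, 14.0, 11.6, 12.8)


@dataclass
class AbmConfig:
    n_study_groups: int = 5
    n_nonstudy_groups: int = 10
    natal_ages: tuple = field(default_factory=_default_natal_ages)
    higher_ages: tuple = field(default_factory=_default_higher_ages)
    n_agents: int = 10000
    alpha: float = 7.0
    prior_strength: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_study_groups < 1 or self.n_nonstudy_groups < 0:
            raise ValueError("need >= 1 study group and >= 0 non-study groups")
        if not len(self.natal_ages) or not len(self.higher_ages):
            raise ValueError("dispersal-age samples must be non-empty")


def abm_dispersal_priors(cfg: AbmConfig) -> PriorSpec:
    """Elicit out-migration priors from the dispersal agent simulation.

    Each agent disperses at an age resampled from the empirical sample
    and picks a destination uniformly among all groups; leaving the study
    population means choosing a non-study group.  The fraction leaving
    becomes Beta pseudo-counts (scaled by ``prior_strength``) for the
    Bernoulli out-migration probability, and the ages at leaving (since
    maturity) are moment-matched to a gamma, supplying truncated-normal
    prior centres for shape and rate.
    """
    rng = np.random.default_rng(cfg.seed)
    n_groups = cfg.n_study_groups + cfg.n_nonstudy_groups
    beta = np.empty((2, 2))
    shape_prior = np.empty((2, 2))
    rate_prior = np.empty((2, 2))
    eps = 1e-3
    for j, sample in ((NATAL, cfg.natal_ages), (IMMIGRANT, cfg.higher_ages)):
        ages = rng.choice(np.asarray(sample, dtype=float), size=cfg.n_agents, replace=True)
        dest = rng.integers(n_groups, size=cfg.n_agents)
        left = dest >= cfg.n_study_groups
        frac = float(left.mean())
        beta[j] = [max(frac * cfg.prior_strength, eps),
                   max((1.0 - frac) * cfg.prior_strength, eps)]
        left_ages = ages[left] if left.any() else ages
        x = np.clip(left_ages - cfg.alpha, 0.1, None)
        m = float(np.mean(x))
        v = max(float(np.var(x)), 1e-8)
        shape_c = m * m / v
        rate_c = m / v
        shape_prior[j] = [shape_c, max(shape_c, 0.5)]
        rate_prior[j] = [rate_c, max(rate_c, 0.5)]
    return PriorSpec(gamma_prob_beta=beta, gam_shape_prior=shape_prior,
                     gam_rate_prior=rate_prior)
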
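"""Metropolis-Hastings-within-Gibbs sampler for the mortality model.

Each iteration, in fixed order: (1) re-derive age-sex stratum moments
under the current imputed births, (2) impute missing covariates from
truncated normals bounded by the stratum extrema, (3) Gibbs-draw the
latent out-migration indicators, (4) Metropolis-update uncertain birth
dates (uniform independence proposals inside the bracket; exposure,
ages and the life-year binning of observed covariates shift with the
proposal), (5) random-walk Metropolis updates of a, b, kappa and the
out-migration parameters (log-scale with Jacobian for positive-domain
parameters, logit-scale for probabilities).

Proposal scales adapt by Robbins-Monro recursion toward ~0.3 acceptance
during burn-in only and are frozen afterwards, preserving detailed
balance for the retained draws.  Convergence is assessed with the
classic (non-split) Gelman-Rubin potential scale reduction factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ndtr, ndtri
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from . import model as mm
from .covariates import SEX_COVARIATES, AgeSexMoments, CovariateTrajectory
from .model import NATAL, IMMIGRANT, PriorSpec
from .records import IndividualRecord

logger = logging.getLogger(__name__)

DEATH, CENSORED, UNKNOWN = 0, 1, 2
_FATE_CODE = {"death": DEATH, "censored": CENSORED, "unknown": UNKNOWN}


@dataclass
class ChainConfig:
    n_chains: int = 8
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    adapt: bool = True
    proposal_scales: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.burn_in > self.n_iter:
            raise ValueError("burn_in must not exceed n_iter")
        if self.burn_in == self.n_iter:
            logger.warning("burn_in == n_iter: no draws will be retained")


@dataclass
class PosteriorSet:
    """Retained draws and diagnostics from a multi-chain run."""

    draws: dict  # parameter -> (n_chains, n_kept)
    acceptance: dict  # parameter -> mean acceptance rate
    rhat: dict  # parameter -> potential scale reduction factor
    ids: list
    o_mean: np.ndarray | None = None  # posterior mean out-migration state per individual
    birth_mean: np.ndarray | None = None
    labels: tuple = ()

    def stacked(self, name: str) -> np.ndarray:
        return np.concatenate([c for c in self.draws[name]])


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def truncated_normal(mean, sd, lo, hi, rng) -> np.ndarray:
    """Vectorised truncated-normal draws via inverse-CDF.

    Degenerate cells (sd <= 0, or numerically empty support) return the
    mean clipped into [lo, hi]; draws never leave the bounds.
    """
    shape = np.broadcast_shapes(*(np.shape(v) for v in (mean, sd, lo, hi)))
    mean, sd, lo, hi = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, dtype=float)) for v in (mean, sd, lo, hi)))
    out = np.clip(mean, lo, hi).copy()
    ok = (sd > 0) & (hi > lo)
    if np.any(ok):
        with np.errstate(divide="ignore", invalid="ignore"):
            plo = ndtr((lo[ok] - mean[ok]) / sd[ok])
            phi = ndtr((hi[ok] - mean[ok]) / sd[ok])
        u = plo + (phi - plo) * rng.random(plo.shape)
        width = phi - plo
        good = width > 1e-14
        x = np.where(good, mean[ok] + sd[ok] * ndtri(np.clip(u, 1e-15, 1 - 1e-15)),
                     np.clip(mean[ok], lo[ok], hi[ok]))
        out[ok] = np.clip(x, lo[ok], hi[ok])
    return out.reshape(shape) if shape else float(out[0])


def mh_update(current: float, log_posterior, scale: float, rng,
              positive: bool = False) -> float:
    """One Metropolis-Hastings step with a Gaussian random-walk proposal.

    Positive-domain parameters random-walk on the log scale, with the
    log(proposal/current) Jacobian term in the acceptance ratio.
    """
    lp_cur = log_posterior(current)
    if not np.isfinite(lp_cur):
        raise ValueError("log-posterior not finite at the current value")
    if positive:
        prop = current * math.exp(scale * rng.standard_normal())
        log_ratio = log_posterior(prop) - lp_cur + math.log(prop / current)
    else:
        prop = current + scale * rng.standard_normal()
        log_ratio = log_posterior(prop) - lp_cur
    if math.log(rng.random()) < log_ratio:
        return prop
    return current


def update_birth_age(rec: IndividualRecord, current_birth: float, loglik, rng) -> float:
    """Metropolis update of an uncertain birth inside its bracket.

    Uniform independence proposal (symmetric within the bracket); a
    degenerate bracket is never updated.  ``loglik`` maps a candidate
    birth to the individual's log-likelihood.
    """
    if rec.birth_min == rec.birth_max:
        return current_birth
    prop = rng.uniform(rec.birth_min, rec.birth_max)
    if math.log(rng.random()) < loglik(prop) - loglik(current_birth):
        return prop
    return current_birth


def update_outmig_states(probs, rng) -> np.ndarray:
    """Gibbs draw of out-migration indicators: o ~ Bernoulli(p), elementwise."""
    p = np.asarray(probs, dtype=float)
    return (rng.random(p.shape) < p).astype(int)


def impute_missing_covariates(trajectories, moments: AgeSexMoments, rng, sex: str,
                              covariates=None) -> list[CovariateTrajectory]:
    """Fill missing trajectory cells with truncated-normal draws.

    Each missing cell draws once from its (sex, covariate, life-year)
    stratum; strata with fewer than two observations fall back to the
    moments pooled across ages within sex.  Draws never leave the
    stratum [min, max]; fully observed trajectories return unchanged.
    """
    covariates = covariates or SEX_COVARIATES[sex]
    out = []
    for traj in trajectories:
        values = traj.values.copy()
        missing = np.argwhere(~traj.observed)
        for t, j in missing:
            row = moments.lookup(sex, covariates[j], int(t))
            values[t, j] = float(
                truncated_normal(row["mean"], row["sd"], row["min"], row["max"], rng))
        out.append(CovariateTrajectory(id=traj.id, values=values,
                                       observed=traj.observed.copy()))
    return out


def impute_linear(values: np.ndarray) -> np.ndarray:
    """Fill gaps in a 1-D trajectory by linear interpolation.

    Interior gaps interpolate between the nearest observed life-years;
    leading/trailing gaps take the nearest observed value.  All-missing
    input is an error.
    """
    v = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(v)
    if not obs.any():
        raise ValueError("cannot interpolate an all-missing trajectory")
    idx = np.arange(len(v))
    v[~obs] = np.interp(idx[~obs], idx[obs], v[obs])
    return v


def rhat(chains) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` is (m, n) with m >= 2 chains of n >= 2 draws.  Zero
    within-chain variance returns +inf as a degeneracy marker.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    n = c.shape[1]
    within = float(np.mean(np.var(c, axis=1, ddof=1)))
    if within == 0.0:
        return float("inf")
    b_over_n = float(np.var(np.mean(c, axis=1), ddof=1))
    v_hat = (n - 1) / n * within + b_over_n
    return math.sqrt(v_hat / within)


def split_rhat(chains) -> float:
    """Split-half variant: each chain halved before the classic statistic."""
    c = np.asarray(chains, dtype=float)
    half = c.shape[1] // 2
    return rhat(np.vstack([c[:, :half], c[:, half:2 * half]]))


# ---------------------------------------------------------------------------
# cohort data, vectorised likelihood
# ---------------------------------------------------------------------------

class FitData:
    """Dense arrays for one sex's cohort, built once before sampling.

    Observed (standardized) covariate values are stored flat with the
    life-year index they received under the bracket-midpoint birth;
    under a different imputed birth the binning shifts by the nearest
    whole year and values are re-scattered into the (n, T, p) grid.
    """

    def __init__(self, records, cov_std, sex, alpha, outmigration_enabled=None):
        labels = SEX_COVARIATES[sex]
        recs = [r for r in records if r.sex == sex]
        keep = []
        for r in recs:
            if (r.last - r.birth_min) - alpha > 0:
                keep.append(r)
        dropped = len(recs) - len(keep)
        if dropped:
            logger.info("%s cohort: %d individuals exit before maturity, excluded", sex, dropped)
        # midpoint birth must already give a usable observation window
        keep = [r for r in keep if (r.last - r.birth_mid) - alpha > 0]
        self.records = keep
        self.sex = sex
        self.alpha = float(alpha)
        self.labels = labels
        self.p = len(labels)
        self.n = len(keep)
        self.ids = [r.id for r in keep]
        self.entry = np.array([r.entry for r in keep])
        self.last = np.array([r.last for r in keep])
        self.birth_min = np.array([r.birth_min for r in keep])
        self.birth_max = np.array([r.birth_max for r in keep])
        self.birth_mid = np.array([r.birth_mid for r in keep])
        self.uncertain = self.birth_min < self.birth_max
        self.fate = np.array([_FATE_CODE[r.fate] for r in keep])
        self.origin_j = np.array([mm.origin_index(r) for r in keep])
        if outmigration_enabled is None:
            outmigration_enabled = sex == "M"
        self.outmig = bool(outmigration_enabled)
        if (self.fate == UNKNOWN).any() and not self.outmig:
            raise ValueError("unknown-fate individuals present but out-migration disabled")
        x_upper = (self.last - self.birth_min) - alpha
        self.T = max(1, int(math.ceil(x_upper.max())) + 1) if self.n else 1
        self.tgrid = np.arange(self.T, dtype=float)

        # flat observed values, binned under birth_mid
        obs_i, obs_t, obs_j, obs_v = [], [], [], []
        index = {idv: i for i, idv in enumerate(self.ids)}
        if cov_std is not None and len(cov_std):
            sub = cov_std[cov_std["id"].astype(str).isin(index)]
            for row in sub.itertuples(index=False):
                i = index[str(row.id)]
                t = int(row.life_year)
                if not 0 <= t < self.T:
                    continue
                for j, c in enumerate(labels):
                    v = getattr(row, c)
                    if v is not None and not (isinstance(v, float) and math.isnan(v)):
                        obs_i.append(i)
                        obs_t.append(t)
                        obs_j.append(j)
                        obs_v.append(float(v))
        self.obs_i = np.array(obs_i, dtype=int)
        self.obs_t = np.array(obs_t, dtype=int)
        self.obs_j = np.array(obs_j, dtype=int)
        self.obs_v = np.array(obs_v, dtype=float)
        if self.n and not len(self.obs_v):
            raise ValueError(f"no observed covariate values for sex {sex}")
        # pooled (across ages) fallback moments per covariate
        self.pooled = np.full((self.p, 4), np.nan)  # mean, sd, lo, hi
        for j in range(self.p):
            v = self.obs_v[self.obs_j == j]
            if len(v) == 0:
                raise ValueError(f"no observed data for covariate {labels[j]} in sex {sex}")
            self.pooled[j] = [v.mean(), v.std(), v.min(), v.max()]

    # -- geometry -----------------------------------------------------------

    def ages(self, births):
        x_entry = np.maximum(self.entry - births, self.alpha) - self.alpha
        x_last = (self.last - births) - self.alpha
        return x_entry, x_last

    def exposure(self, x_entry, x_last):
        t = self.tgrid
        return np.clip(
            np.minimum(x_last[:, None], t + 1.0) - np.maximum(x_entry[:, None], t),
            0.0, 1.0)

    def scatter_observed(self, delta) -> np.ndarray:
        """(n, T, p) grid of observed values under integer binning shifts."""
        W = np.full((self.n, self.T, self.p), np.nan)
        if len(self.obs_i):
            t_idx = self.obs_t + delta[self.obs_i]
            ok = (t_idx >= 0) & (t_idx < self.T)
            W[self.obs_i[ok], t_idx[ok], self.obs_j[ok]] = self.obs_v[ok]
        return W

    def stratum_moments(self, W_obs):
        """Per-(life-year, covariate) mean/sd/lo/hi with pooled fallback."""
        mask = ~np.isnan(W_obs)
        cnt = mask.sum(axis=0)  # (T, p)
        tot = np.where(mask, W_obs, 0.0).sum(axis=0)
        sq = np.where(mask, W_obs**2, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = tot / cnt
            sd = np.sqrt(np.clip(sq / cnt - mean**2, 0.0, None))
        lo = np.where(mask, W_obs, np.inf).min(axis=0)
        hi = np.where(mask, W_obs, -np.inf).max(axis=0)
        use = cnt >= 2
        mean = np.where(use, mean, self.pooled[:, 0])
        sd = np.where(use, sd, self.pooled[:, 1])
        lo = np.where(use, lo, self.pooled[:, 2])
        hi = np.where(use, hi, self.pooled[:, 3])
        return mean, sd, lo, hi

    def draw_base(self, moments, rng) -> np.ndarray:
        """One truncated-normal draw for every grid cell (observed cells
        are overlaid afterwards, so a fully observed cohort ignores these)."""
        mean, sd, lo, hi = moments
        shape = (self.n, self.T, self.p)
        return truncated_normal(
            np.broadcast_to(mean, shape), np.broadcast_to(sd, shape),
            np.broadcast_to(lo, shape), np.broadcast_to(hi, shape), rng)

    def overlay(self, W_base, delta) -> np.ndarray:
        W = W_base.copy()
        if len(self.obs_i):
            t_idx = self.obs_t + delta[self.obs_i]
            ok = (t_idx >= 0) & (t_idx < self.T)
            W[self.obs_i[ok], t_idx[ok], self.obs_j[ok]] = self.obs_v[ok]
        return W

    def linear_fill(self) -> np.ndarray:
        """Alternate imputation: per-individual linear interpolation of the
        observed values, applied once at preparation (filled values are
        then treated as data, only within each observation window)."""
        delta = np.zeros(self.n, dtype=int)
        W = self.scatter_observed(delta)
        x_entry, x_last = self.ages(self.birth_mid)
        for i in range(self.n):
            hi = min(self.T, int(math.floor(x_last[i])) + 1)
            for j in range(self.p):
                seg = W[i, :hi, j]
                if np.isnan(seg).all():
                    W[i, :hi, j] = self.pooled[j, 0]
                else:
                    W[i, :hi, j] = impute_linear(seg)
                if hi < self.T:
                    W[i, hi:, j] = W[i, hi - 1, j]
        return W

    # -- vectorised likelihood ---------------------------------------------

    def per_individual_loglik(self, births, o, W, a, b, kappa,
                              gamma_prob=None, gam_shape=None, gam_rate=None):
        """(n,) log-likelihood vector; -inf for incoherent birth proposals."""
        x_entry, x_last = self.ages(births)
        bad = (x_last < x_entry) | (x_last <= 0)
        E = self.exposure(x_entry, x_last)
        kw = W @ kappa  # (n, T)
        dH = a * np.sum(np.exp(np.minimum(b * self.tgrid + kw, 50.0)) * E, axis=1)
        tl = np.clip(np.floor(x_last).astype(int), 0, self.T - 1)
        logh = math.log(a) + b * x_last + kw[np.arange(self.n), tl]
        deathlike = (self.fate == DEATH) | ((self.fate == UNKNOWN) & (o == 0))
        ll = -dH + np.where(deathlike, logh, 0.0)
        if self.outmig:
            g = np.asarray(gamma_prob)[self.origin_j]
            s = np.asarray(gam_shape)[self.origin_j]
            r = np.asarray(gam_rate)[self.origin_j]
            known = self.fate != UNKNOWN
            unk = ~known
            with np.errstate(divide="ignore", invalid="ignore"):
                log1mg = np.log1p(-np.clip(g, None, 1.0 - 1e-300))
                logg = np.log(np.clip(g, 1e-300, None))
                lpdf = (s * np.log(r) - gammaln(s)
                        + (s - 1.0) * np.log(np.clip(x_last, 1e-300, None)) - r * x_last)
            ll = ll + np.where(known | (unk & (o == 0)), log1mg, 0.0)
            ll = ll + np.where(unk & (o == 1), logg + lpdf, 0.0)
        return np.where(bad, -np.inf, ll)

    def state_probs(self, births, W, a, b, kappa, gamma_prob, gam_shape, gam_rate):
        """Vectorised P(o=1 | rest) for the unknown-fate individuals."""
        x_entry, x_last = self.ages(births)
        kw = W @ kappa
        tl = np.clip(np.floor(x_last).astype(int), 0, self.T - 1)
        h_last = a * np.exp(b * x_last + kw[np.arange(self.n), tl])
        g = np.asarray(gamma_prob)[self.origin_j]
        s = np.asarray(gam_shape)[self.origin_j]
        r = np.asarray(gam_rate)[self.origin_j]
        gpdf = np.exp(s * np.log(r) - gammaln(s)
                      + (s - 1.0) * np.log(np.clip(x_last, 1e-300, None)) - r * x_last)
        A = g * gpdf
        B = (1.0 - g) * h_last
        tot = A + B
        with np.errstate(invalid="ignore"):
            p = np.where(tot > 0, A / np.where(tot > 0, tot, 1.0), 0.5)
        return p


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

def _init_state(data: FitData, prior: PriorSpec, rng):
    x_entry, x_last = data.ages(data.birth_mid)
    exposure = float(np.sum(x_last - x_entry))
    n_death = int(np.sum(data.fate == DEATH))
    a0 = max(n_death, 1) / max(exposure, 1.0)
    state = {
        "a": a0 * math.exp(0.3 * rng.standard_normal()),
        "b": 0.1 * math.exp(0.3 * rng.standard_normal()),
        "kappa": 0.05 * rng.standard_normal(data.p),
        "births": data.birth_mid.copy(),
        "o": np.zeros(data.n, dtype=int),
    }
    unc = data.uncertain
    state["births"][unc] = rng.uniform(data.birth_min[unc], data.birth_max[unc])
    # keep the initial window usable
    bad = (data.last - state["births"]) - data.alpha <= 0
    state["births"][bad] = data.birth_mid[bad]
    if data.outmig:
        pm = prior.gamma_prob_beta[:, 0] / prior.gamma_prob_beta.sum(axis=1)
        state["gamma_prob"] = np.clip(pm + 0.05 * rng.standard_normal(2), 0.02, 0.98)
        state["gam_shape"] = prior.gam_shape_prior[:, 0] * np.exp(0.1 * rng.standard_normal(2))
        state["gam_rate"] = prior.gam_rate_prior[:, 0] * np.exp(0.1 * rng.standard_normal(2))
        unk = data.fate == UNKNOWN
        state["o"][unk] = (rng.random(int(unk.sum())) < 0.5).astype(int)
    else:
        state["gamma_prob"] = np.zeros(2)
        state["gam_shape"] = np.ones(2)
        state["gam_rate"] = np.ones(2)
    return state


def _param_names(data: FitData):
    names = ["a", "b"] + [f"kappa_{c}" for c in data.labels]
    if data.outmig:
        for base in ("gamma_prob", "gam_shape", "gam_rate"):
            names += [f"{base}_natal", f"{base}_immigrant"]
        # joint shape-rate scale moves (not recorded; mixing only)
        names += ["gam_scale_natal", "gam_scale_immigrant"]
    return names


def run_chain(data: FitData, config: ChainConfig, seed, prior: PriorSpec | None = None,
              imputation: str = "truncated_normal") -> dict:
    """One chain; returns retained draws, acceptance rates and latent means."""
    prior = prior or PriorSpec()
    rng = np.random.default_rng(seed)
    st = _init_state(data, prior, rng)
    names = _param_names(data)
    scales = {n: config.proposal_scales.get(n, 0.15) for n in names}
    acc = {n: 0 for n in names}
    tries = {n: 0 for n in names}
    kept = {n: [] for n in names}
    n_kept_target = (config.n_iter - config.burn_in) // config.thin
    o_sum = np.zeros(data.n)
    birth_sum = np.zeros(data.n)
    n_acc_birth = 0
    n_try_birth = 0
    W_linear = data.linear_fill() if imputation == "linear" else None
    unk = data.fate == UNKNOWN
    unc = data.uncertain

    def mig_ll(gamma_prob, gam_shape, gam_rate, x_last):
        if not data.outmig:
            return 0.0
        g = gamma_prob[data.origin_j]
        s = gam_shape[data.origin_j]
        r = gam_rate[data.origin_j]
        known = data.fate != UNKNOWN
        o = st["o"]
        with np.errstate(divide="ignore"):
            log1mg = np.log1p(-np.clip(g, None, 1 - 1e-300))
            logg = np.log(np.clip(g, 1e-300, None))
        lpdf = (s * np.log(r) - gammaln(s)
                + (s - 1.0) * np.log(np.clip(x_last, 1e-300, None)) - r * x_last)
        tot = np.sum(np.where(known | (unk & (o == 0)), log1mg, 0.0))
        tot += np.sum(np.where(unk & (o == 1), logg + lpdf, 0.0))
        return float(tot)

    for it in range(config.n_iter):
        adapt_now = config.adapt and it < config.burn_in
        gain = (it + 1) ** -0.6

        def tune(name, acc_prob):
            if adapt_now:
                scales[name] = float(np.clip(
                    scales[name] * math.exp(gain * (acc_prob - 0.3)), 1e-4, 50.0))

        # (1)-(2) moments under current births; impute
        delta = np.rint(data.birth_mid - st["births"]).astype(int)
        if imputation == "linear":
            W = W_linear
        else:
            W_obs = data.scatter_observed(delta)
            moments = data.stratum_moments(W_obs)
            W_base = data.draw_base(moments, rng)
            W = data.overlay(W_base, delta)

        # (3) Gibbs out-migration states
        if data.outmig and unk.any():
            p1 = data.state_probs(st["births"], W, st["a"], st["b"], st["kappa"],
                                  st["gamma_prob"], st["gam_shape"], st["gam_rate"])
            st["o"][unk] = update_outmig_states(p1[unk], rng)

        # (4) birth-age Metropolis (uniform independence proposal in bracket)
        if unc.any():
            args = (st["a"], st["b"], st["kappa"],
                    st["gamma_prob"], st["gam_shape"], st["gam_rate"])
            ll_cur = data.per_individual_loglik(st["births"], st["o"], W, *args)
            prop = st["births"].copy()
            prop[unc] = rng.uniform(data.birth_min[unc], data.birth_max[unc])
            if imputation == "linear":
                W_prop = W
            else:
                delta_prop = np.rint(data.birth_mid - prop).astype(int)
                W_prop = data.overlay(W_base, delta_prop)
            ll_prop = data.per_individual_loglik(prop, st["o"], W_prop, *args)
            with np.errstate(invalid="ignore"):
                accept = unc & (np.log(rng.random(data.n)) < (ll_prop - ll_cur))
            st["births"][accept] = prop[accept]
            n_acc_birth += int(accept.sum())
            n_try_birth += int(unc.sum())
            if accept.any() and imputation != "linear":
                delta = np.rint(data.birth_mid - st["births"]).astype(int)
                W = data.overlay(W_base, delta)

        # (5) parameter updates; geometry now fixed for this iteration
        x_entry, x_last = data.ages(st["births"])
        E = data.exposure(x_entry, x_last)
        tl = np.clip(np.floor(x_last).astype(int), 0, data.T - 1)
        deathlike = (data.fate == DEATH) | ((data.fate == UNKNOWN) & (st["o"] == 0))
        n_deathlike = int(deathlike.sum())
        idx = np.arange(data.n)

        kw = W @ st["kappa"]
        ewE = np.exp(np.clip(kw, -50, 50)) * E

        def mort_ll(a, b, kw_arr=None, ewE_arr=None):
            kwa = kw if kw_arr is None else kw_arr
            ew = ewE if ewE_arr is None else ewE_arr
            dH = a * float(np.sum(ew @ np.exp(b * data.tgrid)))
            logh = n_deathlike * math.log(a) + float(
                np.sum((b * x_last + kwa[idx, tl])[deathlike]))
            return logh - dH

        # a, b: log-scale random walks
        for name in ("a", "b"):
            cur = st[name]
            prop_v = cur * math.exp(scales[name] * rng.standard_normal())
            if name == "a":
                d = (mort_ll(prop_v, st["b"]) - mort_ll(cur, st["b"])
                     + mm._half_normal_logpdf(prop_v, prior.a_scale)
                     - mm._half_normal_logpdf(cur, prior.a_scale))
            else:
                d = (mort_ll(st["a"], prop_v) - mort_ll(st["a"], cur)
                     + mm._half_normal_logpdf(prop_v, prior.b_scale)
                     - mm._half_normal_logpdf(cur, prior.b_scale))
            d += math.log(prop_v / cur)
            ap = min(1.0, math.exp(min(d, 0.0)) if np.isfinite(d) else 0.0)
            tries[name] += 1
            if rng.random() < ap:
                st[name] = prop_v
                acc[name] += 1
            tune(name, ap)

        # kappa components: plain random walks
        for c in range(data.p):
            name = f"kappa_{data.labels[c]}"
            cur = st["kappa"][c]
            prop_v = cur + scales[name] * rng.standard_normal()
            kap = st["kappa"].copy()
            kap[c] = prop_v
            kw_p = kw + (prop_v - cur) * W[:, :, c]
            ewE_p = np.exp(np.clip(kw_p, -50, 50)) * E
            d = (mort_ll(st["a"], st["b"], kw_p, ewE_p)
                 - mort_ll(st["a"], st["b"])
                 + norm.logpdf(prop_v, 0, prior.kappa_sd)
                 - norm.logpdf(cur, 0, prior.kappa_sd))
            ap = min(1.0, math.exp(min(d, 0.0)) if np.isfinite(d) else 0.0)
            tries[name] += 1
            if rng.random() < ap:
                st["kappa"] = kap
                kw = kw_p
                ewE = ewE_p
                acc[name] += 1
            tune(name, ap)

        # out-migration parameters
        if data.outmig:
            for j, tag in ((NATAL, "natal"), (IMMIGRANT, "immigrant")):
                # gamma_prob: logit random walk
                name = f"gamma_prob_{tag}"
                cur = st["gamma_prob"][j]
                z = math.log(cur / (1 - cur)) + scales[name] * rng.standard_normal()
                prop_v = 1.0 / (1.0 + math.exp(-z))
                gp = st["gamma_prob"].copy()
                gp[j] = prop_v
                a0, b0 = prior.gamma_prob_beta[j]
                d = (mig_ll(gp, st["gam_shape"], st["gam_rate"], x_last)
                     - mig_ll(st["gamma_prob"], st["gam_shape"], st["gam_rate"], x_last)
                     + float(beta_dist.logpdf(prop_v, a0, b0) - beta_dist.logpdf(cur, a0, b0))
                     + math.log(prop_v * (1 - prop_v)) - math.log(cur * (1 - cur)))
                ap = min(1.0, math.exp(min(d, 0.0)) if np.isfinite(d) else 0.0)
                tries[name] += 1
                if rng.random() < ap:
                    st["gamma_prob"] = gp
                    acc[name] += 1
                tune(name, ap)
                # gamma shape and rate: log random walks
                for base, pr in (("gam_shape", prior.gam_shape_prior),
                                 ("gam_rate", prior.gam_rate_prior)):
                    name = f"{base}_{tag}"
                    cur = st[base][j]
                    prop_v = cur * math.exp(scales[name] * rng.standard_normal())
                    vec = st[base].copy()
                    vec[j] = prop_v
                    kwargs = {"gam_shape": vec if base == "gam_shape" else st["gam_shape"],
                              "gam_rate": vec if base == "gam_rate" else st["gam_rate"]}
                    d = (mig_ll(st["gamma_prob"], kwargs["gam_shape"], kwargs["gam_rate"], x_last)
                         - mig_ll(st["gamma_prob"], st["gam_shape"], st["gam_rate"], x_last)
                         + mm._trunc_normal_logpdf(prop_v, *pr[j])
                         - mm._trunc_normal_logpdf(cur, *pr[j])
                         + math.log(prop_v / cur))
                    ap = min(1.0, math.exp(min(d, 0.0)) if np.isfinite(d) else 0.0)
                    tries[name] += 1
                    if rng.random() < ap:
                        st[base] = vec
                        acc[name] += 1
                    tune(name, ap)
                # joint scale move along the shape-rate ridge (mean-preserving)
                name = f"gam_scale_{tag}"
                c = math.exp(scales[name] * rng.standard_normal())
                sh = st["gam_shape"].copy()
                ra = st["gam_rate"].copy()
                sh[j] *= c
                ra[j] *= c
                d = (mig_ll(st["gamma_prob"], sh, ra, x_last)
                     - mig_ll(st["gamma_prob"], st["gam_shape"], st["gam_rate"], x_last)
                     + mm._trunc_normal_logpdf(sh[j], *prior.gam_shape_prior[j])
                     - mm._trunc_normal_logpdf(st["gam_shape"][j], *prior.gam_shape_prior[j])
                     + mm._trunc_normal_logpdf(ra[j], *prior.gam_rate_prior[j])
                     - mm._trunc_normal_logpdf(st["gam_rate"][j], *prior.gam_rate_prior[j])
                     + 2.0 * math.log(c))
                ap = min(1.0, math.exp(min(d, 0.0)) if np.isfinite(d) else 0.0)
                tries[name] += 1
                if rng.random() < ap:
                    st["gam_shape"] = sh
                    st["gam_rate"] = ra
                    acc[name] += 1
                tune(name, ap)

        # retain
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept["a"].append(st["a"])
            kept["b"].append(st["b"])
            for c in range(data.p):
                kept[f"kappa_{data.labels[c]}"].append(st["kappa"][c])
            if data.outmig:
                for j, tag in ((NATAL, "natal"), (IMMIGRANT, "immigrant")):
                    kept[f"gamma_prob_{tag}"].append(st["gamma_prob"][j])
                    kept[f"gam_shape_{tag}"].append(st["gam_shape"][j])
                    kept[f"gam_rate_{tag}"].append(st["gam_rate"][j])
            o_sum += st["o"]
            birth_sum += st["births"]

    n_ret = len(kept["a"])
    if n_ret != n_kept_target:
        logger.warning("retained %d draws, expected %d", n_ret, n_kept_target)
    out = {
        "draws": {n: np.array(v) for n, v in kept.items()},
        "acceptance": {n: (acc[n] / tries[n] if tries[n] else float("nan")) for n in names},
        "o_mean": o_sum / max(n_ret, 1),
        "birth_mean": birth_sum / max(n_ret, 1),
    }
    out["acceptance"]["birth"] = n_acc_birth / n_try_birth if n_try_birth else float("nan")
    return out


def run_chains(data: FitData, config: ChainConfig, prior: PriorSpec | None = None,
               imputation: str = "truncated_normal") -> PosteriorSet:
    """Run ``config.n_chains`` chains with seeds derived from ``config.seed``."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [run_chain(data, config, s, prior=prior, imputation=imputation)
              for s in children]
    names = _param_names(data)
    draws = {n: np.vstack([c["draws"][n] for c in chains]) for n in names
             if chains[0]["draws"][n].size}
    rh = {}
    for n, arr in draws.items():
        rh[n] = rhat(arr) if arr.shape[0] >= 2 and arr.shape[1] >= 2 else float("nan")
    acceptance = {k: float(np.nanmean([c["acceptance"][k] for c in chains]))
                  for k in chains[0]["acceptance"]}
    o_mean = np.mean([c["o_mean"] for c in chains], axis=0)
    birth_mean = np.mean([c["birth_mean"] for c in chains], axis=0)
    return PosteriorSet(draws=draws, acceptance=acceptance, rhat=rh, ids=data.ids,
                        o_mean=o_mean, birth_mean=birth_mean, labels=data.labels)


def summarize_posterior(ps: PosteriorSet):
    """Summary table: median, 68% and 95% credible intervals, R-hat, and
    for each kappa the hazard-effect translation 100*(1 - exp(kappa))
    (percent change in mortality hazard per +1 SD of the covariate).

    Quantiles interpolate linearly between order statistics.
    """
    import pandas as pd

    rows = []
    for name, arr in ps.draws.items():
        flat = arr.ravel()
        if not flat.size:
            continue
        q = np.quantile(flat, [0.025, 0.16, 0.5, 0.84, 0.975])
        row = {
            "parameter": name,
            "median": q[2],
            "lo68": q[1], "hi68": q[3],
            "lo95": q[0], "hi95": q[4],
            "rhat": ps.rhat.get(name, float("nan")),
        }
        if name.startswith("kappa_"):
            row["hazard_effect_pct"] = 100.0 * (1.0 - math.exp(q[2]))
            row["hazard_effect_lo95"] = 100.0 * (1.0 - math.exp(q[4]))
            row["hazard_effect_hi95"] = 100.0 * (1.0 - math.exp(q[0]))
        else:
            row["hazard_effect_pct"] = float("nan")
            row["hazard_effect_lo95"] = float("nan")
            row["hazard_effect_hi95"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
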
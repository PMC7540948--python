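"""Gompertz proportional-hazards mortality with out-migration mixture.

Model, on the age scale x = age - alpha (alpha = maturity age):

* baseline hazard   mu(x) = a * exp(b x),           a, b > 0
* covariate hazard  h(x | w_x) = mu(x) * exp(kappa . w_x)
* cumulative hazard H(x | W) approximated by a discrete sum with 1-year
  steps (the left endpoint of each life-year supplies both mu and w),
  with a fractional final step for non-integer x
* survival          S(x | W) = exp(-H(x | W))
* death density     f(x | W) = h(x | w_x) S(x | W)

Every individual's likelihood is left-truncated at study entry (division
by S(x_entry)).  Males may permanently leave the study population
("out-migration"): a Bernoulli state O (probability gamma_prob[j], with
j = natal or immigrant) selects between death and departure, and ages at
departure follow a gamma distribution per origin class.  For subjects
last seen alive with unknown fate, O is latent and sampled within the
MCMC; known-fate subjects of a dispersing sex contribute the Bernoulli
complement (they demonstrably did not leave).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .records import IndividualRecord

logger = logging.getLogger(__name__)

NATAL, IMMIGRANT = 0, 1


@dataclass
class MortalityParams:
    a: float  # baseline mortality (per year)
    b: float  # Gompertz rate (per year)
    kappa: np.ndarray  # proportional-hazards coefficients, one per covariate

    def __post_init__(self):
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"require a > 0 and b > 0, got a={self.a}, b={self.b}")
        if not np.all(np.isfinite(self.kappa)):
            raise ValueError("kappa must be finite")


@dataclass
class OutMigrationParams:
    """Bernoulli departure probabilities and gamma age parameters.

    Index 0 = natal (first departure of subjects present at maturity),
    index 1 = immigrant (departures of subjects who joined after
    maturity).  Gamma ages are measured from maturity (x-scale) and
    parametrised by shape and rate.
    """

    gamma_prob: np.ndarray  # (2,)
    gam_shape: np.ndarray  # (2,)
    gam_rate: np.ndarray  # (2,)

    def __post_init__(self):
        self.gamma_prob = np.asarray(self.gamma_prob, dtype=float)
        self.gam_shape = np.asarray(self.gam_shape, dtype=float)
        self.gam_rate = np.asarray(self.gam_rate, dtype=float)
        if np.any((self.gamma_prob < 0) | (self.gamma_prob > 1)):
            raise ValueError("gamma_prob must lie in [0, 1]")
        if np.any(self.gam_shape <= 0) or np.any(self.gam_rate <= 0):
            raise ValueError("gamma shape and rate must be positive")


@dataclass
class LatentState:
    """Current MCMC imputations for one individual."""

    birth: float | None = None  # imputed birth (decimal year) when uncertain
    o: int | None = None  # out-migration indicator, fate == unknown only
    imputed: dict = field(default_factory=dict)  # (life_year, covariate) -> value


# ---------------------------------------------------------------------------
# hazard / survival primitives
# ---------------------------------------------------------------------------

def gompertz_hazard(a: float, b: float, x) -> np.ndarray | float:
    """Baseline hazard mu(x) = a exp(b x)."""
    if not (a > 0 and b > 0):
        raise ValueError(f"require a > 0 and b > 0, got a={a}, b={b}")
    return a * np.exp(b * np.asarray(x, dtype=float))


def hazard_tv(params: MortalityParams, w_x, x) -> float:
    """h(x | w_x) = mu(x) exp(kappa . w_x)."""
    w = np.asarray(w_x, dtype=float)
    if w.shape != params.kappa.shape:
        raise ValueError(f"covariate dimension {w.shape} != kappa {params.kappa.shape}")
    return float(gompertz_hazard(params.a, params.b, x) * math.exp(float(params.kappa @ w)))


def cumulative_hazard(params: MortalityParams, W, x: float) -> float:
    """Discrete 1-year-step approximation of H(x | W).

    Left-endpoint rule: whole life-years contribute h(t | w_t) * 1 and
    the final fractional interval contributes h(floor(x) | w_floor(x))
    * (x - floor(x)).  ``W`` must supply a row for every integer
    t <= floor(x) (rows must be fully imputed; NaN raises).
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    tl = int(math.floor(x))
    frac = x - tl
    need = tl + 1 if frac > 0 else tl
    if W.shape[0] < need or np.isnan(W[:need]).any():
        raise ValueError("covariate matrix W missing rows/values needed for H(x)")
    H = 0.0
    for t in range(tl):
        H += hazard_tv(params, W[t], t)
    if frac > 0:
        H += hazard_tv(params, W[tl], tl) * frac
    return H


def survival(H: float) -> float:
    """S = exp(-H), H >= 0."""
    if H < 0:
        raise ValueError("cumulative hazard must be >= 0")
    return math.exp(-H)


def death_density(params: MortalityParams, W, x: float) -> float:
    """f(x | W) = h(x | w_floor(x)) S(x | W)."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    h = hazard_tv(params, W[int(math.floor(x))], x)
    return h * survival(cumulative_hazard(params, W, x))


def outmig_density(z: float, j: int, params: OutMigrationParams) -> float:
    """Gamma density of ages (since maturity) at out-migration, class j."""
    if z < 0:
        raise ValueError("out-migration age must be >= 0")
    return float(stats.gamma.pdf(z, a=params.gam_shape[j], scale=1.0 / params.gam_rate[j]))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _ages(rec: IndividualRecord, birth: float, alpha: float):
    x_entry = max(rec.entry - birth, alpha) - alpha
    x_last = (rec.last - birth) - alpha
    if x_last < x_entry:
        raise ValueError(f"{rec.id}: last-seen age precedes entry age")
    return x_entry, x_last


def origin_index(rec: IndividualRecord) -> int:
    return NATAL if rec.origin == "natal" else IMMIGRANT


def individual_loglik(rec: IndividualRecord, latent: LatentState | None, W,
                      mort: MortalityParams, outm: OutMigrationParams | None,
                      alpha: float, outmigration_enabled: bool = False) -> float:
    """Log-likelihood contribution of one individual.

    Branches by fate: observed death (density over survival-to-entry),
    censoring (survival ratio), and unknown fate via the current latent
    out-migration indicator o.  When out-migration is enabled for the
    sex, known-fate subjects additionally contribute log(1 - gamma_prob)
    for their origin class.
    """
    birth = latent.birth if (latent is not None and latent.birth is not None) else rec.birth_mid
    x_entry, x_last = _ages(rec, birth, alpha)
    H_entry = cumulative_hazard(mort, W, x_entry)
    H_last = cumulative_hazard(mort, W, x_last)
    ll = -(H_last - H_entry)
    j = origin_index(rec)
    if rec.fate == "death":
        ll += math.log(hazard_tv(mort, np.atleast_2d(W)[int(math.floor(x_last))], x_last))
        if outmigration_enabled:
            ll += math.log1p(-outm.gamma_prob[j])
    elif rec.fate == "censored":
        if outmigration_enabled:
            ll += math.log1p(-outm.gamma_prob[j])
    elif rec.fate == "unknown":
        if not outmigration_enabled:
            raise ValueError(f"{rec.id}: unknown fate requires out-migration machinery")
        o = latent.o if latent is not None else None
        if o is None:
            raise ValueError(f"{rec.id}: unknown fate requires a latent o indicator")
        if o == 0:  # died at last-seen age
            ll += math.log1p(-outm.gamma_prob[j])
            ll += math.log(hazard_tv(mort, np.atleast_2d(W)[int(math.floor(x_last))], x_last))
        else:  # out-migrated at last-seen age, alive at departure
            g = outmig_density(x_last, j, outm)
            ll += math.log(outm.gamma_prob[j]) + (math.log(g) if g > 0 else -np.inf)
    return ll


def state_posterior_prob(rec: IndividualRecord, W, mort: MortalityParams,
                         outm: OutMigrationParams, alpha: float,
                         birth: float | None = None) -> float:
    """P(o = 1 | data): out-migration vs death for an unknown-fate subject.

    p = A / (A + B) with A = gamma_prob * g_j(x_last) * S(x_last) and
    B = (1 - gamma_prob) * f(x_last); A = B = 0 degenerates to 0.5.
    """
    if rec.fate != "unknown":
        raise ValueError("state posterior defined only for unknown fate")
    if birth is None:
        birth = rec.birth_mid
    _, x_last = _ages(rec, birth, alpha)
    j = origin_index(rec)
    S = survival(cumulative_hazard(mort, W, x_last))
    A = outm.gamma_prob[j] * outmig_density(x_last, j, outm) * S
    B = (1.0 - outm.gamma_prob[j]) * death_density(mort, W, x_last)
    if A == 0.0 and B == 0.0:
        logger.warning("%s: degenerate out-migration state support, p = 0.5", rec.id)
        return 0.5
    return A / (A + B)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Hyperparameters of the (vague) priors.

    a and b: half-normal on (0, inf); kappa: zero-mean normal; the
    out-migration Bernoulli probability: Beta pseudo-counts elicited from
    the agent-based dispersal simulator; gamma shape/rate: truncated
    normals centred on the simulator's moment-matched values.
    """

    a_scale: float = 1.0
    b_scale: float = 0.5
    kappa_sd: float = 10.0
    gamma_prob_beta: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 1.0], [1.0, 1.0]]))  # (2, 2): per j (alpha0, beta0)
    gam_shape_prior: np.ndarray = field(
        default_factory=lambda: np.array([[2.0, 2.0], [2.0, 2.0]]))  # (2, 2): per j (centre, sd)
    gam_rate_prior: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 1.0], [1.0, 1.0]]))

    def __post_init__(self):
        self.gamma_prob_beta = np.asarray(self.gamma_prob_beta, dtype=float)
        self.gam_shape_prior = np.asarray(self.gam_shape_prior, dtype=float)
        self.gam_rate_prior = np.asarray(self.gam_rate_prior, dtype=float)


def _half_normal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(stats.norm.logpdf(x, 0.0, scale) + math.log(2.0))


def _trunc_normal_logpdf(x: float, centre: float, sd: float) -> float:
    if x <= 0:
        return -np.inf
    z = stats.norm.logpdf(x, centre, sd)
    log_norm = math.log(stats.norm.sf(0.0, centre, sd))
    return float(z - log_norm)


def log_prior(mort: MortalityParams, outm: OutMigrationParams | None,
              prior: PriorSpec) -> float:
    """Sum of independent log prior densities; -inf outside domains."""
    lp = _half_normal_logpdf(mort.a, prior.a_scale)
    lp += _half_normal_logpdf(mort.b, prior.b_scale)
    lp += float(np.sum(stats.norm.logpdf(mort.kappa, 0.0, prior.kappa_sd)))
    if outm is not None:
        for j in (NATAL, IMMIGRANT):
            a0, b0 = prior.gamma_prob_beta[j]
            g = outm.gamma_prob[j]
            if not 0.0 <= g <= 1.0:
                return -np.inf
            if a0 == 1.0 and b0 == 1.0:
                pass  # uniform contributes 0
            else:
                lp += float(stats.beta.logpdf(np.clip(g, 1e-12, 1 - 1e-12), a0, b0))
            lp += _trunc_normal_logpdf(outm.gam_shape[j], *prior.gam_shape_prior[j])
            lp += _trunc_normal_logpdf(outm.gam_rate[j], *prior.gam_rate_prior[j])
    return lp
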
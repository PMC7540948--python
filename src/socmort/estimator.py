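"""Estimator interface to the Bayesian mortality model.

``SocialMortalityModel`` wraps the full fitting workflow for one sex
behind the familiar fit/predict surface: construct with hyperparameters,
``fit`` on a registry plus a standardized covariate table, then read the
posterior from trailing-underscore attributes.  It composes with
scikit-learn tooling (``get_params``/``set_params``, ``clone``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .covariates import SEX_COVARIATES
from .mcmc import ChainConfig, FitData, run_chains, summarize_posterior
from .model import MortalityParams, OutMigrationParams, PriorSpec


class SocialMortalityModel(BaseEstimator):
    """Gompertz proportional-hazards survival with social covariates.

    Parameters
    ----------
    sex : 'F' or 'M'
        Cohort to fit.  Covariates are (DSI_F, DSI_M, rank) for females
        and (DSI_F, rank) for males; out-migration machinery is enabled
        for males only unless overridden.
    alpha : float, optional
        Maturity age in years (default 5 for females, 7 for males).
    n_chains, n_iter, burn_in, thin, seed, adapt
        MCMC schedule (defaults 8 chains x 5000 iterations, burn-in 1000).
    imputation : 'truncated_normal' or 'linear'
        Within-sampler truncated-normal imputation (re-drawn each
        iteration) or one-shot linear interpolation at preparation.
    priors : PriorSpec, optional
        Vague priors by default; out-migration hyperparameters are
        typically elicited from the agent-based dispersal simulator.

    Attributes
    ----------
    posterior_ : PosteriorSet
    summary_ : DataFrame with median, 68%/95% CIs, R-hat and the
        hazard-effect translation 100*(1 - exp(kappa)) per covariate.
    rhat_ : dict, mortality_params_ : MortalityParams (posterior medians),
    outmigration_params_ : OutMigrationParams or None.
    """

    def __init__(self, sex="F", alpha=None, n_chains=8, n_iter=5000, burn_in=1000,
                 thin=1, seed=0, adapt=True, imputation="truncated_normal",
                 priors=None, enable_outmigration=None):
        self.sex = sex
        self.alpha = alpha
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.adapt = adapt
        self.imputation = imputation
        self.priors = priors
        self.enable_outmigration = enable_outmigration

    def fit(self, individuals, covariates: pd.DataFrame):
        """Sample the posterior for one sex's cohort.

        ``individuals`` is a list of IndividualRecord; ``covariates`` the
        long standardized table ``id,sex,life_year,<covariates>``.
        """
        alpha = self.alpha if self.alpha is not None else {"F": 5.0, "M": 7.0}[self.sex]
        data = FitData(individuals, covariates, sex=self.sex, alpha=alpha,
                       outmigration_enabled=self.enable_outmigration)
        config = ChainConfig(n_chains=self.n_chains, n_iter=self.n_iter,
                             burn_in=self.burn_in, thin=self.thin,
                             seed=self.seed, adapt=self.adapt)
        prior = self.priors or PriorSpec()
        self.data_ = data
        self.posterior_ = run_chains(data, config, prior=prior, imputation=self.imputation)
        self.summary_ = summarize_posterior(self.posterior_)
        self.rhat_ = dict(self.posterior_.rhat)
        med = {r["parameter"]: r["median"] for _, r in self.summary_.iterrows()}
        self.mortality_params_ = MortalityParams(
            a=med["a"], b=med["b"],
            kappa=np.array([med[f"kappa_{c}"] for c in SEX_COVARIATES[self.sex]]))
        if data.outmig:
            self.outmigration_params_ = OutMigrationParams(
                gamma_prob=[med["gamma_prob_natal"], med["gamma_prob_immigrant"]],
                gam_shape=[med["gam_shape_natal"], med["gam_shape_immigrant"]],
                gam_rate=[med["gam_rate_natal"], med["gam_rate_immigrant"]])
        else:
            self.outmigration_params_ = None
        return self

    def predict_survival(self, W, ages) -> np.ndarray:
        """Survival S(x | W) at posterior-median parameters.

        ``W`` is a (T, p) covariate matrix on the standardized scale and
        ``ages`` an array of ages since maturity.
        """
        from .model import cumulative_hazard, survival

        return np.array([
            survival(cumulative_hazard(self.mortality_params_, W, float(x)))
            for x in np.atleast_1d(ages)
        ])

    def predict_hazard(self, W, ages) -> np.ndarray:
        """Hazard h(x | w_floor(x)) at posterior-median parameters."""
        from .model import hazard_tv

        W = np.atleast_2d(W)
        return np.array([
            hazard_tv(self.mortality_params_, W[int(np.floor(x))], float(x))
            for x in np.atleast_1d(ages)
        ])
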
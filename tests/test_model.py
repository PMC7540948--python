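import math

import numpy as np
import pytest
from scipy import integrate, stats

from conftest import make_record
from socmort import model as mm
from socmort.model import (LatentState, MortalityParams, OutMigrationParams,
                           PriorSpec, cumulative_hazard, death_density,
                           gompertz_hazard, hazard_tv, individual_loglik,
                           log_prior, outmig_density, state_posterior_prob,
                           survival)


class TestGompertzHazard:
    def test_baseline_at_maturity(self):
        assert gompertz_hazard(0.02, 0.1, 0.0) == pytest.approx(0.02)

    def test_direct_evaluation(self):
        assert gompertz_hazard(0.02, 0.1, 10.0) == pytest.approx(0.02 * math.e)

    def test_exponential_ratio_identity(self, rng):
        a, b = 0.05, 0.2
        for x in rng.uniform(0, 20, size=5):
            ratio = gompertz_hazard(a, b, x + 3.0) / gompertz_hazard(a, b, x)
            assert ratio == pytest.approx(math.exp(b * 3.0))

    @pytest.mark.parametrize("a, b", [(-0.1, 0.1), (0.0, 0.1), (0.1, 0.0)])
    def test_domain_errors(self, a, b):
        with pytest.raises(ValueError):
            gompertz_hazard(a, b, 1.0)


class TestHazardTV:
    def test_null_effect_identity(self, rng):
        p = MortalityParams(a=0.03, b=0.1, kappa=np.zeros(3))
        for _ in range(5):
            w = rng.normal(size=3)
            assert hazard_tv(p, w, 4.0) == pytest.approx(gompertz_hazard(0.03, 0.1, 4.0))

    def test_28_percent_reduction_convention(self):
        # kappa = ln 0.72 for a +1 SD covariate is a 28% hazard reduction
        p = MortalityParams(a=0.03, b=0.1, kappa=np.array([math.log(0.72), 0.0]))
        ratio = hazard_tv(p, [1.0, 0.0], 2.0) / gompertz_hazard(0.03, 0.1, 2.0)
        assert ratio == pytest.approx(0.72)

    def test_scalar_arithmetic(self):
        p = MortalityParams(a=1.0, b=1e-12, kappa=np.array([0.5]))
        assert hazard_tv(p, [-2.0], 0.0) == pytest.approx(math.exp(-1.0))

    def test_dimension_mismatch(self):
        p = MortalityParams(a=0.1, b=0.1, kappa=np.array([0.5]))
        with pytest.raises(ValueError, match="dimension"):
            hazard_tv(p, [1.0, 2.0], 0.0)


class TestCumulativeHazard:
    @pytest.mark.parametrize("a", [0.005, 0.05])
    @pytest.mark.parametrize("b", [0.05, 0.2])
    @pytest.mark.parametrize("x", [1, 4, 13])
    def test_geometric_series_closed_form(self, a, b, x):
        p = MortalityParams(a=a, b=b, kappa=np.zeros(1))
        W = np.zeros((x + 1, 1))
        closed = a * (math.exp(b * x) - 1.0) / (math.exp(b) - 1.0)
        assert cumulative_hazard(p, W, float(x)) == pytest.approx(closed, abs=1e-12)

    def test_empty_sum_at_zero(self):
        p = MortalityParams(a=0.1, b=0.1, kappa=np.zeros(1))
        assert cumulative_hazard(p, np.zeros((1, 1)), 0.0) == 0.0

    def test_piecewise_covariates_hand_example(self):
        # w0=0, w1=1, kappa=ln 2, a=0.1, b->0, x=2: H = 0.1 + 0.2 = 0.3
        p = MortalityParams(a=0.1, b=1e-13, kappa=np.array([math.log(2.0)]))
        W = np.array([[0.0], [1.0], [0.0]])
        assert cumulative_hazard(p, W, 2.0) == pytest.approx(0.3, abs=1e-9)

    def test_missing_covariate_row_is_error(self):
        p = MortalityParams(a=0.1, b=0.1, kappa=np.zeros(1))
        W = np.array([[0.0], [np.nan], [0.0]])
        with pytest.raises(ValueError, match="missing"):
            cumulative_hazard(p, W, 1.5)

    def test_agrees_with_numerical_integration(self, rng):
        """The discrete sum is the exact integral of the piecewise-constant
        hazard h(floor(s) | w_floor(s))."""
        p = MortalityParams(a=0.02, b=0.12, kappa=np.array([-0.3, 0.2]))
        W = rng.normal(size=(12, 2))
        x = 10.6

        def step_hazard(s):
            return hazard_tv(p, W[int(math.floor(s))], math.floor(s))

        quad, _ = integrate.quad(step_hazard, 0.0, x,
                                 points=[t for t in range(11) if t < x], limit=200)
        assert cumulative_hazard(p, W, x) == pytest.approx(quad, abs=1e-10)


class TestSurvivalAndDensity:
    def test_survival_identities(self):
        assert survival(0.0) == 1.0
        with pytest.raises(ValueError):
            survival(-0.1)

    def test_survival_non_increasing(self, rng):
        p = MortalityParams(a=0.03, b=0.15, kappa=np.array([0.4]))
        W = rng.normal(size=(25, 1))
        xs = np.linspace(0, 20, 41)
        S = [survival(cumulative_hazard(p, W, x)) for x in xs]
        assert all(s1 >= s2 for s1, s2 in zip(S, S[1:]))

    def test_exponential_special_case_density(self):
        # b -> 0, w = 0: f(x) = a exp(-a x) on the integer grid
        a = 0.07
        p = MortalityParams(a=a, b=1e-11, kappa=np.zeros(1))
        W = np.zeros((15, 1))
        for x in (1.0, 5.0, 12.0):
            assert death_density(p, W, x) == pytest.approx(a * math.exp(-a * x), rel=1e-6)


class TestOutmigDensity:
    def test_exponential_special_case(self):
        p = OutMigrationParams(gamma_prob=[0.5, 0.5], gam_shape=[1.0, 1.0],
                               gam_rate=[0.7, 0.7])
        assert outmig_density(2.0, 0, p) == pytest.approx(0.7 * math.exp(-1.4))

    def test_mode_location(self):
        p = OutMigrationParams(gamma_prob=[0.5, 0.5], gam_shape=[3.0, 3.0],
                               gam_rate=[2.0, 2.0])
        zs = np.linspace(0.01, 6, 2000)
        dens = [outmig_density(z, 0, p) for z in zs]
        assert zs[int(np.argmax(dens))] == pytest.approx((3.0 - 1.0) / 2.0, abs=0.01)

    def test_direct_evaluation(self):
        p = OutMigrationParams(gamma_prob=[0.5, 0.5], gam_shape=[2.0, 2.0],
                               gam_rate=[0.5, 0.5])
        assert outmig_density(2.0, 1, p) == pytest.approx(0.25 * 2 * math.exp(-1.0), rel=1e-12)

    def test_negative_age_error(self):
        p = OutMigrationParams(gamma_prob=[0.5, 0.5], gam_shape=[2.0, 2.0],
                               gam_rate=[0.5, 0.5])
        with pytest.raises(ValueError):
            outmig_density(-0.1, 0, p)


def independent_gompertz_loglik(a, b, x_entry, x_death):
    """Covariate-free reference implementation on the same discrete grid,
    written with plain loops, independent of the package internals."""
    def H(x):
        total, t = 0.0, 0
        while t < math.floor(x):
            total += a * math.exp(b * t)
            t += 1
        return total + a * math.exp(b * math.floor(x)) * (x - math.floor(x))

    return math.log(a * math.exp(b * x_death)) - H(x_death) + H(x_entry)


class TestIndividualLoglik:
    mort = MortalityParams(a=0.04, b=0.12, kappa=np.zeros(1))
    outm = OutMigrationParams(gamma_prob=[0.4, 0.3], gam_shape=[3.0, 2.5],
                              gam_rate=[2.0, 0.8])

    def test_censored_at_entry_is_zero(self):
        rec = make_record(sex="F", birth=2000.0, entry=2006.0, last=2006.0,
                          fate="censored")
        W = np.zeros((3, 1))
        assert individual_loglik(rec, None, W, self.mort, None, 5.0) == pytest.approx(0.0)

    def test_covariate_free_death_matches_reference(self):
        rec = make_record(sex="M", birth=2000.0, entry=2008.3, last=2015.7,
                          fate="death", origin="immigrant")
        W = np.zeros((10, 1))
        got = individual_loglik(rec, None, W, self.mort, None, 7.0)
        want = independent_gompertz_loglik(0.04, 0.12, 1.3, 8.7)
        assert got == pytest.approx(want, abs=1e-8)

    def test_out_migration_marginalisation(self):
        """Summing the two latent branches equals the analytic mixture
        (1-g) f(x) + g G(x) S(x), each term computed independently."""
        rec = make_record(sex="M", birth=2000.0, entry=2007.0, last=2011.4,
                          fate="unknown", origin="natal")
        mort = MortalityParams(a=0.03, b=0.1, kappa=np.array([0.25]))
        W = np.linspace(-1, 1, 6).reshape(-1, 1)
        branches = [
            individual_loglik(rec, LatentState(o=o), W, mort, self.outm, 7.0,
                              outmigration_enabled=True)
            for o in (0, 1)
        ]
        total = np.logaddexp(*branches)
        x = 4.4
        S_ratio = survival(cumulative_hazard(mort, W, x))
        f = death_density(mort, W, x)
        g = self.outm.gamma_prob[0]
        gd = stats.gamma.pdf(x, a=3.0, scale=0.5)
        expected = math.log((1 - g) * f + g * gd * S_ratio)
        assert total == pytest.approx(expected, abs=1e-12)

    def test_known_fate_contributes_bernoulli_complement(self):
        rec = make_record(sex="M", birth=2000.0, entry=2007.0, last=2012.0,
                          fate="censored", origin="natal")
        W = np.zeros((6, 1))
        off = individual_loglik(rec, None, W, self.mort, self.outm, 7.0,
                                outmigration_enabled=False)
        on = individual_loglik(rec, None, W, self.mort, self.outm, 7.0,
                               outmigration_enabled=True)
        assert on - off == pytest.approx(math.log1p(-0.4))

    def test_last_seen_before_entry_is_error(self):
        rec = make_record(sex="F", birth=2000.0, entry=2008.0, last=2007.0,
                          fate="death")
        rec = rec.__class__(**{**rec.__dict__})  # frozen dataclass copy
        with pytest.raises(ValueError):
            individual_loglik(rec, None, np.zeros((5, 1)), self.mort, None, 5.0)


class TestStatePosterior:
    mort = MortalityParams(a=0.03, b=0.1, kappa=np.zeros(1))

    def rec(self, last=2012.0):
        return make_record(sex="M", birth=2000.0, entry=2007.0, last=last,
                           fate="unknown", origin="natal")

    def outm(self, g):
        return OutMigrationParams(gamma_prob=[g, g], gam_shape=[3.0, 3.0],
                                  gam_rate=[1.0, 1.0])

    def test_zero_probability_when_no_migration(self):
        W = np.zeros((8, 1))
        assert state_posterior_prob(self.rec(), W, self.mort, self.outm(0.0), 7.0) == 0.0

    def test_one_when_migration_certain(self):
        W = np.zeros((8, 1))
        assert state_posterior_prob(self.rec(), W, self.mort, self.outm(1.0), 7.0) == 1.0

    def test_monotone_in_gamma_prob(self):
        W = np.zeros((8, 1))
        ps = [state_posterior_prob(self.rec(), W, self.mort, self.outm(g), 7.0)
              for g in np.linspace(0.05, 0.95, 10)]
        assert all(p1 < p2 for p1, p2 in zip(ps, ps[1:]))

    def test_degenerate_support_gives_half(self):
        rec = make_record(sex="M", birth=2000.0, entry=2007.0, last=2007.0,
                          fate="unknown", origin="natal")
        W = np.zeros((2, 1))
        p = state_posterior_prob(rec, W, self.mort, self.outm(1.0), 7.0)
        assert p == 0.5  # g(0) = 0 for shape > 1 and (1-g) = 0


class TestLogPrior:
    def test_uniform_beta_contributes_nothing(self):
        prior = PriorSpec()  # gamma_prob Beta(1, 1)
        mort = MortalityParams(a=0.05, b=0.1, kappa=np.zeros(2))
        o1 = OutMigrationParams(gamma_prob=[0.2, 0.9], gam_shape=[2.0, 2.0],
                                gam_rate=[1.0, 1.0])
        o2 = OutMigrationParams(gamma_prob=[0.7, 0.1], gam_shape=[2.0, 2.0],
                                gam_rate=[1.0, 1.0])
        assert log_prior(mort, o1, prior) == pytest.approx(log_prior(mort, o2, prior))

    def test_domain_boundaries(self):
        assert mm._half_normal_logpdf(-0.5, 1.0) == -np.inf
        assert mm._trunc_normal_logpdf(0.0, 2.0, 1.0) == -np.inf

    def test_kappa_shrinkage_is_gaussian(self):
        prior = PriorSpec(kappa_sd=10.0)
        m0 = MortalityParams(a=0.05, b=0.1, kappa=np.zeros(1))
        m1 = MortalityParams(a=0.05, b=0.1, kappa=np.array([1.0]))
        assert log_prior(m0, None, prior) - log_prior(m1, None, prior) == \
            pytest.approx(0.5 / 100.0)


def test_vectorised_likelihood_matches_scalar(small_cohort):
    """The sampler's cohort likelihood agrees with the per-individual
    scalar implementation, fate branch by fate branch."""
    from socmort.covariates import AgeSexStandardizer
    from socmort.mcmc import FitData, UNKNOWN

    individuals, records, covariates, _ = small_cohort
    std = AgeSexStandardizer().fit_transform(covariates)
    for sex in ("M", "F"):
        data = FitData(records, std, sex=sex, alpha={"F": 5.0, "M": 7.0}[sex])
        W = data.linear_fill()  # dense, deterministic
        rng = np.random.default_rng(1)
        o = np.zeros(data.n, dtype=int)
        unk = data.fate == UNKNOWN
        o[unk] = rng.integers(0, 2, size=int(unk.sum()))
        mort = MortalityParams(a=0.02, b=0.11,
                               kappa=0.2 * rng.standard_normal(data.p))
        outm = OutMigrationParams(gamma_prob=[0.4, 0.3], gam_shape=[3.0, 2.0],
                                  gam_rate=[2.0, 0.7])
        vec = data.per_individual_loglik(
            data.birth_mid, o, W, mort.a, mort.b, mort.kappa,
            outm.gamma_prob, outm.gam_shape, outm.gam_rate)
        for i, rec in enumerate(data.records):
            latent = LatentState(o=int(o[i]) if rec.fate == "unknown" else None)
            want = individual_loglik(rec, latent, W[i], mort, outm,
                                     data.alpha, outmigration_enabled=data.outmig)
            assert vec[i] == pytest.approx(want, abs=1e-8), (sex, rec.id, rec.fate)
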
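"""Random-effects model, M3 censored likelihood, Laplace marginal
likelihood against quadrature oracles, CV%/LRT conventions, and the
covariance step."""

import math

import numpy as np
import pytest
from scipy.integrate import dblquad, quad
from scipy.stats import multivariate_normal, norm

from cortipk import (Depot, DoseEvent, Observation, PopulationParams,
                     SubjectData, concentration, cv_percent, fit_population,
                     iiv_correlation, individual_params,
                     laplace_subject_loglik, lrt_pvalue, obs_loglik,
                     total_ofv)
from cortipk.likelihood import ofv_hessian_standard_errors
from cortipk.dataset import subjects_from_dataset


# ---------------------------------------------------------------------------
# individual parameters


class TestIndividualParams:
    def test_zero_eta_is_identity(self, dex_params):
        assert individual_params(dex_params, [0.0, 0.0],
                                 ("cl_f", "ka_im")) == dex_params

    def test_log_scale_multiplicative(self, dex_params):
        p = individual_params(dex_params, [math.log(2.0)], ("cl_f",))
        assert p.cl_f == pytest.approx(2.0 * dex_params.cl_f, rel=1e-12)
        assert p.vp_f == dex_params.vp_f

    def test_median_equals_typical(self, dex_params):
        # log-normal median property, Monte-Carlo oracle
        rng = np.random.default_rng(123)
        etas = rng.normal(0.0, math.sqrt(0.0265), 10**5)
        cls = dex_params.cl_f * np.exp(etas)
        assert np.median(cls) == pytest.approx(dex_params.cl_f, rel=5e-3)

    def test_dimension_mismatch_rejected(self, dex_params):
        with pytest.raises(ValueError):
            individual_params(dex_params, [0.1], ("cl_f", "vp_f"))


# ---------------------------------------------------------------------------
# observation likelihood (M3)


class TestObsLoglik:
    def test_blq_at_prediction_equal_lloq_is_half(self):
        rec = Observation(1.0, blq=True, lloq=0.1)
        assert math.exp(obs_loglik(0.1, rec, 0.04)) == pytest.approx(0.5)

    def test_blq_one_sigma_above_lloq(self):
        rec = Observation(1.0, blq=True, lloq=0.1)
        pred = 0.1 * math.exp(math.sqrt(0.04))
        assert math.exp(obs_loglik(pred, rec, 0.04)) == pytest.approx(
            norm.cdf(-1.0), rel=1e-12)

    def test_exact_prediction_density(self):
        # residual variance from the DEX analysis
        rec = Observation(1.0, dv=5.0, lloq=0.1)
        assert obs_loglik(5.0, rec, 0.0455) == pytest.approx(
            -0.5 * math.log(2.0 * math.pi * 0.0455), rel=1e-12)

    def test_m3_censored_probability_monotone(self):
        rec = Observation(1.0, blq=True, lloq=0.1)
        preds = np.logspace(-8, 3, 60)
        probs = [obs_loglik(p, rec, 0.02) for p in preds]
        assert np.all(np.diff(probs) <= 0)         # monotone decreasing
        # strictly decreasing wherever the tail probability is resolvable
        mid = [obs_loglik(p, rec, 0.02) for p in np.logspace(-2, 2, 40)]
        assert np.all(np.diff(mid) < 0)
        assert math.exp(probs[0]) == pytest.approx(1.0, abs=1e-12)
        assert math.exp(probs[-1]) < 1e-10

    def test_nonpositive_quantified_rejected(self):
        with pytest.raises(ValueError):
            obs_loglik(1.0, Observation(1.0, dv=-2.0), 0.04)


# ---------------------------------------------------------------------------
# Laplace vs quadrature oracles


def _pk_subject(times, params, doses, sigma, seed=0, lloq=0.1):
    rng = np.random.default_rng(seed)
    cp = concentration(params, doses, times).cp
    dv = cp * np.exp(rng.normal(0.0, sigma, cp.size))
    blq = dv < lloq
    return SubjectData(id="toy", dose_times=[d.time for d in doses],
                       dose_amounts=[d.amount for d in doses],
                       dose_depots=[d.depot for d in doses],
                       obs_times=times,
                       dv=np.where(blq, np.nan, dv), blq=blq, lloq=lloq)


def _joint_density(subject, pop, eta_scale=1.0):
    """exp(joint loglik) as a plain function of eta, for quadrature."""
    omega = np.atleast_2d(pop.omega)
    doses = [DoseEvent(t, a, Depot(getattr(d, "value", d)))
             for t, a, d in zip(subject.dose_times, subject.dose_amounts,
                                subject.dose_depots)]
    sigma = math.sqrt(pop.sigma2)

    def logjoint(eta):
        eta = np.atleast_1d(eta)
        th = individual_params(pop.theta, eta, pop.iiv_names)
        cp = concentration(th, doses, subject.obs_times).cp
        ll = 0.0
        for pred, dv, blq in zip(cp, subject.dv, subject.blq):
            rec = Observation(0.0, dv=None if blq else dv, blq=bool(blq),
                              lloq=subject.lloq)
            ll += obs_loglik(pred, rec, pop.sigma2)
        if len(eta) == 1:
            ll += norm.logpdf(eta[0], 0.0, math.sqrt(omega[0, 0]))
        else:
            ll += multivariate_normal.logpdf(eta, np.zeros(len(eta)), omega)
        return ll

    return logjoint


def quadrature_marginal(subject, pop):
    logjoint = _joint_density(subject, pop)
    d = len(pop.iiv_names)
    omega = np.atleast_2d(pop.omega)
    sds = np.sqrt(np.diag(omega))
    shift = logjoint(np.zeros(d))
    if d == 1:
        val, _ = quad(lambda e: math.exp(logjoint([e]) - shift),
                      -8 * sds[0], 8 * sds[0], epsabs=1e-13, limit=300)
    else:
        val, _ = dblquad(
            lambda e2, e1: math.exp(logjoint([e1, e2]) - shift),
            -8 * sds[0], 8 * sds[0],
            lambda _: -8 * sds[1], lambda _: 8 * sds[1],
            epsabs=1e-12)
    return math.log(val) + shift


@pytest.fixture(scope="module")
def toy_fixtures(dex_params, bet_params):
    """The <=2-eta toy suite: small-IIV PK subjects (where the Laplace
    expansion is essentially exact) plus a log-linear bioavailability toy
    (where it is exactly exact)."""
    times = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 96.0])
    im = [DoseEvent(0.0, 6.0, Depot.IM_PHOSPHATE)]
    po = [DoseEvent(0.0, 6.0, Depot.ORAL)]
    toys = []
    toys.append(("dex-1eta-cl", _pk_subject(times, dex_params, im, 0.2, 1),
                 PopulationParams(theta=dex_params, iiv_names=("cl_f",),
                                  omega=[[1e-4]], sigma2=0.04)))
    toys.append(("bet-1eta-vp", _pk_subject(times, bet_params, im, 0.15, 2),
                 PopulationParams(theta=bet_params, iiv_names=("vp_f",),
                                  omega=[[2e-4]], sigma2=0.0225)))
    toys.append(("dex-1eta-fr-linear",
                 _pk_subject(times, dex_params, po, 0.2, 3),
                 PopulationParams(theta=dex_params, iiv_names=("fr",),
                                  omega=[[0.09]], sigma2=0.04)))
    toys.append(("dex-2eta", _pk_subject(times, dex_params, im, 0.2, 4),
                 PopulationParams(theta=dex_params,
                                  iiv_names=("cl_f", "ka_im"),
                                  omega=np.diag([1e-4, 2e-4]), sigma2=0.04)))
    toys.append(("bet-2eta-blq",
                 _pk_subject(np.append(times, [192.0, 240.0]), bet_params,
                             im, 0.3, 5),
                 PopulationParams(theta=bet_params,
                                  iiv_names=("cl_f", "vp_f"),
                                  omega=np.array([[2e-4, 5e-5],
                                                  [5e-5, 2e-4]]),
                                  sigma2=0.09)))
    return toys


def test_laplace_matches_quadrature_on_toys(toy_fixtures):
    for name, subject, pop in toy_fixtures:
        lap = laplace_subject_loglik(subject, pop)
        ref = quadrature_marginal(subject, pop)
        assert 2.0 * abs(lap - ref) < 1e-4, name   # OFV units


def test_laplace_exact_for_log_linear_bioavailability(dex_params):
    """With IIV on the oral bioavailability only, log Cp is exactly linear
    in eta, the model is conjugate, and the marginal has a closed form:
    y ~ N(log cp_typ, sigma^2 I + omega^2 J)."""
    times = np.array([1.0, 3.0, 8.0, 24.0])
    doses = [DoseEvent(0.0, 6.0, Depot.ORAL)]
    sub = _pk_subject(times, dex_params, doses, 0.3, seed=11)
    assert not sub.blq.any()
    omega2, sigma2 = 0.16, 0.09
    pop = PopulationParams(theta=dex_params, iiv_names=("fr",),
                           omega=[[omega2]], sigma2=sigma2)
    n = times.size
    cov = sigma2 * np.eye(n) + omega2 * np.ones((n, n))
    mean = np.log(concentration(dex_params, doses, times).cp)
    exact = multivariate_normal.logpdf(np.log(sub.dv), mean, cov)
    lap = laplace_subject_loglik(sub, pop)
    assert lap == pytest.approx(exact, abs=1e-7)


def test_point_mass_prior_limit(dex_params):
    """omega -> 0: the marginal collapses to the observation loglik at
    eta = 0."""
    times = np.array([1.0, 4.0, 24.0])
    doses = [DoseEvent(0.0, 6.0, Depot.IM_PHOSPHATE)]
    sub = _pk_subject(times, dex_params, doses, 0.2, seed=6)
    pop = PopulationParams(theta=dex_params, iiv_names=("cl_f",),
                           omega=[[1e-12]], sigma2=0.04)
    cp = concentration(dex_params, doses, times).cp
    direct = sum(obs_loglik(p, Observation(0.0, dv=v), 0.04)
                 for p, v in zip(cp, sub.dv))
    assert laplace_subject_loglik(sub, pop) == pytest.approx(direct, abs=1e-5)


def test_unconverged_inner_search_is_flagged(dex_params):
    times = np.array([1.0, 4.0, 24.0])
    sub = _pk_subject(times, dex_params,
                      [DoseEvent(0.0, 6.0, Depot.IM_PHOSPHATE)], 0.2, seed=6)
    pop = PopulationParams(theta=dex_params, iiv_names=("cl_f",),
                           omega=[[0.1]], sigma2=0.04)
    _, _, diag = laplace_subject_loglik(sub, pop, max_iter=1,
                                        full_output=True)
    assert diag["converged"] is False


# ---------------------------------------------------------------------------
# total OFV


@pytest.fixture(scope="module")
def trio(dex_params):
    times = np.array([0.5, 2.0, 6.0, 24.0, 48.0])
    doses = [DoseEvent(0.0, 6.0, Depot.IM_PHOSPHATE)]
    return [_pk_subject(times, dex_params, doses, 0.2, seed=s)
            for s in (21, 22, 23)]


@pytest.fixture(scope="module")
def pop1(dex_params):
    # IIV small enough that the Laplace expansion is exact well below
    # the quadrature-comparison tolerance
    return PopulationParams(theta=dex_params, iiv_names=("cl_f",),
                            omega=[[1e-4]], sigma2=0.04)


class TestTotalOfv:
    def test_additive_over_subject_subsets(self, trio, pop1):
        whole = total_ofv(trio, pop1)
        parts = total_ofv(trio[:1], pop1) + total_ofv(trio[1:], pop1)
        assert whole == pytest.approx(parts, abs=1e-8)

    def test_subject_order_invariance(self, trio, pop1):
        assert total_ofv(trio, pop1) == pytest.approx(
            total_ofv(trio[::-1], pop1), abs=1e-8)

    def test_agrees_with_quadrature_ofv(self, trio, pop1):
        quad_ofv = -2.0 * sum(quadrature_marginal(s, pop1) for s in trio)
        assert total_ofv(trio, pop1) == pytest.approx(quad_ofv, abs=1e-4)


# ---------------------------------------------------------------------------
# reporting conventions


@pytest.mark.parametrize("omega2,expected", [
    (0.0265, 16.4), (0.395, 69.6), (0.0633, 25.6),   # DEX table
    (0.0210, 14.6), (0.0188, 13.8), (0.0441, 21.2),  # BET table
    (0.147, 39.8), (0.241, 52.2), (0.0182, 13.6), (0.00773, 8.8),
])
def test_cv_percent_reproduces_report_tables(omega2, expected):
    assert round(cv_percent(omega2), 1) == expected


def test_cv_percent_zero():
    assert cv_percent(0.0) == 0.0


def test_clearance_volume_correlation():
    # the parenthesized 0.78 on the covariance row is a correlation
    assert round(iiv_correlation(0.0155, 0.0210, 0.0188), 2) == 0.78


@pytest.mark.parametrize("delta,df,expected,tol", [
    (5.5, 1, 0.019, 5e-4),     # the inter-occasion variability comparison
    (3.841, 1, 0.050, 5e-4),
    (195.1, 1, 0.0, 1e-10),    # one- vs two-compartment drop (DEX)
])
def test_lrt_pvalues(delta, df, expected, tol):
    assert lrt_pvalue(delta, df) == pytest.approx(expected, abs=tol)


def test_lrt_zero_drop_is_one():
    assert lrt_pvalue(0.0, 1) == 1.0
    assert lrt_pvalue(0.0, 3) == 1.0


# ---------------------------------------------------------------------------
# standard errors


def test_quadratic_ofv_exact_standard_errors():
    A = np.array([[4.0, 1.0, 0.0], [1.0, 3.0, 0.5], [0.0, 0.5, 2.0]])
    a = np.array([0.3, -0.2, 1.0])

    def ofv(x):
        d = x - a
        return float(d @ A @ d) + 17.0

    cov, H, ok, msg = ofv_hessian_standard_errors(ofv, a)
    assert ok
    assert np.allclose(H, 2.0 * A, atol=1e-5)
    assert np.allclose(cov, np.linalg.inv(A), atol=1e-5)


def test_singular_hessian_flagged():
    cov, H, ok, msg = ofv_hessian_standard_errors(
        lambda x: float(x[0] ** 2), np.zeros(2))
    assert not ok and cov is None and "Hessian" in msg


def test_ofv_decreases_along_accepted_steps(mini_study, dex_pop):
    subjects = subjects_from_dataset(mini_study, "DEX")
    fit = fit_population(subjects, dex_pop, maxiter=15)
    traj = np.array(fit.trajectory)
    assert traj.size >= 2
    assert np.all(np.diff(traj) <= 1e-8)
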
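"""Nested-sampling evidence, prior boxes, Bayes factors, Jeffreys scale."""

import math

import numpy as np
import pytest

from kappalen import (
    DoubleKappaModel,
    EmpiricalCDF,
    PriorBox,
    bayes_factor,
    chi_square,
    empirical_cdf,
    fit,
    jeffreys_verdict,
    log_likelihood,
    make_loglike,
    nested_sampling_evidence,
    prior_box_from_fit,
)
from conftest import integer_sample

LN_HALF = math.log(0.5)


def gaussian_loglike(sigma=0.1):
    """Correctly normalized 1-D Gaussian: Z over U(-1,1) is 1/2."""
    const = math.log(sigma * math.sqrt(2 * math.pi))

    def ll(theta):
        return -0.5 * (theta[0] / sigma) ** 2 - const

    return ll


def unit_box(half_width=1.0):
    return PriorBox(("x",), np.array([-half_width]), np.array([half_width]))


def exact_ecdf(model, n_grid=200, sigma=0.01):
    grid = np.asarray(model.quantile(np.linspace(0.002, 0.998, n_grid)))
    return EmpiricalCDF(grid=grid, probs=np.asarray(model.cdf(grid)),
                        sigma_obs=np.full(n_grid, sigma), n=n_grid)


# ------------------------------------------------------------- likelihood
def test_log_likelihood_values():
    m = DoubleKappaModel(0.35, 0.006, 0.007)
    e = exact_ecdf(m)
    assert log_likelihood(m, "double", e) == pytest.approx(0.0, abs=1e-12)
    worse = DoubleKappaModel(0.5, 0.006, 0.007)
    assert log_likelihood(worse, "double", e) == pytest.approx(
        -0.5 * chi_square(e, "double", worse))
    assert log_likelihood(worse, "double", e) < log_likelihood(m, "double", e)


def test_chi2_four_maps_to_minus_two():
    m = DoubleKappaModel(0.35, 0.006, 0.007)
    e = EmpiricalCDF(grid=np.array([100.0]),
                     probs=np.array([m.cdf(100.0) + 0.1]),
                     sigma_obs=np.array([0.05]), n=1)
    assert log_likelihood(m, "double", e) == pytest.approx(-2.0)


# ------------------------------------------------------------- prior boxes
def test_prior_box_validation():
    with pytest.raises(ValueError):
        PriorBox(("a",), np.array([1.0]), np.array([0.5]))
    with pytest.raises(ValueError):
        PriorBox(("kappa",), np.array([0.2]), np.array([1.2]))


def test_prior_transform_orders_rates():
    box = PriorBox(("kappa", "gamma1", "gamma2"),
                   np.array([0.1, 0.004, 0.004]),
                   np.array([0.5, 0.009, 0.009]),
                   ordered=(("gamma1", "gamma2"),))
    theta = box.transform(np.array([0.5, 0.9, 0.1]))
    assert theta[1] <= theta[2]


def test_prior_box_from_fit_shape():
    m = DoubleKappaModel(0.35, 0.006, 0.007)
    res = fit(empirical_cdf(integer_sample(m, 3000, seed=8)), "double", seed=1)
    box = prior_box_from_fit(res, half_width_sigmas=3.0)
    k = res.params.kappa
    se = res.std_errors["kappa"]
    assert box.lower[0] == pytest.approx(max(k - 3 * se, 1e-6))
    assert box.upper[0] == pytest.approx(min(k + 3 * se, 0.99))
    assert box.ordered == (("gamma1", "gamma2"),)
    wide = prior_box_from_fit(res, half_width_sigmas=6.0)
    assert np.all(wide.upper >= box.upper)
    assert np.all(wide.lower <= box.lower)
    assert wide.upper[0] <= 0.99  # clipped to the validity region


def test_prior_box_from_nonconverged_fit_rejected():
    from kappalen import FitResult

    bad = FitResult("double", DoubleKappaModel(0.3, 0.005, 0.006),
                    {"kappa": 0.01, "gamma1": 1e-4, "gamma2": 1e-4},
                    10.0, 100, False, 9)
    with pytest.raises(ValueError):
        prior_box_from_fit(bad)


# -------------------------------------------------------- nested sampling
def test_evidence_gaussian_toy():
    ev = nested_sampling_evidence(gaussian_loglike(), unit_box(),
                                  n_live=300, seed=0)
    assert ev.log_evidence == pytest.approx(LN_HALF, abs=3 * ev.log_evidence_error)
    assert ev.log_evidence_error > 0
    assert ev.weights.sum() == pytest.approx(1.0)
    assert np.all(ev.weights >= 0)


def test_evidence_constant_likelihood():
    with pytest.warns(UserWarning):  # flat posterior touches every bound
        ev = nested_sampling_evidence(lambda th: 0.0, unit_box(3.0),
                                      n_live=100, seed=1)
    assert ev.log_evidence == pytest.approx(0.0, abs=1e-9)


def test_occam_factor_box_doubling():
    """Doubling the prior width of a peaked likelihood costs ln 2."""
    e1 = nested_sampling_evidence(gaussian_loglike(), unit_box(1.0),
                                  n_live=400, seed=5)
    e2 = nested_sampling_evidence(gaussian_loglike(), unit_box(2.0),
                                  n_live=400, seed=6)
    err = math.hypot(e1.log_evidence_error, e2.log_evidence_error)
    assert e1.log_evidence - e2.log_evidence == pytest.approx(math.log(2),
                                                              abs=3 * err)


def test_evidence_invariant_to_n_live():
    evs = [nested_sampling_evidence(gaussian_loglike(), unit_box(),
                                    n_live=nl, seed=3)
           for nl in (200, 800)]
    err = math.hypot(*(e.log_evidence_error for e in evs))
    assert abs(evs[0].log_evidence - evs[1].log_evidence) < 3 * err


def test_posterior_mean_recovers_truth():
    """On a noiseless recovery run the posterior concentrates on truth."""
    m = DoubleKappaModel(0.35, 0.006, 0.007)
    e = exact_ecdf(m)
    box = PriorBox(("kappa", "gamma1", "gamma2"),
                   np.array([0.25, 0.004, 0.004]),
                   np.array([0.45, 0.009, 0.009]),
                   ordered=(("gamma1", "gamma2"),))
    ev = nested_sampling_evidence(make_loglike("double", e), box,
                                  n_live=200, seed=9)
    mean, sd = ev.posterior_mean(), ev.posterior_std()
    assert abs(mean["kappa"] - 0.35) < 2 * sd["kappa"]


def test_nan_likelihood_is_hard_error():
    with pytest.raises(ValueError, match="NaN"):
        nested_sampling_evidence(lambda th: float("nan"), unit_box(),
                                 n_live=60, seed=0)


def test_n_live_minimum_enforced():
    with pytest.raises(ValueError):
        nested_sampling_evidence(gaussian_loglike(), unit_box(), n_live=10)


def test_boundary_contact_warning():
    # a flat likelihood leaves posterior mass on every edge of the box
    with pytest.warns(UserWarning, match="abuts"):
        nested_sampling_evidence(lambda th: 0.0, unit_box(), n_live=100, seed=2)


def test_evidence_deterministic_for_seed():
    a = nested_sampling_evidence(gaussian_loglike(), unit_box(), n_live=100, seed=7)
    b = nested_sampling_evidence(gaussian_loglike(), unit_box(), n_live=100, seed=7)
    assert a.log_evidence == b.log_evidence
    assert np.array_equal(a.samples, b.samples)


# ------------------------------------------------------------ Bayes factor
class _Ev:
    def __init__(self, lnz):
        self.log_evidence = lnz


def test_bayes_factor_values():
    cmpn = bayes_factor(_Ev(-10.0), _Ev(-4.0))
    assert cmpn.log_bayes_factor == pytest.approx(-6.0)
    assert cmpn.bayes_factor == pytest.approx(math.exp(-6.0))
    assert cmpn.verdict == "decisive"
    assert cmpn.favored == "double"  # the reference model
    equal = bayes_factor(_Ev(-3.0), _Ev(-3.0))
    assert equal.bayes_factor == pytest.approx(1.0)
    assert equal.favored == "neither"


def test_bayes_factor_antisymmetry():
    a = bayes_factor(_Ev(-2.0), _Ev(-7.0))
    b = bayes_factor(_Ev(-7.0), _Ev(-2.0))
    assert a.log_bayes_factor == -b.log_bayes_factor


@pytest.mark.parametrize(
    "lnb, label",
    [
        (0.5, "inconclusive"), (-0.5, "inconclusive"),
        (1.5, "moderate"), (3.0, "strong"),
        (-6.0, "decisive"), (7.0, "decisive"),
    ],
)
def test_jeffreys_scale(lnb, label):
    assert jeffreys_verdict(lnb) == label


def test_jeffreys_requires_finite():
    with pytest.raises(ValueError):
        jeffreys_verdict(float("inf"))
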
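"""Length-model PDFs, closed-form CDFs, quantiles and sampling."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from kappalen import DoubleKappaModel, KappaMaxwellModel, SingleKappaModel

DOUBLE = DoubleKappaModel(0.35, 0.006, 0.007)


def integral_cdf(model, l):
    """Quadrature oracle: integrate the PDF from 0 to l."""
    val, _ = quad(model.pdf, 0.0, l, limit=300)
    return val


# ---------------------------------------------------------------- densities
def test_pdf_single_at_origin():
    m = SingleKappaModel(0.3, 100.0)
    assert m.pdf(0.0) == pytest.approx((1 - 0.09) / 100, abs=1e-12)


def test_single_exponential_limit_pdf():
    m = SingleKappaModel(1e-9, 120.0)
    assert m.pdf(120.0) == pytest.approx(math.exp(-1) / 120, rel=1e-6)


@pytest.mark.parametrize(
    "model",
    [
        SingleKappaModel(0.3, 100.0),
        DOUBLE,
        KappaMaxwellModel(0.66, 98.0),
    ],
    ids=["single", "double", "maxwell"],
)
def test_pdf_integrates_to_one(model):
    # split at a tail point so quadrature resolves the power-law tail
    split = model.quantile(0.999)
    head, _ = quad(model.pdf, 0, split, limit=300)
    tail, _ = quad(model.pdf, split, np.inf, limit=300)
    assert head + tail == pytest.approx(1.0, abs=1e-6)


def test_pdf_double_equal_rates_reduces_to_single():
    d = DoubleKappaModel(0.35, 0.0065, 0.0065)
    s = SingleKappaModel(0.35, 1 / 0.0065)
    l = np.array([0.0, 10.0, 200.0, 5000.0])
    assert np.allclose(d.pdf(l), s.pdf(l), rtol=0, atol=1e-15)


def test_pdf_double_exponential_limit_at_origin():
    m = DoubleKappaModel(1e-9, 0.01, 0.01)
    assert m.pdf(0.0) == pytest.approx(0.01, rel=1e-6)


# ----------------------------------------------------------------- CDFs
@pytest.mark.parametrize(
    "model",
    [
        SingleKappaModel(0.2, 150.0),
        DOUBLE,
        KappaMaxwellModel(0.66, 98.0),
    ],
    ids=["single", "double", "maxwell"],
)
def test_cdf_zero_at_origin(model):
    assert model.cdf(0.0) == pytest.approx(0.0, abs=1e-14)


def test_cdf_single_exponential_limit():
    m = SingleKappaModel(1e-9, 100.0)
    assert m.cdf(100.0) == pytest.approx(1 - math.exp(-1), abs=1e-6)


def test_cdf_maxwell_rayleigh_limit():
    m = KappaMaxwellModel(1e-9, 100.0)
    assert m.cdf(100.0) == pytest.approx(1 - math.exp(-0.5), abs=1e-6)


@pytest.mark.parametrize("kappa", [0.2, 0.4])
@pytest.mark.parametrize("l", [10.0, 200.0, 5000.0])
def test_cdf_single_matches_quadrature(l, kappa):
    m = SingleKappaModel(kappa, 120.0)
    assert m.cdf(l) == pytest.approx(integral_cdf(m, l), abs=1e-8)


@pytest.mark.parametrize("l", [50.0, 500.0, 1e4])
def test_cdf_double_matches_quadrature(l):
    assert DOUBLE.cdf(l) == pytest.approx(integral_cdf(DOUBLE, l), abs=1e-8)


def test_cdf_double_equal_rates_reduces_to_single():
    d = DoubleKappaModel(0.35, 0.0065, 0.0065)
    s = SingleKappaModel(0.35, 1 / 0.0065)
    l = np.logspace(0, 5, 60)
    assert np.max(np.abs(d.cdf(l) - s.cdf(l))) < 1e-12


def test_cdf_maxwell_monotone_on_grid():
    m = KappaMaxwellModel(0.66, 98.0)
    vals = m.cdf(np.linspace(0, 1e4, 2000))
    assert np.all(np.diff(vals) >= 0)


@pytest.mark.parametrize(
    "model, rate_note",
    [
        (SingleKappaModel(0.1, 150.0), None),
        (DoubleKappaModel(0.27, 0.004, 0.009), None),
        (DoubleKappaModel(0.43, 0.006, 0.007), None),
        # heavy kappa=0.7 tails converge slowly: survival ~ l^(-3/7), so a
        # larger rate is needed for the 1e-3 check at l = 1e8 to bite
        (SingleKappaModel(0.7, 10.0), None),
        (KappaMaxwellModel(0.66, 98.0), None),
    ],
    ids=["single-0.1", "double-0.27", "double-0.43", "single-0.7", "maxwell"],
)
def test_cdf_limits_and_monotone(model, rate_note):
    l = np.concatenate([[0.0], np.logspace(-1, 8, 300)])
    vals = np.asarray(model.cdf(l))
    assert vals[0] == pytest.approx(0.0, abs=1e-14)
    assert np.all(np.diff(vals) >= -1e-15)
    assert vals[-1] > 1 - 1e-3


def test_kappa_zero_limits_of_all_cdfs():
    l = np.logspace(0, 4, 50)
    s = SingleKappaModel(1e-9, 100.0)
    assert np.max(np.abs(s.cdf(l) - (1 - np.exp(-l / 100)))) < 1e-6
    d = DoubleKappaModel(1e-9, 0.004, 0.009)
    mix = 1 - (0.009 * np.exp(-0.004 * l) + 0.004 * np.exp(-0.009 * l)) / 0.013
    assert np.max(np.abs(d.cdf(l) - mix)) < 1e-6
    m = KappaMaxwellModel(1e-9, 90.0)
    assert np.max(np.abs(m.cdf(l) - (1 - np.exp(-(l**2) / (2 * 90.0**2))))) < 1e-6


def test_survival_tail_slope_single():
    """For kappa = 0.4 the survival decays like l^-(1/kappa - 1)."""
    m = SingleKappaModel(0.4, 100.0)
    l = np.logspace(4, 6, 40)
    slope = np.polyfit(np.log(l), np.log(1 - np.asarray(m.cdf(l))), 1)[0]
    assert slope == pytest.approx(-(1 / 0.4 - 1), rel=0.05)


# ----------------------------------------------------- derivative of maxwell
@pytest.mark.parametrize("l", [10.0, 100.0, 400.0])
def test_pdf_maxwell_is_cdf_derivative(l):
    m = KappaMaxwellModel(0.66, 98.0)
    h = 1e-4 * l
    fd = (m.cdf(l + h) - m.cdf(l - h)) / (2 * h)
    assert m.pdf(l) == pytest.approx(fd, rel=1e-6)


def test_pdf_maxwell_zero_at_origin():
    assert KappaMaxwellModel(0.66, 98.0).pdf(0.0) == 0.0
    assert KappaMaxwellModel(1e-9, 98.0).pdf(0.0) == 0.0


# -------------------------------------------------------------- quantiles
@pytest.mark.parametrize(
    "model",
    [SingleKappaModel(0.3, 100.0), DOUBLE, KappaMaxwellModel(0.66, 98.0)],
    ids=["single", "double", "maxwell"],
)
def test_quantile_roundtrip(model):
    assert model.quantile(0.0) == 0.0
    for p in (0.1, 0.5, 0.99):
        assert model.cdf(model.quantile(p)) == pytest.approx(p, abs=1e-9)


def test_quantile_exponential_median():
    m = SingleKappaModel(1e-9, 100.0)
    assert m.quantile(0.5) == pytest.approx(100 * math.log(2), abs=1e-3)


def test_quantile_monotone_in_p():
    q = DOUBLE.quantile(np.linspace(0, 0.999, 50))
    assert np.all(np.diff(q) > 0)


def test_quantile_domain_errors():
    with pytest.raises(ValueError):
        DOUBLE.quantile(1.0)
    with pytest.raises(ValueError):
        DOUBLE.quantile(-0.1)


# --------------------------------------------------------------- sampling
def test_sample_deterministic():
    a = DOUBLE.sample(100, seed=42)
    b = DOUBLE.sample(100, seed=42)
    assert np.array_equal(a, b)


def test_sample_ks_against_cdf():
    x = DOUBLE.sample(20000, seed=1)
    stat = kstest(x, DOUBLE.cdf).statistic
    assert stat < 1.628 / math.sqrt(20000)  # 1% critical value


def test_sample_mean_exponential_limit():
    m = SingleKappaModel(1e-9, 100.0)
    x = m.sample(20000, seed=2)
    se = 100.0 / math.sqrt(20000)  # exponential: sd = mean
    assert abs(x.mean() - 100.0) < 3 * se


def test_sample_size_error():
    with pytest.raises(ValueError):
        DOUBLE.sample(0, seed=1)


# ---------------------------------------------------------------- validity
def test_negative_length_rejected():
    for m in (SingleKappaModel(0.3, 100.0), DOUBLE, KappaMaxwellModel(0.5, 90.0)):
        with pytest.raises(ValueError):
            m.pdf(-1.0)
        with pytest.raises(ValueError):
            m.cdf(np.array([1.0, -2.0]))


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        SingleKappaModel(1.2, 100.0)
    with pytest.raises(ValueError):
        SingleKappaModel(0.3, -5.0)
    with pytest.raises(ValueError):
        DoubleKappaModel(0.3, 0.0, 0.01)
    with pytest.raises(ValueError):
        KappaMaxwellModel(0.3, 0.0)
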
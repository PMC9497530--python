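"""Chi-square fitting of the kappa length models to empirical CDFs.

The goodness statistic is

    chi2(theta) = sum_i [ (P_obs(l_i) - P_model(l_i; theta))^2 / sigma_obs_i^2 ]

summed over every point of the empirical-CDF grid (CDF fitting needs no
histogram binning).  Minimization is performed in a transformed space
(kappa bounded in [0, 0.99], scale/rate parameters in log space) with a
bounded trust-region least-squares solver, restarted from Latin-hypercube
draws because the double-kappa surface has a gamma1 <-> gamma2 exchange
symmetry; rates are reported in the canonical order gamma1 <= gamma2.
Parameter uncertainties come from the local quadratic approximation of
chi2 at the optimum (covariance = inverse of J^T J for the weighted
residual Jacobian J).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .ingest import EmpiricalCDF, LengthSample, empirical_cdf, iqr_filter, relative_difference
from .models import DoubleKappaModel, KappaMaxwellModel, LengthModel, SingleKappaModel

__all__ = [
    "FitResult",
    "PrePostFit",
    "FAMILIES",
    "make_model",
    "chi_square",
    "fit",
    "fit_pre_post",
    "format_estimate",
]

#: family label -> (model class, ordered free-parameter names)
FAMILIES: dict[str, tuple[type, tuple[str, ...]]] = {
    "single": (SingleKappaModel, ("kappa", "L_kappa")),
    "double": (DoubleKappaModel, ("kappa", "gamma1", "gamma2")),
    "maxwell": (KappaMaxwellModel, ("kappa", "sigma_kappa")),
}

KAPPA_FIT_BOUNDS = (0.0, 0.99)


def make_model(family: str, theta: np.ndarray) -> LengthModel:
    """Build a model instance from its free-parameter vector."""
    cls, names = FAMILIES[family]
    return cls(**dict(zip(names, (float(t) for t in theta))))


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters for one family against one empirical CDF."""

    family: str
    params: LengthModel
    std_errors: dict[str, float]
    chi2: float
    n_points: int
    converged: bool
    n_restarts_used: int

    def theta(self) -> np.ndarray:
        names = FAMILIES[self.family][1]
        return np.array([getattr(self.params, n) for n in names])


@dataclass(frozen=True)
class PrePostFit:
    """Fits before and after outlier filtering, with per-parameter RD."""

    pre: FitResult
    post: FitResult
    rd: dict[str, float]


def chi_square(ecdf: EmpiricalCDF, family: str, params: LengthModel) -> float:
    """Weighted sum of squared CDF residuals over the whole ECDF grid."""
    if not isinstance(params, FAMILIES[family][0]):
        raise ValueError(f"params {params!r} are not a {family!r} model")
    r = (ecdf.probs - params.cdf(ecdf.grid)) / ecdf.sigma_obs
    return float(np.dot(r, r))


def _data_moments(ecdf: EmpiricalCDF) -> tuple[float, float]:
    dp = np.diff(ecdf.probs, prepend=0.0)
    mean = float(np.sum(ecdf.grid * dp))
    median = float(ecdf.grid[np.searchsorted(ecdf.probs, 0.5)])
    return mean, median


def _starting_points(
    family: str, ecdf: EmpiricalCDF, n_restarts: int, seed: int
) -> list[np.ndarray]:
    """Latin-hypercube starts: kappa in [0.05, 0.9], scales bracketing the
    data's 1/mean and 1/median (rates) or median..mean (lengths)."""
    mean, median = _data_moments(ecdf)
    mean = max(mean, 1.0)
    median = max(median, 1.0)
    names = FAMILIES[family][1]
    ndim = len(names)
    sampler = qmc.LatinHypercube(d=ndim, seed=seed)
    unit = sampler.random(n_restarts)
    starts = []
    for u in unit:
        theta = np.empty(ndim)
        theta[0] = 0.05 + u[0] * (0.9 - 0.05)
        for j, name in enumerate(names[1:], start=1):
            if name.startswith("gamma"):
                lo, hi = math.log(0.5 / mean), math.log(2.0 / median)
            else:
                lo, hi = math.log(median / 2.0), math.log(2.0 * mean)
            theta[j] = math.exp(lo + u[j] * (hi - lo))
        starts.append(theta)
    # deterministic moment-based start first
    base = {"single": [0.3, mean], "maxwell": [0.3, median],
            "double": [0.3, 0.8 / mean, 1.6 / median]}[family]
    starts.insert(0, np.asarray(base, dtype=float))
    return starts


def _to_internal(theta: np.ndarray) -> np.ndarray:
    out = np.array(theta, dtype=float)
    out[1:] = np.log(out[1:])
    return out


def _from_internal(x: np.ndarray) -> np.ndarray:
    out = np.array(x, dtype=float)
    out[1:] = np.exp(out[1:])
    return out


def _residual_jacobian(family: str, theta: np.ndarray, ecdf: EmpiricalCDF) -> np.ndarray:
    """Central finite-difference Jacobian of weighted residuals wrt theta."""
    ndim = theta.size
    jac = np.empty((ecdf.grid.size, ndim))
    for j in range(ndim):
        h = 1e-5 * abs(theta[j]) + 1e-10
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        rp = (ecdf.probs - make_model(family, tp).cdf(ecdf.grid)) / ecdf.sigma_obs
        rm = (ecdf.probs - make_model(family, tm).cdf(ecdf.grid)) / ecdf.sigma_obs
        jac[:, j] = (rp - rm) / (2.0 * h)
    return jac


def fit(
    ecdf: EmpiricalCDF,
    family: str,
    init: Optional[np.ndarray] = None,
    seed: int = 0,
    n_restarts: int = 8,
) -> FitResult:
    """Minimize chi-square for ``family`` over the empirical CDF.

    Multi-start bounded least squares; the best chi2 wins, with ties
    (delta chi2 < 1e-9) broken in favour of the smaller kappa.  A failure
    of every restart is flagged (``converged=False``), not raised.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    names = FAMILIES[family][1]
    ndim = len(names)
    if ecdf.grid.size <= ndim:
        raise ValueError(
            f"degenerate ECDF: {ecdf.grid.size} grid points for {ndim} parameters"
        )

    def resid(x: np.ndarray) -> np.ndarray:
        model = make_model(family, _from_internal(x))
        return (ecdf.probs - model.cdf(ecdf.grid)) / ecdf.sigma_obs

    # data-driven scale boxes: rates within [0.01/mean, 5/median] (length
    # scales from half the shortest to a hundred times the mean exon), so a
    # redundant component cannot run off to an unidentifiable infinity
    mean_l, median_l = _data_moments(ecdf)
    mean_l, median_l = max(mean_l, 1.0), max(median_l, 1.0)
    lo = np.empty(ndim)
    hi = np.empty(ndim)
    lo[0], hi[0] = KAPPA_FIT_BOUNDS
    for j, name in enumerate(names[1:], start=1):
        if name.startswith("gamma"):
            lo[j], hi[j] = math.log(0.01 / mean_l), math.log(5.0 / median_l)
        else:
            lo[j], hi[j] = math.log(median_l / 50.0), math.log(50.0 * mean_l)

    starts = _starting_points(family, ecdf, n_restarts, seed)
    if init is not None:
        starts.insert(0, np.asarray(init, dtype=float))

    best = None
    n_used = 0
    for theta0 in starts:
        n_used += 1
        x0 = np.clip(_to_internal(theta0), lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                ftol=1e-12, xtol=1e-12, gtol=1e-12)
        except Exception:
            continue
        chi2 = float(2.0 * res.cost)
        theta = _from_internal(res.x)
        cand = (chi2, float(theta[0]), theta, bool(res.success))
        if best is None or cand[0] < best[0] - 1e-9 or (
            abs(cand[0] - best[0]) < 1e-9 and cand[1] < best[1]
        ):
            best = cand

    if best is None or not np.isfinite(best[0]):
        theta = starts[0]
        model = make_model(family, _canonical(family, theta))
        return FitResult(family, model, {n: float("nan") for n in names},
                         float("inf"), ecdf.grid.size, False, n_used)

    chi2, _, theta, success = best

    # polish with a simplex pass: the trust-region solver can stall in the
    # degenerate valley (kappa -> 0, gamma1 = gamma2) of badly misfit data,
    # where Nelder-Mead still terminates cleanly
    def chi2_internal(x: np.ndarray) -> float:
        r = resid(np.clip(x, lo, hi))
        return float(np.dot(r, r))

    nm = minimize(chi2_internal, _to_internal(theta), method="Nelder-Mead",
                  options=dict(fatol=1e-10, xatol=1e-10,
                               maxiter=4000, maxfev=8000))
    if nm.fun <= chi2:
        chi2 = float(nm.fun)
        theta = _from_internal(np.clip(nm.x, lo, hi))
    success = success or bool(nm.success)

    theta = _canonical(family, theta)
    jac = _residual_jacobian(family, theta, ecdf)
    se = _std_errors_from_jacobian(jac)
    model = make_model(family, theta)
    return FitResult(
        family=family, params=model,
        std_errors=dict(zip(names, (float(s) for s in se))),
        chi2=chi2, n_points=ecdf.grid.size,
        converged=bool(success), n_restarts_used=n_used,
    )


def _std_errors_from_jacobian(jac: np.ndarray) -> np.ndarray:
    """sqrt(diag (J^T J)^-1); flat (degenerate) directions get infinite
    uncertainty rather than a spurious zero."""
    _, s, vt = np.linalg.svd(jac, full_matrices=False)
    tol = (s.max() if s.size else 0.0) * 1e-10
    with np.errstate(divide="ignore"):
        inv2 = np.where(s > tol, 1.0 / np.square(np.where(s > tol, s, 1.0)), np.inf)
    var = (vt.T**2) @ inv2
    var = np.where(np.isnan(var), np.inf, var)
    return np.sqrt(var)


def _canonical(family: str, theta: np.ndarray) -> np.ndarray:
    """Order gamma1 <= gamma2 (the families are exchange-symmetric)."""
    theta = np.array(theta, dtype=float)
    if family == "double" and theta[1] > theta[2]:
        theta[1], theta[2] = theta[2], theta[1]
    return theta


def fit_pre_post(
    raw: LengthSample, family: str = "double", seed: int = 0
) -> PrePostFit:
    """Fit before and after IQR filtering; report RD per parameter."""
    pre = fit(empirical_cdf(raw), family, seed=seed)
    post = fit(empirical_cdf(iqr_filter(raw).retained), family, seed=seed)
    names = FAMILIES[family][1]
    rd = {
        name: relative_difference(getattr(pre.params, name),
                                  getattr(post.params, name))
        for name in names
    }
    return PrePostFit(pre=pre, post=post, rd=rd)


def format_estimate(value: float, err: float) -> str:
    """Compact uncertainty notation, e.g. 0.27 +/- 0.04 -> ``"0.27(4)"``.

    A parameter whose uncertainty exceeds its value (a flat, degenerate
    direction such as the individual rates of two nearly equal
    components) is rendered explicitly as ``"value(+-err)"``.
    """
    if not (np.isfinite(err) and err > 0):
        return f"{value:g}"
    if err >= abs(value) > 0:
        return f"{value:.3g}(+-{err:.1g})"
    exp10 = math.floor(math.log10(err))
    err_digit = round(err / 10**exp10)
    if err_digit == 10:
        err_digit, exp10 = 1, exp10 + 1
    decimals = max(-exp10, 0)
    return f"{value:.{decimals}f}({err_digit:d})"
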
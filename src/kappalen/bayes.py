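"""Bayesian evidence and model comparison for the length models.

The likelihood is Gaussian in the cumulative-probability residuals,
ln L(theta) = -chi2(theta)/2, with the normalization constant
sum ln(sigma_obs sqrt(2 pi)) omitted identically for every model: it
cancels in the Bayes factor, which is the only reported quantity.
Priors are independent uniform boxes, by default centred on the best-fit
parameters (estimate +/- ``half_width_sigmas`` standard errors, clipped to
the validity region), emulating the narrow uniform ranges used when the
evidence is computed from a previously identified optimal range.

Evidence is computed by classic nested sampling: the worst of ``n_live``
live points is repeatedly replaced by a new prior draw subject to a rising
likelihood threshold, the replacement generated by a short random-walk
MCMC in the unit-cube prior coordinates with an adaptive step size; prior
volumes shrink deterministically as X_i = exp(-i / n_live) and evidence
accumulates by the trapezoidal-in-X rule, with the standard information-
based uncertainty sqrt(H / n_live).

Bayes factors ln B = ln E_compared - ln E_reference are read on a Jeffreys
scale with thresholds |ln B| = 1 / 2.5 / 5 separating inconclusive,
moderate, strong and decisive evidence; the sign picks the favored model.
By convention the reference model is the kappa-exponential-sum family and
the compared model the kappa-Maxwellian.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .fit import FAMILIES, FitResult, make_model
from .ingest import EmpiricalCDF

__all__ = [
    "PriorBox",
    "EvidenceResult",
    "BayesComparison",
    "log_likelihood",
    "make_loglike",
    "prior_box_from_fit",
    "nested_sampling_evidence",
    "bayes_factor",
    "jeffreys_verdict",
    "JEFFREYS_THRESHOLDS",
]

#: |ln B| thresholds separating inconclusive / moderate / strong / decisive
JEFFREYS_THRESHOLDS = (1.0, 2.5, 5.0)


@dataclass(frozen=True)
class PriorBox:
    """Independent uniform prior, one (lower, upper) pair per parameter.

    ``ordered`` lists parameter-name groups forced into ascending order
    inside the prior transform (used to break the gamma1 <-> gamma2
    exchange degeneracy of the double-kappa model).
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    ordered: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != (len(self.names),) or hi.shape != lo.shape:
            raise ValueError("bounds must match the parameter names")
        if not np.all(lo < hi):
            raise ValueError("every lower bound must be below its upper bound")
        for i, name in enumerate(self.names):
            if name == "kappa" and not (-1 < lo[i] and hi[i] < 1):
                raise ValueError("kappa prior bounds must lie inside (-1, 1)")

    @property
    def ndim(self) -> int:
        return len(self.names)

    def transform(self, u: np.ndarray) -> np.ndarray:
        """Map unit-cube coordinates to physical parameters."""
        theta = self.lower + u * (self.upper - self.lower)
        for group in self.ordered:
            idx = [self.names.index(n) for n in group]
            theta[..., idx] = np.sort(theta[..., idx], axis=-1)
        return theta


@dataclass(frozen=True)
class EvidenceResult:
    """Nested-sampling evidence with posterior samples."""

    log_evidence: float
    log_evidence_error: float
    samples: np.ndarray          # (n_points, ndim) physical parameters
    weights: np.ndarray          # normalized posterior weights
    param_names: tuple[str, ...]
    n_live: int
    seed: Optional[int]
    n_iter: int
    information: float

    def posterior_mean(self) -> dict[str, float]:
        mean = self.weights @ self.samples
        return dict(zip(self.param_names, (float(m) for m in mean)))

    def posterior_std(self) -> dict[str, float]:
        mean = self.weights @ self.samples
        var = self.weights @ (self.samples - mean) ** 2
        return dict(zip(self.param_names, (float(np.sqrt(v)) for v in var)))


@dataclass(frozen=True)
class BayesComparison:
    """A Bayes factor between two models and its Jeffreys verdict."""

    log_bayes_factor: float
    bayes_factor: float
    verdict: str
    reference_model: str
    compared_model: str

    @property
    def favored(self) -> str:
        if self.log_bayes_factor > 0:
            return self.compared_model
        if self.log_bayes_factor < 0:
            return self.reference_model
        return "neither"


def log_likelihood(params, family: str, ecdf: EmpiricalCDF) -> float:
    """Gaussian CDF-residual log-likelihood, -chi2/2 (constant omitted)."""
    from .fit import chi_square

    try:
        return -0.5 * chi_square(ecdf, family, params)
    except ValueError:
        return -math.inf


def make_loglike(family: str, ecdf: EmpiricalCDF) -> Callable[[np.ndarray], float]:
    """Vector-parameter log-likelihood for the nested sampler."""
    cls, _ = FAMILIES[family]
    grid, probs, sigma = ecdf.grid, ecdf.probs, ecdf.sigma_obs

    def loglike(theta: np.ndarray) -> float:
        try:
            model = make_model(family, theta)
        except ValueError:
            return -math.inf
        r = (probs - model.cdf(grid)) / sigma
        return -0.5 * float(np.dot(r, r))

    return loglike


def prior_box_from_fit(fit: FitResult, half_width_sigmas: float = 5.0) -> PriorBox:
    """Uniform box at best fit +/- ``half_width_sigmas`` standard errors.

    Bounds are intersected with the validity region (kappa inside
    (0, 0.99), scales positive).  Requires a converged fit with finite,
    positive standard errors.
    """
    if half_width_sigmas <= 0:
        raise ValueError("half_width_sigmas must be positive")
    if not fit.converged:
        raise ValueError("cannot build a prior box from a non-converged fit")
    names = FAMILIES[fit.family][1]
    lo, hi = [], []
    for name in names:
        est = getattr(fit.params, name)
        se = fit.std_errors[name]
        if not (np.isfinite(se) and se > 0):
            raise ValueError(f"non-finite standard error for {name!r}")
        a, b = est - half_width_sigmas * se, est + half_width_sigmas * se
        if name == "kappa":
            a, b = max(a, 1e-6), min(b, 0.99)
        else:
            a = max(a, 1e-12)
        lo.append(a)
        hi.append(b)
    ordered = (("gamma1", "gamma2"),) if fit.family == "double" else ()
    return PriorBox(names=names, lower=np.array(lo), upper=np.array(hi),
                    ordered=ordered)


def nested_sampling_evidence(
    loglike: Callable[[np.ndarray], float],
    prior: PriorBox,
    n_live: int = 500,
    seed: Optional[int] = None,
    mcmc_steps: int = 25,
    termination_frac: float = 1e-3,
    max_iter: int = 500_000,
) -> EvidenceResult:
    """Classic nested sampling over a uniform prior box.

    Terminates when the maximum possible remaining contribution,
    max(L_live) * X_i, falls below ``termination_frac`` of the accumulated
    evidence; the live points are then swept into the sum.  A NaN from the
    likelihood is a hard error (reported with the offending parameters).
    """
    if n_live < 50:
        raise ValueError("n_live must be at least 50")
    rng = np.random.default_rng(seed)
    ndim = prior.ndim

    def evaluate(u: np.ndarray) -> tuple[np.ndarray, float]:
        theta = prior.transform(u)
        ll = loglike(theta)
        if math.isnan(ll):
            raise ValueError(f"likelihood returned NaN at parameters {theta}")
        return theta, ll

    u_live = rng.random((n_live, ndim))
    theta_live = np.empty_like(u_live)
    logl_live = np.empty(n_live)
    for i in range(n_live):
        theta_live[i], logl_live[i] = evaluate(u_live[i])

    dead_u: list[np.ndarray] = []
    dead_theta: list[np.ndarray] = []
    dead_logl: list[float] = []
    dead_logw: list[float] = []

    log_shrink = -1.0 / n_live                      # ln(X_i / X_{i-1})
    logw_step = math.log1p(-math.exp(log_shrink))   # ln(1 - e^{-1/n})
    logz = -math.inf
    scale = 0.1
    it = 0
    while it < max_iter:
        it += 1
        worst = int(np.argmin(logl_live))
        logl_star = float(logl_live[worst])
        logx_prev = (it - 1) * log_shrink
        logw = logx_prev + logw_step
        logz = np.logaddexp(logz, logl_star + logw)
        dead_u.append(u_live[worst].copy())
        dead_theta.append(theta_live[worst].copy())
        dead_logl.append(logl_star)
        dead_logw.append(logw)

        # replace the worst point: random walk from a random live point,
        # constrained to L >= L*; acceptance rate steers the step size
        start = int(rng.integers(n_live - 1))
        if start >= worst:  # copy any survivor, not the discarded point
            start += 1
        u_cur = u_live[start].copy()
        th_cur = theta_live[start].copy()
        ll_cur = float(logl_live[start])
        n_acc = n_rej = 0
        for _ in range(mcmc_steps):
            u_prop = u_cur + scale * rng.standard_normal(ndim)
            if np.any(u_prop < 0.0) or np.any(u_prop > 1.0):
                n_rej += 1
                continue
            th_prop, ll_prop = evaluate(u_prop)
            if ll_prop >= logl_star:
                u_cur, th_cur, ll_cur = u_prop, th_prop, ll_prop
                n_acc += 1
            else:
                n_rej += 1
        if n_acc > n_rej:
            scale *= math.exp(1.0 / max(n_acc, 1))
        elif n_rej > n_acc:
            scale /= math.exp(1.0 / max(n_rej, 1))
        scale = min(max(scale, 1e-6), 10.0)
        u_live[worst], theta_live[worst], logl_live[worst] = u_cur, th_cur, ll_cur

        logx = it * log_shrink
        remaining = float(np.max(logl_live)) + logx
        if remaining - logz < math.log(termination_frac):
            break

    # sweep the survivors in with equal weights X_final / n_live
    logx_final = it * log_shrink
    logw_live = logx_final - math.log(n_live)
    order = np.argsort(logl_live)
    for i in order:
        logz = np.logaddexp(logz, float(logl_live[i]) + logw_live)
        dead_u.append(u_live[i].copy())
        dead_theta.append(theta_live[i].copy())
        dead_logl.append(float(logl_live[i]))
        dead_logw.append(logw_live)

    logl_arr = np.array(dead_logl)
    logw_arr = np.array(dead_logw)
    finite = np.isfinite(logl_arr)
    log_post = np.where(finite, logl_arr + logw_arr - logz, -np.inf)
    weights = np.exp(log_post)
    weights /= weights.sum()
    info = float(np.sum(weights[finite] * (logl_arr[finite] - logz)))
    err = math.sqrt(max(info, 0.0) / n_live) + 1e-12

    u_arr = np.array(dead_u)
    for d, name in enumerate(prior.names):
        edge = float(weights[(u_arr[:, d] < 0.01) | (u_arr[:, d] > 0.99)].sum())
        if edge > 0.01:
            warnings.warn(
                f"posterior mass ({edge:.1%}) abuts the prior bound of "
                f"{name!r}; consider widening the box",
                stacklevel=2,
            )

    return EvidenceResult(
        log_evidence=float(logz), log_evidence_error=err,
        samples=np.array(dead_theta), weights=weights,
        param_names=prior.names, n_live=n_live,
        seed=seed, n_iter=it, information=info,
    )


def jeffreys_verdict(log_bayes_factor: float) -> str:
    """Ordinal strength label for |ln B| on the adopted Jeffreys scale."""
    if not np.isfinite(log_bayes_factor):
        raise ValueError("log Bayes factor must be finite")
    a = abs(log_bayes_factor)
    t1, t2, t3 = JEFFREYS_THRESHOLDS
    if a < t1:
        return "inconclusive"
    if a < t2:
        return "moderate"
    if a < t3:
        return "strong"
    return "decisive"


def bayes_factor(
    evidence_i: EvidenceResult,
    evidence_j: EvidenceResult,
    compared_model: str = "maxwell",
    reference_model: str = "double",
) -> BayesComparison:
    """B_ij = E_i / E_j with model i compared against reference model j."""
    lnb = evidence_i.log_evidence - evidence_j.log_evidence
    if not np.isfinite(lnb):
        raise ValueError("both evidences must be finite")
    return BayesComparison(
        log_bayes_factor=float(lnb),
        bayes_factor=float(np.exp(lnb)),
        verdict=jeffreys_verdict(lnb),
        reference_model=reference_model,
        compared_model=compared_model,
    )
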
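"""Maximum-likelihood estimation of the advection-diffusion capture-recapture model.

The observation model is a Poisson count detector: individual ``i`` with
activity centre ``mu_i`` is detected at detector ``j`` on occasion ``k`` a
Poisson(lambda_ijk) number of times with

    lambda_ijk = exp(g0) * p*(s_j | mu_i),

where ``p*`` is the equilibrium utilization distribution of the movement
model.  Activity centres follow a homogeneous Poisson point process of log
density ``rho`` over the discretized region, i.e. a discrete uniform over
cell centres with prior weight ``a = h^2`` each.  Marginalizing the centres
and the unobserved individuals gives the full likelihood for the ``n``
detected individuals (Borchers-Efford form for count detectors):

    ln L = -exp(rho) * sum_m a (1 - exp(-Lambda(m)))
         + sum_i ln[ exp(rho) * sum_m a * prod_{j,k} Pois(y_ijk; lambda_j(m)) ]
         - ln n!,

with ``Lambda(m) = K * sum_j lambda_j(m)``.  One equilibrium solve per
candidate centre is needed per evaluation; solves are cached per
``(gamma0, beta)`` so that perturbations of ``rho`` and ``g0`` during
quasi-Newton iterations are cheap.  The ``-ln n!`` constant is kept so that
log-likelihoods are comparable across models; it does not affect the optimum.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.optimize
from scipy.special import gammaln, logsumexp

from .homerange import (HomeRangeParams, UtilizationDistribution,
                        build_generator, equilibrium_distribution)
from .landscape import Landscape
from .simulate import CaptureData

__all__ = [
    "AdcrParams",
    "FitResult",
    "AdcrModel",
    "detection_rates",
    "full_loglik",
    "fit_adcr",
    "predict_homerange",
]

_LOG_TINY = -745.0  # ln of the smallest positive double


@dataclass
class AdcrParams:
    """ADCR parameters, all on an unconstrained (log) scale."""

    rho: float
    g0: float
    gamma0: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        vals = [self.rho, self.g0, self.gamma0, *self.beta]
        if not np.all(np.isfinite(vals)):
            raise ValueError("parameters must be finite")

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.rho, self.g0, self.gamma0], self.beta])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "AdcrParams":
        x = np.asarray(x, dtype=float)
        return cls(x[0], x[1], x[2], x[3:])

    @property
    def names(self) -> list[str]:
        return ["rho", "g0", "gamma0"] + [f"beta_{i + 1}" for i in range(len(self.beta))]


@dataclass
class FitResult:
    """Maximum-likelihood fit: point estimates, uncertainty, diagnostics."""

    model: str
    params: dict[str, float]
    se: dict[str, float | None]
    ci: dict[str, tuple[float | None, float | None]]
    loglik: float
    converged: bool
    n_iter: int = 0
    n_evals: int = 0
    message: str = ""
    n_detected: int = 0
    trace: list = field(default_factory=list)

    def beta_vector(self) -> np.ndarray:
        keys = sorted(k for k in self.params if k.startswith("beta_"))
        return np.array([self.params[k] for k in keys])


def detection_rates(ud: UtilizationDistribution, g0: float,
                    detector_cells: np.ndarray) -> np.ndarray:
    """Expected detections per occasion at each detector: exp(g0) p*(s_j | mu)."""
    return np.exp(g0) * ud.p[np.asarray(detector_cells, dtype=int)]


def poisson_count_loglik(log_lambda: np.ndarray, rho: float, Ysum: np.ndarray,
                         K: int, a: float, log_y_factorials: float) -> float:
    """Shared full-likelihood skeleton given per-centre log detection rates.

    ``log_lambda`` is (n_centres, J): log per-occasion rate at each detector
    for an individual centred at each candidate cell.  ``Ysum`` is the (n, J)
    matrix of occasion-summed counts of the detected individuals.
    """
    log_lambda = np.maximum(log_lambda, _LOG_TINY)
    Lam = K * np.exp(log_lambda).sum(axis=1)  # (m,)
    surveyed = a * (1.0 - np.exp(-Lam))
    term1 = -np.exp(rho) * surveyed.sum()
    n = Ysum.shape[0]
    if n == 0:
        return float(term1)
    lw = Ysum @ log_lambda.T - Lam[None, :]   # (n, m) log prod_j Pois kernels
    li = logsumexp(lw, axis=1) + np.log(a)
    total = term1 + n * rho + li.sum() - gammaln(n + 1) - log_y_factorials
    if not np.isfinite(total):
        warnings.warn("non-finite log-likelihood; returning -inf")
        return -np.inf
    return float(total)


class AdcrModel:
    """ADCR likelihood machinery bound to one dataset and landscape.

    Caches the detector-column matrix ``U[m, j] = p*(s_j | mu_m)`` per
    ``(gamma0, beta)`` so repeated likelihood evaluations during optimization
    re-solve the PDE only when the movement parameters change.
    """

    def __init__(self, data: CaptureData, landscape: Landscape,
                 scheme: str = "exponential", cache_size: int = 32):
        self.data = data
        self.landscape = landscape
        self.scheme = scheme
        self.det_cells = data.detectors.cells(landscape)
        self.K = float(data.effort)
        self.a = landscape.h ** 2
        self.Ysum = data.Y.sum(axis=2).astype(float)  # (n, J)
        self.log_y_factorials = float(gammaln(data.Y + 1.0).sum())
        self._cache: dict[tuple, np.ndarray] = {}
        self._cache_size = cache_size
        self.n_evals = 0

    # -- home-range surfaces ------------------------------------------------
    def detector_surface(self, gamma0: float, beta: np.ndarray) -> np.ndarray:
        """U[m, j] = p*(s_j | mu_m) for every candidate centre m (all cells)."""
        key = (float(gamma0), tuple(np.asarray(beta, float).ravel()))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        land = self.landscape
        hr = HomeRangeParams(gamma0, beta)
        U = np.empty((land.n_cells, len(self.det_cells)))
        for m in range(land.n_cells):
            gen = build_generator(land, land.cell_center_of(m), hr,
                                  scheme=self.scheme)
            U[m] = equilibrium_distribution(gen).p[self.det_cells]
        if len(self._cache) >= self._cache_size:
            self._cache.pop(next(iter(self._cache)))
        self._cache[key] = U
        return U

    # -- likelihood ---------------------------------------------------------
    def loglik(self, params: AdcrParams) -> float:
        self.n_evals += 1
        U = self.detector_surface(params.gamma0, params.beta)
        with np.errstate(divide="ignore"):
            log_lambda = params.g0 + np.log(U)
        return poisson_count_loglik(log_lambda, params.rho, self.Ysum, self.K,
                                    self.a, self.log_y_factorials)

    def loglik_vector(self, x: np.ndarray) -> float:
        return self.loglik(AdcrParams.from_vector(x))

    def default_init(self) -> AdcrParams:
        """Crude moment-based starting values (kept deliberately simple)."""
        data, land = self.data, self.landscape
        n = max(data.n, 1)
        rho0 = float(np.log(n / land.area))
        total = max(data.total_detections, 1)
        det_per_ind = max(float((data.Y.sum(axis=2) > 0).sum(axis=1).mean())
                          if data.n else 1.0, 1.0)
        g00 = float(np.log(total / (n * self.K * det_per_ind)))
        gamma00 = self._displacement_gamma0()
        p = self.landscape.n_layers
        return AdcrParams(rho0, g00, gamma00, np.zeros(p))

    def _displacement_gamma0(self) -> float:
        """gamma0 start from the mean squared recapture displacement per axis."""
        coords = self.data.detectors.coords
        Ysum = self.Ysum
        ss, wt = 0.0, 0.0
        for i in range(self.data.n):
            y = Ysum[i]
            w = y.sum()
            if w < 2 or (y > 0).sum() < 2:
                continue
            mean = (coords * y[:, None]).sum(axis=0) / w
            dev2 = (((coords - mean) ** 2) * y[:, None]).sum() / w / 2.0  # per axis
            ss += dev2
            wt += 1.0
        if wt == 0:
            span = self.landscape.nx * self.landscape.h
            return float(np.log((span / 8.0) ** 2))
        return float(np.clip(np.log(max(ss / wt, 1e-3)), -5.0, 10.0))


def full_loglik(params: AdcrParams, data: CaptureData, landscape: Landscape,
                model: AdcrModel | None = None) -> float:
    """ADCR full log-likelihood (convenience wrapper around :class:`AdcrModel`)."""
    if model is None:
        model = AdcrModel(data, landscape)
    return model.loglik(params)


def _wald(names, mles, negloglik: Callable, x_opt: np.ndarray):
    """SEs and 95% Wald CIs from the numerically differenced observed information."""
    from statsmodels.tools.numdiff import approx_hess

    se = {k: None for k in names}
    ci = {k: (None, None) for k in names}
    try:
        H = approx_hess(x_opt, negloglik)
        evals = np.linalg.eigvalsh(H)
        if np.all(evals > 0):
            cov = np.linalg.inv(H)
            sd = np.sqrt(np.diag(cov))
            for k, m, s in zip(names, mles, sd):
                se[k] = float(s)
                ci[k] = (float(m - 1.96 * s), float(m + 1.96 * s))
        else:
            warnings.warn("Hessian not positive definite; SEs unavailable")
    except Exception as exc:  # numerical failure must not kill the fit
        warnings.warn(f"Hessian computation failed: {exc}")
    return se, ci


def _run_quasi_newton(negloglik: Callable, x0: np.ndarray, options: dict):
    opts = dict(maxiter=options.get("maxiter", 200),
                ftol=options.get("ftol", 1e-10),
                gtol=options.get("gtol", 1e-6),
                eps=options.get("eps", 1e-5))
    return scipy.optimize.minimize(negloglik, x0, method="L-BFGS-B", options=opts)


def fit_adcr(data: CaptureData, landscape: Landscape,
             init: AdcrParams | None = None,
             options: dict | None = None) -> FitResult:
    """Fit ADCR by quasi-Newton maximization of the full likelihood.

    Returns a :class:`FitResult` with MLEs, SEs from the inverse observed
    information, 95% Wald intervals and a convergence flag (non-convergence is
    flagged, never raised).
    """
    if data.n == 0:
        raise ValueError("cannot estimate all parameters from empty data")
    options = options or {}
    model = AdcrModel(data, landscape, scheme=options.get("scheme", "exponential"))
    if init is None:
        init = model.default_init()
    negloglik = lambda x: -model.loglik_vector(x)
    res = _run_quasi_newton(negloglik, init.to_vector(), options)
    mles = res.x
    names = AdcrParams.from_vector(mles).names
    if options.get("compute_se", True):
        se, ci = _wald(names, mles, negloglik, mles)
    else:
        se = {k: None for k in names}
        ci = {k: (None, None) for k in names}
    return FitResult(
        model="adcr",
        params={k: float(v) for k, v in zip(names, mles)},
        se=se,
        ci=ci,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_evals=model.n_evals,
        message=str(res.message),
        n_detected=data.n,
    )


def predict_homerange(fit: FitResult, mu, landscape: Landscape,
                      scheme: str = "exponential") -> UtilizationDistribution:
    """Equilibrium utilization distribution at the fitted (gamma0, beta)."""
    hr = HomeRangeParams(fit.params["gamma0"], fit.beta_vector())
    gen = build_generator(landscape, mu, hr, scheme=scheme)
    return equilibrium_distribution(gen)
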
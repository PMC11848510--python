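"""Comparison estimators: basic SCR and SCR with least-cost-path distance.

Both share the full-likelihood skeleton of the ADCR module; only the
detection function differs.  Basic SCR uses a Gaussian (half-normal) function
of Euclidean distance,

    ln(lambda_ijk) = g0 + g1 ||s_j - mu_i||^2,        g1 < 0,

and SCR-LCP replaces the Euclidean distance by the least-cost-path distance
``d_lcp(s_j, mu_i; g2)`` on the 8-neighbour lattice graph whose log unit cost
from cell ``s`` to adjacent ``s'`` is ``g2 (z(s) + z(s')) / 2`` (so a
positive ``g2`` means the covariate *impedes* movement -- the sign convention
is opposite to ADCR's permeability coefficient ``beta``).  The printed
formulation uses the unsquared distance for the LCP variant; the exponent is
configurable (``lcp_exponent`` in {1, 2}).

For home-range comparisons each fitted model also implies a utilization
surface proportional to ``exp(g1 d^q)`` renormalized over the region; the
euclidean variant additionally supports ``surface="gaussian"``, the
grid-renormalized Gaussian, which makes it exactly the beta = 0 reduction of
ADCR (with g1 = -1 / (2 exp(gamma0))).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import dijkstra
from scipy.special import logsumexp

from .homerange import UtilizationDistribution
from .inference import FitResult, _run_quasi_newton, _wald, poisson_count_loglik
from .landscape import Landscape
from .simulate import CaptureData

__all__ = [
    "ScrParams",
    "lcp_distances",
    "scr_loglik",
    "fit_scr",
    "scr_homerange",
    "ScrModel",
]


@dataclass
class ScrParams:
    """Basic / least-cost-path SCR parameters; g1 < 0 is enforced internally
    by optimizing log(-g1)."""

    rho: float
    g0: float
    g1: float
    g2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.g1 >= 0:
            raise ValueError("g1 must be negative")
        if self.g2 is not None:
            self.g2 = np.atleast_1d(np.asarray(self.g2, dtype=float))


def _lattice_graph(landscape: Landscape, g2) -> scipy.sparse.csr_matrix:
    """8-neighbour graph with edge cost exp(g2.(z+z')/2) * centre distance."""
    nx, ny, h = landscape.nx, landscape.ny, landscape.h
    g2 = np.atleast_1d(np.asarray(g2, dtype=float))
    logcost = landscape.z @ g2  # per-cell g2 . z
    idx = np.arange(nx * ny).reshape(ny, nx)
    rows, cols, wts = [], [], []

    def add(a, b, length):
        rows.append(a.ravel())
        cols.append(b.ravel())
        wts.append(np.exp(0.5 * (logcost[a.ravel()] + logcost[b.ravel()])) * length)

    if nx > 1:
        add(idx[:, :-1], idx[:, 1:], h)
    if ny > 1:
        add(idx[:-1, :], idx[1:, :], h)
    if nx > 1 and ny > 1:
        add(idx[:-1, :-1], idx[1:, 1:], h * np.sqrt(2.0))
        add(idx[1:, :-1], idx[:-1, 1:], h * np.sqrt(2.0))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    wts = np.concatenate(wts)
    n = nx * ny
    g = scipy.sparse.csr_matrix((wts, (rows, cols)), shape=(n, n))
    return g + g.T  # symmetric edge costs


def lcp_distances(landscape: Landscape, g2, sources, targets=None) -> np.ndarray:
    """Least-cost-path distances by Dijkstra on the 8-neighbour lattice.

    Returns a ``(len(sources), n_targets)`` matrix (targets default to all
    cells).  Symmetric in its arguments since edge costs are symmetric.
    """
    graph = _lattice_graph(landscape, g2)
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    dist = dijkstra(graph, directed=False, indices=sources)
    if targets is not None:
        dist = dist[:, np.atleast_1d(np.asarray(targets, dtype=int))]
    return dist


class ScrModel:
    """SCR likelihood machinery for euclidean or least-cost-path detection."""

    def __init__(self, data: CaptureData, landscape: Landscape,
                 mode: str = "euclidean", lcp_exponent: int = 1,
                 surface: str = "halfnormal", cache_size: int = 32):
        if mode not in ("euclidean", "lcp"):
            raise ValueError("mode must be 'euclidean' or 'lcp'")
        if lcp_exponent not in (1, 2):
            raise ValueError("lcp_exponent must be 1 or 2")
        self.data = data
        self.landscape = landscape
        self.mode = mode
        self.lcp_exponent = lcp_exponent
        self.surface = surface
        self.det_cells = data.detectors.cells(landscape)
        self.K = float(data.effort)
        self.a = landscape.h ** 2
        self.Ysum = data.Y.sum(axis=2).astype(float)
        from scipy.special import gammaln
        self.log_y_factorials = float(gammaln(data.Y + 1.0).sum())
        centers = landscape.cell_centers
        det_xy = centers[self.det_cells]
        diff = centers[:, None, :] - det_xy[None, :, :]
        self.d2 = (diff ** 2).sum(axis=2)           # (m, J) squared euclidean
        if surface == "gaussian":
            # log normalizer of the grid-renormalized Gaussian per centre
            dd = centers[:, None, :] - centers[None, :, :]
            self._all_d2 = (dd ** 2).sum(axis=2)    # (m, m)
        self._lcp_cache: dict[tuple, np.ndarray] = {}
        self._cache_size = cache_size
        self.n_evals = 0

    def _lcp_matrix(self, g2) -> np.ndarray:
        key = tuple(np.atleast_1d(np.asarray(g2, float)).ravel())
        hit = self._lcp_cache.get(key)
        if hit is None:
            hit = lcp_distances(self.landscape, g2, self.det_cells).T  # (m, J)
            if len(self._lcp_cache) >= self._cache_size:
                self._lcp_cache.pop(next(iter(self._lcp_cache)))
            self._lcp_cache[key] = hit
        return hit

    def log_lambda(self, params: ScrParams) -> np.ndarray:
        """(n_centres, J) log per-occasion detection rate."""
        if self.mode == "euclidean":
            if self.surface == "gaussian":
                logZ = logsumexp(params.g1 * self._all_d2, axis=1)
                return params.g0 + params.g1 * self.d2 - logZ[:, None]
            return params.g0 + params.g1 * self.d2
        d = self._lcp_matrix(params.g2)
        return params.g0 + params.g1 * d ** self.lcp_exponent

    def loglik(self, params: ScrParams) -> float:
        self.n_evals += 1
        return poisson_count_loglik(self.log_lambda(params), params.rho,
                                    self.Ysum, self.K, self.a,
                                    self.log_y_factorials)

    # -- unconstrained vector parameterization ------------------------------
    def n_params(self) -> int:
        return 3 + (self.landscape.n_layers if self.mode == "lcp" else 0)

    def names(self) -> list[str]:
        base = ["rho", "g0", "g1"]
        if self.mode == "lcp":
            base += [f"g2_{i + 1}" for i in range(self.landscape.n_layers)]
        return base

    def vector_to_params(self, x: np.ndarray) -> ScrParams:
        g2 = x[3:] if self.mode == "lcp" else None
        return ScrParams(x[0], x[1], -np.exp(x[2]), g2)

    def loglik_vector(self, x: np.ndarray) -> float:
        return self.loglik(self.vector_to_params(x))

    def loglik_natural(self, theta: np.ndarray) -> float:
        """Log-likelihood in the reported (rho, g0, g1[, g2]) parameterization."""
        g2 = theta[3:] if self.mode == "lcp" else None
        return self.loglik(ScrParams(theta[0], theta[1], theta[2], g2))

    def default_init(self) -> np.ndarray:
        data, land = self.data, self.landscape
        n = max(data.n, 1)
        rho0 = np.log(n / land.area)
        total = max(data.total_detections, 1)
        g00 = np.log(total / (n * self.K))
        sigma2 = self._displacement_sigma2()
        x = [rho0, g00, np.log(1.0 / (2.0 * sigma2))]  # log(-g1)
        if self.mode == "lcp":
            x += [0.0] * land.n_layers
        return np.array(x)

    def _displacement_sigma2(self) -> float:
        coords = self.data.detectors.coords
        ss, wt = 0.0, 0.0
        for i in range(self.data.n):
            y = self.Ysum[i]
            if y.sum() < 2 or (y > 0).sum() < 2:
                continue
            mean = (coords * y[:, None]).sum(axis=0) / y.sum()
            ss += (((coords - mean) ** 2) * y[:, None]).sum() / y.sum() / 2.0
            wt += 1.0
        if wt == 0:
            return (self.landscape.nx * self.landscape.h / 8.0) ** 2
        return max(ss / wt, 1e-3)


def scr_loglik(params: ScrParams, data: CaptureData, landscape: Landscape,
               mode: str = "euclidean", lcp_exponent: int = 1,
               surface: str = "halfnormal",
               model: ScrModel | None = None) -> float:
    """SCR full log-likelihood (same skeleton as the ADCR likelihood)."""
    if model is None:
        model = ScrModel(data, landscape, mode, lcp_exponent, surface)
    return model.loglik(params)


def fit_scr(data: CaptureData, landscape: Landscape, mode: str = "euclidean",
            init: np.ndarray | None = None,
            options: dict | None = None) -> FitResult:
    """Fit basic SCR (``mode='euclidean'``) or SCR-LCP (``mode='lcp'``)."""
    if data.n == 0:
        raise ValueError("cannot estimate all parameters from empty data")
    options = options or {}
    model = ScrModel(data, landscape, mode,
                     lcp_exponent=options.get("lcp_exponent", 1),
                     surface=options.get("surface", "halfnormal"))
    x0 = model.default_init() if init is None else np.asarray(init, dtype=float)
    negloglik = lambda x: -model.loglik_vector(x)
    res = _run_quasi_newton(negloglik, x0, options)
    params = model.vector_to_params(res.x)
    names = model.names()
    theta = [params.rho, params.g0, params.g1]
    if model.mode == "lcp":
        theta += list(params.g2)
    theta = np.array(theta)
    if options.get("compute_se", True):
        se, ci = _wald(names, theta, lambda t: -model.loglik_natural(t), theta)
    else:
        se = {k: None for k in names}
        ci = {k: (None, None) for k in names}
    return FitResult(
        model=f"scr-{mode}" if mode == "lcp" else "scr",
        params={k: float(v) for k, v in zip(names, theta)},
        se=se,
        ci=ci,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_evals=model.n_evals,
        message=str(res.message),
        n_detected=data.n,
    )


def scr_homerange(fit: FitResult, mu, landscape: Landscape,
                  mode: str = "euclidean",
                  lcp_exponent: int = 1) -> UtilizationDistribution:
    """Model-implied utilization surface: exp(g1 d^q) renormalized over cells."""
    g1 = fit.params["g1"]
    mu_cell = int(landscape.cell_index(mu[0], mu[1]))
    if mode == "euclidean":
        centers = landscape.cell_centers
        d = np.sqrt(((centers - centers[mu_cell]) ** 2).sum(axis=1))
        q = 2
    else:
        g2 = [fit.params[k] for k in sorted(fit.params) if k.startswith("g2_")]
        d = lcp_distances(landscape, np.array(g2), [mu_cell])[0]
        q = lcp_exponent
    logp = g1 * d ** q
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return UtilizationDistribution(p, (float(mu[0]), float(mu[1])),
                                   landscape.nx, landscape.ny, landscape.h)
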
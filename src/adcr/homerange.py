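"""Equilibrium home ranges from an advection-diffusion movement model.

An individual performs an Ornstein-Uhlenbeck-type movement: deterministic
drift of intensity ``c`` toward its activity centre ``mu`` plus a random walk
whose local intensity (permeability) ``D(x, y) = exp(beta0 + beta . z(x, y))``
depends on landscape covariates.  The probability density ``p`` of the
individual's location then evolves by an advection-diffusion equation with
reflecting (zero-flux) boundaries, and the home range is its equilibrium,
the utilization distribution ``p*(s | mu)``.

The continuum operator is discretized on the landscape raster as a
continuous-time Markov chain generator ``Q`` over cells (rook neighbourhood):
off-diagonal entries are non-negative jump rates, rows sum to zero, so total
probability is conserved and the reflecting boundary holds by construction.
Each cell face carries a conductance equal to the face-averaged permeability
``Df`` (Fickian diffusive flux, the circuit-theory analogue), combined with
an exponential-fitting (Scharfetter-Gummel) weighting of the drift across
the face,

    rate(L -> R) = Df/h^2 * B(-u h / Df),    B(x) = x / (e^x - 1),

where ``u`` is the drift velocity at the face.  The stationary density then
decays like ``exp(integral of v/D)`` along each axis: decay is slow through
permeable habitat, so home ranges skew toward high-permeability patches.
With spatially constant ``D`` the equilibrium is *exactly* the
grid-renormalized bivariate normal with variance ``exp(gamma0)`` per axis
(the model's Gaussian limit); a first-order upwind weighting of the drift is
available via ``scheme="upwind"``.

Only the ratio ``D/c`` is identifiable from equilibrium data, hence the
reparameterization ``gamma0 = beta0 - alpha0`` used for estimation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .landscape import Landscape

__all__ = [
    "MovementParams",
    "HomeRangeParams",
    "Generator",
    "UtilizationDistribution",
    "build_generator",
    "equilibrium_distribution",
    "gaussian_reference",
    "EquilibriumError",
]


class EquilibriumError(RuntimeError):
    """Raised when the stationary distribution cannot be solved reliably."""


@dataclass
class MovementParams:
    """Movement parameters on the natural (simulation) scale.

    alpha0 : log drift intensity, c = exp(alpha0).
    beta0  : log-permeability intercept.
    beta   : covariate coefficients of log-permeability.
    """

    alpha0: float
    beta0: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))

    @property
    def c(self) -> float:
        return float(np.exp(self.alpha0))

    def D(self, landscape: Landscape) -> np.ndarray:
        """Per-cell diffusion coefficient (permeability), flat order."""
        d = np.exp(self.beta0 + landscape.z @ self.beta)
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("non-finite or non-positive diffusion coefficient")
        return d

    @property
    def gamma0(self) -> float:
        return self.beta0 - self.alpha0


@dataclass
class HomeRangeParams:
    """Equilibrium (identifiable) parameters: gamma0 = beta0 - alpha0, beta."""

    gamma0: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        with np.errstate(over="ignore"):
            ratio = np.exp(self.gamma0)
        if not np.isfinite(ratio) or ratio <= 0:
            raise ValueError("exp(gamma0) must be finite and positive")

    def D_over_c(self, landscape: Landscape) -> np.ndarray:
        d = np.exp(self.gamma0 + landscape.z @ self.beta)
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("non-finite or non-positive diffusion coefficient")
        return d


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), the exponential-fitting weight, stably."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 - x[small] / 2.0
    big = x > 500.0
    out[big] = 0.0  # x e^-x underflows
    mid = ~small & ~big
    out[mid] = x[mid] / np.expm1(x[mid])
    return out


@dataclass(eq=False)
class Generator:
    """Sparse CTMC generator of the movement model for one activity centre.

    Rates are stored as four flat arrays over cells (east/west/north/south
    neighbour jumps); the diagonal is minus their sum, so every row of the
    implied matrix ``Q`` sums to zero exactly.
    """

    nx: int
    ny: int
    h: float
    mu: tuple[float, float]
    rate_e: np.ndarray
    rate_w: np.ndarray
    rate_n: np.ndarray
    rate_s: np.ndarray
    scheme: str = "exponential"

    @property
    def n(self) -> int:
        return self.nx * self.ny

    @property
    def diag(self) -> np.ndarray:
        return -(self.rate_e + self.rate_w + self.rate_n + self.rate_s)

    @property
    def max_rate(self) -> float:
        """Largest total outflow rate, max_i |Q_ii|."""
        return float(-self.diag.min()) if self.n > 1 else 0.0

    @property
    def Q(self) -> scipy.sparse.csr_matrix:
        """The generator as a sparse matrix (rows = origin cells)."""
        n, nx = self.n, self.nx
        q = np.arange(n)
        rows = [q]
        cols = [q]
        data = [self.diag]
        for rate, off in ((self.rate_e, 1), (self.rate_w, -1),
                          (self.rate_n, nx), (self.rate_s, -nx)):
            nz = np.flatnonzero(rate)
            rows.append(nz)
            cols.append(nz + off)
            data.append(rate[nz])
        return scipy.sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )

    def apply_left(self, v: np.ndarray) -> np.ndarray:
        """Return v @ Q without building the sparse matrix."""
        nx = self.nx
        res = v * self.diag
        if nx > 1 or self.ny > 1:
            res[1:] += v[:-1] * self.rate_e[:-1]
            res[:-1] += v[1:] * self.rate_w[1:]
        if self.ny > 1:
            res[nx:] += v[:-nx] * self.rate_n[:-nx]
            res[:-nx] += v[nx:] * self.rate_s[nx:]
        return res


def _face_rates(nx: int, ny: int, h: float, mu: tuple[float, float],
                Dc: np.ndarray, drift: float, scheme: str):
    """Jump-rate arrays for drift `drift * (mu - s)` and diffusion field Dc."""
    D2 = Dc.reshape(ny, nx)
    rate_e = np.zeros((ny, nx))
    rate_w = np.zeros((ny, nx))
    rate_n = np.zeros((ny, nx))
    rate_s = np.zeros((ny, nx))
    mux, muy = mu
    if scheme not in ("exponential", "upwind"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if nx > 1:
        xf = np.arange(1, nx) * h                      # face coordinates
        u = drift * (mux - xf)                         # (nx-1,)
        Df = 0.5 * (D2[:, :-1] + D2[:, 1:])            # face conductance
        if scheme == "exponential":
            phi = u[None, :] * h / Df
            rate_e[:, :-1] = Df / h ** 2 * _bernoulli(-phi)
            rate_w[:, 1:] = Df / h ** 2 * _bernoulli(phi)
        else:
            rate_e[:, :-1] = Df / h ** 2 + np.maximum(u[None, :], 0.0) / h
            rate_w[:, 1:] = Df / h ** 2 + np.maximum(-u[None, :], 0.0) / h
    if ny > 1:
        yf = np.arange(1, ny) * h
        v = drift * (muy - yf)                         # (ny-1,)
        Df = 0.5 * (D2[:-1, :] + D2[1:, :])
        if scheme == "exponential":
            phi = v[:, None] * h / Df
            rate_n[:-1, :] = Df / h ** 2 * _bernoulli(-phi)
            rate_s[1:, :] = Df / h ** 2 * _bernoulli(phi)
        else:
            rate_n[:-1, :] = Df / h ** 2 + np.maximum(v[:, None], 0.0) / h
            rate_s[1:, :] = Df / h ** 2 + np.maximum(-v[:, None], 0.0) / h
    return rate_e.ravel(), rate_w.ravel(), rate_n.ravel(), rate_s.ravel()


def build_generator(landscape: Landscape, mu, params,
                    scheme: str = "exponential") -> Generator:
    """Discretize the advection-diffusion operator for activity centre ``mu``.

    ``params`` may be :class:`MovementParams` (natural time scale; rates carry
    the drift intensity ``c`` explicitly) or :class:`HomeRangeParams` (time
    rescaled by ``1/c`` so only ``D/c = exp(gamma0 + beta . z)`` and a unit
    drift enter -- the equilibrium is identical).
    """
    mux, muy = float(mu[0]), float(mu[1])
    x0, x1, y0, y1 = landscape.extent
    if not (x0 <= mux <= x1 and y0 <= muy <= y1):
        raise ValueError(f"activity centre {mu} outside the landscape extent")
    if isinstance(params, MovementParams):
        Dc = params.D(landscape)
        drift = params.c
    elif isinstance(params, HomeRangeParams):
        Dc = params.D_over_c(landscape)
        drift = 1.0
    else:
        raise TypeError("params must be MovementParams or HomeRangeParams")
    re_, rw_, rn_, rs_ = _face_rates(
        landscape.nx, landscape.ny, landscape.h, (mux, muy), Dc, drift, scheme
    )
    return Generator(landscape.nx, landscape.ny, landscape.h, (mux, muy),
                     re_, rw_, rn_, rs_, scheme)


@dataclass(eq=False)
class UtilizationDistribution:
    """Per-cell probability mass of one individual's location at equilibrium."""

    p: np.ndarray
    mu: tuple[float, float]
    nx: int
    ny: int
    h: float = 1.0

    def grid(self) -> np.ndarray:
        """(ny, nx) view, southern row first."""
        return self.p.reshape(self.ny, self.nx)

    def same_grid(self, other: "UtilizationDistribution") -> bool:
        return (self.nx, self.ny) == (other.nx, other.ny) and np.isclose(
            self.h, other.h
        )


def _residual_inf_norm(gen: Generator, p: np.ndarray) -> float:
    return float(np.abs(gen.apply_left(p)).max())


def _stationary_banded(gen: Generator, anchor: int) -> np.ndarray:
    """Solve p^T Q = 0 by fixing p[anchor] = 1 in banded form, then renormalize."""
    n, nx, ny = gen.n, gen.nx, gen.ny
    bw = nx if ny > 1 else 1
    ab = np.zeros((2 * bw + 1, n))
    diag = gen.diag
    # M = Q^T in LAPACK band storage: ab[bw + i - j, j] = M[i, j]
    ab[bw, :] = diag
    ab[bw - 1, 1:] = gen.rate_w[1:]          # M[q-1, q] = rate (q -> q-1)
    ab[bw + 1, :-1] = gen.rate_e[:-1]        # M[q+1, q] = rate (q -> q+1)
    if ny > 1:
        ab[bw - nx, nx:] = gen.rate_s[nx:]   # M[q-nx, q]
        ab[bw + nx, :-nx] = gen.rate_n[:-nx]  # M[q+nx, q]
    # replace equation `anchor` with p[anchor] = 1
    for d in (-nx, -1, 1, nx) if ny > 1 else (-1, 1):
        j = anchor + d
        if 0 <= j < n and abs(d) <= bw:
            ab[bw - d, j] = 0.0
    ab[bw, anchor] = 1.0
    rhs = np.zeros(n)
    rhs[anchor] = 1.0
    p = scipy.linalg.solve_banded((bw, bw), ab, rhs, check_finite=False)
    return p


def _stationary_dense(gen: Generator, anchor: int) -> np.ndarray:
    M = gen.Q.T.toarray()
    M[anchor, :] = 0.0
    M[anchor, anchor] = 1.0
    rhs = np.zeros(gen.n)
    rhs[anchor] = 1.0
    return np.linalg.solve(M, rhs)


def _stationary_svd(gen: Generator) -> np.ndarray:
    _, _, vt = np.linalg.svd(gen.Q.T.toarray())
    p = vt[-1]
    return p * np.sign(p.sum())


def equilibrium_distribution(gen: Generator,
                             rtol: float = 1e-8) -> UtilizationDistribution:
    """Solve for the stationary distribution p* of the generator.

    Returns p >= 0 with sum 1 and residual ``||p^T Q||_inf <= rtol * max|Q|``.
    The linear system is solved in banded form with the probability pinned to
    1 at the activity-centre cell and renormalized (small grids use a dense
    solve); a dense smallest-singular-vector solve is the last resort.
    """
    n = gen.n
    if n == 1:
        return UtilizationDistribution(np.ones(1), gen.mu, gen.nx, gen.ny, gen.h)
    anchor_ix = min(int(gen.mu[0] / gen.h), gen.nx - 1)
    anchor_iy = min(int(gen.mu[1] / gen.h), gen.ny - 1)
    anchor = anchor_iy * gen.nx + anchor_ix
    scale = max(gen.max_rate, 1.0)
    tol = rtol * scale

    solvers = ([_stationary_dense] if n <= 64 else [_stationary_banded, _stationary_dense])
    last_res = np.inf
    for solver in solvers:
        try:
            p = solver(gen, anchor)
        except np.linalg.LinAlgError:
            continue
        p = np.where(p > 0, p, 0.0)
        s = p.sum()
        if s > 0 and np.all(np.isfinite(p)):
            p = p / s
            last_res = _residual_inf_norm(gen, p)
            if last_res <= tol:
                return UtilizationDistribution(p, gen.mu, gen.nx, gen.ny, gen.h)
    # fall back to the smallest singular vector (small systems only)
    if n <= 10_000:
        p = _stationary_svd(gen)
        p = np.where(p > 0, p, 0.0)
        p = p / p.sum()
        res = _residual_inf_norm(gen, p)
        if res <= tol:
            return UtilizationDistribution(p, gen.mu, gen.nx, gen.ny, gen.h)
        last_res = min(last_res, res)
    raise EquilibriumError(
        f"stationary solve failed: residual {last_res:.3e} > tolerance {tol:.3e} "
        f"(max rate {scale:.3e}, n={n})"
    )


def gaussian_reference(mu, gamma0: float, landscape: Landscape) -> UtilizationDistribution:
    """Cell-centre-evaluated bivariate normal N(mu, exp(gamma0) I), renormalized.

    This is the model's home range in the homogeneous-permeability limit
    (beta = 0) and doubles as the basic-SCR home-range surface.  Evaluation is
    at cell centres (not cell-integrated), matching the discretized operator
    whose beta = 0 equilibrium it reproduces.
    """
    mux, muy = float(mu[0]), float(mu[1])
    sigma2 = np.exp(gamma0)
    d2 = (landscape.cell_x - mux) ** 2 + (landscape.cell_y - muy) ** 2
    if sigma2 == 0.0 or not np.isfinite(sigma2):
        logp = np.where(d2 == d2.min(), 0.0, -np.inf)
    else:
        logp = -d2 / (2.0 * sigma2)
    logp -= logp.max()
    p = np.exp(logp)
    psum = p.sum()
    if psum == 0 or not np.isfinite(psum):  # degenerate: all mass at nearest cell
        p = np.where(d2 == d2.min(), 1.0, 0.0)
        psum = p.sum()
    return UtilizationDistribution(p / psum, (mux, muy), landscape.nx,
                                   landscape.ny, landscape.h)
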
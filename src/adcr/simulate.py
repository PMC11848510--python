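"""Forward simulation of movement tracks and capture-recapture datasets.

The data-generating process mirrors a step-selection-function view of the
movement model: at each unit time step the probability vector of the next
location is obtained by explicit (forward-Euler) propagation of the
advection-diffusion generator, and the location is drawn categorically.
Explicit Euler at dt = 1 violates positivity for realistic permeability, so
each unit step is split into ``m`` sub-steps with ``delta = 1/m`` chosen so
that ``1 + delta * Q_ii >= 0`` with a 10% margin.  Sampling the chain at every
sub-step and recording each m-th state draws from exactly the same
distribution as one categorical draw from ``(I + delta Q)^m``
(Chapman-Kolmogorov), and is what the numba kernel below does.

Detection uses count detectors: while the individual occupies a detector's
cell, the number of detections per time step is Poisson with mean
``exp(g0)``.  Individuals never detected are censored from the returned
capture data, as in a real survey.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .homerange import Generator, MovementParams, build_generator
from .landscape import Landscape, PatchSpec, generate_patch_landscape

__all__ = [
    "DetectorArray",
    "SimScenario",
    "SimTruth",
    "CaptureData",
    "baseline_detectors",
    "baseline_scenario",
    "required_substeps",
    "step_kernel",
    "simulate_track",
    "simulate_detections",
    "simulate_dataset",
    "simulate_iid_dataset",
    "sparse_scenario",
]

#: baseline survey geometry: 9 x 9 count detectors on cell indices 9..41 step 4
BASELINE_DET_LO = 9
BASELINE_DET_HI = 41
BASELINE_DET_SPACING = 4


@dataclass(eq=False)
class DetectorArray:
    """Locations (world coordinates) of count detectors plus occasion count."""

    coords: np.ndarray  # (J, 2)
    K: int = 1

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 2:
            raise ValueError("detector coords must be (J, 2)")
        if self.K < 1:
            raise ValueError("need at least one occasion")

    @property
    def J(self) -> int:
        return self.coords.shape[0]

    def cells(self, landscape: Landscape) -> np.ndarray:
        """Flat cell index of each detector (errors if outside the extent)."""
        return landscape.cell_index(self.coords[:, 0], self.coords[:, 1])

    def subset(self, keep: np.ndarray) -> "DetectorArray":
        return DetectorArray(self.coords[keep], self.K)


def grid_detectors(landscape: Landscape, lo: int, hi: int, spacing: int,
                   K: int = 1) -> DetectorArray:
    """Detectors at the centres of cells with ix, iy in {lo, lo+s, ..., hi}."""
    idx = np.arange(lo, hi + 1, spacing)
    xs = (idx + 0.5) * landscape.h
    gx, gy = np.meshgrid(xs, xs)
    return DetectorArray(np.column_stack([gx.ravel(), gy.ravel()]), K)


def baseline_detectors(landscape: Landscape, K: int = 1) -> DetectorArray:
    """The 81-detector baseline array (cells 9..41, spacing 4) of the 50x50 study."""
    return grid_detectors(landscape, BASELINE_DET_LO, BASELINE_DET_HI,
                          BASELINE_DET_SPACING, K)


@dataclass(eq=False)
class CaptureData:
    """Capture histories of the detected individuals.

    ``Y[i, j, k]`` is the detection count of individual ``i`` at detector
    ``j`` on occasion ``k``; every retained individual has at least one
    detection in total.

    ``effort`` is the number of unit-time detection opportunities behind each
    stored occasion column in total: the likelihood's expected count at a
    detector is ``effort * exp(g0) * p*``.  It defaults to the number of
    stored occasions ``K``; movement simulations store their counts summed
    over all ``T`` time steps in a single column and set ``effort = T`` so
    that ``g0`` keeps its per-time-step meaning.
    """

    detectors: DetectorArray
    Y: np.ndarray  # (n, J, K) non-negative integers
    effort: float | None = None

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y)
        if Y.ndim == 2:
            Y = Y[:, :, None]
        if Y.ndim != 3 or Y.shape[1] != self.detectors.J:
            raise ValueError("Y must have shape (n, J, K)")
        if Y.size and (np.any(Y < 0) or not np.issubdtype(Y.dtype, np.integer)):
            raise ValueError("counts must be non-negative integers")
        if Y.shape[0] and np.any(Y.sum(axis=(1, 2)) < 1):
            raise ValueError("every retained individual needs >= 1 detection")
        self.Y = Y
        if self.effort is None:
            self.effort = float(Y.shape[2])
        elif self.effort <= 0:
            raise ValueError("effort must be positive")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def K(self) -> int:
        return self.Y.shape[2]

    @property
    def total_detections(self) -> int:
        return int(self.Y.sum())


@dataclass(eq=False)
class SimScenario:
    """Everything needed to simulate one capture-recapture dataset."""

    landscape: Landscape
    detectors: DetectorArray
    rho: float = -2.0
    alpha0: float = -0.5
    beta0: float = 1.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(1))
    g0: float = -3.0
    T: int = 5000
    burn_in: int = 100
    seed: int = 0
    scheme: str = "exponential"

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not self.T > self.burn_in >= 0:
            raise ValueError("need T > burn_in >= 0")

    @property
    def movement_params(self) -> MovementParams:
        return MovementParams(self.alpha0, self.beta0, self.beta)


@dataclass(eq=False)
class SimTruth:
    """Ground truth for one simulated population (before censoring)."""

    N: int
    centers: np.ndarray          # (N,) flat cell index of each activity centre
    tracks: np.ndarray | None    # (N, T) int32 cell indices, or None
    Y_full: np.ndarray           # (N, J) uncensored detection counts
    params: dict


def required_substeps(gen: Generator, dt: float, margin: float = 0.1) -> int:
    """Smallest m with delta = dt/m satisfying positivity with a safety margin."""
    if dt == 0:
        return 1
    return max(1, math.ceil(dt * gen.max_rate * (1.0 + margin)))


def step_kernel(gen: Generator, cell: int, dt: float = 1.0,
                substeps: int | None = None) -> np.ndarray:
    """Probability vector over cells after time ``dt`` from a point mass at ``cell``.

    Returns the ``cell`` row of ``(I + delta Q)^substeps`` with
    ``delta = dt / substeps``.  If ``substeps`` is given but violates the
    positivity condition ``1 + delta Q_ii >= 0``, the call is refused and the
    required sub-step count reported.
    """
    needed = required_substeps(gen, dt, margin=0.0)
    if substeps is None:
        substeps = required_substeps(gen, dt)
    elif dt > 0 and dt / substeps > (1.0 / gen.max_rate if gen.max_rate > 0 else np.inf):
        raise ValueError(
            f"substeps={substeps} violates positivity; need at least {needed}"
        )
    v = np.zeros(gen.n)
    v[cell] = 1.0
    if dt == 0:
        return v
    delta = dt / substeps
    for _ in range(substeps):
        v = v + delta * gen.apply_left(v)
    return v


def _substep_tables(gen: Generator, delta: float):
    """Neighbour indices and cumulative probabilities of (I + delta Q) rows."""
    n, nx = gen.n, gen.nx
    q = np.arange(n)
    nbr = np.empty((n, 5), dtype=np.int64)
    prob = np.empty((n, 5))
    nbr[:, 0] = q
    prob[:, 0] = 1.0 + delta * gen.diag
    for col, (rate, off) in enumerate(
        ((gen.rate_e, 1), (gen.rate_w, -1), (gen.rate_n, nx), (gen.rate_s, -nx)),
        start=1,
    ):
        dest = np.clip(q + off, 0, n - 1)
        nbr[:, col] = np.where(rate > 0, dest, q)
        prob[:, col] = delta * rate
    cum = np.cumsum(prob, axis=1)
    cum[:, -1] = 1.0  # guard against roundoff
    return nbr, cum


@njit(cache=True)
def _track_kernel(nbr, cum, start, T, burn_in, m, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    track = np.empty(T, np.int64)
    cell = start
    for step in range(T + burn_in):
        for _ in range(m):
            u = np.random.random()
            for k in range(5):
                if u <= cum[cell, k]:
                    cell = nbr[cell, k]
                    break
        if step >= burn_in:
            track[step - burn_in] = cell
    return track


def simulate_track(gen: Generator, start_cell: int, T: int, burn_in: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Simulate a movement track of ``T`` unit steps after ``burn_in`` steps.

    One unit time step consists of ``m`` categorical sub-steps of the
    explicit-method chain; recorded states are exactly distributed as draws
    from the unit-step kernel.
    """
    m = required_substeps(gen, 1.0)
    nbr, cum = _substep_tables(gen, 1.0 / m)
    seed = int(rng.integers(0, 2**31 - 1))
    return _track_kernel(nbr, cum, int(start_cell), int(T), int(burn_in), m, seed)


def simulate_detections(track: np.ndarray, detectors: DetectorArray,
                        g0: float, landscape: Landscape,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-detector Poisson detection counts along one track (single occasion).

    At each time step spent in a detector's cell the count is
    Poisson(exp(g0)); cells without detectors never produce detections.
    """
    det_cells = detectors.cells(landscape)
    det_map = np.full(landscape.n_cells, -1, dtype=np.int64)
    det_map[det_cells] = np.arange(detectors.J)
    y = np.zeros(detectors.J, dtype=np.int64)
    at_det = det_map[track]
    hits = at_det >= 0
    if hits.any():
        counts = rng.poisson(np.exp(g0), size=int(hits.sum()))
        np.add.at(y, at_det[hits], counts)
    return y


def simulate_dataset(scenario: SimScenario,
                     store_tracks: bool = True) -> tuple[CaptureData, SimTruth]:
    """Simulate one full capture-recapture dataset under the movement model.

    Draws N ~ Poisson(exp(rho) * area), activity centres from the discrete
    uniform over cells, simulates every individual's track and detections,
    then censors individuals never detected.  Fully reproducible from
    ``scenario.seed``.
    """
    land = scenario.landscape
    rng = np.random.default_rng(scenario.seed)
    N = int(rng.poisson(np.exp(scenario.rho) * land.area))
    centers = rng.integers(0, land.n_cells, size=N)
    params = scenario.movement_params
    J = scenario.detectors.J
    Y_full = np.zeros((N, J), dtype=np.int64)
    tracks = np.zeros((N, scenario.T), dtype=np.int64) if store_tracks else None
    for i in range(N):
        mu = land.cell_center_of(int(centers[i]))
        gen = build_generator(land, mu, params, scheme=scenario.scheme)
        track = simulate_track(gen, int(centers[i]), scenario.T,
                               scenario.burn_in, rng)
        if store_tracks:
            tracks[i] = track
        Y_full[i] = simulate_detections(track, scenario.detectors, scenario.g0,
                                        land, rng)
    detected = Y_full.sum(axis=1) >= 1
    data = CaptureData(scenario.detectors, Y_full[detected][:, :, None],
                       effort=float(scenario.T))
    truth = SimTruth(
        N=N,
        centers=centers,
        tracks=tracks,
        Y_full=Y_full,
        params=dict(rho=scenario.rho, alpha0=scenario.alpha0,
                    beta0=scenario.beta0, beta=np.array(scenario.beta),
                    g0=scenario.g0, gamma0=scenario.beta0 - scenario.alpha0),
    )
    return data, truth


def simulate_iid_dataset(landscape: Landscape, detectors: DetectorArray,
                         rho: float, g0: float, gamma0: float, beta,
                         seed: int = 0,
                         scheme: str = "exponential") -> tuple[CaptureData, SimTruth]:
    """Simulate data i.i.d. from the observation model itself (no movement).

    Activity centres are uniform over cells and counts are independent
    Poisson draws with mean ``exp(g0) p*(s_j | mu)`` per occasion -- the exact
    likelihood's data-generating process, used for parameter-recovery checks.
    """
    from .homerange import HomeRangeParams, equilibrium_distribution

    rng = np.random.default_rng(seed)
    N = int(rng.poisson(np.exp(rho) * landscape.area))
    centers = rng.integers(0, landscape.n_cells, size=N)
    det_cells = detectors.cells(landscape)
    hr = HomeRangeParams(gamma0, beta)
    cache: dict[int, np.ndarray] = {}
    Y_full = np.zeros((N, detectors.J, detectors.K), dtype=np.int64)
    for i in range(N):
        c = int(centers[i])
        if c not in cache:
            gen = build_generator(landscape, landscape.cell_center_of(c), hr,
                                  scheme=scheme)
            cache[c] = equilibrium_distribution(gen).p[det_cells]
        lam = np.exp(g0) * cache[c]
        Y_full[i] = rng.poisson(lam[:, None], size=(detectors.J, detectors.K))
    detected = Y_full.sum(axis=(1, 2)) >= 1
    data = CaptureData(detectors, Y_full[detected])
    truth = SimTruth(N=N, centers=centers, tracks=None,
                     Y_full=Y_full.sum(axis=2),
                     params=dict(rho=rho, g0=g0, gamma0=gamma0,
                                 beta=np.atleast_1d(np.asarray(beta, float))))
    return data, truth


def baseline_scenario(seed: int = 0, *, nx: int = 50, ny: int = 50,
                      patch_spec: PatchSpec | None = None,
                      rho: float | None = None, alpha0: float | None = None,
                      beta: float | None = None, T: int = 5000,
                      burn_in: int = 100,
                      det_lo: int = BASELINE_DET_LO,
                      det_hi: int = BASELINE_DET_HI,
                      det_spacing: int = BASELINE_DET_SPACING) -> SimScenario:
    """One draw of the baseline study conditions.

    Landscape and true parameters are redrawn per call: five random patches on
    a 50 x 50 grid, rho ~ U(-3, -1), alpha0 ~ U(-1, 0), beta ~ U(-2, 2), with
    g0 = -3 and beta0 = 1 fixed.  Pass explicit values to pin any of them.
    """
    rng = np.random.default_rng(seed)
    spec = patch_spec or PatchSpec(seed=int(rng.integers(2**31 - 1)))
    land = generate_patch_landscape(nx, ny, spec)
    dets = grid_detectors(land, det_lo, det_hi, det_spacing)
    return SimScenario(
        landscape=land,
        detectors=dets,
        rho=float(rng.uniform(-3, -1)) if rho is None else rho,
        alpha0=float(rng.uniform(-1, 0)) if alpha0 is None else alpha0,
        beta0=1.0,
        beta=np.array([float(rng.uniform(-2, 2)) if beta is None else beta]),
        g0=-3.0,
        T=T,
        burn_in=burn_in,
        seed=int(rng.integers(2**31 - 1)),
    )


def sparse_scenario(base: SimScenario) -> SimScenario:
    """The sparse-data variant: weak detectability, detectors only on patches.

    Fixes g0 = -5, rho = -2, alpha0 = -0.5, beta = 2, beta0 = 1 and removes
    every detector whose cell carries the low-permeability covariate value;
    raises if no detector would remain.
    """
    land = base.landscape
    z = land.z[:, 0]
    det_cells = base.detectors.cells(land)
    keep = z[det_cells] > 0
    if not keep.any():
        raise ValueError("all detectors fall on low-permeability cells")
    return SimScenario(
        landscape=land,
        detectors=base.detectors.subset(keep),
        rho=-2.0,
        alpha0=-0.5,
        beta0=1.0,
        beta=np.array([2.0]),
        g0=-5.0,
        T=base.T,
        burn_in=base.burn_in,
        seed=base.seed,
        scheme=base.scheme,
    )
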
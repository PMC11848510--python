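"""Least-cost-path distances and the comparison SCR estimators."""
import itertools

import numpy as np
import pytest

from adcr import (CaptureData, DetectorArray, Landscape, fit_scr,
                  grid_detectors, lcp_distances, scr_homerange, scr_loglik)
from adcr.inference import poisson_count_loglik
from adcr.scr import ScrModel, ScrParams


def octile(a, b, nx):
    """Closed-form 8-neighbour lattice distance between flat cell indices."""
    ax, ay = a % nx, a // nx
    bx, by = b % nx, b // nx
    dx, dy = abs(ax - bx), abs(ay - by)
    return max(dx, dy) + (np.sqrt(2) - 1) * min(dx, dy)


def test_flat_cost_rook_neighbours():
    land = Landscape(5, 5)
    d = lcp_distances(land, [0.0], [12], [13])
    assert d[0, 0] == pytest.approx(1.0)


def test_flat_cost_equals_octile_everywhere():
    land = Landscape(6, 4)
    d = lcp_distances(land, [0.0], np.arange(24))
    for a in range(24):
        for b in range(24):
            assert d[a, b] == pytest.approx(octile(a, b, 6), abs=1e-12)


def brute_force_lcp(land, g2, src, dst, max_len=8):
    """Exhaustive path enumeration oracle on a small grid."""
    nx, ny = land.nx, land.ny
    logcost = land.z @ np.atleast_1d(g2)

    def neighbors(q):
        x, y = q % nx, q // nx
        for dx, dy in itertools.product((-1, 0, 1), repeat=2):
            if dx == dy == 0:
                continue
            px, py = x + dx, y + dy
            if 0 <= px < nx and 0 <= py < ny:
                length = np.hypot(dx, dy)
                yield py * nx + px, length

    best = [np.inf]

    def walk(q, cost, visited):
        if cost >= best[0] or len(visited) > max_len:
            return
        if q == dst:
            best[0] = cost
            return
        for p, length in neighbors(q):
            if p not in visited:
                step = np.exp(0.5 * (logcost[q] + logcost[p])) * length
                walk(p, cost + step, visited | {p})

    walk(src, 0.0, {src})
    return best[0]


def test_lcp_wall_matches_path_enumeration():
    """High-cost column: Dijkstra equals the brute-force minimum over paths."""
    z = np.zeros((5, 5))
    z[:, 2] = 1.0  # costly wall down the middle
    land = Landscape(5, 5, 1.0, z)
    src, dst = 10, 14  # flanking the wall on row 2
    d = lcp_distances(land, [5.0], [src], [dst])[0, 0]
    assert d == pytest.approx(brute_force_lcp(land, [5.0], src, dst), rel=1e-12)


def test_lcp_symmetry_and_triangle_inequality():
    rng = np.random.default_rng(0)
    land = Landscape(6, 6, 1.0, rng.normal(size=(6, 6)))
    d = lcp_distances(land, [0.7], np.arange(36))
    np.testing.assert_allclose(d, d.T, atol=1e-10)
    assert np.all(np.diag(d) == 0)
    for a, b, c in rng.integers(0, 36, size=(50, 3)):
        assert d[a, c] <= d[a, b] + d[b, c] + 1e-10


@pytest.fixture(scope="module")
def scr_data():
    land = Landscape(12, 12)
    dets = grid_detectors(land, 2, 10, 2, K=3)
    rng = np.random.default_rng(4)
    # i.i.d. draws from the euclidean half-normal SCR model itself
    rho, g0, g1 = -1.2, -0.3, -0.25
    N = rng.poisson(np.exp(rho) * land.area)
    cells = rng.integers(0, land.n_cells, N)
    centers = land.cell_centers[cells]
    det_xy = land.cell_centers[dets.cells(land)]
    d2 = ((centers[:, None, :] - det_xy[None, :, :]) ** 2).sum(axis=2)
    lam = np.exp(g0 + g1 * d2)
    Y = rng.poisson(lam[:, :, None].repeat(3, axis=2))
    keep = Y.sum(axis=(1, 2)) >= 1
    return land, dets, CaptureData(dets, Y[keep]), (rho, g0, g1)


def test_scr_loglik_empty_matches_first_term(scr_data):
    land, dets, data, _ = scr_data
    empty = CaptureData(dets, np.zeros((0, dets.J, 3), dtype=int))
    params = ScrParams(-1.0, -0.5, -0.3)
    ll = scr_loglik(params, empty, land)
    model = ScrModel(empty, land)
    lam = np.exp(model.log_lambda(params))
    expected = -np.exp(-1.0) * np.sum(1 - np.exp(-3.0 * lam.sum(axis=1)))
    assert ll == pytest.approx(expected, rel=1e-12)


def test_lcp_zero_cost_collapses_to_octile_form(scr_data):
    """At g2 = 0 the LCP likelihood equals the euclidean-style functional form
    evaluated with the octile distance."""
    land, dets, data, _ = scr_data
    params = ScrParams(-1.0, -0.5, -0.3, [0.0])
    ll_lcp = scr_loglik(params, data, land, mode="lcp", lcp_exponent=1)
    model = ScrModel(data, land)
    det_cells = dets.cells(land)
    d_oct = np.array([[octile(m, c, land.nx) for c in det_cells]
                      for m in range(land.n_cells)])
    ll_direct = poisson_count_loglik(params.g0 + params.g1 * d_oct, params.rho,
                                     model.Ysum, model.K, model.a,
                                     model.log_y_factorials)
    assert ll_lcp == pytest.approx(ll_direct, rel=1e-12)


def test_scr_parameter_recovery_over_replicates():
    """Self-generated euclidean-SCR data: each parameter within 2 SE of truth
    in >= 90% of 20 replicates."""
    land = Landscape(12, 12)
    dets = grid_detectors(land, 2, 10, 2, K=3)
    det_xy = land.cell_centers[dets.cells(land)]
    truth = dict(rho=-1.2, g0=-0.3, g1=-0.25)
    hits = {k: 0 for k in truth}
    n_rep = 20
    for r in range(n_rep):
        rng = np.random.default_rng(300 + r)
        N = rng.poisson(np.exp(truth["rho"]) * land.area)
        cells = rng.integers(0, land.n_cells, N)
        d2 = ((land.cell_centers[cells][:, None, :] - det_xy[None, :, :]) ** 2).sum(axis=2)
        Y = rng.poisson(np.exp(truth["g0"] + truth["g1"] * d2)[:, :, None]
                        .repeat(3, axis=2))
        data = CaptureData(dets, Y[Y.sum(axis=(1, 2)) >= 1])
        fit = fit_scr(data, land, mode="euclidean")
        for k, v in truth.items():
            if fit.se[k] is not None and abs(fit.params[k] - v) <= 2 * fit.se[k]:
                hits[k] += 1
    for k, cnt in hits.items():
        assert cnt >= 0.9 * n_rep, (k, cnt)


def test_scr_fit_deterministic(scr_data):
    land, _, data, _ = scr_data
    f1 = fit_scr(data, land, options={"compute_se": False})
    f2 = fit_scr(data, land, options={"compute_se": False})
    assert f1.params == f2.params


def test_scr_homerange_surface_properties(scr_data):
    land, _, data, _ = scr_data
    fit = fit_scr(data, land, options={"compute_se": False})
    ud = scr_homerange(fit, (6.5, 6.5), land, mode="euclidean")
    assert ud.p.sum() == pytest.approx(1.0, abs=1e-12)
    g = ud.grid()
    np.testing.assert_allclose(g[5, :], g[7, :], atol=1e-12)  # symmetric about mu
    np.testing.assert_allclose(g[:, 5], g[:, 7], atol=1e-12)
    assert g[6, 6] == g.max()


def test_lcp_homerange_wall_blocks_mass():
    """A strong cost wall depresses mass beyond it relative to euclidean."""
    z = np.zeros((9, 9))
    z[:, 4] = 1.0
    land = Landscape(9, 9, 1.0, z)
    from adcr.inference import FitResult

    mk = lambda params: FitResult("x", params, {}, {}, 0.0, True)
    mu = (2.5, 4.5)
    beyond = np.flatnonzero(land.cell_x > 5.0)
    p_euc = scr_homerange(mk({"g1": -0.2}), mu, land, mode="euclidean")
    p_lcp = scr_homerange(mk({"g1": -0.2, "g2_1": 3.0}), mu, land, mode="lcp",
                          lcp_exponent=2)
    assert p_lcp.p[beyond].sum() < p_euc.p[beyond].sum()
    # and the attenuation grows with the cost coefficient
    p_lcp2 = scr_homerange(mk({"g1": -0.2, "g2_1": 6.0}), mu, land, mode="lcp",
                           lcp_exponent=2)
    assert p_lcp2.p[beyond].sum() < p_lcp.p[beyond].sum()
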
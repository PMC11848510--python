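"""ADCR likelihood and maximum-likelihood fitting."""
import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import poisson

from adcr import (CaptureData, DetectorArray, HomeRangeParams, Landscape,
                  build_generator, detection_rates, equilibrium_distribution,
                  fit_adcr, full_loglik, predict_homerange,
                  simulate_iid_dataset)
from adcr.inference import AdcrModel, AdcrParams


def test_detection_rates_identities():
    land = Landscape(50, 50)
    ud = equilibrium_distribution(
        build_generator(land, (25.5, 25.5), HomeRangeParams(1.0, [0.0])))
    cells = np.array([0, 1275, 2499])
    lam0 = detection_rates(ud, 0.0, cells)
    np.testing.assert_allclose(lam0, ud.p[cells])  # g0 = 0 is the identity
    # uniform p* over 2500 cells at g0 = -3: every rate is e^-3 / 2500
    uniform = ud
    uniform.p = np.full(2500, 1 / 2500)
    lam = detection_rates(uniform, -3.0, cells)
    np.testing.assert_allclose(lam, np.exp(-3.0) / 2500, rtol=1e-12)
    zero = ud
    zero.p = np.zeros(2500)
    assert detection_rates(zero, 1.0, cells).sum() == 0


def test_loglik_no_detections(two_cell_world):
    land, dets = two_cell_world
    params = AdcrParams(-1.0, -0.5, 0.3, [0.2])
    data = CaptureData(dets, np.zeros((0, 1, 1), dtype=int))
    ll = full_loglik(params, data, land)
    # independent recomputation of the survey-exposure term
    ud_fn = lambda q: equilibrium_distribution(
        build_generator(land, land.cell_center_of(q),
                        HomeRangeParams(0.3, [0.2])))
    det_cell = int(dets.cells(land)[0])
    lam = np.array([np.exp(-0.5) * ud_fn(m).p[det_cell] for m in range(2)])
    expected = -np.exp(-1.0) * np.sum(1.0 - np.exp(-lam))
    assert ll == pytest.approx(expected, abs=1e-12)


def test_loglik_two_cell_hand_computation(two_cell_world):
    """One individual with y = 1: the likelihood formula evaluated by hand."""
    land, dets = two_cell_world
    params = AdcrParams(-1.0, -0.5, 0.3, [0.2])
    data = CaptureData(dets, np.array([[[1]]], dtype=int))
    det_cell = int(dets.cells(land)[0])
    lam = []
    for m in range(2):
        ud = equilibrium_distribution(
            build_generator(land, land.cell_center_of(m),
                            HomeRangeParams(0.3, [0.2])))
        lam.append(np.exp(-0.5) * ud.p[det_cell])
    lam = np.array(lam)
    term1 = -np.exp(-1.0) * np.sum(1.0 - np.exp(-lam))
    term2 = np.log(np.exp(-1.0) * np.sum(poisson.pmf(1, lam)))
    expected = term1 + term2 - math.log(math.factorial(1))
    assert full_loglik(params, data, land) == pytest.approx(expected, abs=1e-10)


def test_loglik_normalizes_over_all_datasets(two_cell_world):
    """Exhaustive enumeration: exp(ln L) summed over every possible dataset
    (n <= 3 individuals, counts <= 20) approaches 1."""
    land, dets = two_cell_world
    params = AdcrParams(-1.5, -0.3, 0.2, [0.4])
    total = math.exp(full_loglik(params, CaptureData(
        dets, np.zeros((0, 1, 1), dtype=int)), land))
    for n in range(1, 4):
        for ys in itertools.combinations_with_replacement(range(1, 21), n):
            cnt = Counter(ys)
            perms = math.factorial(n)
            for v in cnt.values():
                perms //= math.factorial(v)
            Y = np.array(ys, dtype=int).reshape(n, 1, 1)
            ll = full_loglik(params, CaptureData(dets, Y), land)
            total += perms * math.exp(ll)
    assert total == pytest.approx(1.0, abs=1e-4)


def test_caching_does_not_change_loglik(patchy15, dets15):
    data, _ = simulate_iid_dataset(patchy15, dets15, rho=-0.6, g0=0.5,
                                   gamma0=1.0, beta=[1.0], seed=11)
    params = AdcrParams(-0.7, 0.4, 0.9, [0.8])
    model = AdcrModel(data, patchy15)
    first = model.loglik(params)
    second = model.loglik(params)  # cached surface
    fresh = AdcrModel(data, patchy15).loglik(params)
    assert abs(first - second) <= 1e-10
    assert abs(first - fresh) <= 1e-10


def test_local_optimality_at_mle(patchy15, dets15):
    """Perturbing any parameter away from the MLE decreases the likelihood."""
    data, _ = simulate_iid_dataset(patchy15, dets15, rho=-0.6, g0=0.5,
                                   gamma0=1.0, beta=[1.0], seed=11)
    fit = fit_adcr(data, patchy15, options={"compute_se": False})
    model = AdcrModel(data, patchy15)
    x = np.array([fit.params["rho"], fit.params["g0"], fit.params["gamma0"],
                  fit.params["beta_1"]])
    best = model.loglik_vector(x)
    for i in range(4):
        for eps in (-0.05, 0.05):
            xp = x.copy()
            xp[i] += eps
            assert model.loglik_vector(xp) < best + 1e-9


def test_fit_recovers_truth_single_replicate(patchy15, dets15):
    data, truth = simulate_iid_dataset(patchy15, dets15, rho=-0.6, g0=0.5,
                                       gamma0=1.0, beta=[1.0], seed=11)
    fit = fit_adcr(data, patchy15)
    assert fit.converged
    truthp = dict(rho=-0.6, g0=0.5, gamma0=1.0, beta_1=1.0)
    for k, v in truthp.items():
        assert fit.se[k] is not None and fit.se[k] > 0
        lo, hi = fit.ci[k]
        assert hi - lo == pytest.approx(2 * 1.96 * fit.se[k], rel=1e-9)
        assert abs(fit.params[k] - v) < 4 * fit.se[k]


def test_predict_homerange_deterministic_and_exact(patchy15, dets15):
    data, _ = simulate_iid_dataset(patchy15, dets15, rho=-0.6, g0=0.5,
                                   gamma0=1.0, beta=[1.0], seed=11)
    fit = fit_adcr(data, patchy15, options={"compute_se": False})
    mu = (7.5, 7.5)
    a = predict_homerange(fit, mu, patchy15)
    b = predict_homerange(fit, mu, patchy15)
    np.testing.assert_array_equal(a.p, b.p)
    # at the true parameters the prediction IS the true utilization distribution
    direct = equilibrium_distribution(
        build_generator(patchy15, mu,
                        HomeRangeParams(fit.params["gamma0"],
                                        [fit.params["beta_1"]])))
    np.testing.assert_allclose(a.p, direct.p, atol=1e-14)


def test_fit_empty_data_raises(two_cell_world):
    land, dets = two_cell_world
    with pytest.raises(ValueError):
        fit_adcr(CaptureData(dets, np.zeros((0, 1, 1), dtype=int)), land)
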
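"""Overlap coefficient, highest-density areas, and accuracy aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from adcr import (HomeRangeParams, Landscape, accuracy_summary,
                  build_generator, equilibrium_distribution,
                  gaussian_reference, hda90, overlap_coefficient)
from adcr.homerange import UtilizationDistribution
from adcr.metrics import AccuracyTable, region_cells


def ud_from(p, nx, ny, h=1.0):
    p = np.asarray(p, dtype=float)
    return UtilizationDistribution(p / p.sum(), (0.0, 0.0), nx, ny, h)


def test_overlap_identity_and_disjoint():
    p = ud_from([0.2, 0.3, 0.5, 0.0], 2, 2)
    q = ud_from([0.0, 0.0, 0.0, 1.0], 2, 2)
    assert overlap_coefficient(p, p) == pytest.approx(1.0)
    assert overlap_coefficient(ud_from([1, 0, 0, 0], 2, 2), q) == 0.0


def test_overlap_hand_sum():
    p = ud_from([0.5, 0.5, 0.0], 3, 1)
    q = ud_from([0.0, 0.5, 0.5], 3, 1)
    assert overlap_coefficient(p, q) == pytest.approx(0.5)


def test_overlap_symmetry_bounds_random():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = ud_from(rng.random(12), 4, 3)
        q = ud_from(rng.random(12), 4, 3)
        o = overlap_coefficient(p, q)
        assert 0.0 <= o <= 1.0
        assert o == pytest.approx(overlap_coefficient(q, p))
        assert o < 1.0 or np.allclose(p.p, q.p)


_masses = hnp.arrays(np.float64, 12,
                     elements=st.floats(1e-6, 1.0, allow_nan=False))


@settings(max_examples=50, derandomize=True, deadline=None)
@given(_masses, _masses)
def test_overlap_properties_hold_for_arbitrary_masses(a, b):
    p, q = ud_from(a, 4, 3), ud_from(b, 4, 3)
    o = overlap_coefficient(p, q)
    assert 0.0 <= o <= 1.0 + 1e-12
    assert o == pytest.approx(overlap_coefficient(q, p))
    assert overlap_coefficient(p, p) == pytest.approx(1.0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(_masses)
def test_hda_bounds_for_arbitrary_masses(a):
    ud = ud_from(a, 4, 3, h=0.5)
    area = hda90(ud)
    assert 0.25 <= area <= 12 * 0.25  # between one cell and the whole grid
    # covering less mass can never need more area
    assert hda90(ud, mass=0.5) <= area


def test_overlap_grid_mismatch_raises():
    with pytest.raises(ValueError):
        overlap_coefficient(ud_from(np.ones(4), 2, 2), ud_from(np.ones(6), 3, 2))


def test_hda_uniform_and_point_mass():
    assert hda90(ud_from(np.ones(100), 10, 10)) == pytest.approx(90.0)
    p = np.zeros(100)
    p[3] = 1.0
    assert hda90(ud_from(p, 10, 10)) == pytest.approx(1.0)


def test_hda_gaussian_closed_form():
    """Fine-grid N(0, sigma^2 I): HDA90 ~ 2 pi sigma^2 ln 10 within 2%."""
    sigma = 1.0
    h = sigma / 10
    land = Landscape(101, 101, h)
    ud = gaussian_reference((101 * h / 2, 101 * h / 2), np.log(sigma**2), land)
    expected = 2 * np.pi * sigma**2 * np.log(10)
    assert hda90(ud) == pytest.approx(expected, rel=0.02)


def test_hda_monotone_under_spread():
    """HDA90 grows with the variance of nested Gaussians."""
    land = Landscape(61, 61)
    areas = [hda90(gaussian_reference((30.5, 30.5), g, land))
             for g in (0.0, 0.5, 1.0, 1.5, 2.0)]
    assert np.all(np.diff(areas) > 0)


def test_accuracy_summary_trivials():
    t = accuracy_summary(pd.DataFrame({"true": [0.0, 1.0], "est": [0.0, 1.0]}))
    agg = t.aggregate("true", "est")
    assert agg["rmse"] == 0.0 and agg["mbe"] == 0.0
    t2 = accuracy_summary(pd.DataFrame({"true": [0.0, 1.0], "est": [1.0, 2.0]}))
    agg2 = t2.aggregate("true", "est")
    assert agg2["rmse"] == pytest.approx(1.0)
    assert agg2["mbe"] == pytest.approx(1.0)


def test_accuracy_summary_hand_computation():
    true = np.array([0.0, 1.0, 2.0])
    est = np.array([0.1, 0.9, 2.1])
    t = accuracy_summary(pd.DataFrame({"true": true, "est": est}))
    agg = t.aggregate("true", "est")
    assert agg["rmse"] == pytest.approx(0.1)
    assert agg["mbe"] == pytest.approx(1 / 30)
    # Pearson r by the hand formula
    r = (np.sum((true - 1.0) * (est - est.mean()))
         / np.sqrt(np.sum((true - 1.0) ** 2) * np.sum((est - est.mean()) ** 2)))
    assert agg["pearson_r"] == pytest.approx(r)


def test_rmse_bounds_mbe_on_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(10):
        df = pd.DataFrame({"true": rng.normal(size=30),
                           "est": rng.normal(size=30)})
        agg = accuracy_summary(df).aggregate("true", "est")
        # one-line reference implementation
        err = df["est"] - df["true"]
        assert agg["rmse"] == pytest.approx(float(np.sqrt((err**2).mean())))
        assert agg["mbe"] == pytest.approx(float(err.mean()))
        assert agg["rmse"] >= abs(agg["mbe"])


def test_ci_exclusion_count():
    df = pd.DataFrame({"true": [1.0] * 4, "est": [1.0] * 4,
                       "lo": [0.5, -0.5, 0.1, -1.0],
                       "hi": [1.5, 0.5, 0.2, -0.1]})
    agg = accuracy_summary(df).aggregate("true", "est", "lo", "hi")
    assert agg["ci_exclusion_count"] == 3


def test_beta_bins_partition():
    df = pd.DataFrame({"true_beta": [-2.0, -0.5, 0.0, 0.5, 1.7],
                       "true": np.zeros(5), "est": np.zeros(5)})
    tab = AccuracyTable(df).by_beta_bins("true_beta", "true", "est")
    ns = tab.set_index("bin")["n"]
    assert ns["Total"] == 5
    assert ns["beta < -0.5"] + ns["|beta| <= 0.5"] + ns["beta > 0.5"] == 5


def test_region_cells_shape_and_error():
    land = Landscape(50, 50)
    cells = region_cells(land, 9, 41)
    assert len(cells) == 33 * 33
    assert cells.min() == 9 * 50 + 9
    with pytest.raises(ValueError):
        region_cells(land, 10, 9)


def test_mean_overlap_identical_models_is_one():
    from adcr.metrics import mean_overlap_over_array

    land = Landscape(9, 9)
    fn = lambda mu: equilibrium_distribution(
        build_generator(land, mu, HomeRangeParams(0.5, [0.0])))
    val = mean_overlap_over_array(fn, fn, land, region_cells(land, 3, 5))
    assert val == pytest.approx(1.0)
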
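"""Replicate statistics, threshold scans, dose-response fits and comparison."""

import math

import numpy as np
import pytest

import dsbkit as dk
from oracles import normal_equations_quadratic

TABLE1_DOSES = [25.0, 50.0, 100.0, 150.0, 200.0]
TABLE1_P = [0.043, 0.081, 0.149, 0.196, 0.242]

# elevated doses at which the parametric track model actually deposits
# multiple interaction clusters on a small naked-DNA fixture (see
# docs/methods.md on dose scale)
FIXTURE_DOSES_GY = [2.0e5, 6.0e5, 1.2e6]


# --- P(DSB) statistics -----------------------------------------------------

def test_pdsb_hand_example():
    point = dk.estimate_pdsb([1, 0, 0, 0])
    assert point.p_dsb == 0.25
    assert point.sd == pytest.approx(0.5)
    assert point.sem == pytest.approx(0.25)


def test_pdsb_all_false_has_zero_sem():
    point = dk.estimate_pdsb([False] * 10)
    assert point.p_dsb == 0.0 and point.sem == 0.0


def test_pdsb_requires_two_replicates():
    with pytest.raises(ValueError):
        dk.estimate_pdsb([True])


def test_sem_matches_bernoulli_closed_form(rng):
    for _ in range(100):
        n = int(rng.integers(2, 400))
        flags = rng.random(n) < rng.random()
        point = dk.estimate_pdsb(flags)
        p = point.p_dsb
        expected = math.sqrt(p * (1 - p) * n / (n - 1)) / math.sqrt(n)
        assert point.sem == pytest.approx(expected, abs=1e-12)


def test_pdsb_recovers_binomial_rate(rng):
    rate = 0.043  # the experimental 25 Gy break probability
    flags = rng.random(1000) < rate
    point = dk.estimate_pdsb(flags)
    sem_true = math.sqrt(rate * (1 - rate) / 1000)
    assert abs(point.p_dsb - rate) < 3 * sem_true


# --- quadratic dose-response fit -------------------------------------------

def test_fit_recovers_noiseless_linear_response():
    points = [
        dk.DoseResponsePoint(dose_gy=d, p_dsb=2e-3 * d, sem=0.0,
                             n_replicates=2)
        for d in TABLE1_DOSES
    ]
    fit = dk.fit_dose_response(points)
    assert abs(fit.a) < 1e-12
    assert fit.b == pytest.approx(2e-3, abs=1e-12)
    assert abs(fit.c) < 1e-12


def test_fit_of_experimental_table_matches_normal_equations():
    points = dk.load_experimental_table()
    fit = dk.fit_dose_response(points)
    a, b, c = normal_equations_quadratic(TABLE1_DOSES, TABLE1_P)
    assert fit.a == pytest.approx(a, rel=1e-9)
    assert fit.b == pytest.approx(b, rel=1e-9)
    assert fit.c == pytest.approx(c, rel=1e-9)
    # the linear coefficient reproduces 1.7e-3 / Gy at two significant figures
    assert float(f"{fit.b:.2g}") == pytest.approx(1.7e-3)


def test_fit_invariant_to_point_order():
    points = dk.load_experimental_table()
    fit1 = dk.fit_dose_response(points)
    fit2 = dk.fit_dose_response(points[::-1])
    assert (fit1.a, fit1.b, fit1.c) == pytest.approx((fit2.a, fit2.b, fit2.c))


def test_fit_needs_three_distinct_doses():
    points = [
        dk.DoseResponsePoint(dose_gy=d, p_dsb=0.1, sem=0.0, n_replicates=2)
        for d in (25.0, 25.0, 50.0)
    ]
    with pytest.raises(ValueError):
        dk.fit_dose_response(points)


def test_fit_residuals_evaluate_at_printed_doses():
    points = dk.load_experimental_table()
    fit = dk.fit_dose_response(points)
    predicted = fit.predict(TABLE1_DOSES)
    assert np.allclose(np.array(TABLE1_P) - predicted, fit.residuals)


# --- comparison ------------------------------------------------------------

def test_compare_identical_is_zero():
    exp = dk.load_experimental_table()
    result = dk.compare_to_experiment(exp, exp)
    assert result.max_abs == 0.0 and result.max_rel == 0.0


def test_compare_constant_offset():
    exp = dk.load_experimental_table()
    sim = [
        dk.DoseResponsePoint(dose_gy=p.dose_gy, p_dsb=p.p_dsb + 0.01,
                             sem=0.0, n_replicates=2)
        for p in exp
    ]
    result = dk.compare_to_experiment(sim, exp)
    assert np.allclose(result.table.abs_diff, 0.01)


def test_compare_rejects_dose_mismatch():
    exp = dk.load_experimental_table()
    with pytest.raises(ValueError, match="dose mismatch"):
        dk.compare_to_experiment(exp[:-1], exp)


# --- experimental table I/O ------------------------------------------------

def test_packaged_table_contents():
    points = dk.load_experimental_table()
    assert [p.dose_gy for p in points] == TABLE1_DOSES
    assert [p.p_dsb for p in points] == TABLE1_P
    assert all(p.source == "experiment" for p in points)


def test_table_roundtrip(tmp_path):
    points = dk.load_experimental_table()
    path = tmp_path / "table.csv"
    dk.save_experimental_table(points, path)
    back = dk.load_experimental_table(path)
    assert [(p.dose_gy, p.p_dsb, p.sem) for p in back] == [
        (p.dose_gy, p.p_dsb, p.sem) for p in points
    ]


def test_table_missing_columns_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("dose_gy,prob\n25,0.04\n")
    with pytest.raises(ValueError, match="columns"):
        dk.load_experimental_table(path)


def test_table_empty_error(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("dose_gy,p_dsb,sem\n")
    with pytest.raises(ValueError, match="empty"):
        dk.load_experimental_table(path)


# --- simulation drivers ----------------------------------------------------

def test_dose_series_smoke_and_determinism(fixture_20bp, linac_spectrum,
                                           physics):
    params = dk.DamageParams()
    kwargs = dict(doses=FIXTURE_DOSES_GY[:2], n_replicates=3, base_seed=5,
                  pilot_primaries=500)
    first = dk.run_dose_series(fixture_20bp, linac_spectrum, physics, params,
                               **kwargs)
    second = dk.run_dose_series(fixture_20bp, linac_spectrum, physics, params,
                                **kwargs)
    assert [(p.dose_gy, p.p_dsb, p.sem) for p in first] == [
        (p.dose_gy, p.p_dsb, p.sem) for p in second
    ]
    for p in first:
        assert 0.0 <= p.p_dsb <= 1.0 and p.sem >= 0.0 and p.n_replicates == 3


def test_dose_series_monotone_within_3_sem(fixture_20bp, linac_spectrum,
                                           physics):
    points = dk.run_dose_series(
        fixture_20bp, linac_spectrum, physics, dk.DamageParams(et_ev=15.0),
        doses=FIXTURE_DOSES_GY, n_replicates=60, base_seed=11,
        pilot_primaries=1000,
    )
    assert points[-1].p_dsb > 0, "top dose produced no breaks"
    for lo, hi in zip(points, points[1:]):
        slack = 3 * math.hypot(lo.sem, hi.sem)
        assert hi.p_dsb >= lo.p_dsb - slack


def test_scan_1x1_grid_reduces_to_dose_series(fixture_20bp, linac_spectrum,
                                              physics):
    params = dk.DamageParams(et_ev=15.0, bpt_bp=10)
    kwargs = dict(doses=FIXTURE_DOSES_GY[:2], n_replicates=10, base_seed=21,
                  pilot_primaries=500)
    series = dk.run_dose_series(fixture_20bp, linac_spectrum, physics, params,
                                **kwargs)
    grid = dk.scan_thresholds(
        fixture_20bp, linac_spectrum, physics,
        et_values=[15.0], bpt_values=[10], **kwargs,
    )
    assert np.allclose(grid.p_dsb[0, 0, :], [p.p_dsb for p in series])
    assert np.allclose(grid.sem[0, 0, :], [p.sem for p in series])


def test_scan_monotone_in_et_and_bpt(fixture_20bp, linac_spectrum, physics):
    grid = dk.scan_thresholds(
        fixture_20bp, linac_spectrum, physics,
        et_values=[10.0, 19.0], bpt_values=[6, 14],
        doses=FIXTURE_DOSES_GY[:2], n_replicates=30, base_seed=31,
        pilot_primaries=1000,
    )
    # shared event streams make the orderings exact, not statistical
    assert np.all(grid.p_dsb[0] >= grid.p_dsb[1])  # lower ET breaks more
    assert np.all(grid.p_dsb[:, 0, :] <= grid.p_dsb[:, 1, :])  # wider BPT


def test_scan_rejects_empty_grid(fixture_20bp, linac_spectrum, physics):
    with pytest.raises(ValueError):
        dk.scan_thresholds(fixture_20bp, linac_spectrum, physics,
                           et_values=[], bpt_values=[10],
                           doses=FIXTURE_DOSES_GY[:1], n_replicates=2)


# --- parameter recovery under replicate noise -------------------------------

def test_fit_recovery_under_bernoulli_noise(rng):
    """Fitting seeded Bernoulli tables at N=1000 recovers the linear
    coefficient of the generating curve within 3 SE over 100 repeats."""
    truth = dk.fit_dose_response(dk.load_experimental_table())
    rates = np.clip(truth.predict(TABLE1_DOSES), 0.0, 1.0)
    n = 1000
    b_hats = []
    for _ in range(100):
        points = []
        for dose, rate in zip(TABLE1_DOSES, rates):
            flags = rng.random(n) < rate
            points.append(dk.estimate_pdsb(flags, dose_gy=dose))
        b_hats.append(dk.fit_dose_response(points).b)
    b_hats = np.asarray(b_hats)
    se_mean = b_hats.std(ddof=1) / math.sqrt(len(b_hats))
    assert abs(b_hats.mean() - truth.b) < 3 * se_mean
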
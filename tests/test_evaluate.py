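"""Sliding windows, thresholds, detection outcomes, and score vectorisation."""

import math

import numpy as np
import pytest

from omegascan import ScanParams, scan_location
from omegascan.evaluate import (
    detection_threshold,
    empirical_threshold,
    nearest_rank,
    sensitivity_specificity,
    sliding_windows,
    window_scores,
)
from omegascan.omega import OmegaReport, OmegaResult
from omegascan.stats import (
    dv_k_h,
    fay_wu_h_norm,
    fu_li_dstar,
    fu_li_fstar,
    hudsons_c,
    sfs,
    tajimas_d,
    theta_h,
    theta_pi,
    theta_w,
)


def test_sliding_windows_counts():
    grid = sliding_windows(1_000_000, 10_000, 1_000)
    assert grid.n_windows == 991
    assert grid.starts[0] == 0 and grid.starts[-1] == 990_000
    assert sliding_windows(10_000, 10_000, 1_000).n_windows == 1
    with pytest.raises(ValueError):
        sliding_windows(5_000, 10_000, 1_000)


def test_nearest_rank_percentiles():
    vals = np.arange(1, 101, dtype=float)
    assert nearest_rank(vals, 0.05) == 5.0
    assert nearest_rank(vals, 0.95) == 95.0
    assert nearest_rank(vals, 1.0) == 100.0
    assert nearest_rank(np.array([7.0]), 0.05) == 7.0


def test_detection_threshold_uses_per_replicate_extrema():
    reps = [np.array([float(i), i + 50.0]) for i in range(1, 101)]
    assert detection_threshold(reps, "low", 0.05) == 5.0
    assert detection_threshold(reps, "high", 0.95) == 145.0
    with pytest.warns(UserWarning):
        single = detection_threshold([np.array([3.0, 9.0])], "low")
    assert single == 3.0
    nan_rep = [np.array([np.nan, np.nan])] + reps
    with pytest.warns(UserWarning):
        assert detection_threshold(nan_rep, "low", 0.05) == 5.0


def test_empirical_threshold_on_report():
    results = [
        OmegaResult(float(i), float(i), 2, 4, 0.0, 1.0) for i in range(1, 101)
    ]
    rep = OmegaReport(results, ScanParams(minwin=1, maxwin=2))
    assert empirical_threshold(rep, 0.95) == 95.0
    assert empirical_threshold(rep, 1.0) == 100.0


def test_sensitivity_specificity_hand_trace():
    grid = sliding_windows(100.0, 20.0, 10.0)  # centers 10, 20, ..., 90
    scores = [
        np.array([5, 1, 5, 5, 5, 5, 5, 5, 5.0]),  # min 1 at center 20 -> detected
        np.array([5, 5, 5, 5, 5, 5, 5, 2, 5.0]),  # min 2 at center 80 -> detected
        np.array([5, 5, 5, 5, 4, 5, 5, 5, 5.0]),  # min 4 -> not detected
    ]
    out = sensitivity_specificity(scores, threshold=3.0, tail="low",
                                  true_target=50.0, grid=grid)
    assert out.sensitivity == pytest.approx(2 / 3)
    assert out.mean_distance == pytest.approx(30.0)
    none = sensitivity_specificity(scores, threshold=0.0, tail="low",
                                   true_target=50.0, grid=grid)
    assert none.sensitivity == 0.0 and math.isnan(none.mean_distance)
    allhit = sensitivity_specificity(scores, threshold=10.0, tail="low",
                                     true_target=50.0, grid=grid)
    assert allhit.sensitivity == 1.0


def test_window_scores_match_per_window_statistics(sim_replicate):
    snps = sim_replicate
    grid = sliding_windows(100_000.0, 10_000.0, 5_000.0)
    per_window = {
        "theta_pi": theta_pi,
        "theta_w": theta_w,
        "theta_h": theta_h,
        "tajimas_d": tajimas_d,
        "fay_wu_h": fay_wu_h_norm,
        "fu_li_dstar": fu_li_dstar,
        "fu_li_fstar": fu_li_fstar,
    }
    for name, fn in per_window.items():
        fast = window_scores(snps, grid, name)
        for w, start in enumerate(grid.starts):
            spec = sfs(snps, snps.window(start, start + grid.window))
            if spec.S == 0 and name not in ("theta_pi", "theta_w", "theta_h"):
                assert math.isnan(fast[w])
            else:
                with np.errstate(all="ignore"):
                    assert fast[w] == pytest.approx(fn(spec), abs=1e-10), name


def test_window_scores_haplotype_and_recombination(sim_replicate):
    snps = sim_replicate
    grid = sliding_windows(100_000.0, 20_000.0, 20_000.0)
    k_scores = window_scores(snps, grid, "dv_k")
    h_scores = window_scores(snps, grid, "dv_h")
    c_scores = window_scores(snps, grid, "hudsons_c")
    for w, start in enumerate(grid.starts):
        win = snps.window(start, start + grid.window)
        k, h = dv_k_h(snps, win)
        assert k_scores[w] == k and h_scores[w] == pytest.approx(h)
        c = hudsons_c(snps, win)
        assert (math.isnan(c) and math.isnan(c_scores[w])) or c_scores[w] == pytest.approx(c)


def test_window_scores_omega_delegates_to_engine(sim_replicate):
    snps = sim_replicate
    grid = sliding_windows(100_000.0, 20_000.0, 25_000.0)
    sp = ScanParams(grid_size=4, minwin=2_000.0, maxwin=30_000.0, minsnps=4)
    scores = window_scores(snps, grid, "omega", scan_params=sp)
    for w, center in enumerate(grid.centers):
        assert scores[w] == scan_location(snps, float(center), sp).omega_max


def test_unknown_statistic_rejected(sim_replicate):
    grid = sliding_windows(100_000.0, 10_000.0, 10_000.0)
    with pytest.raises(KeyError):
        window_scores(sim_replicate, grid, "not_a_statistic")
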
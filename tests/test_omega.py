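"""The ω engine: LD-sum DP, border enumeration, grid scan, data reuse."""

import math

import numpy as np
import pytest

from omegascan import (
    LdSumMatrix,
    ScanParams,
    build_ld_sums,
    make_grid,
    omega_value,
    r2,
    region_sums,
    scan,
    scan_location,
)
from omegascan.omega import EPS_CROSS_SUM

from conftest import make_binary, random_binary_matrix


def _brute_pair_sum(m, lo, hi_i, lo_j):
    """Independent double-loop sum of r² over pairs lo_j <= a < b <= hi_i."""
    total = 0.0
    for a in range(lo_j, hi_i + 1):
        for b in range(a + 1, hi_i + 1):
            total += r2(m, lo + a, lo + b)
    return total


def test_ld_sums_base_cases():
    pair = make_binary(np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8))
    dp = build_ld_sums(pair, 0, 1)
    assert dp.M[1, 0] == pytest.approx(r2(pair, 0, 1))
    # three identical columns: every pair has r² = 1, so M[2,0] = 3
    tri = make_binary(np.tile([[1], [1], [0], [0]], (1, 3)).astype(np.int8))
    assert build_ld_sums(tri, 0, 2).M[2, 0] == pytest.approx(3.0)


def test_ld_sums_random_window_against_brute_force(rng):
    m = random_binary_matrix(rng, 10, 6)
    dp = build_ld_sums(m, 0, 5)
    for i in range(6):
        for j in range(i + 1):
            assert dp.M[i, j] == pytest.approx(
                _brute_pair_sum(m, 0, i, j), abs=1e-12
            )


def test_region_sums_decomposition(rng):
    m = random_binary_matrix(rng, 12, 8)
    dp = build_ld_sums(m, 0, 7)
    total = dp.M[7, 0]
    for split in range(1, 8):
        s_l, s_r, s_x = region_sums(dp, split)
        assert s_l == pytest.approx(_brute_pair_sum(m, 0, split - 1, 0), abs=1e-12)
        assert s_r == pytest.approx(_brute_pair_sum(m, 0, 7, split) , abs=1e-12)
        assert s_l + s_r + s_x == pytest.approx(total, abs=1e-12)
    assert region_sums(dp, 1)[0] == 0.0  # a single SNP has no pairs


def test_omega_value_arithmetic():
    assert omega_value(1.0, 1.0, 0.4, 2, 4) == pytest.approx(10.0)
    # homogeneous LD: sums proportional to pair counts give ω = 1
    r = 0.37
    for l, w in [(2, 5), (3, 8), (4, 9)]:
        s_l = math.comb(l, 2) * r
        s_r = math.comb(w - l, 2) * r
        s_x = l * (w - l) * r
        assert omega_value(s_l, s_r, s_x, l, w) == pytest.approx(1.0)
    # zero cross sum hits the floor
    assert omega_value(1.0, 1.0, 0.0, 2, 4) == pytest.approx(4 / EPS_CROSS_SUM)
    with pytest.raises(ValueError):
        omega_value(1.0, 1.0, 0.1, 1, 4)


def test_make_grid_conventions():
    np.testing.assert_allclose(make_grid(0, 1000, 5), [0, 250, 500, 750, 1000])
    np.testing.assert_allclose(make_grid(0, 1000, 1), [500])
    np.testing.assert_allclose(make_grid(100, 101, 3), [100, 100.5, 101])


def _two_block_matrix():
    """5 + 5 perfectly linked SNP blocks with zero cross-block r²."""
    left = [1, 1, 0, 0]
    right = [1, 0, 1, 0]  # independent of `left` (D = 0)
    codes = np.array([left] * 5 + [right] * 5, dtype=np.int8).T
    positions = np.array([100, 150, 200, 250, 300, 800, 850, 900, 950, 1000.0])
    return make_binary(codes, positions)


def test_scan_location_finds_block_boundary():
    m = _two_block_matrix()
    p = ScanParams(grid_size=1, minwin=50, maxwin=600, minsnps=4)
    res = scan_location(m, 550.0, p)
    assert res.best_l == 5 and res.best_w == 10
    assert res.left_border == 100.0 and res.right_border == 1000.0
    assert res.omega_max > 1e6  # cross sum is exactly zero -> floored denominator


def test_scan_location_inadmissible_side():
    m = _two_block_matrix()
    p = ScanParams(grid_size=1, minwin=50, maxwin=600, minsnps=4)
    res = scan_location(m, 90.0, p)  # < 2 SNPs on the left within maxwin
    assert res.omega_max == 0.0 and res.best_w == 0


def test_scan_location_reuse_is_transparent(rng):
    m = random_binary_matrix(rng, 14, 40, spacing=25.0)
    p = ScanParams(grid_size=1, minwin=30, maxwin=400, minsnps=4)
    pos = float(np.median(m.positions))
    plain = scan_location(m, pos, p)
    a, b = m.window(pos - p.maxwin, pos + p.maxwin)
    cover = LdSumMatrix.build(m, max(0, a - 3), min(m.n_snps - 1, b + 2))
    reused = scan_location(m, pos, p, reuse=cover)
    assert plain == reused


def test_scan_equals_independent_locations(rng):
    m = random_binary_matrix(rng, 12, 60, spacing=20.0)
    p = ScanParams(grid_size=15, minwin=40, maxwin=400, minsnps=4)
    report = scan(m, p)
    assert len(report) == 15
    grid = make_grid(float(m.positions[0]), float(m.positions[-1]), 15)
    for res, pos in zip(report, grid):
        assert res == scan_location(m, float(pos), p)


def test_scan_homogeneous_ld_is_flat(rng):
    # identical columns everywhere: every admissible split gives ω = 1
    codes = np.tile([[1], [1], [1], [0], [0], [0]], (1, 30)).astype(np.int8)
    m = make_binary(codes, np.arange(1.0, 31.0) * 10)
    p = ScanParams(grid_size=7, minwin=15, maxwin=200, minsnps=4)
    rep = scan(m, p)
    evaluated = [r for r in rep if r.best_w > 0]
    assert evaluated, "grid interior must be evaluable"
    for r in evaluated:
        assert r.omega_max == pytest.approx(1.0, abs=1e-9)
        # tie-break: the smallest admissible window wins
        assert r.best_w == p.minsnps


def test_omega_invariant_under_sample_permutation(rng):
    m = random_binary_matrix(rng, 10, 30, spacing=30.0)
    p = ScanParams(grid_size=5, minwin=40, maxwin=500, minsnps=4)
    base = scan(m, p)
    perm = rng.permutation(m.n_samples)
    mp = make_binary(m.to_codes()[perm], m.positions)
    again = scan(mp, p)
    for a, b in zip(base, again):
        assert a.omega_max == pytest.approx(b.omega_max, rel=1e-12)
        assert (a.best_l, a.best_w) == (b.best_l, b.best_w)


def test_scan_empty_and_single(rng):
    empty = make_binary(np.zeros((4, 0), dtype=np.int8), [])
    with pytest.warns(UserWarning):
        rep = scan(empty, ScanParams(grid_size=3, minwin=10, maxwin=100))
    assert len(rep) == 0


def test_scan_d1_is_midpoint(rng):
    m = random_binary_matrix(rng, 10, 20, spacing=20.0)
    p = ScanParams(grid_size=1, minwin=20, maxwin=300, minsnps=4)
    rep = scan(m, p)
    mid = (m.positions[0] + m.positions[-1]) / 2
    assert rep.results[0].position == pytest.approx(mid)


def test_ld_sum_matrix_retarget_matches_fresh_build(rng):
    m = random_binary_matrix(rng, 10, 50, spacing=10.0)
    dp = LdSumMatrix.build(m, 0, 19)
    shifted = dp.retarget(m, 7, 34)
    fresh = LdSumMatrix.build(m, 7, 34)
    np.testing.assert_allclose(
        np.tril(shifted.M), np.tril(fresh.M), atol=1e-12
    )
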
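"""SNP grouping, compute lists, memory-budgeted plans, tiled execution."""

import numpy as np
import pytest

from omegascan import (
    ComputeGroup,
    ScanParams,
    balance_omega_queues,
    build_compute_list,
    build_snp_groups,
    execute_plan,
    make_grid,
    plan_iteration,
    scan,
)
from omegascan.omega import LdSumMatrix
from omegascan.workplan import Region, _tiled_region_matrix, _compute_tile, scan_tiled

from conftest import random_binary_matrix


def test_build_snp_groups_partition():
    groups = build_snp_groups(300, 128)
    assert [g.size for g in groups] == [128, 128, 44]
    assert groups[1].start == 128 and groups[2].stop == 300
    assert len(build_snp_groups(128, 128)) == 1
    assert build_snp_groups(0, 128) == []


def test_compute_list_two_neighboring_regions():
    # two regions over three SNP groups -> five deduplicated compute groups
    cl = build_compute_list([(0, 1), (1, 2)])
    assert len(cl) == 5
    assert set((c.x, c.y) for c in cl) == {(0, 0), (1, 0), (1, 1), (2, 1), (2, 2)}


def test_compute_list_dedup_and_single():
    assert len(build_compute_list([(2, 2)])) == 1
    assert build_compute_list([(0, 2), (0, 2)]) == build_compute_list([(0, 2)])


def test_compute_list_max_diag_prunes_distant_tiles():
    cl = build_compute_list([(0, 3)], max_diag=1)
    assert all(c.diagonal <= 1 for c in cl)
    assert len(cl) == 7  # 4 diagonal + 3 off-diagonal tiles


def test_compute_list_overlap_smaller_than_sum():
    a, b = (0, 2), (2, 4)
    merged = build_compute_list([a, b])
    standalone = len(build_compute_list([a])) + len(build_compute_list([b]))
    assert len(merged) < standalone


@pytest.fixture
def small_scan_setup(rng):
    snps = random_binary_matrix(rng, 10, 60, spacing=20.0)
    p = ScanParams(grid_size=12, minwin=40, maxwin=300, minsnps=4)
    grid = make_grid(float(snps.positions[0]), float(snps.positions[-1]), 12)
    return snps, p, grid


def test_plan_unbounded_budget_covers_all_locations(small_scan_setup):
    snps, p, grid = small_scan_setup
    plan = plan_iteration(grid, snps, p, mem_limit=2**40, G=4)
    assert plan.k == len(grid)


def test_plan_too_small_budget_names_minimum(small_scan_setup):
    snps, p, grid = small_scan_setup
    # start at an interior location whose window genuinely needs tiles
    with pytest.raises(ValueError, match="minimum feasible"):
        plan_iteration(grid, snps, p, mem_limit=16, start=6, G=4)


def test_plan_k_varies_with_snp_density(rng):
    p = ScanParams(grid_size=8, minwin=20, maxwin=100, minsnps=4)
    dense = random_binary_matrix(rng, 10, 80, spacing=5.0)
    sparse = random_binary_matrix(rng, 10, 80, spacing=50.0)
    budget = 40 * 4 * 4 * 8  # enough tiles for a handful of groups of G=4
    grids = {
        "dense": make_grid(float(dense.positions[0]), float(dense.positions[-1]), 8),
        "sparse": make_grid(float(sparse.positions[0]), float(sparse.positions[-1]), 8),
    }
    k_dense = plan_iteration(grids["dense"], dense, p, budget, G=4).k
    k_sparse = plan_iteration(grids["sparse"], sparse, p, budget, G=4).k
    assert k_sparse >= k_dense


def test_balance_queues_lpt_trace():
    queues = balance_omega_queues([5, 3, 2, 2], 2)
    loads = [sum([5, 3, 2, 2][i] for i in q) for q in queues]
    assert sorted(loads) == [5, 7]
    assert balance_omega_queues([4, 1], 1) == [[0, 1]]
    equal = balance_omega_queues([3] * 10, 4)
    sizes = sorted(len(q) for q in equal)
    assert sizes[-1] - sizes[0] <= 1
    assert sorted(i for q in equal for i in q) == list(range(10))


def test_tiled_region_matrix_equals_direct_dp(rng):
    snps = random_binary_matrix(rng, 10, 20, spacing=10.0)
    groups = build_snp_groups(20, 4)
    tiles = {
        cg: _compute_tile(snps, groups, cg) for cg in build_compute_list([(0, 4)])
    }
    region = Region(0, 100.0, (2, 17), (0, 4))
    tiled = _tiled_region_matrix(region, groups, tiles)
    direct = LdSumMatrix.build(snps, 2, 16)
    np.testing.assert_allclose(np.tril(tiled.M), np.tril(direct.M), atol=1e-12)


@pytest.mark.parametrize("workers", [1, 2, 4, 8])
def test_execute_plan_equals_scan(small_scan_setup, workers):
    snps, p, grid = small_scan_setup
    plan = plan_iteration(grid, snps, p, mem_limit=2**40, G=4)
    results = execute_plan(plan, snps, p, workers=workers)
    expected = scan(snps, p).results
    assert results == expected  # bit-for-bit, any worker count


def test_multi_iteration_tiled_scan_equals_scan(small_scan_setup):
    snps, p, grid = small_scan_setup
    # budget that forces several offload-compute iterations but still
    # admits the widest single window
    single = plan_iteration(grid, snps, p, mem_limit=2**40, G=4)
    tight = int(single.tile_bytes * 0.7)
    results = scan_tiled(snps, p, mem_limit=tight, G=4)
    assert results == scan(snps, p).results


def test_diagonal_batches_respect_dp_dependencies(small_scan_setup):
    snps, p, grid = small_scan_setup
    plan = plan_iteration(grid, snps, p, mem_limit=2**40, G=4)
    trace: list[ComputeGroup] = []
    execute_plan(plan, snps, p, trace=trace)
    seen = {}
    for order, cg in enumerate(trace):
        seen[(cg.x, cg.y)] = order
    for cg in trace:
        for dep in [(cg.x, cg.y + 1), (cg.x - 1, cg.y), (cg.x - 1, cg.y + 1)]:
            if dep in seen and dep != (cg.x, cg.y):
                assert seen[dep] < seen[(cg.x, cg.y)], (cg, dep)
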
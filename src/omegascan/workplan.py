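"""Offload-compute organisation of the ω scan.

Large scans are broken into iterations that fit a memory budget: SNPs are
packed into contiguous groups of size G, every pair of groups touched by a
candidate region becomes a "compute group" (a GxG tile of r² values), and
overlapping regions share tiles through a deduplicated compute list.  The
cumulative LD-sum table is then filled tile by tile; the recurrence makes a
tile depend only on its upper/right neighbours, so tiles on one diagonal of
the tile table are mutually independent and diagonals are processed in
ascending order.  Finally the ω evaluations of the iteration's locations
are spread over "omega queues" balanced by SNP count.

Executing a plan — sequentially or with a thread pool — yields results
identical to the plain sequential scan.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .io import SnpMatrix
from .ld import r2_pairs
from .omega import (
    LdSumMatrix,
    OmegaResult,
    ScanParams,
    _best_split,
    _candidate_borders,
    _null_result,
    make_grid,
)

__all__ = [
    "SnpGroup",
    "ComputeGroup",
    "ComputePlan",
    "build_snp_groups",
    "build_compute_list",
    "plan_iteration",
    "balance_omega_queues",
    "execute_plan",
]

DEFAULT_GROUP_SIZE = 128  # G; small values only make sense for tests
TILE_ENTRY_BYTES = 8  # one float per (SNP pair) cumulative-sum entry


@dataclass(frozen=True)
class SnpGroup:
    """A contiguous block of at most G SNPs; groups partition the SNP sequence."""

    index: int
    start: int  # global SNP index, inclusive
    stop: int  # exclusive

    @property
    def size(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class ComputeGroup:
    """One tile: the r² block between SNP groups x and y (y <= x)."""

    x: int
    y: int

    def __post_init__(self) -> None:
        if self.y > self.x:
            raise ValueError("compute group requires y <= x")

    @property
    def diagonal(self) -> int:
        return self.x - self.y


@dataclass
class Region:
    """One grid location's candidate window within an iteration."""

    grid_index: int
    position: float
    snp_range: tuple[int, int] | None  # [a, b) or None when inadmissible
    group_range: tuple[int, int] | None  # inclusive group indices

    @property
    def n_snps(self) -> int:
        return 0 if self.snp_range is None else self.snp_range[1] - self.snp_range[0]


@dataclass
class ComputePlan:
    """One offload-compute iteration: T groups, k locations, dedup tiles."""

    T: int
    k: int
    start: int
    groups: list[SnpGroup]
    regions: list[Region]
    compute_list: list[ComputeGroup]
    batches: list[list[ComputeGroup]]
    tile_bytes: int

    def to_dict(self) -> dict:
        """JSON-ready introspection dump."""
        return {
            "T": self.T,
            "k": self.k,
            "start": self.start,
            "tile_bytes": self.tile_bytes,
            "compute_list": [[cg.x, cg.y] for cg in self.compute_list],
            "batches": [[[cg.x, cg.y] for cg in batch] for batch in self.batches],
            "regions": [
                {
                    "grid_index": r.grid_index,
                    "position": r.position,
                    "snp_range": r.snp_range,
                    "group_range": r.group_range,
                }
                for r in self.regions
            ],
        }


def build_snp_groups(n_snps: int, G: int = DEFAULT_GROUP_SIZE) -> list[SnpGroup]:
    """Partition ``n_snps`` SNPs into ceil(n/G) contiguous groups of size G."""
    if G < 1:
        raise ValueError("G must be >= 1")
    return [
        SnpGroup(i, start, min(start + G, n_snps))
        for i, start in enumerate(range(0, n_snps, G))
    ]


def build_compute_list(
    regions: list[tuple[int, int]], max_diag: int | None = None
) -> list[ComputeGroup]:
    """Deduplicated tiles covering every group pair of every region.

    Each region contributes all pairs (x, y), y <= x, within its inclusive
    group range; pairs whose diagonal exceeds ``max_diag`` are omitted
    (they correspond to SNPs further apart than any window needs).
    """
    seen: dict[ComputeGroup, None] = {}
    for lo, hi in regions:
        for x in range(lo, hi + 1):
            for y in range(lo, x + 1):
                if max_diag is not None and x - y > max_diag:
                    continue
                seen.setdefault(ComputeGroup(x, y))
    return list(seen)


def _group_batches(compute_list: list[ComputeGroup]) -> list[list[ComputeGroup]]:
    """Partition tiles by diagonal, ascending (the DP dependency order)."""
    if not compute_list:
        return []
    by_diag: dict[int, list[ComputeGroup]] = {}
    for cg in compute_list:
        by_diag.setdefault(cg.diagonal, []).append(cg)
    return [by_diag[d] for d in sorted(by_diag)]


def _region_for_location(
    snps: SnpMatrix, grid_index: int, pos: float, p: ScanParams, groups: list[SnpGroup]
) -> Region:
    cand = _candidate_borders(snps, pos, p)
    if cand is None:
        return Region(grid_index, pos, None, None)
    a, b = cand[0], cand[1]
    G = groups[0].size if groups else 1
    return Region(grid_index, pos, (a, b), (a // G, (b - 1) // G))


def plan_iteration(
    grid: np.ndarray,
    snps: SnpMatrix,
    p: ScanParams,
    mem_limit: int,
    start: int = 0,
    G: int = DEFAULT_GROUP_SIZE,
) -> ComputePlan:
    """Size one iteration against a tile-memory budget.

    Consecutive grid locations (from ``start``) are added while the
    deduplicated compute list of their windows, at G² floats per tile,
    stays within ``mem_limit`` bytes.  ``k`` therefore varies with local
    SNP density.  A budget too small for even one location raises with
    the minimum feasible value.
    """
    groups = build_snp_groups(snps.n_snps, G)
    regions: list[Region] = []
    compute_list: list[ComputeGroup] = []
    tile_bytes = 0
    k = 0
    for gi in range(start, len(grid)):
        region = _region_for_location(snps, gi, float(grid[gi]), p, groups)
        trial = regions + [region]
        ranges = [r.group_range for r in trial if r.group_range is not None]
        cl = build_compute_list(ranges)
        nbytes = len(cl) * G * G * TILE_ENTRY_BYTES
        if nbytes > mem_limit:
            if k == 0:
                raise ValueError(
                    "mem_limit too small for a single window; "
                    f"minimum feasible: {nbytes} bytes"
                )
            break
        regions, compute_list, tile_bytes = trial, cl, nbytes
        k += 1
    span = [r.group_range for r in regions if r.group_range is not None]
    T = (max(h for _, h in span) - min(l for l, _ in span) + 1) if span else 0
    return ComputePlan(
        T=T,
        k=k,
        start=start,
        groups=groups,
        regions=regions,
        compute_list=compute_list,
        batches=_group_batches(compute_list),
        tile_bytes=tile_bytes,
    )


def balance_omega_queues(
    snp_counts: list[int], n_queues: int
) -> list[list[int]]:
    """Distribute locations over queues by longest-processing-time greedy.

    Locations (identified by index into ``snp_counts``) are sorted by SNP
    count descending and each is placed into the currently lightest queue,
    so queues end up with approximately equal total SNP counts.
    """
    if n_queues < 1:
        raise ValueError("need at least one queue")
    order = sorted(range(len(snp_counts)), key=lambda i: (-snp_counts[i], i))
    queues: list[list[int]] = [[] for _ in range(n_queues)]
    loads = [0] * n_queues
    for i in order:
        q = loads.index(min(loads))
        queues[q].append(i)
        loads[q] += snp_counts[i]
    return queues


def _compute_tile(
    snps: SnpMatrix, groups: list[SnpGroup], cg: ComputeGroup
) -> np.ndarray:
    """r² block for tile (x, y): rows = SNPs of group x, cols = group y.

    On the main diagonal only the strict lower triangle is filled (half
    the kernel invocations, as pairs (i, j) require j < i).
    """
    gx, gy = groups[cg.x], groups[cg.y]
    tile = np.zeros((gx.size, gy.size))
    rows = np.arange(gx.start, gx.stop)
    cols = np.arange(gy.start, gy.stop)
    ii, jj = np.meshgrid(rows, cols, indexing="ij")
    mask = jj < ii
    if mask.any():
        tile[mask] = r2_pairs(snps, ii[mask], jj[mask])
    return tile


def _tiled_region_matrix(
    region: Region,
    groups: list[SnpGroup],
    tiles: dict[ComputeGroup, np.ndarray],
) -> LdSumMatrix:
    """Assemble a region's cumulative LD-sum table from its tiles.

    Within each tile, entries follow M[i,j] = M[i,j+1] + M[i-1,j]
    - M[i-1,j+1] + r²_ij (rows ascending, columns right to left, realised
    as a reversed cumulative sum per row); tiles are visited by ascending
    diagonal so every neighbour entry is already available.
    """
    a, b = region.snp_range
    W = b - a
    M = np.zeros((W, W))
    lo, hi = region.group_range
    for d in range(0, hi - lo + 1):
        for x in range(lo + d, hi + 1):
            y = x - d
            tile = tiles[ComputeGroup(x, y)]
            gx, gy = groups[x], groups[y]
            r0, r1 = max(gx.start, a), min(gx.stop, b)
            c0, c1 = max(gy.start, a), min(gy.stop, b)
            for gi in range(r0, r1):
                i = gi - a
                j_hi = min(c1 - 1, gi - 1) - a  # rightmost column to fill
                j_lo = c0 - a
                if j_hi < j_lo:
                    continue
                js = np.arange(j_lo, j_hi + 1)
                r2row = tile[gi - gx.start, js + a - gy.start]
                prev = M[i - 1, js] if i > 0 else np.zeros(js.size)
                prev_right = M[i - 1, js + 1] if i > 0 else np.zeros(js.size)
                delta = prev - prev_right + r2row
                # continue the sequential right-to-left accumulation from the
                # boundary value so tiling never changes the addition order
                seeded = np.concatenate([[M[i, j_hi + 1]], delta[::-1]])
                M[i, js] = np.cumsum(seeded)[1:][::-1]
    return LdSumMatrix(a, M)


def execute_plan(
    plan: ComputePlan,
    snps: SnpMatrix,
    p: ScanParams,
    workers: int = 1,
    trace: list | None = None,
) -> list[OmegaResult]:
    """Run one iteration: tile r², tile-aware DP, then ω per location.

    ``workers > 1`` computes the tiles of each diagonal batch in a thread
    pool; output is identical to sequential execution (and to
    :func:`omegascan.omega.scan` restricted to the plan's locations).
    ``trace`` collects tile completion order for dependency checks.
    """
    tiles: dict[ComputeGroup, np.ndarray] = {}
    for batch in plan.batches:
        if workers > 1 and len(batch) > 1:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                for cg, tile in zip(
                    batch, pool.map(lambda c: _compute_tile(snps, plan.groups, c), batch)
                ):
                    tiles[cg] = tile
        else:
            for cg in batch:
                tiles[cg] = _compute_tile(snps, plan.groups, cg)
        if trace is not None:
            trace.extend(batch)

    def _evaluate(region: Region) -> OmegaResult:
        if region.snp_range is None:
            return _null_result(region.position)
        dp = _tiled_region_matrix(region, plan.groups, tiles)
        cand = _candidate_borders(snps, region.position, p)
        return _best_split(snps, region.position, p, dp, cand)

    queues = balance_omega_queues([r.n_snps for r in plan.regions], max(workers, 1))
    results: dict[int, OmegaResult] = {}

    def _drain(queue: list[int]) -> list[tuple[int, OmegaResult]]:
        return [(i, _evaluate(plan.regions[i])) for i in queue]

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            for chunk in pool.map(_drain, queues):
                results.update(chunk)
    else:
        for queue in queues:
            results.update(_drain(queue))
    return [results[i] for i in range(len(plan.regions))]


def scan_tiled(
    snps: SnpMatrix,
    p: ScanParams,
    mem_limit: int,
    workers: int = 1,
    G: int = DEFAULT_GROUP_SIZE,
) -> list[OmegaResult]:
    """Full scan via repeated memory-budgeted iterations (offload-compute loop)."""
    if p.no_singletons:
        from .io import filter_singletons

        snps = filter_singletons(snps)
        p = ScanParams(p.grid_size, p.minwin, p.maxwin, p.minsnps, p.balance, False)
    if snps.n_snps < 2:
        return []
    grid = make_grid(float(snps.positions[0]), float(snps.positions[-1]), p.grid_size)
    out: list[OmegaResult] = []
    start = 0
    while start < len(grid):
        plan = plan_iteration(grid, snps, p, mem_limit, start, G)
        out.extend(execute_plan(plan, snps, p, workers))
        start += plan.k
    return out
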
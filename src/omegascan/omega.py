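"""The ω statistic engine.

ω contrasts the average LD inside the left and right flanks of a
candidate sweep site with the average LD across it:

    ω = [ (C(l,2) + C(W-l,2))^-1 (ΣΣ_L r² + ΣΣ_R r²) ]
        / [ (l (W-l))^-1 Σ_{i∈L, j∈R} r² ]

for a window of W SNPs split into l left and W-l right SNPs.  A completed
selective sweep leaves strong LD within each flank but little across the
fixation site, so ω peaks at sweep centres.

All region sums are served by a cumulative lower-triangular table M with
M[i, j] = Σ_{j ≤ a < b ≤ i} r²_ab, filled by the dynamic-programming
recurrence M[i,j] = M[i,j+1] + M[i-1,j] - M[i-1,j+1] + r²_ij (equivalently,
per row, a reversed cumulative sum of the new r² column added to the
previous row).  Consecutive grid locations share most of their window, so
the scan reuses the overlapping block of M instead of recomputing it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SnpMatrix, filter_singletons
from .ld import r2_pairs

__all__ = [
    "ScanParams",
    "LdSumMatrix",
    "OmegaResult",
    "OmegaReport",
    "build_ld_sums",
    "region_sums",
    "omega_value",
    "make_grid",
    "scan_location",
    "scan_positions",
    "scan",
]

#: Floor for a zero cross-region LD sum: Eq. for ω is undefined at ΣX = 0,
#: yet that is the ideal sweep signature; the floor keeps ω finite while
#: preserving the ranking of candidate windows.
EPS_CROSS_SUM = 1e-9


@dataclass
class ScanParams:
    """Scan configuration (names mirror the classical CLI flags)."""

    grid_size: int = 1000  # D: number of equidistant evaluation locations
    minwin: float = 1000.0  # bp: region a sweep minimally affects on each side
    maxwin: float = 100_000.0  # bp: furthest border considered on each side
    minsnps: int = 5  # minimum W = |L| + |R| per evaluation
    balance: int | None = None  # max | |L| - |R| |, None disables
    no_singletons: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.minwin < self.maxwin):
            raise ValueError("need 0 < minwin < maxwin")
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")
        if self.minsnps < 2:
            raise ValueError("minsnps must be >= 2")


class LdSumMatrix:
    """Cumulative LD-sum table for a window of W consecutive SNPs.

    ``M[i, j]`` (0-based, j <= i) holds the sum of r² over all SNP pairs
    (a, b) with j <= a < b <= i, where indices are window-relative;
    ``first_snp`` maps them back to the global SNP sequence.
    """

    def __init__(self, first_snp: int, M: np.ndarray) -> None:
        self.first_snp = int(first_snp)
        self.M = M

    @property
    def W(self) -> int:
        return self.M.shape[0]

    @classmethod
    def empty(cls, first_snp: int = 0) -> "LdSumMatrix":
        return cls(first_snp, np.zeros((0, 0)))

    @classmethod
    def build(cls, snps: SnpMatrix, first: int, last: int) -> "LdSumMatrix":
        """Build the table for global SNPs ``first..last`` inclusive."""
        W = last - first + 1
        M = np.zeros((max(W, 0), max(W, 0)))
        out = cls(first, M)
        out._fill_rows(snps, 1)
        return out

    def _fill_rows(self, snps: SnpMatrix, start_row: int) -> None:
        """Compute rows ``start_row..W-1`` assuming earlier rows are done."""
        f, M = self.first_snp, self.M
        for i in range(max(start_row, 1), self.W):
            jj = np.arange(i)
            row = r2_pairs(snps, np.full(i, f + i), f + jj)
            # recurrence in telescoped form: M[i,j] - M[i,j+1] =
            # M[i-1,j] - M[i-1,j+1] + r²_ij, accumulated right to left from
            # M[i,i] = 0 (the tiled executor uses the same order, so both
            # paths agree bit for bit)
            delta = M[i - 1, :i] - M[i - 1, 1 : i + 1] + row
            M[i, :i] = np.cumsum(delta[::-1])[::-1]

    def retarget(self, snps: SnpMatrix, first: int, last: int) -> "LdSumMatrix":
        """Table for a new window, reusing the overlapping block of this one.

        The cumulative table of a shifted window is a diagonal sub-block of
        the old one, so only rows introduced by the shift are recomputed.
        Results are identical to :meth:`build`.
        """
        W_new = last - first + 1
        if W_new <= 0:
            return LdSumMatrix.empty(first)
        new = LdSumMatrix(first, np.zeros((W_new, W_new)))
        delta = first - self.first_snp
        if 0 <= delta < self.W:
            k = min(self.W - delta, W_new)
            new.M[:k, :k] = self.M[delta : delta + k, delta : delta + k]
            new._fill_rows(snps, k)
        else:
            new._fill_rows(snps, 1)
        return new

    def region_sums(self, l: int) -> tuple[float, float, float]:
        """(ΣΣ left, ΣΣ right, Σ cross) for a split with ``l`` left SNPs."""
        if not (1 <= l < self.W):
            raise ValueError("split must leave at least one SNP on each side")
        sum_l = float(self.M[l - 1, 0])
        sum_r = float(self.M[self.W - 1, l])
        sum_x = float(self.M[self.W - 1, 0]) - sum_l - sum_r
        return sum_l, sum_r, max(sum_x, 0.0)


def build_ld_sums(snps: SnpMatrix, first: int, last: int) -> LdSumMatrix:
    """Functional wrapper around :meth:`LdSumMatrix.build`."""
    if last - first + 1 < 2:
        raise ValueError("window needs at least 2 SNPs")
    return LdSumMatrix.build(snps, first, last)


def region_sums(m: LdSumMatrix, split: int) -> tuple[float, float, float]:
    """Left/right/cross r² sums for a split with ``split`` SNPs on the left."""
    return m.region_sums(split)


def omega_value(
    sum_l: float, sum_r: float, sum_x: float, l: int, w: int
) -> float:
    """Evaluate ω from precomputed region sums (2 <= l <= w - 2)."""
    if not (2 <= l <= w - 2):
        raise ValueError("both sides need at least 2 SNPs")
    pairs_within = math.comb(l, 2) + math.comb(w - l, 2)
    num = (sum_l + sum_r) / pairs_within
    den = max(sum_x, EPS_CROSS_SUM) / (l * (w - l))
    return num / den


def make_grid(first_pos: float, last_pos: float, d: int) -> np.ndarray:
    """D equidistant evaluation positions spanning [first_pos, last_pos]."""
    if first_pos >= last_pos:
        raise ValueError("need first_pos < last_pos")
    if d == 1:
        return np.array([(first_pos + last_pos) / 2.0])
    return np.linspace(first_pos, last_pos, d)


@dataclass
class OmegaResult:
    """Best ω at one grid location with the winning window borders."""

    position: float
    omega_max: float
    best_l: int
    best_w: int
    left_border: float
    right_border: float


@dataclass
class OmegaReport:
    """Whole-scan result: one :class:`OmegaResult` per grid location."""

    results: list[OmegaResult]
    params: ScanParams

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    @property
    def omegas(self) -> np.ndarray:
        return np.array([r.omega_max for r in self.results])

    @property
    def positions(self) -> np.ndarray:
        return np.array([r.position for r in self.results])

    def argmax(self) -> OmegaResult:
        """Highest-ω location (first in grid order on ties)."""
        if not self.results:
            raise ValueError("empty report")
        return self.results[int(np.argmax(self.omegas))]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [r.position for r in self.results],
                "omega": [r.omega_max for r in self.results],
                "left_border": [r.left_border for r in self.results],
                "right_border": [r.right_border for r in self.results],
                "l": [r.best_l for r in self.results],
                "W": [r.best_w for r in self.results],
            }
        )


def _null_result(pos: float) -> OmegaResult:
    return OmegaResult(pos, 0.0, 0, 0, pos, pos)


def _candidate_borders(
    snps: SnpMatrix, pos: float, p: ScanParams
) -> tuple[int, int, int, int, int] | None:
    """Window and border index ranges for one grid location.

    Returns (a, b, c, la_max, rb_min): window SNPs [a, b), split after c
    (last SNP with position <= pos), left borders la in [a, la_max],
    right borders rb in [rb_min, b-1].  None when no admissible pair of
    borders can exist.
    """
    positions = snps.positions
    a, b = snps.window(pos - p.maxwin, pos + p.maxwin)
    c = int(np.searchsorted(positions, pos, side="right")) - 1  # last left SNP
    if c < a + 1 or c + 2 > b - 1:  # need >= 2 SNPs on each side
        return None
    # mandatory core: every SNP strictly closer than minwin must be included
    core_left = int(np.searchsorted(positions, pos - p.minwin, side="right"))
    core_right = int(np.searchsorted(positions, pos + p.minwin, side="left")) - 1
    la_max = min(core_left, c - 1)
    rb_min = max(core_right, c + 2)
    if la_max < a or rb_min > b - 1:
        return None
    return a, b, c, la_max, rb_min


def _best_split(
    snps: SnpMatrix,
    pos: float,
    p: ScanParams,
    dp: LdSumMatrix,
    cand: tuple[int, int, int, int, int],
) -> OmegaResult:
    a, b, c, la_max, rb_min = cand
    M = dp.M
    off = dp.first_snp
    la = np.arange(a, la_max + 1)
    rb = np.arange(rb_min, b)
    l_arr = c - la + 1  # left SNP counts per left border
    r_arr = rb - c  # right SNP counts per right border
    sum_l = M[c - off, la - off]
    sum_r = M[rb - off, c + 1 - off]
    total = M[np.ix_(rb - off, la - off)]  # (R, L)
    sum_x = np.maximum(total - sum_l[None, :] - sum_r[:, None], 0.0)
    w_tot = l_arr[None, :] + r_arr[:, None]
    pairs_within = (
        l_arr * (l_arr - 1) // 2
    )[None, :] + (r_arr * (r_arr - 1) // 2)[:, None]
    cross_pairs = l_arr[None, :] * r_arr[:, None]
    omega = (
        (sum_l[None, :] + sum_r[:, None]) / pairs_within
    ) / (np.maximum(sum_x, EPS_CROSS_SUM) / cross_pairs)
    admissible = w_tot >= p.minsnps
    if p.balance is not None:
        admissible &= np.abs(l_arr[None, :] - r_arr[:, None]) <= p.balance
    if not admissible.any():
        return _null_result(pos)
    omega = np.where(admissible, omega, -np.inf)
    best = omega.max()
    # tie-break: smallest total window, then leftmost left border
    ties = np.argwhere(omega == best)
    w_ties = w_tot[ties[:, 0], ties[:, 1]]
    ties = ties[w_ties == w_ties.min()]
    ri, li = ties[np.argmin(la[ties[:, 1]])]
    return OmegaResult(
        position=pos,
        omega_max=float(best),
        best_l=int(l_arr[li]),
        best_w=int(w_tot[ri, li]),
        left_border=float(snps.positions[la[li]]),
        right_border=float(snps.positions[rb[ri]]),
    )


def scan_location(
    snps: SnpMatrix,
    pos: float,
    p: ScanParams,
    reuse: LdSumMatrix | None = None,
) -> OmegaResult:
    """Best ω at one position over all admissible left/right border pairs.

    The mandatory core (SNPs closer than ``minwin``) is always included;
    borders then extend SNP by SNP out to ``maxwin``.  Each border pair
    with at least two SNPs per side, ``minsnps`` SNPs in total and (when
    set) a side imbalance of at most ``balance`` is evaluated; the
    maximum is returned (ties: smallest window, then leftmost border).
    ``reuse`` may carry the LD-sum table of an overlapping window; the
    result is identical with or without it.
    """
    if p.no_singletons:
        snps = filter_singletons(snps)
    cand = _candidate_borders(snps, pos, p)
    if cand is None:
        return _null_result(pos)
    a, b = cand[0], cand[1]
    if reuse is not None and reuse.first_snp <= a and reuse.first_snp + reuse.W >= b:
        dp = reuse
    else:
        dp = LdSumMatrix.build(snps, a, b - 1)
    return _best_split(snps, pos, p, dp, cand)


def scan_positions(
    snps: SnpMatrix, positions, p: ScanParams
) -> list[OmegaResult]:
    """ω at an explicit increasing sequence of positions, with block reuse.

    The LD-sum table of each location's window is obtained by shifting
    the previous one and filling only the rows its window adds; the
    output equals calling :func:`scan_location` per position.
    """
    if p.no_singletons:
        snps = filter_singletons(snps)
        p = ScanParams(p.grid_size, p.minwin, p.maxwin, p.minsnps, p.balance, False)
    results: list[OmegaResult] = []
    dp = LdSumMatrix.empty()
    for pos in np.asarray(positions, dtype=float):
        cand = _candidate_borders(snps, pos, p)
        if cand is None:
            results.append(_null_result(float(pos)))
            continue
        a, b = cand[0], cand[1]
        dp = dp.retarget(snps, a, b - 1)
        results.append(_best_split(snps, float(pos), p, dp, cand))
    return results


def scan(snps: SnpMatrix, p: ScanParams) -> OmegaReport:
    """ω over a grid of ``p.grid_size`` equidistant locations.

    The grid spans the polymorphic span [first SNP, last SNP].  r² sums
    shared between the overlapping windows of consecutive locations are
    computed once (LD-sum block reuse); the output equals calling
    :func:`scan_location` independently per location.
    """
    if p.no_singletons:
        snps = filter_singletons(snps)
        p = ScanParams(
            p.grid_size, p.minwin, p.maxwin, p.minsnps, p.balance, False
        )
    if snps.n_snps == 0:
        warnings.warn("scan on an empty SNP matrix: empty report")
        return OmegaReport([], p)
    if snps.n_snps < 2:
        return OmegaReport([_null_result(float(snps.positions[0]))], p)
    grid = make_grid(float(snps.positions[0]), float(snps.positions[-1]), p.grid_size)
    return OmegaReport(scan_positions(snps, grid, p), p)
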
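"""Sensitivity/specificity evaluation of sweep-detection statistics.

The study design: a simulated region is scored in overlapping sliding
windows (classical summary statistics) or on a grid (ω).  Detection
thresholds come from matched neutral simulations via per-replicate
extrema — the 5th percentile of per-replicate *minima* for statistics
that drop near sweeps, the 95th percentile of per-replicate *maxima* for
ω — so the number of windows introduces no multiple-testing problem.
Sensitivity is the fraction of selection replicates whose extreme score
is beyond the threshold; specificity is measured as the distance between
the most extreme window (or grid location) and the true sweep target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SnpMatrix, popcount
from .omega import OmegaReport, ScanParams, make_grid, scan_positions
from . import stats as nstats

__all__ = [
    "WindowGrid",
    "DetectionOutcome",
    "sliding_windows",
    "window_scores",
    "detection_threshold",
    "empirical_threshold",
    "sensitivity_specificity",
    "nearest_rank",
    "WINDOW_STATISTICS",
]

#: statistics that assume *low* values near a sweep (threshold on minima);
#: ω is the lone high-tail statistic.
LOW_TAIL_STATISTICS = frozenset(
    {
        "theta_pi",
        "theta_w",
        "theta_h",
        "tajimas_d",
        "fu_li_dstar",
        "fu_li_fstar",
        "fay_wu_h",
        "dv_k",
        "dv_h",
        "hudsons_c",
    }
)

WINDOW_STATISTICS = tuple(sorted(LOW_TAIL_STATISTICS)) + ("omega",)


@dataclass
class WindowGrid:
    """Sliding windows: [start, start + window) every ``offset`` bp."""

    region_length: float
    window: float
    offset: float
    starts: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.starts.size

    @property
    def windows(self) -> np.ndarray:
        return np.column_stack([self.starts, self.starts + self.window])

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.window / 2.0


def sliding_windows(
    region_length: float, window: float = 10_000.0, offset: float = 1_000.0
) -> WindowGrid:
    """All full windows with start + window <= region_length."""
    if window > region_length:
        raise ValueError("window exceeds the region")
    if offset < 1:
        raise ValueError("offset must be >= 1 bp")
    n = int(math.floor((region_length - window) / offset)) + 1
    starts = np.arange(n, dtype=float) * offset
    return WindowGrid(region_length, window, offset, starts)


def _sfs_prefix_scores(
    snps: SnpMatrix, grid: WindowGrid, statistic: str
) -> np.ndarray:
    """O(1)-per-window SFS statistics via prefix sums over site terms."""
    n = snps.n_samples
    complete = snps.valid_counts() == n
    derived = snps.derived_counts()[complete].astype(float)
    pos = snps.positions[complete]

    def windowed(values: np.ndarray) -> np.ndarray:
        csum = np.concatenate([[0.0], np.cumsum(values)])
        lo = np.searchsorted(pos, grid.starts, side="left")
        hi = np.searchsorted(pos, grid.starts + grid.window, side="left")
        return csum[hi] - csum[lo]

    S = windowed(np.ones_like(derived))
    with np.errstate(invalid="ignore", divide="ignore"):
        if statistic == "theta_pi":
            return windowed(derived * (n - derived)) / math.comb(n, 2)
        if statistic == "theta_w":
            return S / nstats.harmonic(n - 1)
        if statistic == "theta_h":
            return windowed(2.0 * derived**2) / (n * (n - 1))
        pi = windowed(derived * (n - derived)) / math.comb(n, 2)
        out = np.full(grid.n_windows, np.nan)
        has = S > 0
        if statistic == "tajimas_d":
            e1, e2 = nstats._tajima_constants(n)
            a1 = nstats.harmonic(n - 1)
            out[has] = (pi[has] - S[has] / a1) / np.sqrt(
                e1 * S[has] + e2 * S[has] * (S[has] - 1)
            )
            return out
        if statistic == "fu_li_dstar":
            u, v, _, _ = nstats._fu_li_constants(n)
            eta = windowed((derived == 1).astype(float))
            num = (n / (n - 1.0)) * S - nstats.harmonic(n - 1) * eta
            out[has] = num[has] / np.sqrt(u * S[has] + v * S[has] ** 2)
            return out
        if statistic == "fu_li_fstar":
            _, _, u, v = nstats._fu_li_constants(n)
            eta = windowed((derived == 1).astype(float))
            num = pi - ((n - 1.0) / n) * eta
            out[has] = num[has] / np.sqrt(u * S[has] + v * S[has] ** 2)
            return out
        if statistic == "fay_wu_h":
            a_n = nstats.harmonic(n - 1)
            b_n = nstats.harmonic2(n - 1)
            b_n1 = nstats.harmonic2(n)
            theta = S / a_n
            theta_sq = S * (S - 1.0) / (a_n**2 + b_n)
            var = (n - 2.0) / (6.0 * (n - 1.0)) * theta + (
                18.0 * n**2 * (3.0 * n + 2.0) * b_n1
                - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
            ) / (9.0 * n * (n - 1.0) ** 2) * theta_sq
            tl = windowed(derived) / (n - 1.0)
            out[has] = (pi[has] - tl[has]) / np.sqrt(var[has])
            return out
    raise KeyError(statistic)


def window_scores(
    snps: SnpMatrix,
    grid: WindowGrid,
    statistic: str,
    scan_params: ScanParams | None = None,
) -> np.ndarray:
    """One score per window; NaN where the statistic is undefined.

    SFS-based statistics run through a vectorised prefix-sum path that
    matches the per-window functions of :mod:`omegascan.stats` exactly.
    ``"omega"`` evaluates ω at window centers with ``scan_params``.
    """
    if statistic == "omega":
        if scan_params is None:
            raise ValueError("omega scores need scan_params")
        results = scan_positions(snps, grid.centers, scan_params)
        return np.array([r.omega_max for r in results])
    if statistic in {
        "theta_pi",
        "theta_w",
        "theta_h",
        "tajimas_d",
        "fu_li_dstar",
        "fu_li_fstar",
        "fay_wu_h",
    }:
        return _sfs_prefix_scores(snps, grid, statistic)
    if statistic in {"dv_k", "dv_h", "hudsons_c"}:
        out = np.full(grid.n_windows, np.nan)
        for w, start in enumerate(grid.starts):
            win = snps.window(start, start + grid.window)
            win = (win[0], win[1])
            if statistic == "hudsons_c":
                out[w] = nstats.hudsons_c(snps, win)
            else:
                k, h = nstats.dv_k_h(snps, win)
                out[w] = k if statistic == "dv_k" else h
        return out
    raise KeyError(f"unknown statistic {statistic!r}")


def nearest_rank(values: np.ndarray, quantile: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("no values")
    k = max(1, math.ceil(quantile * values.size))
    return float(values[min(k, values.size) - 1])


def detection_threshold(
    neutral_scores: list[np.ndarray], tail: str, quantile: float | None = None
) -> float:
    """Threshold from per-replicate extrema of neutral replicates.

    ``tail="low"``: the ``quantile`` (default 5th) percentile of
    per-replicate minima; ``tail="high"``: the (default 95th) percentile
    of per-replicate maxima.  All-NaN replicates are excluded.
    """
    if tail not in ("low", "high"):
        raise ValueError("tail must be 'low' or 'high'")
    if quantile is None:
        quantile = 0.05 if tail == "low" else 0.95
    if len(neutral_scores) < 20:
        warnings.warn("fewer than 20 calibration replicates; threshold is noisy")
    extrema = []
    for scores in neutral_scores:
        scores = np.asarray(scores, dtype=float)
        if np.all(np.isnan(scores)):
            warnings.warn("excluding an all-NaN calibration replicate")
            continue
        extrema.append(np.nanmin(scores) if tail == "low" else np.nanmax(scores))
    return nearest_rank(np.array(extrema), quantile)


def empirical_threshold(report: OmegaReport, quantile: float = 0.95) -> float:
    """Whole-scan alternative: the quantile of the scan's own ω values."""
    if len(report) == 0:
        raise ValueError("empty report")
    return nearest_rank(report.omegas, quantile)


@dataclass
class DetectionOutcome:
    """Detection summary for one statistic under one scenario."""

    statistic: str
    threshold: float
    sensitivity: float
    mean_distance: float  # bp, over detected replicates (NaN if none)
    n_detected: int
    n_replicates: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "statistic": self.statistic,
                "threshold": self.threshold,
                "sensitivity": self.sensitivity,
                "mean_distance": self.mean_distance,
                "n_detected": self.n_detected,
                "n_replicates": self.n_replicates,
            }
        )


def sensitivity_specificity(
    selection_scores: list[np.ndarray],
    threshold: float,
    tail: str,
    true_target: float,
    grid: "WindowGrid | np.ndarray",
    statistic: str = "",
) -> DetectionOutcome:
    """Detection rate and mean distance to the true target.

    A replicate counts as detected when its extreme score is strictly
    beyond the threshold; its reported sweep location is the center of
    the most extreme window (NaN-scored windows ignored).  The mean
    distance is computed over detected replicates only.
    """
    if isinstance(grid, WindowGrid):
        per_rep_centers = [grid.centers] * len(selection_scores)
    elif isinstance(grid, (list, tuple)):
        per_rep_centers = [np.asarray(c) for c in grid]
    else:
        per_rep_centers = [np.asarray(grid)] * len(selection_scores)
    detected = 0
    distances: list[float] = []
    for scores, centers in zip(selection_scores, per_rep_centers):
        scores = np.asarray(scores, dtype=float)
        if np.all(np.isnan(scores)):
            continue
        if tail == "low":
            extreme = np.nanmin(scores)
            hit = extreme < threshold
            arg = int(np.nanargmin(scores))
        else:
            extreme = np.nanmax(scores)
            hit = extreme > threshold
            arg = int(np.nanargmax(scores))
        if hit:
            detected += 1
            distances.append(abs(centers[arg] - true_target))
    n = len(selection_scores)
    return DetectionOutcome(
        statistic=statistic,
        threshold=threshold,
        sensitivity=detected / n if n else float("nan"),
        mean_distance=float(np.mean(distances)) if distances else float("nan"),
        n_detected=detected,
        n_replicates=n,
    )


def sweep_detection_study(
    params,
    reps: int,
    seed: int,
    scan_params: ScanParams | None = None,
    grid: WindowGrid | None = None,
    statistics: tuple[str, ...] = ("omega", "theta_pi", "dv_h", "tajimas_d"),
) -> pd.DataFrame:
    """End-to-end sensitivity/specificity study for one demographic scenario.

    Simulates ``reps`` matched neutral/sweep replicate pairs under
    ``params`` (which must carry a sweep), calibrates each statistic's
    threshold on the neutral replicates (95th percentile of per-replicate
    ω maxima; 5th percentile of per-replicate window minima for the
    low-tail statistics) and scores the sweep replicates against it.
    Returns one :class:`DetectionOutcome` row per statistic.
    """
    from .simulate import simulate_paired

    scan_params = scan_params or ScanParams(
        grid_size=200, minwin=10_000.0, maxwin=100_000.0, minsnps=5
    )
    grid = grid or sliding_windows(params.region_length)
    neutral, sweeps = simulate_paired(params, reps, seed)
    target = params.sweep.position_fraction * params.region_length
    rows = []
    for stat in statistics:
        if stat == "omega":
            from .omega import scan

            neu_scores = [scan(m, scan_params).omegas for m in neutral]
            reports = [scan(m, scan_params) for m in sweeps]
            thr = detection_threshold(neu_scores, "high")
            outcome = sensitivity_specificity(
                [r.omegas for r in reports],
                thr,
                "high",
                target,
                [r.positions for r in reports],
                statistic=stat,
            )
        else:
            neu_scores = [window_scores(m, grid, stat) for m in neutral]
            sel_scores = [window_scores(m, grid, stat) for m in sweeps]
            thr = detection_threshold(neu_scores, "low")
            outcome = sensitivity_specificity(
                sel_scores, thr, "low", target, grid, statistic=stat
            )
        rows.append(outcome.to_series())
    return pd.DataFrame(rows)


def detection_heatmap(table: pd.DataFrame, value: str = "sensitivity", ax=None):
    """Heatmap of a statistic x scenario table (columns: statistic, scenario, value)."""
    import matplotlib.pyplot as plt

    pivot = table.pivot(index="statistic", columns="scenario", values=value)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * pivot.shape[1] + 3, 0.5 * pivot.shape[0] + 2))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.figure.colorbar(im, ax=ax, label=value)
    return ax
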
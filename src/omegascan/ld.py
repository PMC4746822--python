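"""Linkage-disequilibrium kernels: squared correlation between SNP pairs.

Binary data use the classical r² of the 2x2 haplotype table,
r² = (p_ij - p_i p_j)^2 / (p_i (1-p_i) p_j (1-p_j)),
evaluated for the derived/derived state pair.  Multi-state DNA data sum
the per-state-pair r² terms over the polymorphic state pairs and scale by
(v_i-1)(v_j-1) v_ij / (v_i v_j), where v_i, v_j count the states present
at each SNP and v_ij is the fraction of samples valid at both SNPs.  That
normalisation keeps r² equal to the binary kernel on gap-free biallelic
columns and bounded on gappy ones.

All counting runs on the packed bitvectors of :class:`~omegascan.io.SnpMatrix`
via word-level population counts, so the cost per pair is proportional to
ceil(N/64) rather than N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Alphabet, SnpMatrix, popcount

__all__ = ["StatePairCounts", "pair_counts", "r2_binary", "r2_dna", "r2_pairs"]


@dataclass
class StatePairCounts:
    """Joint state counts for one SNP pair over the jointly-valid samples."""

    n_valid_pairs: int
    n_total: int
    alphabet: Alphabet
    count_i: np.ndarray  # (n_symbols,)
    count_j: np.ndarray  # (n_symbols,)
    count_ij: np.ndarray  # (n_symbols, n_symbols)

    @property
    def degenerate(self) -> bool:
        """Fewer than two jointly-valid samples: r² is undefined, treated as 0."""
        return self.n_valid_pairs < 2


def pair_counts(snps: SnpMatrix, i: int, j: int) -> StatePairCounts:
    """Count per-SNP and joint state occurrences over the shared valid mask."""
    if i == j:
        raise ValueError("pair_counts requires two distinct SNPs")
    n_sym = snps.alphabet.n_symbols
    valid_i, valid_j = snps.valid[i], snps.valid[j]
    joint = valid_i & valid_j
    count_i = popcount(snps.states[i] & valid_j)
    count_j = popcount(snps.states[j] & valid_i)
    count_ij = np.empty((n_sym, n_sym), dtype=np.int64)
    for s in range(n_sym):
        for t in range(n_sym):
            count_ij[s, t] = popcount(snps.states[i, s] & snps.states[j, t])
    return StatePairCounts(
        n_valid_pairs=int(popcount(joint)),
        n_total=snps.n_samples,
        alphabet=snps.alphabet,
        count_i=count_i,
        count_j=count_j,
        count_ij=count_ij,
    )


def r2_binary(c: StatePairCounts) -> float:
    """r² for the (1, 1) state pair of a binary SNP pair; in [0, 1].

    A SNP that is monomorphic over the jointly-valid samples (or a
    degenerate pair) yields 0 so that scans can proceed.
    """
    if c.degenerate:
        return 0.0
    n = c.n_valid_pairs
    p_i = c.count_i[1] / n
    p_j = c.count_j[1] / n
    if p_i <= 0.0 or p_i >= 1.0 or p_j <= 0.0 or p_j >= 1.0:
        return 0.0
    p_ij = c.count_ij[1, 1] / n
    d = p_ij - p_i * p_j
    r2 = (d * d) / (p_i * (1.0 - p_i) * p_j * (1.0 - p_j))
    return float(min(1.0, r2))


def r2_dna(c: StatePairCounts) -> float:
    """Multi-state r² for a DNA SNP pair (non-negative).

    Sums the per-state-pair r² over state pairs polymorphic at both
    members and applies the (v_i-1)(v_j-1) v_ij / (v_i v_j) prefactor
    with v_ij = n_valid_pairs / N (equal to 1 on gap-free data).
    """
    if c.degenerate:
        return 0.0
    n = c.n_valid_pairs
    v_i = int((c.count_i > 0).sum())
    v_j = int((c.count_j > 0).sum())
    if v_i < 2 or v_j < 2:
        return 0.0
    p_i = c.count_i / n
    p_j = c.count_j / n
    p_ij = c.count_ij / n
    total = 0.0
    for s in range(c.alphabet.n_symbols):
        if not (0.0 < p_i[s] < 1.0):
            continue
        for t in range(c.alphabet.n_symbols):
            if not (0.0 < p_j[t] < 1.0):
                continue
            d = p_ij[s, t] - p_i[s] * p_j[t]
            total += (d * d) / (p_i[s] * (1.0 - p_i[s]) * p_j[t] * (1.0 - p_j[t]))
    v_ij = n / c.n_total
    return float((v_i - 1) * (v_j - 1) * v_ij / (v_i * v_j) * total)


def r2(snps: SnpMatrix, i: int, j: int) -> float:
    """r² between SNPs i and j, dispatching on the matrix alphabet."""
    c = pair_counts(snps, i, j)
    return r2_binary(c) if snps.alphabet is Alphabet.BINARY else r2_dna(c)


def r2_pairs(snps: SnpMatrix, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """Vectorised r² for many SNP pairs (same semantics as the scalar kernels)."""
    ii = np.asarray(ii, dtype=np.intp)
    jj = np.asarray(jj, dtype=np.intp)
    if ii.size == 0:
        return np.zeros(0)
    valid_i = snps.valid[ii]
    valid_j = snps.valid[jj]
    nv = popcount(valid_i & valid_j).astype(np.float64)
    ok = nv >= 2
    safe_nv = np.where(ok, nv, 1.0)

    if snps.alphabet is Alphabet.BINARY:
        ones_i = snps.states[ii, 1]
        ones_j = snps.states[jj, 1]
        p_i = popcount(ones_i & valid_j) / safe_nv
        p_j = popcount(ones_j & valid_i) / safe_nv
        p_ij = popcount(ones_i & ones_j) / safe_nv
        poly = ok & (p_i > 0) & (p_i < 1) & (p_j > 0) & (p_j < 1)
        denom = np.where(poly, p_i * (1 - p_i) * p_j * (1 - p_j), 1.0)
        d = p_ij - p_i * p_j
        return np.where(poly, np.minimum(1.0, d * d / denom), 0.0)

    n_sym = snps.alphabet.n_symbols
    c_i = np.stack(
        [popcount(snps.states[ii, s] & valid_j) for s in range(n_sym)], axis=1
    )
    c_j = np.stack(
        [popcount(snps.states[jj, t] & valid_i) for t in range(n_sym)], axis=1
    )
    p_i = c_i / safe_nv[:, None]
    p_j = c_j / safe_nv[:, None]
    v_i = (c_i > 0).sum(axis=1)
    v_j = (c_j > 0).sum(axis=1)
    total = np.zeros(ii.size)
    for s in range(n_sym):
        pis = p_i[:, s]
        sel_s = (pis > 0) & (pis < 1)
        if not sel_s.any():
            continue
        for t in range(n_sym):
            pjt = p_j[:, t]
            sel = sel_s & (pjt > 0) & (pjt < 1)
            if not sel.any():
                continue
            p_st = popcount(snps.states[ii, s] & snps.states[jj, t]) / safe_nv
            d = p_st - pis * pjt
            denom = np.where(sel, pis * (1 - pis) * pjt * (1 - pjt), 1.0)
            total += np.where(sel, d * d / denom, 0.0)
    v_ij = nv / snps.n_samples
    usable = ok & (v_i >= 2) & (v_j >= 2)
    pref = (v_i - 1) * (v_j - 1) * v_ij / np.maximum(v_i * v_j, 1)
    return np.where(usable, pref * total, 0.0)
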
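"""Classical neutrality statistics on binary SNP windows.

These are the summary statistics the ω scan is benchmarked against:
estimators of θ = 4Nμ from the unfolded site frequency spectrum (θπ,
Watterson's θW, Fay & Wu's θH), the normalised SFS tests (Tajima's D,
Fu & Li's D* and F*, the normalised Fay & Wu H), haplotype counts and
heterozygosity (Depaulis & Veuille K and H), and Hudson's moment
estimator of the population recombination rate C = 4Nc.

The unfolded spectrum takes '0' as ancestral (the ms convention); DNA
data must be binary-deduced first.  Sites with missing samples are
dropped — the classical formulas assume complete columns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .io import Alphabet, SnpMatrix, popcount

__all__ = [
    "SiteFrequencySpectrum",
    "sfs",
    "theta_pi",
    "theta_w",
    "theta_h",
    "theta_l",
    "tajimas_d",
    "fu_li_dstar",
    "fu_li_fstar",
    "fay_wu_h_norm",
    "dv_k_h",
    "hudsons_c",
]


def harmonic(n: int) -> float:
    """a_n = sum_{k=1}^{n} 1/k."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def harmonic2(n: int) -> float:
    """b_n = sum_{k=1}^{n} 1/k^2."""
    return float(np.sum(1.0 / np.arange(1, n + 1) ** 2))


@dataclass
class SiteFrequencySpectrum:
    """Unfolded SFS: counts[i-1] sites carry the derived allele in i samples."""

    n: int
    counts: np.ndarray  # length n-1; index i-1 <-> derived count i

    @property
    def S(self) -> int:
        return int(self.counts.sum())

    @property
    def eta_s(self) -> int:
        """Number of singletons (derived count 1)."""
        return int(self.counts[0]) if self.counts.size else 0

    @property
    def i(self) -> np.ndarray:
        return np.arange(1, self.n)


def sfs(
    snps: SnpMatrix, window: tuple[int, int] | None = None
) -> SiteFrequencySpectrum:
    """Unfolded SFS of (a SNP-index window of) a binary matrix.

    Sites where any sample is invalid are excluded.
    """
    if snps.alphabet is not Alphabet.BINARY:
        raise ValueError("sfs expects a binary matrix (deduce DNA data first)")
    n = snps.n_samples
    a, b = window if window is not None else (0, snps.n_snps)
    sub = snps.take(np.arange(a, b))
    complete = popcount(sub.valid) == n
    derived = popcount(sub.states[:, 1])[complete]
    counts = np.bincount(derived, minlength=n + 1)[1:n]
    return SiteFrequencySpectrum(n, counts)


# ---------------------------------------------------------------------------
# theta estimators
# ---------------------------------------------------------------------------


def theta_pi(spec: SiteFrequencySpectrum) -> float:
    """Mean number of pairwise differences (nucleotide diversity estimator)."""
    n, i = spec.n, spec.i
    return float((spec.counts * i * (n - i)).sum() / math.comb(n, 2))


def theta_w(spec: SiteFrequencySpectrum) -> float:
    """Watterson's estimator S / a_{n-1}."""
    return spec.S / harmonic(spec.n - 1)


def theta_h(spec: SiteFrequencySpectrum) -> float:
    """Fay & Wu's homozygosity-weighted estimator (sensitive to high-frequency derived)."""
    n, i = spec.n, spec.i
    return float((spec.counts * 2.0 * i**2).sum() / (n * (n - 1)))


def theta_l(spec: SiteFrequencySpectrum) -> float:
    """Zeng et al.'s linear estimator; satisfies θH = 2 θL - θπ."""
    return float((spec.counts * spec.i).sum() / (spec.n - 1))


# ---------------------------------------------------------------------------
# normalised tests
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = harmonic(n - 1)
    a2 = harmonic2(n - 1)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(spec: SiteFrequencySpectrum) -> float:
    """Normalised θπ - θW difference; negative after sweeps (excess rare alleles)."""
    S = spec.S
    if S == 0:
        warnings.warn("Tajima's D undefined for S = 0")
        return float("nan")
    e1, e2 = _tajima_constants(spec.n)
    return (theta_pi(spec) - theta_w(spec)) / math.sqrt(e1 * S + e2 * S * (S - 1))


@lru_cache(maxsize=None)
def _fu_li_constants(n: int) -> tuple[float, float, float, float]:
    """(uD*, vD*, uF*, vF*) with the corrected (Simonsen et al.) constants."""
    a = harmonic(n - 1)
    b = harmonic2(n - 1)
    a_n1 = a + 1.0 / n  # a_{n+1} in the 1..n sum convention
    c = 2.0 * (n * a - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    d = c + (n - 2.0) / (n - 1) ** 2 + (2.0 / (n - 1)) * (
        1.5 - (2.0 * a_n1 - 3.0) / (n - 2) - 1.0 / n
    )
    v_dstar = (
        (n / (n - 1.0)) ** 2 * b
        + a**2 * d
        - 2.0 * (n * a * (a + 1.0)) / (n - 1.0) ** 2
    ) / (a**2 + b)
    u_dstar = (n / (n - 1.0)) * (a - n / (n - 1.0)) - v_dstar
    v_fstar = (
        d
        + 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
        - (2.0 / (n - 1.0)) * (4.0 * b - 6.0 + 8.0 / n)
    ) / (a**2 + b)
    u_fstar = (
        n / (n - 1.0)
        + (n + 1.0) / (3.0 * (n - 1.0))
        - 4.0 / (n * (n - 1.0))
        + 2.0 * (n + 1.0) / (n - 1.0) ** 2 * (a_n1 - 2.0 * n / (n + 1.0))
    ) / a - v_fstar
    return u_dstar, v_dstar, u_fstar, v_fstar


def fu_li_dstar(spec: SiteFrequencySpectrum) -> float:
    """Fu & Li's D* (contrasts total sites with singletons; no outgroup needed)."""
    S, n = spec.S, spec.n
    if S == 0:
        warnings.warn("Fu & Li D* undefined for S = 0")
        return float("nan")
    u, v, _, _ = _fu_li_constants(n)
    num = (n / (n - 1.0)) * S - harmonic(n - 1) * spec.eta_s
    return num / math.sqrt(u * S + v * S**2)


def fu_li_fstar(spec: SiteFrequencySpectrum) -> float:
    """Fu & Li's F* (contrasts θπ with singletons)."""
    S, n = spec.S, spec.n
    if S == 0:
        warnings.warn("Fu & Li F* undefined for S = 0")
        return float("nan")
    _, _, u, v = _fu_li_constants(n)
    num = theta_pi(spec) - ((n - 1.0) / n) * spec.eta_s
    return num / math.sqrt(u * S + v * S**2)


def fay_wu_h_norm(spec: SiteFrequencySpectrum) -> float:
    """Normalised Fay & Wu H (Zeng et al. variance): (θπ - θL) / sqrt(Var).

    Negative when high-frequency derived variants are in excess, i.e.
    near a completed sweep.  θπ - θL is half of the original θπ - θH.
    """
    S, n = spec.S, spec.n
    if S == 0:
        warnings.warn("normalised H undefined for S = 0")
        return float("nan")
    a_n = harmonic(n - 1)
    b_n = harmonic2(n - 1)
    b_n1 = harmonic2(n)
    theta = S / a_n
    theta_sq = S * (S - 1.0) / (a_n**2 + b_n)
    var = (n - 2.0) / (6.0 * (n - 1.0)) * theta + (
        18.0 * n**2 * (3.0 * n + 2.0) * b_n1
        - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1.0) ** 2) * theta_sq
    return (theta_pi(spec) - theta_l(spec)) / math.sqrt(var)


# ---------------------------------------------------------------------------
# haplotype- and LD-based statistics
# ---------------------------------------------------------------------------


def _complete_window_codes(
    snps: SnpMatrix, window: tuple[int, int] | None
) -> np.ndarray:
    a, b = window if window is not None else (0, snps.n_snps)
    sub = snps.take(np.arange(a, b))
    codes = sub.to_codes()
    complete = (codes >= 0).all(axis=0)
    return codes[:, complete]


def dv_k_h(
    snps: SnpMatrix, window: tuple[int, int] | None = None
) -> tuple[int, float]:
    """Depaulis & Veuille K (distinct haplotypes) and H (haplotype heterozygosity).

    H = (1 - Σ f_h²) · n/(n-1); both drop near sweeps, where one haplotype
    dominates the sample.
    """
    codes = _complete_window_codes(snps, window)
    n = codes.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    _, counts = np.unique(codes, axis=0, return_counts=True)
    freqs = counts / n
    k = int(counts.size)
    h = float((1.0 - (freqs**2).sum()) * n / (n - 1.0))
    return k, h


_C_ROOTS = np.roots([1.0, 13.0, 18.0])  # x^2 + 13x + 18


def _pair_time_covariance_integral(c: float) -> float:
    """h(C) = (2/C²) ∫₀^C (C-x)(x+18)/(x²+13x+18) dx; h(0) = 1, decreasing.

    (x+18)/(x²+13x+18) is the correlation of pairwise coalescence times
    at two loci separated by recombination distance x = 4Nc·d.
    """
    if c < 1e-4:  # series expansion; the closed form cancels catastrophically
        return 1.0 - 2.0 * c / 9.0
    r1, r2 = _C_ROOTS
    A = (r1 + 18.0) / (r1 - r2)
    B = (r2 + 18.0) / (r2 - r1)
    log1 = math.log((c - r1) / (-r1))
    log2 = math.log((c - r2) / (-r2))
    i0 = A * log1 + B * log2  # integral of f
    i1 = A * (c + r1 * log1) + B * (c + r2 * log2)  # integral of x f
    return (2.0 / c**2) * (c * i0 - i1)


C_MAX = 1e7


def hudsons_c(
    snps: SnpMatrix, window: tuple[int, int] | None = None
) -> float:
    """Moment estimate of the population recombination rate C = 4Nc per window.

    Equates the observed variance of pairwise sequence differences with
    its neutral-coalescent expectation θ̂ + θ̂² h(C), where h derives from
    the two-locus covariance of coalescence times, and solves for C.
    Tight linkage inflates the variance (C near 0); free recombination
    deflates it (large C).  Clamped to [0, 1e7]; windows with S < 2 or
    n < 3 return NaN.
    """
    codes = _complete_window_codes(snps, window)
    n, S = codes.shape
    if S < 2 or n < 3:
        return float("nan")
    gram = codes.astype(np.float64) @ codes.T.astype(np.float64)
    ones = codes.sum(axis=1).astype(np.float64)
    # pairwise Hamming distances for 0/1 codes
    diff = ones[:, None] + ones[None, :] - 2.0 * gram
    iu = np.triu_indices(n, k=1)
    k_ij = diff[iu]
    khat = k_ij.mean()
    if khat == 0:
        return float("nan")
    v_obs = k_ij.var()
    hi = v_obs / khat**2 - 1.0 / khat  # target for h(C)
    lo = 1e-9
    if hi >= _pair_time_covariance_integral(lo):
        return 0.0
    if hi <= _pair_time_covariance_integral(C_MAX):
        warnings.warn("observed variance below the free-recombination bound")
        return C_MAX
    return float(
        brentq(lambda c: _pair_time_covariance_integral(c) - hi, lo, C_MAX)
    )
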
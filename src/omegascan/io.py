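"""Input parsing and the packed SNP matrix container.

Polymorphism data enter the scan from three directions: multi-FASTA
intra-species alignments (DNA), Hudson ``ms``-style simulator output
(binary 0/1 haplotypes with fractional positions), and a minimal VCF
subset (biallelic SNPs, diploid genotypes split into two haplotypes).
All of them are normalised into a :class:`SnpMatrix`: per-SNP, per-state
presence bitvectors packed into 64-bit words so that allele and
allele-pair counts reduce to word-level population counts.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Alphabet",
    "FormatError",
    "InputError",
    "HaplotypeAlignment",
    "SnpMatrix",
    "read_fasta",
    "read_ms",
    "write_ms",
    "read_vcf",
    "extract_snps",
    "deduce_binary",
    "filter_singletons",
]

_WORD = 64


class FormatError(ValueError):
    """Malformed input file (ragged alignment, inconsistent ms block, ...)."""


class InputError(ValueError):
    """Well-formed file that violates a precondition (too few records, no GT, ...)."""


class Alphabet(Enum):
    BINARY = "01"
    DNA = "ACGT"

    @property
    def symbols(self) -> str:
        return self.value

    @property
    def n_symbols(self) -> int:
        return len(self.value)


# Symbols that mark a sample as invalid at a site (no state observed).
INVALID_SYMBOLS = frozenset("-N?")


@dataclass
class HaplotypeAlignment:
    """An intra-species alignment: n equal-length haplotype sequences."""

    sequences: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise InputError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


def _pack_bool(rows: np.ndarray) -> np.ndarray:
    """Pack a boolean array (..., n) into little-endian uint64 words (..., ceil(n/64))."""
    n = rows.shape[-1]
    n_words = max(1, -(-n // _WORD))
    padded = np.zeros(rows.shape[:-1] + (n_words * _WORD,), dtype=bool)
    padded[..., :n] = rows
    packed8 = np.packbits(padded, axis=-1, bitorder="little")
    return np.ascontiguousarray(packed8).view(np.uint64)


def popcount(words: np.ndarray) -> np.ndarray:
    """Population count summed over the last (word) axis."""
    return np.bitwise_count(words).sum(axis=-1, dtype=np.int64)


class SnpMatrix:
    """Packed haplotype/SNP matrix with per-site positions and validity masks.

    Parameters
    ----------
    n_samples
        Number of haplotypes N.
    positions
        Strictly increasing site coordinates in base pairs (fractions allowed).
    alphabet
        ``Alphabet.BINARY`` (states 0/1) or ``Alphabet.DNA`` (A/C/G/T).
    states
        uint64 array of shape (n_snps, n_symbols, n_words); bit *k* of word
        *w* in ``states[s, a]`` is set iff sample ``64*w + k`` carries state
        *a* at SNP *s*.
    valid
        uint64 array (n_snps, n_words); union of the per-state bitvectors,
        i.e. the samples that are neither gap nor N at the SNP.
    """

    def __init__(
        self,
        n_samples: int,
        positions: np.ndarray,
        alphabet: Alphabet,
        states: np.ndarray,
        valid: np.ndarray,
    ) -> None:
        positions = np.asarray(positions, dtype=np.float64)
        if positions.ndim != 1:
            raise ValueError("positions must be 1-D")
        if positions.size > 1 and not np.all(np.diff(positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if states.shape[0] != positions.size or valid.shape[0] != positions.size:
            raise ValueError("states/valid first axis must match positions")
        if states.shape[1] != alphabet.n_symbols:
            raise ValueError("states second axis must match alphabet size")
        self.n_samples = int(n_samples)
        self.positions = positions
        self.alphabet = alphabet
        self.states = states
        self.valid = valid

    # -- construction -------------------------------------------------

    @classmethod
    def from_codes(
        cls,
        codes: np.ndarray,
        positions: Sequence[float],
        alphabet: Alphabet,
        *,
        require_polymorphic: bool = True,
    ) -> "SnpMatrix":
        """Build from an integer code matrix of shape (n_samples, n_snps).

        Codes index the alphabet symbols; -1 marks an invalid sample
        (alignment gap or N). With ``require_polymorphic`` a site that is
        not polymorphic among its valid samples raises.
        """
        codes = np.asarray(codes)
        n_samples, n_snps = codes.shape
        n_sym = alphabet.n_symbols
        per_state = np.stack(
            [(codes.T == a) for a in range(n_sym)], axis=1
        )  # (S, n_sym, n)
        states = _pack_bool(per_state)
        valid = _pack_bool(codes.T >= 0)
        m = cls(n_samples, np.asarray(positions, dtype=float), alphabet, states, valid)
        if require_polymorphic and n_snps:
            counts = m.state_counts()
            poly = ((counts > 0).sum(axis=1) >= 2) & (counts.sum(axis=1) >= 2)
            if not np.all(poly):
                raise ValueError("matrix contains non-polymorphic sites")
        return m

    # -- basic queries ------------------------------------------------

    @property
    def n_snps(self) -> int:
        return self.positions.size

    @property
    def n_words(self) -> int:
        return self.valid.shape[1] if self.valid.ndim == 2 else 1

    def state_counts(self, index: int | None = None) -> np.ndarray:
        """Per-state sample counts; shape (n_symbols,) or (n_snps, n_symbols)."""
        if index is not None:
            return popcount(self.states[index])
        return popcount(self.states)

    def valid_counts(self) -> np.ndarray:
        return popcount(self.valid)

    @property
    def is_complete(self) -> bool:
        """True when no sample is masked at any SNP."""
        return bool(np.all(self.valid_counts() == self.n_samples))

    def to_codes(self) -> np.ndarray:
        """Dense (n_samples, n_snps) int8 code matrix; -1 for invalid samples."""
        out = np.full((self.n_snps, self.n_samples), -1, dtype=np.int8)
        for a in range(self.alphabet.n_symbols):
            bits = np.unpackbits(
                self.states[:, a].view(np.uint8), axis=-1, bitorder="little"
            )[:, : self.n_samples]
            out[bits.astype(bool)] = a
        return out.T

    def derived_counts(self) -> np.ndarray:
        """Counts of state '1' per SNP (binary matrices; ms ancestral-0 convention)."""
        if self.alphabet is not Alphabet.BINARY:
            raise ValueError("derived_counts is defined for binary matrices")
        return popcount(self.states[:, 1])

    def take(self, index) -> "SnpMatrix":
        """Sub-matrix over a SNP index array/slice (samples unchanged)."""
        idx = np.arange(self.n_snps)[index]
        return SnpMatrix(
            self.n_samples,
            self.positions[idx],
            self.alphabet,
            self.states[idx],
            self.valid[idx],
        )

    def window(self, left_bp: float, right_bp: float) -> tuple[int, int]:
        """Half-open SNP index range [a, b) with left_bp <= position <= right_bp."""
        a = int(np.searchsorted(self.positions, left_bp, side="left"))
        b = int(np.searchsorted(self.positions, right_bp, side="right"))
        return a, b

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SnpMatrix(n_samples={self.n_samples}, n_snps={self.n_snps}, "
            f"alphabet={self.alphabet.name})"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> HaplotypeAlignment:
    """Read a multi-record FASTA alignment; sequences are uppercased."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if len(records) < 2:
        raise InputError(f"{path}: need at least 2 FASTA records, got {len(records)}")
    seqs = [str(r.seq).upper() for r in records]
    labels = [r.id for r in records]
    return HaplotypeAlignment(seqs, labels)


def _strictly_increasing(pos: np.ndarray, eps: float) -> np.ndarray:
    """Sort and de-duplicate positions: ties keep input order, later ties +k*eps."""
    order = np.argsort(pos, kind="stable")
    if not np.array_equal(order, np.arange(pos.size)):
        warnings.warn("ms positions not monotone; sorting", stacklevel=3)
    pos = pos[order]
    out = pos.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


def _parse_ms_block(
    lines: list[str], region_length: float, block_no: int
) -> SnpMatrix:
    seg = None
    positions: np.ndarray | None = None
    rows: list[str] = []
    for ln in lines:
        if ln.startswith("segsites:"):
            seg = int(ln.split(":", 1)[1])
        elif ln.startswith("positions:"):
            positions = np.array(ln.split(":", 1)[1].split(), dtype=float)
        elif ln and set(ln) <= {"0", "1"}:
            rows.append(ln)
    if seg is None:
        raise FormatError(f"ms replicate {block_no}: missing 'segsites:' line")
    if seg == 0:
        n = max(2, len(rows))
        codes = np.zeros((n, 0), dtype=np.int8)
        return SnpMatrix.from_codes(codes, [], Alphabet.BINARY)
    if positions is None or positions.size != seg:
        raise FormatError(f"ms replicate {block_no}: positions do not match segsites")
    if not rows:
        raise FormatError(f"ms replicate {block_no}: no haplotype rows")
    if len({len(r) for r in rows}) != 1 or len(rows[0]) != seg:
        raise FormatError(f"ms replicate {block_no}: haplotype row length mismatch")
    codes = (
        np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), seg)
        - ord("0")
    ).astype(np.int8)
    pos_bp = _strictly_increasing(positions, 1e-6) * region_length
    # sorting of positions must reorder columns identically
    order = np.argsort(positions, kind="stable")
    codes = codes[:, order]
    return SnpMatrix.from_codes(codes, pos_bp, Alphabet.BINARY, require_polymorphic=False)


def read_ms(path: str | Path, region_length: float = 1_000_000.0) -> list[SnpMatrix]:
    """Parse Hudson ms-format replicates into binary SNP matrices.

    Fractional positions on [0, 1] are scaled by ``region_length`` (the
    simulated genome length in bp).  One matrix per ``//`` block.
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    with _open_text(path) as fh:
        text = fh.read()
    lines = [ln.strip() for ln in text.splitlines()]
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for ln in lines:
        if ln.startswith("//"):
            if current is not None:
                blocks.append(current)
            current = []
        elif current is not None:
            current.append(ln)
    if current is not None:
        blocks.append(current)
    if not blocks:
        raise FormatError(f"{path}: no '//' replicate delimiters found")
    return [
        _parse_ms_block(block, region_length, i) for i, block in enumerate(blocks)
    ]


def write_ms(
    reps: Sequence[SnpMatrix], path: str | Path, region_length: float = 1_000_000.0
) -> None:
    """Write binary replicates in the ms dialect (inverse of :func:`read_ms`)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(f"omegascan write_ms {len(reps)} replicates\n\n")
        for rep in reps:
            if rep.alphabet is not Alphabet.BINARY:
                raise ValueError("write_ms requires binary matrices")
            fh.write("//\n")
            fh.write(f"segsites: {rep.n_snps}\n")
            if rep.n_snps:
                frac = rep.positions / region_length
                fh.write("positions: " + " ".join(f"{p:.6f}" for p in frac) + "\n")
                codes = rep.to_codes()
                for row in codes:
                    fh.write("".join("1" if c == 1 else "0" for c in row) + "\n")
            fh.write("\n")


def read_vcf(path: str | Path) -> SnpMatrix:
    """Read biallelic SNPs from a VCF into a DNA matrix of phased haplotypes.

    Each diploid sample contributes two haplotypes; a missing genotype
    marks both haplotypes invalid at that SNP.  Indels and multi-allelic
    records are skipped (count logged).  Unphased heterozygotes are split
    as (0, 1) in sample order.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise InputError(f"{path}: VCF has no samples / GT fields")
        n_hap = 2 * len(samples)
        sym_index = {c: i for i, c in enumerate(Alphabet.DNA.symbols)}
        cols: list[np.ndarray] = []
        positions: list[float] = []
        skipped = 0
        for rec in vf:
            ref, alts = rec.ref, rec.alts
            if (
                ref is None
                or alts is None
                or len(alts) != 1
                or len(ref) != 1
                or len(alts[0]) != 1
                or ref.upper() not in sym_index
                or alts[0].upper() not in sym_index
            ):
                skipped += 1
                continue
            allele_codes = (sym_index[ref.upper()], sym_index[alts[0].upper()])
            col = np.full(n_hap, -1, dtype=np.int8)
            for s_idx, name in enumerate(samples):
                gt = rec.samples[name].get("GT")
                if gt is None:
                    raise InputError(f"{path}: record without GT field")
                for hap, allele in enumerate(gt[:2]):
                    if allele is not None and 0 <= allele <= 1:
                        col[2 * s_idx + hap] = allele_codes[allele]
            if (col >= 0).sum() >= 2 and len(set(col[col >= 0])) >= 2:
                cols.append(col)
                positions.append(float(rec.pos))
            else:
                skipped += 1
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic/indel/monomorphic records", skipped)
    if not cols:
        codes = np.zeros((n_hap, 0), dtype=np.int8)
        return SnpMatrix.from_codes(codes, [], Alphabet.DNA)
    codes = np.stack(cols, axis=1)
    pos = _strictly_increasing(np.asarray(positions, dtype=float), 1e-6)
    return SnpMatrix.from_codes(codes, pos, Alphabet.DNA)


# ---------------------------------------------------------------------------
# SNP extraction and site filters
# ---------------------------------------------------------------------------


def extract_snps(aln: HaplotypeAlignment) -> SnpMatrix:
    """Extract polymorphic columns of an alignment as a SNP matrix.

    A column is a SNP when at least two distinct valid (non-gap, non-N)
    states occur.  Positions are the 1-based alignment column indices.
    The result is binary when the alignment is written over {0, 1},
    otherwise DNA.
    """
    chars = np.frombuffer("".join(aln.sequences).encode(), dtype=np.uint8)
    mat = chars.reshape(aln.n_sequences, aln.length)
    observed = set(np.unique(mat).tobytes().decode())
    alphabet = (
        Alphabet.BINARY
        if observed <= (set("01") | INVALID_SYMBOLS)
        else Alphabet.DNA
    )
    codes = np.full(mat.shape, -1, dtype=np.int8)
    for i, c in enumerate(alphabet.symbols):
        codes[mat == ord(c)] = i
    unknown = set(observed) - set(alphabet.symbols) - INVALID_SYMBOLS
    if unknown:
        raise FormatError(f"unsupported alignment symbols: {sorted(unknown)}")
    n_states = np.stack(
        [(codes == i).sum(axis=0) for i in range(alphabet.n_symbols)]
    )  # (n_sym, length)
    is_snp = ((n_states > 0).sum(axis=0) >= 2) & ((codes >= 0).sum(axis=0) >= 2)
    cols = np.flatnonzero(is_snp)
    return SnpMatrix.from_codes(
        codes[:, cols], (cols + 1).astype(float), alphabet
    )


def deduce_binary(snps: SnpMatrix) -> SnpMatrix:
    """Deduce a binary representation of a DNA matrix.

    The majority state of each SNP maps to 0 and every other valid state
    to 1; ties are broken alphabetically (first symbol wins), so the
    deduction is deterministic.  Validity masks are preserved.
    """
    if snps.alphabet is not Alphabet.DNA:
        raise ValueError("deduce_binary expects a DNA matrix")
    counts = snps.state_counts()  # (S, 4)
    majority = np.argmax(counts, axis=1)  # argmax takes the first (alphabetical) tie
    zeros = snps.states[np.arange(snps.n_snps), majority]  # (S, n_words)
    ones = snps.valid & ~zeros
    states = np.stack([zeros, ones], axis=1)
    m = SnpMatrix(snps.n_samples, snps.positions, Alphabet.BINARY, states, snps.valid)
    poly = (popcount(zeros) > 0) & (popcount(ones) > 0)
    return m.take(poly) if not np.all(poly) else m


def filter_singletons(snps: SnpMatrix) -> SnpMatrix:
    """Drop SNPs whose minor variant is carried by exactly one valid sample.

    Binary: minor state count == 1.  DNA: all but one valid sample share
    the same state (a site with two different singleton minor states is
    kept, since two samples deviate from the majority).
    """
    counts = snps.state_counts()
    valid = snps.valid_counts()
    keep = (valid - counts.max(axis=1)) != 1
    return snps.take(keep)
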
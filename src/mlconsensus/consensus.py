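"""Column/pair profiles, information content, and the ambiguity-code consensus.

Given a multiple sequence alignment A of N binding sites with width W, the
per-column frequency of base b is f_j(b) = n_j(b)/N — note that gapped rows
stay in the denominator, so a column holding one C and three gaps has
f(C) = 0.25.  The consensus symbol at column j is then

* the base b if f_j(b) > 0.5 (strictly),
* else the two-base ambiguity code amb(b, d) if f_j(b) + f_j(d) > 0.75
  (strictly) for some base pair,
* else the gap character ``-``.

The ambiguity codes are model-specific, not IUPAC: I=A/C, J=A/G, K=A/T,
L=C/G, M=C/T, N=G/T.  An IUPAC rendering is available for interoperability
(:func:`to_iupac`), clearly separated from the native alphabet.

Conservation is measured in bits with base-2 logarithms so that a fully
conserved column scores exactly 2 bits and a fully conserved column pair
exactly 4 bits; 0*log(0) terms contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .align import Alignment

BASES = "ACGT"
GAP = "-"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Two-base ambiguity codes (model-specific alphabet).
AMBIGUITY_CODES: dict[frozenset, str] = {
    frozenset("AC"): "I",
    frozenset("AG"): "J",
    frozenset("AT"): "K",
    frozenset("CG"): "L",
    frozenset("CT"): "M",
    frozenset("GT"): "N",
}

#: Which bases each consensus symbol stands for.
SYMBOL_COVERAGE: dict[str, frozenset] = {
    **{b: frozenset(b) for b in BASES},
    **{code: pair for pair, code in AMBIGUITY_CODES.items()},
    GAP: frozenset(),
}

#: Display mapping of the native codes onto IUPAC one-letter codes.
IUPAC_DISPLAY = {"I": "M", "J": "R", "K": "W", "L": "S", "M": "Y", "N": "K"}

#: Bitmask per symbol: bit i set iff the symbol covers base BASES[i].
SYMBOL_MASKS: dict[str, int] = {
    sym: sum(1 << _BASE_INDEX[b] for b in cov) for sym, cov in SYMBOL_COVERAGE.items()
}


def amb(b: str, d: str) -> str:
    """The ambiguity code for two distinct bases."""
    if b == d:
        raise ValueError("ambiguity code requires two distinct bases")
    return AMBIGUITY_CODES[frozenset((b, d))]


def to_iupac(consensus_string: str) -> str:
    """Render a consensus string in IUPAC codes (gaps pass through)."""
    return "".join(IUPAC_DISPLAY.get(c, c) for c in consensus_string)


def encode_rows(rows: list[str]) -> np.ndarray:
    """Alignment rows as an (N, W) integer matrix, A..T -> 0..3, gap -> 4."""
    lut = np.full(128, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    lut[ord(GAP)] = 4
    mat = lut[np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)]
    if (mat < 0).any():
        raise ValueError("alignment rows contain characters outside A,C,G,T,-")
    return mat.reshape(len(rows), -1).astype(np.int64)


@dataclass
class ColumnProfile:
    """Per-column base counts and frequencies of an alignment.

    ``counts[j, b]`` is n_{j+1}(base b); frequencies divide by the number of
    rows N, so columns with gaps sum to less than one.  Overall counts and
    frequencies n(b), f(b) are exposed for completeness although no score
    uses them.
    """

    counts: np.ndarray  # (W, 4) int
    n_rows: int

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @cached_property
    def freqs(self) -> np.ndarray:
        return self.counts / self.n_rows

    @cached_property
    def overall_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @cached_property
    def overall_freqs(self) -> np.ndarray:
        total = self.overall_counts.sum()
        return self.overall_counts / total if total else self.overall_counts * 0.0

    def freq(self, j: int, base: str) -> float:
        """f_j(base) with 1-based column index j."""
        return float(self.freqs[j - 1, _BASE_INDEX[base]])


@dataclass
class PairProfile:
    """Joint base frequencies f_ij(b, d) for ordered column pairs.

    ``freqs[i, j, b, d]`` is the fraction of rows carrying base b at column
    i+1 and base d at column j+1; rows gapped at either column are excluded
    from the numerator only, so the 16 cells sum to at most one.
    """

    freqs: np.ndarray  # (W, W, 4, 4) float
    n_rows: int

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    def freq(self, i: int, j: int, b: str, d: str) -> float:
        """f_ij(b, d) with 1-based column indices."""
        return float(self.freqs[i - 1, j - 1, _BASE_INDEX[b], _BASE_INDEX[d]])


def build_profiles(alignment: "Alignment") -> tuple[ColumnProfile, PairProfile]:
    """Exact column and pair profiles of an alignment.

    The pair profile equals the direct double loop over rows and column
    pairs; it is computed with a one-hot contraction for speed.
    """
    col = build_column_profile(alignment)
    pair = build_pair_profile(alignment)
    return col, pair


def build_column_profile(alignment: "Alignment") -> ColumnProfile:
    mat = encode_rows(alignment.rows)
    n, w = mat.shape
    counts = np.zeros((w, 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (mat == b).sum(axis=0)
    return ColumnProfile(counts=counts, n_rows=n)


def build_pair_profile(alignment: "Alignment") -> PairProfile:
    mat = encode_rows(alignment.rows)
    n, w = mat.shape
    onehot = np.zeros((n, w, 4), dtype=np.float64)
    rows_idx, cols_idx = np.nonzero(mat < 4)
    onehot[rows_idx, cols_idx, mat[rows_idx, cols_idx]] = 1.0
    joint = np.einsum("nia,njb->ijab", onehot, onehot) / n
    return PairProfile(freqs=joint, n_rows=n)


def _plogp(f: np.ndarray) -> np.ndarray:
    out = np.zeros_like(f)
    nz = f > 0
    out[nz] = f[nz] * np.log2(f[nz])
    return out


def column_ic_array(profile: ColumnProfile) -> np.ndarray:
    """IC of every column, in bits: 2 + sum_b f_j(b) log2 f_j(b)."""
    return 2.0 + _plogp(profile.freqs).sum(axis=1)


def ic_column(profile: ColumnProfile, j: int) -> float:
    """Information content of column j (1-based), in bits."""
    if not 1 <= j <= profile.width:
        raise IndexError(f"column {j} out of range 1..{profile.width}")
    return float(column_ic_array(profile)[j - 1])


def pair_ic_matrix(pair_profile: PairProfile) -> np.ndarray:
    """IC of every ordered column pair: 4 + sum_{b,d} f_ij log2 f_ij.

    The diagonal (i == j) is not a pair and is set to NaN.
    """
    mat = 4.0 + _plogp(pair_profile.freqs).sum(axis=(2, 3))
    np.fill_diagonal(mat, np.nan)
    return mat


def ic_pair(pair_profile: PairProfile, i: int, j: int) -> float:
    """Information content of the column pair (i, j), 1-based, i != j."""
    w = pair_profile.width
    if i == j:
        raise ValueError("pair information content requires two distinct columns")
    if not (1 <= i <= w and 1 <= j <= w):
        raise IndexError(f"column pair ({i}, {j}) out of range 1..{w}")
    f = pair_profile.freqs[i - 1, j - 1]
    return float(4.0 + _plogp(f).sum())


def _consensus_symbol(freqs: np.ndarray) -> str:
    """Apply the threshold rules to one column's base frequencies."""
    # single base with strict majority
    best = int(np.argmax(freqs))
    if freqs[best] > 0.5:
        return BASES[best]
    # two-base rule; at most one pair can exceed 0.75 (the frequencies sum
    # to at most 1), but break hypothetical ties deterministically anyway:
    # highest pair sum, then alphabetical.
    best_pair, best_sum = None, 0.75
    for a in range(4):
        for b in range(a + 1, 4):
            s = freqs[a] + freqs[b]
            if s > best_sum + 1e-12 or (best_pair is None and s > best_sum):
                best_pair, best_sum = (a, b), s
    if best_pair is not None:
        return amb(BASES[best_pair[0]], BASES[best_pair[1]])
    return GAP


@dataclass
class Consensus:
    """A consensus string with its supporting profiles and IC tables.

    ``sequence`` uses the native alphabet {A,C,G,T,I,J,K,L,M,N,-} and has
    one symbol per alignment column, so consensus positions map 1:1 onto
    alignment columns.  ``column_ic`` is indexed by column-1; ``pair_ic``
    is the full (W, W) matrix (NaN diagonal) when the pair profile was
    built, else None.
    """

    sequence: str
    column_profile: ColumnProfile
    column_ic: np.ndarray
    pair_profile: PairProfile | None = None
    pair_ic: np.ndarray | None = None

    @property
    def width(self) -> int:
        return len(self.sequence)

    @cached_property
    def masks(self) -> np.ndarray:
        """uint8 coverage bitmask per consensus position (bit i = base ACGT[i])."""
        return np.array([SYMBOL_MASKS[c] for c in self.sequence], dtype=np.uint8)

    @property
    def iupac(self) -> str:
        return to_iupac(self.sequence)

    def require_pair_ic(self) -> np.ndarray:
        if self.pair_ic is None:
            raise ValueError(
                "pair information content not built; construct the consensus "
                "with with_pairs=True"
            )
        return self.pair_ic


def consensus_from_alignment(
    alignment: "Alignment", *, with_pairs: bool = True
) -> Consensus:
    """Derive the ambiguity-code consensus (plus IC tables) from an alignment.

    The consensus is a pure function of the column profile; the pair profile
    and its IC matrix are attached for pair-aware scoring and can be skipped
    (``with_pairs=False``) when only the basic score is needed, e.g. during
    alignment construction.
    """
    col = build_column_profile(alignment)
    symbols = "".join(_consensus_symbol(col.freqs[j]) for j in range(col.width))
    cons = Consensus(
        sequence=symbols, column_profile=col, column_ic=column_ic_array(col)
    )
    if with_pairs:
        cons.pair_profile = build_pair_profile(alignment)
        cons.pair_ic = pair_ic_matrix(cons.pair_profile)
    return cons
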
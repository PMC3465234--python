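"""Scoring a putative site against a consensus, maximised over all overlaps.

A test sequence t is slid along the consensus C; at each offset the shared
columns form an overlap w.  Four per-overlap scores are defined:

* basic          — the number of matching positions, where a position
                   matches when the consensus symbol equals the test base
                   or is an ambiguity code covering it (a consensus gap
                   never matches);
* IC-weighted    — each match weighted by the information content of the
                   underlying alignment column;
* pairwise (PS)  — the triple sum over pair separations s = 1..K of
                   MatchPair(w, i, k) terms (each worth 2 when both
                   positions match), K being the *scope*; ``"full"`` scope
                   resolves to |w| - 1 per overlap.  The sum is implemented
                   literally, index bounds included, so a pair at distance
                   k is revisited by every s from k up to min(K, |w| - i);
* combined       — the pairwise sum with each MatchPair term weighted by
                   the pair information content of the underlying column
                   pair.

The score of t against C under a configuration is the maximum of the
configured per-overlap score over every offset with at least one overlap
column.  :func:`scan` evaluates this with a vectorised engine
(:class:`ConsensusScanner`) whose contract is value-equality with the
literal per-overlap functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .consensus import BASES, Consensus, GAP, SYMBOL_COVERAGE, _BASE_INDEX

#: The twelve pairwise-score scope settings of the experiment grid.
SCOPES: tuple = (None, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, "full")

ALIGNMENT_STRATEGIES = ("sorted", "imported")


def normalize_scope(scope) -> "None | int | str":
    """Canonicalise a scope spec: None/'none' -> None, 'full' -> 'full', int."""
    if scope is None or (isinstance(scope, str) and scope.lower() == "none"):
        return None
    if isinstance(scope, str):
        if scope.lower() == "full":
            return "full"
        return int(scope)
    if isinstance(scope, (int, np.integer)):
        if scope < 1:
            raise ValueError("integer scope must be >= 1")
        return int(scope)
    raise ValueError(f"invalid scope {scope!r}")


@dataclass(frozen=True)
class ScoringConfig:
    """One cell of the experiment grid: alignment strategy x IC x PS scope."""

    use_ic: bool = False
    ps_scope: "None | int | str" = None
    alignment_strategy: str = "sorted"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ps_scope", normalize_scope(self.ps_scope))
        if self.alignment_strategy not in ALIGNMENT_STRATEGIES:
            raise ValueError(
                f"alignment_strategy must be one of {ALIGNMENT_STRATEGIES}"
            )

    @property
    def label(self) -> str:
        ic = "ic" if self.use_ic else "noic"
        scope = "none" if self.ps_scope is None else str(self.ps_scope)
        return f"{self.alignment_strategy}_{ic}_scope-{scope}"


def match_symbol(consensus_symbol: str, base: str) -> int:
    """1 if the consensus symbol covers the test base, else 0 (gaps never match)."""
    return 1 if base in SYMBOL_COVERAGE[consensus_symbol] else 0


@dataclass(frozen=True)
class Overlap:
    """The shared columns of a test sequence and a consensus at one offset.

    Position i (1-based) of the overlap pairs consensus symbol
    ``cons_symbols[i-1]`` with test base ``test_bases[i-1]``; ``columns``
    gives the underlying 1-based alignment column of each position
    (consensus positions map 1:1 onto alignment columns).
    """

    offset: int
    cons_symbols: str
    test_bases: str
    columns: tuple

    def __post_init__(self) -> None:
        if len(self) < 1:
            raise ValueError("overlap must span at least one column")
        if not (len(self.cons_symbols) == len(self.test_bases) == len(self.columns)):
            raise ValueError("inconsistent overlap components")

    def __len__(self) -> int:
        return len(self.cons_symbols)


def make_overlap(t: str, consensus: "Consensus | str", offset: int) -> Overlap:
    """The overlap of ``t`` against the consensus at a given offset."""
    cons = consensus if isinstance(consensus, str) else consensus.sequence
    width = len(cons)
    lo = max(1, offset)
    hi = min(width, offset + len(t) - 1)
    if lo > hi:
        raise ValueError(f"offset {offset} yields no overlap")
    cols = tuple(range(lo, hi + 1))
    return Overlap(
        offset=offset,
        cons_symbols="".join(cons[c - 1] for c in cols),
        test_bases="".join(t[c - offset] for c in cols),
        columns=cols,
    )


def enumerate_overlaps(
    t: str, consensus: "Consensus | str", min_overlap: int = 1
) -> Iterator[Overlap]:
    """All overlaps of ``t`` against the consensus, scanning left to right."""
    cons = consensus if isinstance(consensus, str) else consensus.sequence
    if not t or not cons:
        raise ValueError("test sequence and consensus must be non-empty")
    for offset in range(2 - len(t), len(cons) + 1):
        ov = make_overlap(t, cons, offset)
        if len(ov) >= min_overlap:
            yield ov


def match(overlap: Overlap, i: int) -> int:
    """Match indicator at overlap position i (1-based)."""
    if not 1 <= i <= len(overlap):
        raise IndexError(f"overlap position {i} out of range 1..{len(overlap)}")
    return match_symbol(overlap.cons_symbols[i - 1], overlap.test_bases[i - 1])


def match_pair(overlap: Overlap, i: int, k: int) -> int:
    """Pair match score: 2 when positions i and i+k both match, else 0."""
    if k < 1:
        raise ValueError("pair separation k must be >= 1")
    if not (1 <= i and i + k <= len(overlap)):
        raise IndexError(
            f"pair ({i}, {i + k}) out of range for overlap of length {len(overlap)}"
        )
    return 2 if match(overlap, i) and match(overlap, i + k) else 0


def _resolve_scope(overlap_len: int, scope) -> int:
    scope = normalize_scope(scope)
    if scope is None:
        raise ValueError("pairwise score requires an integer or 'full' scope")
    if scope == "full":
        return overlap_len - 1
    return scope


def score_overlap_basic(overlap: Overlap) -> int:
    """Basic score: number of matches across the overlap."""
    return sum(match(overlap, i) for i in range(1, len(overlap) + 1))


def score_overlap_ic(overlap: Overlap, column_ic: np.ndarray) -> float:
    """IC-weighted score; ``column_ic`` is indexed by alignment column - 1."""
    return float(
        sum(
            match(overlap, i) * column_ic[overlap.columns[i - 1] - 1]
            for i in range(1, len(overlap) + 1)
        )
    )


def score_overlap_ps(overlap: Overlap, scope) -> int:
    """Pairwise score: the literal triple sum over s = 1..K, i = 1..|w|-s,
    k = 1..s of MatchPair(w, i, k)."""
    k_max = _resolve_scope(len(overlap), scope)
    m = [match(overlap, i) for i in range(1, len(overlap) + 1)]
    total = 0
    n = len(overlap)
    for s in range(1, k_max + 1):
        for i in range(1, n - s + 1):
            for k in range(1, s + 1):
                if m[i - 1] and m[i + k - 1]:
                    total += 2
    return total


def score_overlap_icps(overlap: Overlap, scope, pair_ic: np.ndarray) -> float:
    """Combined score: the pairwise triple sum with each MatchPair term
    weighted by the pair IC of the underlying alignment-column pair."""
    k_max = _resolve_scope(len(overlap), scope)
    m = [match(overlap, i) for i in range(1, len(overlap) + 1)]
    cols = overlap.columns
    total = 0.0
    n = len(overlap)
    for s in range(1, k_max + 1):
        for i in range(1, n - s + 1):
            for k in range(1, s + 1):
                if m[i - 1] and m[i + k - 1]:
                    total += 2.0 * pair_ic[cols[i - 1] - 1, cols[i + k - 1] - 1]
    return total


def score_overlap(overlap: Overlap, consensus: Consensus, config: ScoringConfig):
    """The configured per-overlap score."""
    if config.ps_scope is None:
        if config.use_ic:
            return score_overlap_ic(overlap, consensus.column_ic)
        return score_overlap_basic(overlap)
    if config.use_ic:
        return score_overlap_icps(overlap, config.ps_scope, consensus.require_pair_ic())
    return score_overlap_ps(overlap, config.ps_scope)


class ConsensusScanner:
    """Vectorised sliding-window scorer for one consensus.

    Precomputes the consensus coverage masks and IC tables once, then scores
    test sequences under any set of (use_ic, scope) variants in one pass.
    Per-offset scores are accumulated as diagonal sums of a column-by-
    position match matrix; pair terms reuse the cumulative structure of the
    triple sum (the score at scope K extends the score at K - 1), which the
    unit tests pin against the literal per-overlap loops.
    """

    def __init__(self, consensus: Consensus, min_overlap: int = 1) -> None:
        if min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        self.consensus = consensus
        self.min_overlap = min_overlap
        self.masks = consensus.masks.astype(np.int64)
        self.column_ic = np.asarray(consensus.column_ic, dtype=np.float64)
        self.pair_ic = consensus.pair_ic

    def _encode(self, t: str) -> np.ndarray:
        try:
            return np.array([_BASE_INDEX[b] for b in t.upper()], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"test sequence contains non-ACGT character {exc}") from exc

    def scores(self, t: str, variants: Sequence[tuple]) -> np.ndarray:
        """Max-over-overlaps score of ``t`` for each (use_ic, scope) variant."""
        if not t:
            raise ValueError("test sequence must be non-empty")
        variants = [(bool(ic), normalize_scope(sc)) for ic, sc in variants]
        t_codes = self._encode(t)
        W, L = len(self.masks), len(t_codes)
        D = W + L - 1
        # match matrix: B[i, j] = 1 iff consensus position i+1 covers t base j+1
        B = ((self.masks[:, None] >> t_codes[None, :]) & 1).astype(np.float64)
        ii = np.arange(W)[:, None]
        jj = np.arange(L)[None, :]
        diag = (ii - jj + (L - 1)).ravel()
        shift = np.arange(D) - (L - 1)
        overlap_len = np.minimum(W, L + shift) - np.maximum(0, shift)
        valid = overlap_len >= self.min_overlap
        if not valid.any():
            raise ValueError(
                f"no offset yields an overlap of at least {self.min_overlap} column(s)"
            )

        basic = np.bincount(diag, weights=B.ravel(), minlength=D)
        need_ic = any(ic and sc is None for ic, sc in variants)
        need_ps = any(not ic and sc is not None for ic, sc in variants)
        need_icps = any(ic and sc is not None for ic, sc in variants)
        ic_scores = (
            np.bincount(diag, weights=(B * self.column_ic[:, None]).ravel(), minlength=D)
            if need_ic
            else None
        )

        ps_cum = icps_cum = None
        s_max = min(W, L) - 1
        if (need_ps or need_icps) and s_max >= 1:
            if need_icps and self.pair_ic is None:
                self.consensus.require_pair_ic()  # raises with guidance
            # R[i, j] = |w| - (within-overlap index of position (i, j))
            R = np.minimum(W - 1 - ii, L - 1 - jj)  # broadcast to (W, L)
            R = np.broadcast_to(R, (W, L))
            ps_cum = np.zeros((s_max + 1, D))
            m_plain = np.zeros((W, L))
            if need_icps:
                icps_cum = np.zeros((s_max + 1, D))
                m_ic = np.zeros((W, L))
            for s in range(1, s_max + 1):
                pair_hits = B[: W - s, : L - s] * B[s:, s:]
                m_plain[: W - s, : L - s] += 2.0 * pair_hits
                sel = (R >= s).ravel()
                ps_cum[s] = ps_cum[s - 1] + np.bincount(
                    diag[sel], weights=m_plain.ravel()[sel], minlength=D
                )
                if need_icps:
                    ic_diag = np.diagonal(self.pair_ic, offset=s)  # (W - s,)
                    m_ic[: W - s, : L - s] += 2.0 * pair_hits * ic_diag[:, None]
                    icps_cum[s] = icps_cum[s - 1] + np.bincount(
                        diag[sel], weights=m_ic.ravel()[sel], minlength=D
                    )

        def per_offset(ic: bool, scope) -> np.ndarray:
            if scope is None:
                return ic_scores if ic else basic
            cum = icps_cum if ic else ps_cum
            if cum is None:  # s_max < 1: no pairs exist anywhere
                return np.zeros(D)
            if scope == "full":
                k_full = np.clip(overlap_len - 1, 0, s_max)
                return cum[k_full, np.arange(D)]
            return cum[min(int(scope), s_max)]

        return np.array(
            [per_offset(ic, sc)[valid].max() for ic, sc in variants], dtype=np.float64
        )

    def scan(self, t: str, config: ScoringConfig) -> float:
        return float(self.scores(t, [(config.use_ic, config.ps_scope)])[0])


def scan(
    t: str,
    consensus: Consensus,
    config: ScoringConfig | None = None,
    *,
    min_overlap: int = 1,
) -> float:
    """Score of ``t`` against the consensus: the configured per-overlap score
    maximised over every offset with at least ``min_overlap`` overlap columns."""
    config = config or ScoringConfig()
    return ConsensusScanner(consensus, min_overlap=min_overlap).scan(t, config)


def scan_reference(
    t: str,
    consensus: Consensus,
    config: ScoringConfig | None = None,
    *,
    min_overlap: int = 1,
) -> float:
    """Literal (per-overlap loop) evaluation of :func:`scan`; slow but direct."""
    config = config or ScoringConfig()
    return float(
        max(
            score_overlap(ov, consensus, config)
            for ov in enumerate_overlaps(t, consensus, min_overlap=min_overlap)
        )
    )
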
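"""The naive sorting-based multiple aligner for variable-length binding sites.

The aligner rests on the assumption that one core pattern is shared, in part
or whole, by every binding site of a factor, and that a short site is more
likely to consist mostly of core positions.  It therefore sorts the sites
from shortest to longest, seeds the alignment with the shortest, and adds
each next site at the ungapped offset that maximises the basic match score
against the consensus of the partial alignment, re-deriving the consensus
after every addition.  Sites are placed as contiguous blocks — the aligner
only pads row ends with ``-`` and never introduces internal gaps, so every
row degaps back to its source sequence exactly.

Offsets are 1-based: offset 1 places the site's first base under consensus
position 1, values below 1 overhang to the left.  Ties between equal-scoring
offsets are broken by ``tie_rule`` (``first_best`` keeps the leftmost,
``last_best`` — the default — the rightmost).  Equal-length sites are
ordered lexicographically unless a seed is supplied, in which case their
order within each length class is drawn from a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .consensus import BASES, GAP, SYMBOL_COVERAGE, consensus_from_alignment

if TYPE_CHECKING:  # pragma: no cover
    from .consensus import Consensus
    from .seqio import SiteSet

TIE_RULES = ("first_best", "last_best")


@dataclass(frozen=True)
class OffsetPlacement:
    """A candidate placement: offset of the site's first base relative to
    consensus position 1, and its basic match score there."""

    offset: int
    score: int


@dataclass(frozen=True)
class PlacementStep:
    """One step of the greedy build, kept for provenance and oracle replay."""

    site_id: str
    sequence: str
    consensus_before: str
    offset: int
    score: int


@dataclass
class Alignment:
    """N gapped rows of identical width over {A,C,G,T,-}.

    ``site_ids`` preserves row-to-site provenance; ``build_log`` (present on
    aligner output) records, per placement, the consensus the site was
    scored against and the offset chosen.
    """

    rows: list[str]
    site_ids: list[str]
    build_log: list[PlacementStep] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        if len(self.rows) != len(self.site_ids):
            raise ValueError("rows and site_ids must have equal length")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(widths)}")
        alphabet = set(BASES + GAP)
        for sid, row in zip(self.site_ids, self.rows):
            bad = set(row) - alphabet
            if bad:
                raise ValueError(
                    f"row {sid!r} contains invalid character(s) {''.join(sorted(bad))!r}"
                )

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degapped(self, index: int) -> str:
        return self.rows[index].replace(GAP, "")

    def without_row(self, index: int, *, drop_empty_columns: bool = True) -> "Alignment":
        """A copy with one row removed (columns left all-gap are dropped)."""
        if not 0 <= index < self.n_rows:
            raise IndexError(f"row index {index} out of range")
        rows = self.rows[:index] + self.rows[index + 1 :]
        ids = self.site_ids[:index] + self.site_ids[index + 1 :]
        if not rows:
            raise ValueError("cannot remove the only row of an alignment")
        if drop_empty_columns:
            keep = [j for j in range(len(rows[0])) if any(r[j] != GAP for r in rows)]
            rows = ["".join(r[j] for j in keep) for r in rows]
        return Alignment(rows=rows, site_ids=ids)


def _consensus_string(consensus: "Consensus | str") -> str:
    return consensus if isinstance(consensus, str) else consensus.sequence


def _basic_offset_score(site: str, cons: str, offset: int) -> int:
    """Basic match count of ``site`` placed at ``offset`` against ``cons``."""
    width = len(cons)
    score = 0
    for p, base in enumerate(site, start=1):
        col = offset + p - 1
        if 1 <= col <= width and base in SYMBOL_COVERAGE[cons[col - 1]]:
            score += 1
    return score


def best_offset(
    site: str, consensus: "Consensus | str", tie_rule: str = "last_best"
) -> OffsetPlacement:
    """The highest-scoring ungapped placement of ``site`` against a consensus.

    Every offset with at least one overlap column is scored with the basic
    match score; ``tie_rule`` picks the leftmost (``first_best``) or
    rightmost (``last_best``) among equal maxima scanning left to right.
    """
    if tie_rule not in TIE_RULES:
        raise ValueError(f"tie_rule must be one of {TIE_RULES}")
    cons = _consensus_string(consensus)
    if not site or not cons:
        raise ValueError("site and consensus must be non-empty")
    best: OffsetPlacement | None = None
    for offset in range(2 - len(site), len(cons) + 1):
        score = _basic_offset_score(site, cons, offset)
        if (
            best is None
            or score > best.score
            or (score == best.score and tie_rule == "last_best")
        ):
            best = OffsetPlacement(offset=offset, score=score)
    assert best is not None
    return best


def _order_sites(site_set: "SiteSet", rng_seed: int | None) -> list:
    records = list(site_set.sites)
    if rng_seed is None:
        return sorted(records, key=lambda r: (len(r.sequence), r.sequence))
    rng = np.random.default_rng(rng_seed)
    by_length: dict[int, list] = {}
    for rec in records:
        by_length.setdefault(len(rec.sequence), []).append(rec)
    ordered = []
    for length in sorted(by_length):
        group = by_length[length]
        ordered.extend(group[i] for i in rng.permutation(len(group)))
    return ordered


def sorted_align(
    site_set: "SiteSet",
    tie_rule: str = "last_best",
    rng_seed: int | None = None,
) -> Alignment:
    """Greedy shortest-first multiple alignment of one factor's sites.

    Implements the sort / seed / re-derive-consensus / place-at-best-offset
    loop described in the module docstring.  The result is deterministic
    given ``(tie_rule, rng_seed, input order)``; its rows appear in
    placement order, and column 1 is always the leftmost occupied column.
    """
    if len(site_set) == 0:
        raise ValueError("cannot align an empty site set")
    ordered = _order_sites(site_set, rng_seed)

    # placements as (record, start column) in a shared 1-based coordinate
    placed = [(ordered[0], 1)]
    log = [
        PlacementStep(
            site_id=ordered[0].site_id,
            sequence=ordered[0].sequence,
            consensus_before="",
            offset=1,
            score=0,
        )
    ]

    def render() -> Alignment:
        width = max(start + len(rec.sequence) - 1 for rec, start in placed)
        rows = [
            GAP * (start - 1)
            + rec.sequence
            + GAP * (width - start - len(rec.sequence) + 1)
            for rec, start in placed
        ]
        return Alignment(rows=rows, site_ids=[rec.site_id for rec, _ in placed])

    for rec in ordered[1:]:
        cons = consensus_from_alignment(render(), with_pairs=False)
        placement = best_offset(rec.sequence, cons, tie_rule=tie_rule)
        log.append(
            PlacementStep(
                site_id=rec.site_id,
                sequence=rec.sequence,
                consensus_before=cons.sequence,
                offset=placement.offset,
                score=placement.score,
            )
        )
        placed.append((rec, placement.offset))
        # re-base so that column 1 is the leftmost occupied column
        shift = 1 - min(start for _, start in placed)
        if shift:
            placed = [(r, start + shift) for r, start in placed]

    out = render()
    out.build_log = log
    return out


def degap_check(alignment: Alignment, site_set: "SiteSet | Iterable") -> bool:
    """True iff every row, with gaps removed, equals its source site sequence."""
    lookup = {rec.site_id: rec.sequence for rec in site_set}
    return all(
        sid in lookup and alignment.degapped(i) == lookup[sid]
        for i, sid in enumerate(alignment.site_ids)
    )
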
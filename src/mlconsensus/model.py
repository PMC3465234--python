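"""Model-style interface: fit a consensus to a set of binding sites.

:class:`MLConsensus` is constructed from one factor's binding sites (any
lengths, none excluded) and ``fit()`` produces an
:class:`MLConsensusResults` carrying the alignment, the ambiguity-code
consensus, the per-column and per-pair information content, and scoring
methods.  Example::

    model = MLConsensus(site_set)                # sorted-alignment strategy
    res = model.fit()
    print(res.summary())
    res.score("ACCTAAGCTG", ScoringConfig(use_ic=True, ps_scope=2))

A pre-computed alignment (e.g. imported ClustalW2 output) can stand in for
the built-in aligner via ``strategy="imported"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .align import Alignment, degap_check, sorted_align
from .consensus import Consensus, consensus_from_alignment, to_iupac
from .scoring import ConsensusScanner, ScoringConfig, scan
from .seqio import SiteRecord, SiteSet


class MLConsensus:
    """Consensus model for the variable-length binding sites of one factor.

    Parameters
    ----------
    sites : SiteSet or iterable of SiteRecord
        The known binding sites (the model never drops any of them).
    strategy : {"sorted", "imported"}
        Use the built-in shortest-first aligner, or an alignment supplied
        via ``alignment`` (its rows must degap to the given sites).
    tie_rule : {"first_best", "last_best"}
        Offset tie-breaking for the built-in aligner.
    rng_seed : int, optional
        Seed for ordering equal-length sites; deterministic lexicographic
        order when omitted.
    """

    def __init__(
        self,
        sites: "SiteSet | Iterable[SiteRecord]",
        *,
        strategy: str = "sorted",
        tie_rule: str = "last_best",
        alignment: Alignment | None = None,
        rng_seed: int | None = None,
    ) -> None:
        if not isinstance(sites, SiteSet):
            sites = list(sites)
            if not sites:
                raise ValueError("need at least one binding site")
            sites = SiteSet(sites[0].tf_id, sites)
        if len(sites) == 0:
            raise ValueError("need at least one binding site")
        if strategy not in ("sorted", "imported"):
            raise ValueError("strategy must be 'sorted' or 'imported'")
        if strategy == "imported":
            if alignment is None:
                raise ValueError("strategy='imported' requires an alignment")
            if not degap_check(alignment, sites):
                raise ValueError(
                    "imported alignment rows do not degap to the given sites"
                )
        self.sites = sites
        self.strategy = strategy
        self.tie_rule = tie_rule
        self.alignment = alignment
        self.rng_seed = rng_seed

    @classmethod
    def from_dataframe(
        cls, df, *, tf_id: str | None = None, species: str = "unknown", **kwargs
    ) -> "MLConsensus":
        """Build from a DataFrame with columns tf_id, site_id, sequence
        (and optionally species); ``tf_id`` selects one factor if the frame
        holds several."""
        if tf_id is not None:
            df = df[df["tf_id"] == tf_id]
        tfs = df["tf_id"].unique()
        if len(tfs) != 1:
            raise ValueError(
                f"expected exactly one tf_id, found {len(tfs)}; pass tf_id=..."
            )
        records = [
            SiteRecord(
                site_id=str(row.site_id),
                tf_id=str(row.tf_id),
                species=str(getattr(row, "species", species)),
                sequence=str(row.sequence),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(SiteSet(str(tfs[0]), records), **kwargs)

    def fit(self, *, with_pairs: bool = True) -> "MLConsensusResults":
        """Align the sites (unless imported), derive the consensus and its
        information-content tables, and return the results object."""
        if self.strategy == "sorted":
            alignment = sorted_align(
                self.sites, tie_rule=self.tie_rule, rng_seed=self.rng_seed
            )
        else:
            alignment = self.alignment
        consensus = consensus_from_alignment(alignment, with_pairs=with_pairs)
        return MLConsensusResults(model=self, alignment=alignment, consensus=consensus)


@dataclass
class MLConsensusResults:
    """Fitted consensus: estimates, conservation diagnostics, and scoring."""

    model: MLConsensus | None
    alignment: Alignment
    consensus: Consensus
    _scanners: dict = field(default_factory=dict, repr=False)

    @property
    def consensus_string(self) -> str:
        return self.consensus.sequence

    @property
    def column_ic(self) -> np.ndarray:
        return self.consensus.column_ic

    @property
    def pair_ic(self) -> np.ndarray | None:
        return self.consensus.pair_ic

    @property
    def n_sites(self) -> int:
        return self.alignment.n_rows

    @property
    def width(self) -> int:
        return self.alignment.width

    def scanner(self, min_overlap: int = 1) -> ConsensusScanner:
        if min_overlap not in self._scanners:
            self._scanners[min_overlap] = ConsensusScanner(
                self.consensus, min_overlap=min_overlap
            )
        return self._scanners[min_overlap]

    def score(
        self,
        sequence: str,
        config: ScoringConfig | None = None,
        *,
        min_overlap: int = 1,
    ) -> float:
        """Score one putative site (max over all overlaps) under a config."""
        config = config or ScoringConfig()
        return self.scanner(min_overlap).scan(sequence, config)

    def score_many(
        self,
        sequences: Sequence[str],
        config: ScoringConfig | None = None,
        *,
        min_overlap: int = 1,
    ) -> np.ndarray:
        config = config or ScoringConfig()
        scanner = self.scanner(min_overlap)
        return np.array([scanner.scan(s, config) for s in sequences])

    def summary(self) -> str:
        """Plain-text per-column summary of the fitted consensus."""
        prof = self.consensus.column_profile
        lines = [
            "ML-Consensus fit",
            "=" * 58,
            f"sites (N):        {self.n_sites}",
            f"alignment width:  {self.width}",
            f"strategy:         {self.model.strategy if self.model else 'unknown'}",
            f"consensus:        {self.consensus_string}",
            f"consensus(IUPAC): {to_iupac(self.consensus_string)}",
            "-" * 58,
            f"{'col':>4} {'sym':>3} {'A':>4} {'C':>4} {'G':>4} {'T':>4} {'gap':>4} {'IC':>7}",
        ]
        for j in range(self.width):
            counts = prof.counts[j]
            gaps = prof.n_rows - counts.sum()
            lines.append(
                f"{j + 1:>4} {self.consensus_string[j]:>3} "
                f"{counts[0]:>4} {counts[1]:>4} {counts[2]:>4} {counts[3]:>4} "
                f"{gaps:>4} {self.consensus.column_ic[j]:>7.3f}"
            )
        return "\n".join(lines)

    # -- persistence (JSON model bundle: consensus + IC tables) ------------

    def to_dict(self) -> dict:
        return {
            "consensus": self.consensus_string,
            "column_ic": [float(x) for x in self.consensus.column_ic],
            "pair_ic": (
                None
                if self.consensus.pair_ic is None
                else [
                    [None if np.isnan(v) else float(v) for v in row]
                    for row in self.consensus.pair_ic
                ]
            ),
            "alignment": {"rows": self.alignment.rows, "site_ids": self.alignment.site_ids},
            "n_sites": self.n_sites,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MLConsensusResults":
        data = json.loads(Path(path).read_text())
        alignment = Alignment(
            rows=data["alignment"]["rows"], site_ids=data["alignment"]["site_ids"]
        )
        consensus = consensus_from_alignment(
            alignment, with_pairs=data["pair_ic"] is not None
        )
        if consensus.sequence != data["consensus"]:
            raise ValueError("model file inconsistent: consensus does not re-derive")
        return cls(model=None, alignment=alignment, consensus=consensus)
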
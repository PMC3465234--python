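"""Reading and writing binding-site collections and alignments.

The canonical on-disk dataset is a tab-separated *site table* with header
columns ``species, tf_id, site_id, sequence`` — one row per documented
binding site.  Per-factor FASTA files are accepted as an alternative, and
multiple sequence alignments travel as aligned FASTA or Clustal files
(Biopython handles the parsing).  Site sequences are restricted to the
four-letter DNA alphabet; the single gap character in alignments is ``-``.

Coordinates in reports produced from these containers are 1-based
inclusive columns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import Alignment

DNA_BASES = "ACGT"
GAP = "-"

_SITE_TABLE_COLUMNS = ("species", "tf_id", "site_id", "sequence")


def _validate_dna(sequence: str, *, site_id: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError(f"site {site_id!r}: empty sequence")
    bad = set(seq) - set(DNA_BASES)
    if bad:
        raise ValueError(
            f"site {site_id!r}: sequence contains non-ACGT character(s) "
            f"{''.join(sorted(bad))!r}"
        )
    return seq


@dataclass(frozen=True)
class SiteRecord:
    """One documented binding site of one transcription factor."""

    site_id: str
    tf_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _validate_dna(self.sequence, site_id=self.site_id)
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SiteSet:
    """The ordered collection of known binding sites of one factor (the
    training set S, with N = ``len(site_set)``)."""

    tf_id: str
    sites: list[SiteRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.sites:
            if rec.tf_id != self.tf_id:
                raise ValueError(
                    f"site {rec.site_id!r} belongs to {rec.tf_id!r}, not {self.tf_id!r}"
                )
            if rec.site_id in seen:
                raise ValueError(f"duplicate site_id {rec.site_id!r} in {self.tf_id!r}")
            seen.add(rec.site_id)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[SiteRecord]:
        return iter(self.sites)

    @property
    def sequences(self) -> list[str]:
        return [rec.sequence for rec in self.sites]

    def without(self, index: int) -> "SiteSet":
        """A copy with the site at ``index`` removed (leave-one-out training)."""
        if not 0 <= index < len(self.sites):
            raise IndexError(f"site index {index} out of range for {self.tf_id!r}")
        return SiteSet(self.tf_id, self.sites[:index] + self.sites[index + 1 :])


@dataclass
class SpeciesDataset:
    """All admitted factors of one species, keyed by ``tf_id``.

    The admission rule for cross-validation is at least three sites per
    factor; ``lenient=True`` keeps smaller sets (they are skipped by the
    evaluation harness, which re-applies the rule).
    """

    species: str
    site_sets: dict[str, SiteSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.site_sets)

    def __iter__(self) -> Iterator[SiteSet]:
        for tf_id in sorted(self.site_sets):
            yield self.site_sets[tf_id]

    @property
    def n_sites(self) -> int:
        return sum(len(s) for s in self.site_sets.values())

    @classmethod
    def from_records(
        cls, species: str, records: Iterable[SiteRecord], *, lenient: bool = True
    ) -> "SpeciesDataset":
        grouped: dict[str, list[SiteRecord]] = {}
        for rec in records:
            if rec.species != species:
                raise ValueError(
                    f"record {rec.site_id!r} has species {rec.species!r}, "
                    f"expected {species!r}"
                )
            grouped.setdefault(rec.tf_id, []).append(rec)
        sets = {tf: SiteSet(tf, recs) for tf, recs in grouped.items()}
        if not lenient:
            sets = {tf: s for tf, s in sets.items() if len(s) >= 3}
        return cls(species, sets)

    def admissible(self, min_sites: int = 3) -> "SpeciesDataset":
        """Restrict to factors with at least ``min_sites`` sites."""
        return SpeciesDataset(
            self.species,
            {tf: s for tf, s in self.site_sets.items() if len(s) >= min_sites},
        )


def read_site_table(path: str | Path) -> SpeciesDataset:
    """Read the canonical TSV site table into a :class:`SpeciesDataset`.

    The file must carry a header with columns ``species, tf_id, site_id,
    sequence`` (any order).  Row order is preserved within each factor.
    """
    path = Path(path)
    records: list[SiteRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty site table") from None
        missing = [c for c in _SITE_TABLE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
        idx = {c: header.index(c) for c in _SITE_TABLE_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: malformed row at line {lineno} "
                    f"({len(row)} fields, expected {len(header)})"
                )
            records.append(
                SiteRecord(
                    site_id=row[idx["site_id"]],
                    tf_id=row[idx["tf_id"]],
                    species=row[idx["species"]],
                    sequence=row[idx["sequence"]],
                )
            )
    if not records:
        raise ValueError(f"{path}: no data rows")
    species = {rec.species for rec in records}
    if len(species) > 1:
        raise ValueError(
            f"{path}: multiple species in one table ({', '.join(sorted(species))}); "
            "split into one table per species"
        )
    return SpeciesDataset.from_records(species.pop(), records)


def write_site_table(dataset: SpeciesDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SITE_TABLE_COLUMNS)
        for site_set in dataset:
            for rec in site_set:
                writer.writerow([rec.species, rec.tf_id, rec.site_id, rec.sequence])


def read_fasta_sites(path: str | Path, tf_id: str, species: str) -> SiteSet:
    """Read one factor's sites from a FASTA file (one site per record)."""
    path = Path(path)
    records: list[SiteRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SiteRecord(site_id=rec.id, tf_id=tf_id, species=species, sequence=str(rec.seq))
        )
    if not records:
        raise ValueError(f"{path}: no records")
    return SiteSet(tf_id, records)


def _sniff_alignment_format(path: Path) -> str:
    with path.open() as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.lstrip().startswith(">") else "clustal"
    raise ValueError(f"{path}: empty alignment file")


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read an aligned FASTA or Clustal file.

    All rows must have equal length and use only ``A,C,G,T,-``; degapping a
    row recovers the original site sequence, so imported alignments (for
    example ClustalW2 output) can stand in for the built-in aligner.
    """
    path = Path(path)
    fmt = fmt or _sniff_alignment_format(path)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    rows, ids = [], []
    for rec in msa:
        row = str(rec.seq).upper()
        bad = set(row) - set(DNA_BASES + GAP)
        if bad:
            raise ValueError(
                f"{path}: row {rec.id!r} contains invalid character(s) "
                f"{''.join(sorted(bad))!r}"
            )
        rows.append(row)
        ids.append(rec.id)
    return Alignment(rows=rows, site_ids=ids)


def write_alignment(alignment: Alignment, path: str | Path, fmt: str = "fasta") -> None:
    """Write an alignment as aligned FASTA (default) or Clustal."""
    path = Path(path)
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=site_id, description="")
        for row, site_id in zip(alignment.rows, alignment.site_ids)
    )
    with path.open("w") as fh:
        AlignIO.write(msa, fh, fmt)


def site_lookup(site_sets: Iterable[SiteSet]) -> Mapping[str, str]:
    """Map ``site_id`` to sequence over several site sets."""
    out: dict[str, str] = {}
    for site_set in site_sets:
        for rec in site_set:
            out[rec.site_id] = rec.sequence
    return out
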
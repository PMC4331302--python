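"""Reference sequence collections with taxonomy.

Reads plain and gapped (aligned) FASTA into :class:`ReferenceSet`, attaches
semicolon-delimited taxonomic lineages from headers or a sidecar TSV, and maps
between alignment columns and ungapped template positions.

All coordinates are 0-based, half-open; 1-based numbering appears only in
rendered reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO

CANONICAL_RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

GAP_CHARS = "-."
_VALID_CHARS = frozenset("ACGTURYSWKMBDHVN-")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be read into a reference set."""


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ordered (rank, label) assignments from kingdom down to species.

    Ranks below the last labelled one are simply absent; rank names follow
    :data:`CANONICAL_RANKS`.
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [r for r, _ in self.ranks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate rank names in lineage: {names}")
        order = [CANONICAL_RANKS.index(n) for n in names]
        if order != sorted(order):
            raise ValueError(f"ranks out of canonical order: {names}")
        if not self.ranks:
            raise ValueError("lineage must label at least one rank")

    def label(self, rank: str) -> Optional[str]:
        """Label at `rank`, or None if unlabelled."""
        for name, value in self.ranks:
            if name == rank:
                return value
        return None

    def __str__(self) -> str:
        return ";".join(label for _, label in self.ranks)

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "TaxonomyLineage":
        labels = [x.strip() for x in labels if x.strip()]
        if len(labels) > len(CANONICAL_RANKS):
            warnings.warn(
                f"lineage has {len(labels)} fields; keeping the first "
                f"{len(CANONICAL_RANKS)} (canonical ranks)",
                stacklevel=2,
            )
            labels = labels[: len(CANONICAL_RANKS)]
        return cls(tuple(zip(CANONICAL_RANKS, labels)))


UNCLASSIFIED = TaxonomyLineage((("kingdom", "Unclassified"),))


def _normalize_seq(raw: str, *, allow_gaps: bool) -> str:
    seq = raw.upper().replace("U", "T").replace(".", "-")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise FastaParseError(f"invalid sequence characters: {sorted(bad)}")
    if not allow_gaps and "-" in seq:
        raise FastaParseError("gap characters in unaligned FASTA input")
    return seq


@dataclass(frozen=True)
class ReferenceRecord:
    """One marker sequence with its lineage.

    `aligned_seq` may contain '-' gaps; `ungapped_seq` is derived from it.
    Sequences are stored uppercase with U normalized to T.
    """

    id: str
    lineage: TaxonomyLineage
    aligned_seq: str
    ungapped_seq: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "ungapped_seq", self.aligned_seq.replace("-", ""))

    def column_to_ungapped(self, column: int) -> Optional[int]:
        """Ungapped index of the residue at alignment `column` (0-based).

        Returns None when this record holds a gap at the column.
        """
        if not 0 <= column < len(self.aligned_seq):
            raise IndexError(
                f"column {column} out of range for alignment of length "
                f"{len(self.aligned_seq)}"
            )
        if self.aligned_seq[column] == "-":
            return None
        return column - self.aligned_seq.count("-", 0, column)

    def ungapped_to_column(self, position: int) -> int:
        """Alignment column holding ungapped `position` (inverse of above)."""
        if not 0 <= position < len(self.ungapped_seq):
            raise IndexError(f"ungapped position {position} out of range")
        seen = -1
        for col, base in enumerate(self.aligned_seq):
            if base != "-":
                seen += 1
                if seen == position:
                    return col
        raise AssertionError("unreachable")


@dataclass
class ReferenceSet:
    """A collection of reference records, optionally as an alignment."""

    records: list[ReferenceRecord]
    is_aligned: bool = False

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise FastaParseError(f"duplicate record ids: {dupes}")
        if self.is_aligned:
            lengths = {len(r.aligned_seq) for r in self.records}
            if len(lengths) > 1:
                detail = ", ".join(
                    f"{r.id}:{len(r.aligned_seq)}" for r in self.records
                )
                raise FastaParseError(f"unequal alignment lengths ({detail})")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def alignment_length(self) -> int:
        if not self.is_aligned:
            raise ValueError("reference set is not aligned")
        return len(self.records[0].aligned_seq) if self.records else 0

    def get(self, record_id: str) -> ReferenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)


def parse_lineage(
    header: str, sidecar: Optional[Mapping[str, str]] = None
) -> TaxonomyLineage:
    """Lineage for a FASTA header, preferring the sidecar mapping.

    The header is ``id[ description]``; a semicolon-delimited description or a
    sidecar entry keyed by id supplies the labels. Records without either get
    an ``Unclassified`` kingdom (with a warning).
    """
    parts = header.split(None, 1)
    rec_id = parts[0] if parts else ""
    if sidecar and rec_id in sidecar:
        return TaxonomyLineage.from_labels(sidecar[rec_id].split(";"))
    if len(parts) == 2 and parts[1].strip():
        return TaxonomyLineage.from_labels(parts[1].split(";"))
    warnings.warn(f"no lineage for record {rec_id!r}; using Unclassified", stacklevel=2)
    return UNCLASSIFIED


def read_taxonomy_sidecar(path: str | Path) -> dict[str, str]:
    """Two-column TSV (id TAB semicolon-delimited lineage), no header."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FastaParseError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def _read(path: str | Path, *, aligned: bool, sidecar=None) -> ReferenceSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_seq(str(entry.seq), allow_gaps=aligned)
        lineage = parse_lineage(entry.description, sidecar)
        records.append(ReferenceRecord(entry.id, lineage, seq))
    if not records:
        raise FastaParseError(f"no records in {path}")
    return ReferenceSet(records, is_aligned=aligned)


def read_fasta(path: str | Path, sidecar: Optional[Mapping[str, str]] = None) -> ReferenceSet:
    """Read an unaligned FASTA file (gaps rejected, U→T, uppercased)."""
    return _read(path, aligned=False, sidecar=sidecar)


def read_aligned_fasta(
    path: str | Path, sidecar: Optional[Mapping[str, str]] = None
) -> ReferenceSet:
    """Read a gapped FASTA alignment ('.' gaps normalized to '-')."""
    return _read(path, aligned=True, sidecar=sidecar)


def write_fasta(refset: ReferenceSet, path: str | Path, *, with_lineage: bool = True) -> None:
    """Write records back out; lineage goes in the description when asked."""
    with open(path, "w") as fh:
        for r in refset:
            desc = f" {r.lineage}" if with_lineage else ""
            seq = r.aligned_seq if refset.is_aligned else r.ungapped_seq
            fh.write(f">{r.id}{desc}\n{seq}\n")


def write_taxonomy_sidecar(refset: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in refset:
            fh.write(f"{r.id}\t{r.lineage}\n")


def subset_by_taxon(refset: ReferenceSet, rank: str, label: str) -> ReferenceSet:
    """Records whose lineage carries `label` at canonical `rank`."""
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}; canonical: {CANONICAL_RANKS}")
    kept = [r for r in refset if r.lineage.label(rank) == label]
    return ReferenceSet(kept, is_aligned=refset.is_aligned)
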
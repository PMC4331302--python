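"""Per-position primer conservation within taxon groups.

Given an aligned reference set and a primer, this module locates the primer
site as a run of alignment columns, computes the fraction of each taxon
group's sequences matching the primer base at every position, and renders the
classic specificity table: the primer on top, an in-group percentage row
(e.g. nematodes), and dot-notation consensus rows for the out-groups where a
dot marks agreement with the primer base.

Conservation here is the percentage of sequences whose residue IUPAC-matches
the *primer* base (not the frequency of the modal base); gap residues are
excluded from numerator and denominator, since an indel carries no evidence
about base identity.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .primer_engine import (
    IUPAC,
    MatchParams,
    Primer,
    best_site,
    count_mismatch_positions,
    iupac_match,
)
from .reference_io import ReferenceSet


class PrimerSiteNotFoundError(ValueError):
    """No record in the reference set carries an acceptable primer site."""


@dataclass(frozen=True)
class PrimerSiteLocation:
    """The modal alignment-column run of a primer site.

    `columns` has one alignment column per primer position (5'->3').  Records
    that placed the site elsewhere or had no acceptable site are reported, not
    dropped.
    """

    columns: tuple[int, ...]
    n_supporting: int
    off_modal_ids: tuple[str, ...]
    no_site_ids: tuple[str, ...]


@dataclass(frozen=True)
class ConservationProfile:
    """Per-position % of a taxon group's sequences matching the primer base."""

    primer: Primer
    taxon_label: str
    n_sequences: int
    per_position_match_pct: tuple[Optional[int], ...]
    per_position_counts: tuple[tuple[int, int], ...]  # (matching, non-gap total)

    def __post_init__(self) -> None:
        if len(self.per_position_match_pct) != len(self.primer):
            raise ValueError("profile length differs from primer length")
        for pct in self.per_position_match_pct:
            if pct is not None and not 0 <= pct <= 100:
                raise ValueError(f"percentage {pct} outside [0, 100]")


@dataclass(frozen=True)
class ConsensusRow:
    """Dot-notation consensus of a taxon group over the primer positions."""

    taxon_label: str
    consensus: str  # IUPAC letters, '.' where the group agrees with the primer
    majority_threshold: float


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def locate_primer_site(
    refset: ReferenceSet,
    primer: Primer,
    params: MatchParams = MatchParams(),
) -> PrimerSiteLocation:
    """Modal run of alignment columns occupied by the primer site.

    Each record's ungapped sequence is scanned for its best site; the site's
    positions map back to alignment columns via the record's gap structure.
    The run supported by the most records wins; ties break toward the leftmost
    first column.
    """
    if not refset.is_aligned:
        raise ValueError("reference set must be aligned")
    if not len(refset):
        raise ValueError("empty reference set")
    runs: Counter[tuple[int, ...]] = Counter()
    placements: dict[str, tuple[int, ...] | None] = {}
    for record in refset:
        site = best_site(record.ungapped_seq, primer, "plus", params, record.id)
        if site is None:
            placements[record.id] = None
            continue
        cols = tuple(
            record.ungapped_to_column(pos) for pos in range(site.start, site.end)
        )
        placements[record.id] = cols
        runs[cols] += 1
    if not runs:
        raise PrimerSiteNotFoundError(
            f"primer site not found: no record carries an acceptable "
            f"{primer.name} site under {params}"
        )
    modal, support = min(runs.items(), key=lambda kv: (-kv[1], kv[0][0]))
    off_modal = tuple(
        rid for rid, cols in placements.items() if cols is not None and cols != modal
    )
    no_site = tuple(rid for rid, cols in placements.items() if cols is None)
    return PrimerSiteLocation(modal, support, off_modal, no_site)


def conservation_profile(
    refset: ReferenceSet,
    primer: Primer,
    columns: Sequence[int],
    taxon_label: str = "",
    params: MatchParams = MatchParams(),
) -> ConservationProfile:
    """Per-position conservation of `primer` over records at `columns`.

    pct = round(100 * matching / non-gap total), half-up to an integer;
    positions where every record is gapped report None.
    """
    if len(columns) != len(primer):
        raise ValueError("need one alignment column per primer position")
    if not len(refset):
        raise ValueError("empty reference set")
    pcts: list[Optional[int]] = []
    counts: list[tuple[int, int]] = []
    for base, col in zip(primer.seq, columns):
        total = matching = 0
        for record in refset:
            residue = record.aligned_seq[col]
            if residue == "-":
                continue
            total += 1
            if iupac_match(base, residue, params.template_n_policy):
                matching += 1
        counts.append((matching, total))
        pcts.append(_round_half_up(100 * matching / total) if total else None)
    return ConservationProfile(
        primer, taxon_label, len(refset), tuple(pcts), tuple(counts)
    )


def _minimal_iupac(bases: set[str]) -> str:
    """Smallest-expansion IUPAC code covering all of `bases`."""
    need = set()
    for b in bases:
        need |= IUPAC[b]
    candidates = [c for c, s in IUPAC.items() if need <= s]
    return min(candidates, key=lambda c: (len(IUPAC[c]), c))


def consensus_row(
    refset: ReferenceSet,
    primer: Primer,
    columns: Sequence[int],
    taxon_label: str = "",
    majority_threshold: float = 0.5,
) -> ConsensusRow:
    """Dot-notation consensus of the group at the primer-site columns.

    Per position: the unique most frequent non-gap residue whose frequency
    reaches `majority_threshold`; on a tie at the top (or no majority), the
    minimal IUPAC code covering every residue with frequency >= 0.25.  The
    letter is rendered as '.' when it IUPAC-matches the primer base.
    """
    if len(columns) != len(primer):
        raise ValueError("need one alignment column per primer position")
    if not len(refset):
        raise ValueError("empty reference set")
    out = []
    for base, col in zip(primer.seq, columns):
        residues = Counter(
            record.aligned_seq[col]
            for record in refset
            if record.aligned_seq[col] != "-"
        )
        if not residues:
            out.append("-")
            continue
        total = sum(residues.values())
        top_count = max(residues.values())
        top = [b for b, c in residues.items() if c == top_count]
        if len(top) == 1 and top_count / total >= majority_threshold:
            letter = top[0]
        else:
            frequent = {b for b, c in residues.items() if c / total >= 0.25}
            letter = _minimal_iupac(frequent or set(residues))
        out.append("." if iupac_match(base, letter) else letter)
    return ConsensusRow(taxon_label, "".join(out), majority_threshold)


def format_specificity_table(
    primer: Primer,
    profiles: Sequence[ConservationProfile],
    consensus_rows: Sequence[ConsensusRow],
) -> tuple[str, str]:
    """Render the specificity table as (fixed-width text, TSV).

    Row 1: the primer bases; next rows: the in-group conservation percentages;
    then one dot-notation consensus row per out-group.  The two renderings
    hold identical cell values.
    """
    for p in profiles:
        if len(p.per_position_match_pct) != len(primer):
            raise ValueError(f"profile {p.taxon_label!r} length mismatch")
    for c in consensus_rows:
        if len(c.consensus) != len(primer):
            raise ValueError(f"consensus row {c.taxon_label!r} length mismatch")

    header = ["Position"] + [str(i) for i in range(1, len(primer) + 1)]
    rows: list[list[str]] = [[primer.name] + list(primer.seq)]
    for p in profiles:
        cells = ["" if pct is None else str(pct) for pct in p.per_position_match_pct]
        rows.append([p.taxon_label] + cells)
    for c in consensus_rows:
        rows.append([c.taxon_label] + list(c.consensus))

    tsv = "\n".join("\t".join(r) for r in [header] + rows) + "\n"

    widths = [
        max(len(row[i]) for row in [header] + rows) for i in range(len(header))
    ]
    text_lines = [
        "  ".join(cell.rjust(w) if i else cell.ljust(w)
                  for i, (cell, w) in enumerate(zip(row, widths)))
        for row in [header] + rows
    ]
    return "\n".join(text_lines) + "\n", tsv
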
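"""Amplicon prediction for primer pairs and the semi-nested tagged strategy.

A primer pair amplifies a template when the forward primer binds the plus
strand and the reverse primer's reverse complement binds downstream, with the
product length inside configured bounds.  The semi-nested strategy runs an
outer pre-amplification (NemF/18Sr2b in the shipped defaults) and re-amplifies
each outer product with an inner pair sharing the reverse primer
(NF1/18Sr2b); per-round match tolerances may differ, standing in for the two
annealing temperatures of the wet protocol.  Amplification is binary per
template — no efficiency or bias model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .primer_engine import BindingSite, MatchParams, Primer, revcomp, scan
from .reference_io import CANONICAL_RANKS, ReferenceRecord, ReferenceSet


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers with matching tolerances and product bounds."""

    forward: Primer
    reverse: Primer
    params: MatchParams = MatchParams()
    min_product: int = 100
    max_product: int = 2000

    def __post_init__(self) -> None:
        floor = len(self.forward) + len(self.reverse)
        if self.min_product < floor:
            raise ValueError(
                f"min_product {self.min_product} below combined primer length {floor}"
            )
        if self.min_product > self.max_product:
            raise ValueError("min_product exceeds max_product")


@dataclass(frozen=True)
class Amplicon:
    """A predicted product, 0-based half-open on the original template."""

    record_id: str
    start: int
    end: int
    seq: str
    fwd_site: BindingSite
    rev_site: BindingSite
    round_label: str = "single"
    length: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", self.end - self.start)
        if len(self.seq) != self.length:
            raise ValueError("amplicon sequence length differs from coordinates")


@dataclass(frozen=True)
class TagScheme:
    """454-style tag decoration: adapter + 10-nt MID on the forward side."""

    adapter_fwd: str
    mid: str
    adapter_rev: str

    def __post_init__(self) -> None:
        if len(self.mid) != 10:
            raise ValueError(f"MID must be 10 nt, got {len(self.mid)}")
        if not self.adapter_fwd or not self.adapter_rev:
            raise ValueError("adapters must be non-empty")

    @property
    def overhead(self) -> int:
        return len(self.adapter_fwd) + len(self.mid) + len(self.adapter_rev)


@dataclass(frozen=True)
class NestedStrategy:
    """Outer pre-amplification plus inner semi-nested pair.

    The inner pair must reuse the outer reverse primer — that is what makes
    the procedure semi-nested.
    """

    outer: PrimerPair
    inner: PrimerPair

    def __post_init__(self) -> None:
        if self.inner.reverse.seq != self.outer.reverse.seq:
            raise ValueError(
                "semi-nested strategy requires inner and outer reverse "
                "primers to be identical"
            )


@dataclass(frozen=True)
class CommunityProfile:
    """Taxon composition of the amplifiable templates at one rank."""

    rank: str
    proportions: dict[str, float]
    n_templates: int
    n_amplifiable: int
    amplifiable_fraction_by_taxon: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_amplifiable > 0:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions sum to {total}, expected 1")


def find_amplicons(template: ReferenceRecord, pair: PrimerPair) -> list[Amplicon]:
    """Every in-bounds (forward, reverse) product on the plus strand.

    The product spans the forward site's start through the reverse site's end,
    inclusive of both primer footprints.
    """
    seq = template.ungapped_seq
    fwd_sites = scan(seq, pair.forward, "plus", pair.params, template.id)
    rev_sites = scan(seq, pair.reverse, "minus", pair.params, template.id)
    amplicons = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.start < f.end:
                continue
            length = r.end - f.start
            if pair.min_product <= length <= pair.max_product:
                amplicons.append(
                    Amplicon(
                        record_id=template.id,
                        start=f.start,
                        end=r.end,
                        seq=seq[f.start:r.end],
                        fwd_site=f,
                        rev_site=r,
                    )
                )
    amplicons.sort(key=lambda a: (a.start, a.end))
    return amplicons


def semi_nested(
    template: ReferenceRecord,
    outer: PrimerPair,
    inner: PrimerPair,
) -> list[Amplicon]:
    """Nested products of the two-round strategy, on original coordinates.

    Round 1 amplifies with the outer pair; each round-1 product is the round-2
    template for the inner pair.  Every returned amplicon lies inside its
    parent outer product and carries ``round_label="nested"``.
    """
    NestedStrategy(outer, inner)  # validates shared reverse primer
    nested: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()
    for parent in find_amplicons(template, outer):
        sub = ReferenceRecord(template.id, template.lineage, parent.seq)
        for amp in find_amplicons(sub, inner):
            start, end = parent.start + amp.start, parent.start + amp.end
            if (start, end) in seen:
                continue
            seen.add((start, end))
            nested.append(
                Amplicon(
                    record_id=template.id,
                    start=start,
                    end=end,
                    seq=amp.seq,
                    fwd_site=amp.fwd_site,
                    rev_site=amp.rev_site,
                    round_label="nested",
                )
            )
    nested.sort(key=lambda a: (a.start, a.end))
    return nested


def tag_amplicon(amplicon: Amplicon, scheme: TagScheme) -> tuple[str, int]:
    """Tagged read-strand sequence and its length.

    The forward tag (adapter + MID) is prepended as printed; the reverse
    adapter enters the product on the opposite strand, so its reverse
    complement is appended on the plus strand.
    """
    tagged = scheme.adapter_fwd + scheme.mid + amplicon.seq + revcomp(scheme.adapter_rev)
    return tagged, len(tagged)


def taxon_amplification_summary(
    refset: ReferenceSet,
    strategy: NestedStrategy,
    rank: str = "phylum",
    weights: Optional[dict[str, float]] = None,
) -> CommunityProfile:
    """Taxon composition of templates the nested strategy amplifies.

    A record is amplifiable iff `semi_nested` yields at least one product.
    Proportions count templates (optionally abundance-weighted), never
    products, so multi-product templates are not double-counted.  Also reports
    the amplifiable fraction within each taxon group.
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if not len(refset):
        raise ValueError("empty reference set")
    group_total: dict[str, float] = {}
    group_amplifiable: dict[str, float] = {}
    group_sizes: dict[str, int] = {}
    group_amp_count: dict[str, int] = {}
    for record in refset:
        label = record.lineage.label(rank) or "Unclassified"
        w = 1.0 if weights is None else weights.get(record.id, 0.0)
        group_total[label] = group_total.get(label, 0.0) + w
        group_sizes[label] = group_sizes.get(label, 0) + 1
        if semi_nested(record, strategy.outer, strategy.inner):
            group_amplifiable[label] = group_amplifiable.get(label, 0.0) + w
            group_amp_count[label] = group_amp_count.get(label, 0) + 1
    total_amp = sum(group_amplifiable.values())
    proportions = (
        {k: v / total_amp for k, v in sorted(group_amplifiable.items())}
        if total_amp > 0
        else {}
    )
    fractions = {
        k: group_amp_count.get(k, 0) / n for k, n in sorted(group_sizes.items())
    }
    return CommunityProfile(
        rank=rank,
        proportions=proportions,
        n_templates=len(refset),
        n_amplifiable=sum(group_amp_count.values()),
        amplifiable_fraction_by_taxon=fractions,
    )


def with_params(pair: PrimerPair, params: MatchParams) -> PrimerPair:
    """The same pair under different matching tolerances."""
    return replace(pair, params=params)
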
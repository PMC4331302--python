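"""IUPAC-aware primer-template matching with 3'-terminal mismatch scoring.

The matching model is the one used throughout in-silico PCR tools: a primer
base matches a template base when their IUPAC expansion sets intersect, and a
placement is accepted when its total mismatch count and its mismatch count in
a short 3'-terminal window both fall under the configured tolerances.  The
3'-terminal window is the specificity mechanism: a mismatch at or near the
primer's 3' end blocks polymerase extension, so a strict window (0 mismatches
in the last 3 nt by default) models taxon-selective amplification without a
thermodynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

TemplateNPolicy = Literal["permissive-match", "count-as-mismatch"]


@dataclass(frozen=True)
class Primer:
    """A named primer, sequence written 5'->3' in IUPAC letters."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("U", "T")
        object.__setattr__(self, "seq", seq)
        if len(seq) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")
        bad = set(seq) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name!r}: non-IUPAC letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MatchParams:
    """Acceptance tolerances for a primer placement.

    `three_prime_window` counts nucleotides from the primer's 3' end; a strict
    `max_three_prime_mismatches = 0` with a small body tolerance is the default
    proxy for the annealing stringency of a real PCR round.
    `template_n_policy` governs template N only: under "permissive-match" an N
    residue matches any primer base, under "count-as-mismatch" it matches none.
    """

    max_mismatches: int = 2
    three_prime_window: int = 3
    max_three_prime_mismatches: int = 0
    template_n_policy: TemplateNPolicy = "permissive-match"

    def __post_init__(self) -> None:
        if self.max_three_prime_mismatches > self.max_mismatches:
            raise ValueError("max_three_prime_mismatches exceeds max_mismatches")
        if self.three_prime_window < 0 or self.max_mismatches < 0:
            raise ValueError("tolerances must be non-negative")


@dataclass(frozen=True)
class BindingSite:
    """One scored placement of a primer on an ungapped template.

    Coordinates are 0-based half-open on the template; `mismatch_vector` is in
    the primer's own 5'->3' order regardless of strand.
    """

    record_id: str
    strand: Literal["plus", "minus"]
    start: int
    end: int
    mismatch_vector: tuple[bool, ...]
    n_mismatches: int = field(init=False)
    n_three_prime_mismatches: int = field(init=False)
    three_prime_window: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_mismatches", sum(self.mismatch_vector))
        w = self.three_prime_window
        tail = self.mismatch_vector[len(self.mismatch_vector) - w:] if w else ()
        object.__setattr__(self, "n_three_prime_mismatches", sum(tail))


def iupac_match(
    primer_base: str,
    template_base: str,
    policy: TemplateNPolicy = "permissive-match",
) -> bool:
    """True when the two bases' IUPAC expansion sets intersect.

    A template ``N`` is resolved by `policy` instead of set intersection.
    """
    try:
        p = IUPAC[primer_base]
    except KeyError:
        raise ValueError(f"invalid IUPAC letter {primer_base!r}") from None
    if template_base == "N":
        return policy == "permissive-match"
    try:
        t = IUPAC[template_base]
    except KeyError:
        raise ValueError(f"invalid IUPAC letter {template_base!r}") from None
    return bool(p & t)


def revcomp(seq: str) -> str:
    """Reverse complement with full IUPAC ambiguity mapping."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper().replace("U", "T")))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r}") from None


def count_mismatch_positions(
    primer: Primer,
    site_residues: str,
    policy: TemplateNPolicy = "permissive-match",
) -> tuple[bool, ...]:
    """Per-position mismatch flags, both sequences 5'->3' of the primer."""
    if len(site_residues) != len(primer):
        raise ValueError(
            f"site length {len(site_residues)} != primer length {len(primer)}"
        )
    return tuple(
        not iupac_match(p, t, policy) for p, t in zip(primer.seq, site_residues)
    )


def scan(
    template: str,
    primer: Primer,
    strand: Literal["plus", "minus"] = "plus",
    params: MatchParams = MatchParams(),
    record_id: str = "",
) -> list[BindingSite]:
    """All acceptable placements of `primer` on an ungapped `template`.

    On the plus strand the primer is slid 5'->3' over the template; on the
    minus strand its reverse complement is matched and the mismatch vector is
    reported back in primer orientation.  Sites are filtered by `params` and
    sorted by (n_mismatches, start).
    """
    template = template.upper().replace("U", "T")
    k = len(primer)
    query = primer.seq if strand == "plus" else revcomp(primer.seq)
    sites: list[BindingSite] = []
    for start in range(len(template) - k + 1):
        window = template[start:start + k]
        mm = [
            not iupac_match(q, t, params.template_n_policy)
            for q, t in zip(query, window)
        ]
        if strand == "minus":
            mm.reverse()  # back to primer 5'->3'
        site = BindingSite(
            record_id=record_id,
            strand=strand,
            start=start,
            end=start + k,
            mismatch_vector=tuple(mm),
            three_prime_window=params.three_prime_window,
        )
        if (
            site.n_mismatches <= params.max_mismatches
            and site.n_three_prime_mismatches <= params.max_three_prime_mismatches
        ):
            sites.append(site)
    sites.sort(key=lambda s: (s.n_mismatches, s.start))
    return sites


def best_site(
    template: str,
    primer: Primer,
    strand: Literal["plus", "minus"] = "plus",
    params: MatchParams = MatchParams(),
    record_id: str = "",
) -> BindingSite | None:
    """Lowest-mismatch (ties: leftmost) acceptable site, or None."""
    sites = scan(template, primer, strand, params, record_id)
    return sites[0] if sites else None
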
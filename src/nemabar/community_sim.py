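"""Synthetic SSU-like reference sets and mock communities with known truth.

Every template follows one layout, mirroring the marker region the nested
strategy targets: upstream flank, NemF site, spacer, NF1 site, insert,
reverse-complemented 18Sr2b site, downstream flank.  Taxon signatures place
exact substitutions at chosen primer positions (e.g. the fungal/plant
3'-terminal NemF mismatch), while background substitutions add neutral
divergence strictly outside the primer sites, so the specificity mechanism
stays separable from noise.  All outputs are bit-reproducible under a fixed
seed.

The generator emulates primer-site signatures and abundance structure only;
it does not model real SSU secondary structure, indels, chimeras, or
sequencer-specific (homopolymer) errors.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .defaults import default_primers
from .insilico_pcr import Amplicon, CommunityProfile, NestedStrategy, semi_nested
from .primer_engine import Primer, revcomp
from .reference_io import (
    CANONICAL_RANKS,
    ReferenceRecord,
    ReferenceSet,
    TaxonomyLineage,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class TaxonSignature:
    """Exact substitutions a taxon carries at a primer site.

    `substitutions` maps 1-based primer positions (5'->3' of the primer) to
    the replacement base; each replacement must differ from the primer base.
    """

    taxon_label: str
    primer_name: str
    substitutions: dict[int, str]


@dataclass(frozen=True)
class TaxonSpec:
    """One simulated taxon: size, abundance weight, primer-site signatures."""

    label: str
    n_records: int
    signatures: tuple[TaxonSignature, ...] = ()
    abundance: float = 1.0
    lineage: Optional[str] = None  # semicolon-delimited override

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Reference-set generator configuration.

    Defaults put the NF1->18Sr2b product at 350 nt, so the tagged product is
    410 nt — the scale of the sequenced amplicon.
    """

    taxa: tuple[TaxonSpec, ...]
    background_sub_rate: float = 0.0
    insert_length: int = 305
    flank_length: int = 100
    spacer_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_sub_rate <= 1:
            raise ValueError("background_sub_rate must be in [0, 1]")
        if not self.taxa:
            raise ValueError("at least one taxon required")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        taxa = []
        for t in d["taxa"]:
            sigs = tuple(
                TaxonSignature(
                    taxon_label=t["label"],
                    primer_name=s["primer"],
                    substitutions={int(k): str(v).upper() for k, v in s["substitutions"].items()},
                )
                for s in t.get("signatures", [])
            )
            taxa.append(
                TaxonSpec(
                    label=t["label"],
                    n_records=int(t["n_records"]),
                    signatures=sigs,
                    abundance=float(t.get("abundance", 1.0)),
                    lineage=t.get("lineage"),
                )
            )
        return cls(
            taxa=tuple(taxa),
            background_sub_rate=float(d.get("background_sub_rate", 0.0)),
            insert_length=int(d.get("insert_length", 305)),
            flank_length=int(d.get("flank_length", 100)),
            spacer_length=int(d.get("spacer_length", 30)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class MockCommunity:
    """Synthetic references plus per-record truth labels and abundances."""

    refset: ReferenceSet
    truth: dict[str, str]
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        ids = {r.id for r in self.refset}
        if set(self.truth) != ids or set(self.abundances) != ids:
            raise ValueError("truth/abundances must cover exactly the records")
        if any(w < 0 for w in self.abundances.values()):
            raise ValueError("abundances must be >= 0")


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _site_intervals(config: SimConfig, primers: dict[str, Primer]) -> dict[str, tuple[int, int, bool]]:
    """(start, end, is_reverse_complemented) of each primer site on the template."""
    f = config.flank_length
    nemf, nf1, r2b = primers["NemF"], primers["NF1"], primers["18Sr2b"]
    nemf_start = f
    nf1_start = nemf_start + len(nemf) + config.spacer_length
    r2b_start = nf1_start + len(nf1) + config.insert_length
    return {
        "NemF": (nemf_start, nemf_start + len(nemf), False),
        "NF1": (nf1_start, nf1_start + len(nf1), False),
        "18Sr2b": (r2b_start, r2b_start + len(r2b), True),
    }


def generate_reference_set(config: SimConfig) -> MockCommunity:
    """Build the mock community the configuration describes.

    A shared base template carries exact sites for all three primers; each
    record applies its taxon's signatures exactly and then background
    substitutions outside every primer site.  Same-length outputs are marked
    as an (gap-free) alignment so the specificity profiler can consume them
    directly.
    """
    primers = default_primers()
    rng = random.Random(config.seed)
    sites = _site_intervals(config, primers)
    template = (
        _random_dna(rng, config.flank_length)
        + primers["NemF"].seq
        + _random_dna(rng, config.spacer_length)
        + primers["NF1"].seq
        + _random_dna(rng, config.insert_length)
        + revcomp(primers["18Sr2b"].seq)
        + _random_dna(rng, config.flank_length)
    )
    protected = [(s, e) for s, e, _ in sites.values()]

    records: list[ReferenceRecord] = []
    truth: dict[str, str] = {}
    abundances: dict[str, float] = {}
    for taxon in config.taxa:
        base = list(template)
        for sig in taxon.signatures:
            if sig.primer_name not in sites:
                raise ValueError(f"signature references unknown primer {sig.primer_name!r}")
            start, end, is_rc = sites[sig.primer_name]
            primer = primers[sig.primer_name]
            for pos1, repl in sig.substitutions.items():
                if not 1 <= pos1 <= len(primer):
                    raise ValueError(
                        f"position {pos1} outside primer {primer.name} "
                        f"(length {len(primer)})"
                    )
                if repl == primer.seq[pos1 - 1]:
                    raise ValueError(
                        f"replacement at {primer.name} position {pos1} equals "
                        f"the primer base {repl!r}"
                    )
                if is_rc:
                    base[end - pos1] = revcomp(repl)
                else:
                    base[start + pos1 - 1] = repl
        lineage = (
            TaxonomyLineage.from_labels(taxon.lineage.split(";"))
            if taxon.lineage
            else TaxonomyLineage((("kingdom", "Eukaryota"), ("phylum", taxon.label)))
        )
        for i in range(taxon.n_records):
            seq = list(base)
            if config.background_sub_rate > 0:
                for pos in range(len(seq)):
                    if any(s <= pos < e for s, e in protected):
                        continue
                    if rng.random() < config.background_sub_rate:
                        seq[pos] = rng.choice([b for b in _BASES if b != seq[pos]])
            rec_id = f"{taxon.label}_{i + 1:04d}"
            records.append(ReferenceRecord(rec_id, lineage, "".join(seq)))
            truth[rec_id] = taxon.label
            abundances[rec_id] = taxon.abundance / taxon.n_records
    refset = ReferenceSet(records, is_aligned=True)
    return MockCommunity(refset, truth, abundances)


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    seq: str
    truth_label: str
    source_record: str


def simulate_reads(
    community: MockCommunity,
    strategy: NestedStrategy,
    n_reads: int,
    per_base_error: float = 0.0,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Error-bearing reads from the nested amplicons of amplifiable records.

    Records are drawn with probability proportional to abundance among the
    amplifiable ones; each read is a full nested amplicon with independent
    per-base substitution errors.  Read ids carry no truth information.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = random.Random(seed)
    amplifiable: list[tuple[ReferenceRecord, list[Amplicon]]] = []
    for record in community.refset:
        amps = semi_nested(record, strategy.outer, strategy.inner)
        if amps and community.abundances[record.id] > 0:
            amplifiable.append((record, amps))
    if n_reads > 0 and not amplifiable:
        raise ValueError("no amplifiable record with positive abundance")
    weights = [community.abundances[r.id] for r, _ in amplifiable]
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        record, amps = rng.choices(amplifiable, weights=weights, k=1)[0]
        amp = amps[0] if len(amps) == 1 else rng.choice(amps)
        seq = list(amp.seq)
        if per_base_error > 0:
            for pos in range(len(seq)):
                if rng.random() < per_base_error:
                    seq[pos] = rng.choice([b for b in _BASES if b != seq[pos]])
        reads.append(
            SimulatedRead(
                read_id=f"read_{i + 1:06d}",
                seq="".join(seq),
                truth_label=community.truth[record.id],
                source_record=record.id,
            )
        )
    return reads


def write_reads(reads: Sequence[SimulatedRead], fasta_path: str | Path, truth_path: str | Path) -> None:
    """Read FASTA plus the read_id TAB truth-label sidecar."""
    with open(fasta_path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.seq}\n")
    with open(truth_path, "w") as fh:
        for r in reads:
            fh.write(f"{r.read_id}\t{r.truth_label}\n")


def truth_composition(
    community: MockCommunity,
    rank: str = "phylum",
    strategy: Optional[NestedStrategy] = None,
) -> CommunityProfile:
    """Abundance-weighted expected proportions, optionally among amplifiable records.

    With a strategy, a record contributes only if the nested procedure yields
    at least one product — the expectation the read simulator converges to.
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    group: dict[str, float] = {}
    n_amp = 0
    for record in community.refset:
        if strategy is not None and not semi_nested(
            record, strategy.outer, strategy.inner
        ):
            continue
        n_amp += 1
        label = record.lineage.label(rank) or "Unclassified"
        group[label] = group.get(label, 0.0) + community.abundances[record.id]
    total = sum(group.values())
    proportions = (
        {k: v / total for k, v in sorted(group.items())} if total > 0 else {}
    )
    return CommunityProfile(
        rank=rank,
        proportions=proportions,
        n_templates=len(community.refset),
        n_amplifiable=n_amp,
    )
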
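"""Packaged defaults: study primers, 454 adapters, multiplex tags.

The primer TSV ships the three study primers (NemF, NF1, 18Sr2b).  The two
Lib-L adapters are the published tagged-primer prefixes.  The 22 ten-nt MIDs
are synthetic stand-ins chosen by this package (pairwise Hamming distance
>= 3, no homopolymer runs over 2 nt); the study's actual commercial MID
sequences are unpublished.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .insilico_pcr import MatchParams, NestedStrategy, PrimerPair, TagScheme
from .primer_engine import Primer

ADAPTER_FWD = "CGTATCGCCTCCCTCGCGCCATCAG"
ADAPTER_REV = "CTATGCGCCTTGCCAGCCCGCTCAG"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("nemabar").joinpath("data", name)))


def load_primer_tsv(path: str | Path) -> dict[str, Primer]:
    """Read a name TAB sequence primer file into a dict."""
    primers: dict[str, Primer] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected name<TAB>sequence")
        name, seq = fields[0].strip(), fields[1].strip()
        if name in primers:
            raise ValueError(f"{path}:{lineno}: duplicate primer name {name!r}")
        primers[name] = Primer(name, seq)
    return primers


def default_primers() -> dict[str, Primer]:
    """The shipped study primers: NemF, NF1, 18Sr2b."""
    return load_primer_tsv(_data_path("primers.tsv"))


def default_mids() -> dict[str, str]:
    """The shipped 22 synthetic 10-nt multiplex identifier tags."""
    mids: dict[str, str] = {}
    for line in _data_path("mids.tsv").read_text().splitlines():
        if line.strip():
            name, seq = line.split("\t")
            mids[name] = seq
    return mids


def default_tag_scheme(mid_name: str = "MID01") -> TagScheme:
    """Published adapters with one of the shipped MIDs."""
    return TagScheme(ADAPTER_FWD, default_mids()[mid_name], ADAPTER_REV)


def default_strategy(
    outer_params: MatchParams | None = None,
    inner_params: MatchParams | None = None,
    min_product: int = 100,
    max_product: int = 2000,
) -> NestedStrategy:
    """NemF/18Sr2b outer pre-amplification, NF1/18Sr2b inner pair."""
    primers = default_primers()
    outer = PrimerPair(
        primers["NemF"],
        primers["18Sr2b"],
        outer_params or MatchParams(),
        min_product,
        max_product,
    )
    inner = PrimerPair(
        primers["NF1"],
        primers["18Sr2b"],
        inner_params or MatchParams(),
        min_product,
        max_product,
    )
    return NestedStrategy(outer, inner)
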
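import pytest

from nemabar import default_primers, default_strategy
from nemabar.community_sim import (
    SimConfig,
    TaxonSignature,
    TaxonSpec,
    generate_reference_set,
)

FUNGAL_SIGNATURE = {5: "G", 14: "C", 19: "G"}


@pytest.fixture(scope="session")
def primers():
    return default_primers()


@pytest.fixture(scope="session")
def strategy():
    return default_strategy()


@pytest.fixture(scope="session")
def table2_community():
    """100 nematodes (81 exact + 19 with A->G at NemF position 5), 20 fungi and
    10 plants carrying the 3'-blocking G/C/G signature, 10 clean tardigrades."""
    cfg = SimConfig(
        taxa=(
            TaxonSpec("Nematoda", 81),
            TaxonSpec(
                "NematodaVar", 19,
                (TaxonSignature("NematodaVar", "NemF", {5: "G"}),),
                lineage="Eukaryota;Nematoda",
            ),
            TaxonSpec("Fungi", 20, (TaxonSignature("Fungi", "NemF", FUNGAL_SIGNATURE),)),
            TaxonSpec("Plantae", 10, (TaxonSignature("Plantae", "NemF", FUNGAL_SIGNATURE),)),
            TaxonSpec("Tardigrada", 10),
        ),
        background_sub_rate=0.0,
        seed=11,
    )
    return generate_reference_set(cfg)


@pytest.fixture(scope="session")
def four_taxon_community():
    """Abundance-structured mock community with one 3'-blocked taxon."""
    cfg = SimConfig(
        taxa=(
            TaxonSpec("Nematoda", 30, abundance=6.0),
            TaxonSpec("Tardigrada", 10, abundance=1.0),
            TaxonSpec("Annelida", 10, abundance=1.0),
            TaxonSpec("Fungi", 10, (TaxonSignature("Fungi", "NemF", FUNGAL_SIGNATURE),),
                      abundance=2.0),
        ),
        background_sub_rate=0.005,
        seed=7,
    )
    return generate_reference_set(cfg)
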
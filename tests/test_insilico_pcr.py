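"""Amplicon prediction, semi-nested exclusion and tag arithmetic."""

import itertools
import random

import pytest

from nemabar.defaults import ADAPTER_FWD, ADAPTER_REV, default_tag_scheme
from nemabar.insilico_pcr import (
    Amplicon,
    MatchParams,
    NestedStrategy,
    PrimerPair,
    TagScheme,
    find_amplicons,
    semi_nested,
    tag_amplicon,
    taxon_amplification_summary,
)
from nemabar.primer_engine import Primer, revcomp
from nemabar.reference_io import ReferenceRecord, ReferenceSet, TaxonomyLineage

NEMF = Primer("NemF", "GGGGAAGTATGGTTGCAAA")
NF1 = Primer("NF1", "GGTGGTGCATGGCCGTTCTTAGTT")
R2B = Primer("18Sr2b", "TACAAAGGGCAGGGACGTAAT")
FUNGAL_NEMF = "GGGGGAGTATGGTCGCAAG"  # 3'-terminal mismatch at position 19

LIN = TaxonomyLineage.from_labels(["Eukaryota", "Testia"])


def _record(seq, rec_id="t", lineage=LIN):
    return ReferenceRecord(rec_id, lineage, seq)


def _rand(rng, n):
    return "".join(rng.choices("ACGT", k=n))


def _template(rng, nemf_site=NEMF.seq, spacer=30, insert=305, flank=100):
    """flank + NemF + spacer + NF1 + insert + rc(18Sr2b) + flank."""
    return (_rand(rng, flank) + nemf_site + _rand(rng, spacer) + NF1.seq
            + _rand(rng, insert) + revcomp(R2B.seq) + _rand(rng, flank))


@pytest.fixture()
def rng():
    return random.Random(42)


def _pair(fwd, rev, params=None, lo=100, hi=2000):
    return PrimerPair(fwd, rev, params or MatchParams(), lo, hi)


class TestFindAmplicons:
    def test_constructed_product_coordinates(self, rng):
        template = (_rand(rng, 50) + NEMF.seq + _rand(rng, 360)
                    + revcomp(R2B.seq) + _rand(rng, 50))
        amps = find_amplicons(_record(template), _pair(NEMF, R2B))
        assert len(amps) == 1
        amp = amps[0]
        assert (amp.start, amp.end, amp.length) == (50, 450, 400)
        assert amp.seq == template[50:450]

    def test_three_prime_blocked_forward_site_gives_nothing(self, rng):
        template = (_rand(rng, 50) + FUNGAL_NEMF + _rand(rng, 360)
                    + revcomp(R2B.seq) + _rand(rng, 50))
        params = MatchParams(max_mismatches=3, three_prime_window=3,
                             max_three_prime_mismatches=0)
        assert find_amplicons(_record(template), _pair(NEMF, R2B, params)) == []

    def test_two_forward_sites_both_reported(self, rng):
        template = (NEMF.seq + _rand(rng, 100) + NEMF.seq + _rand(rng, 200)
                    + revcomp(R2B.seq))
        amps = find_amplicons(_record(template), _pair(NEMF, R2B))
        assert len(amps) == 2
        assert sorted(a.start for a in amps) == [0, 119]

    def test_product_length_bounds_respected(self, rng):
        template = NEMF.seq + _rand(rng, 50) + revcomp(R2B.seq)
        short = find_amplicons(_record(template), _pair(NEMF, R2B, lo=100, hi=2000))
        assert short == []
        ok = find_amplicons(_record(template), _pair(NEMF, R2B, lo=40, hi=2000))
        assert len(ok) == 1 and ok[0].length == 90

    def test_exhaustive_pairing_oracle(self, rng):
        """All (i, j) placements on short templates, checked independently."""
        from nemabar.primer_engine import scan
        for _ in range(20):
            template = _rand(rng, 400)
            # implant 1-3 sites of each primer at random non-overlapping spots
            for seq in rng.sample(
                [NEMF.seq, revcomp(R2B.seq), NEMF.seq], k=rng.randint(1, 3)
            ):
                pos = rng.randrange(0, len(template) - len(seq))
                template = template[:pos] + seq + template[pos + len(seq):]
            pair = _pair(NEMF, R2B, MatchParams(1, 3, 0), lo=50, hi=400)
            got = {(a.start, a.end) for a in find_amplicons(_record(template), pair)}
            fwd = scan(template, NEMF, "plus", pair.params)
            rev = scan(template, R2B, "minus", pair.params)
            expected = {
                (f.start, r.end)
                for f, r in itertools.product(fwd, rev)
                if r.start >= f.end and 50 <= r.end - f.start <= 400
            }
            assert got == expected

    def test_min_product_floor_validated(self):
        with pytest.raises(ValueError, match="min_product"):
            PrimerPair(NEMF, R2B, MatchParams(), 10, 2000)


class TestSemiNested:
    def test_nested_product_bounded_by_inner_primers(self, rng):
        template = _template(rng)
        outer = _pair(NEMF, R2B)
        inner = _pair(NF1, R2B)
        nested = semi_nested(_record(template), outer, inner)
        assert len(nested) == 1
        amp = nested[0]
        assert amp.round_label == "nested"
        assert amp.length == len(NF1) + 305 + len(R2B) == 350
        assert template[amp.start:amp.start + len(NF1)] == NF1.seq
        # containment in the outer product
        outer_amp = find_amplicons(_record(template), outer)[0]
        assert outer_amp.start <= amp.start and amp.end <= outer_amp.end

    def test_blocked_outer_site_blocks_nesting_but_not_inner_alone(self, rng):
        template = _template(rng, nemf_site=FUNGAL_NEMF)
        outer = _pair(NEMF, R2B, MatchParams(3, 3, 0))
        inner = _pair(NF1, R2B, MatchParams(3, 3, 0))
        assert semi_nested(_record(template), outer, inner) == []
        assert len(find_amplicons(_record(template), inner)) >= 1

    def test_missing_outer_reverse_site_gives_empty(self, rng):
        template = _rand(rng, 50) + NEMF.seq + _rand(rng, 30) + NF1.seq + _rand(rng, 400)
        assert semi_nested(_record(template), _pair(NEMF, R2B), _pair(NF1, R2B)) == []

    def test_differing_reverse_primers_rejected(self, rng):
        other_rev = Primer("other", "ACGTACGTACGTACG")
        with pytest.raises(ValueError, match="reverse"):
            semi_nested(_record(_template(rng)), _pair(NEMF, R2B), _pair(NF1, other_rev))

    def test_relaxing_params_never_removes_nested_products(self, rng):
        for _ in range(10):
            template = _template(rng, insert=rng.randrange(200, 400))
            strict = {
                (a.start, a.end) for a in semi_nested(
                    _record(template),
                    _pair(NEMF, R2B, MatchParams(0, 3, 0)),
                    _pair(NF1, R2B, MatchParams(0, 3, 0)))
            }
            loose = {
                (a.start, a.end) for a in semi_nested(
                    _record(template),
                    _pair(NEMF, R2B, MatchParams(3, 3, 1)),
                    _pair(NF1, R2B, MatchParams(3, 3, 1)))
            }
            assert strict <= loose


class TestTagging:
    def _amp(self, length=350):
        seq = "A" * length
        from nemabar.primer_engine import BindingSite
        site = BindingSite("t", "plus", 0, 10, (False,) * 10)
        return Amplicon("t", 0, length, seq, site, site, "nested")

    def test_published_scheme_adds_exactly_60(self):
        scheme = default_tag_scheme()
        for length in (300, 350, 360, 420):
            tagged, n = tag_amplicon(self._amp(length), scheme)
            assert n - length == 60
            assert tagged.startswith(ADAPTER_FWD)
            assert tagged.endswith(revcomp(ADAPTER_REV))

    def test_360_insert_gives_420(self):
        _, n = tag_amplicon(self._amp(360), default_tag_scheme())
        assert n == 420

    def test_mid_embedded_between_adapter_and_insert(self):
        scheme = TagScheme(ADAPTER_FWD, "ACGTACGTAC", ADAPTER_REV)
        tagged, _ = tag_amplicon(self._amp(50), scheme)
        assert tagged[len(ADAPTER_FWD):len(ADAPTER_FWD) + 10] == "ACGTACGTAC"

    def test_bad_mid_rejected(self):
        with pytest.raises(ValueError, match="10 nt"):
            TagScheme(ADAPTER_FWD, "", ADAPTER_REV)


class TestCommunitySummary:
    def test_blocked_taxa_excluded_from_composition(self, rng):
        lin = TaxonomyLineage.from_labels
        records = []
        for i in range(6):
            records.append(ReferenceRecord(
                f"nem{i}", lin(["Eukaryota", "Nematoda"]), _template(rng)))
        for i in range(2):
            records.append(ReferenceRecord(
                f"fun{i}", lin(["Eukaryota", "Fungi"]),
                _template(rng, nemf_site=FUNGAL_NEMF)))
        records.append(ReferenceRecord(
            "tar0", lin(["Eukaryota", "Tardigrada"]), _template(rng)))
        strategy = NestedStrategy(_pair(NEMF, R2B), _pair(NF1, R2B))
        profile = taxon_amplification_summary(
            ReferenceSet(records), strategy, "phylum")
        assert profile.n_amplifiable == 7
        assert profile.proportions == pytest.approx(
            {"Nematoda": 6 / 7, "Tardigrada": 1 / 7})
        assert profile.amplifiable_fraction_by_taxon["Fungi"] == 0.0
        assert sum(profile.proportions.values()) == pytest.approx(1.0)

    def test_uniform_set_single_label(self, rng):
        records = [ReferenceRecord(f"n{i}", LIN, _template(rng)) for i in range(3)]
        strategy = NestedStrategy(_pair(NEMF, R2B), _pair(NF1, R2B))
        profile = taxon_amplification_summary(ReferenceSet(records), strategy, "phylum")
        assert profile.proportions == {"Testia": 1.0}

    def test_no_amplifiable_records_is_not_an_error(self, rng):
        records = [ReferenceRecord("x", LIN, _rand(rng, 500))]
        strategy = NestedStrategy(_pair(NEMF, R2B), _pair(NF1, R2B))
        profile = taxon_amplification_summary(ReferenceSet(records), strategy, "phylum")
        assert profile.n_amplifiable == 0 and profile.proportions == {}
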
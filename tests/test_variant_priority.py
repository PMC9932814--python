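import itertools

import pytest

from riqtl.core_io import ValidationError
from riqtl.variant_priority import (
    GeneEvidence,
    VariantRecord,
    classify,
    classify_functional,
    classify_regulatory,
    ecr_overlap,
    rank_candidates,
    read_gene_evidence_tsv,
    read_variants_tsv,
    side_chain_group,
    write_variants_tsv,
)


def make_variant(**kw):
    base = dict(
        chrom="9",
        pos=46_000_100,
        ref="A",
        alt="G",
        vclass="SNP",
        consequences=frozenset({"intronic"}),
        gene="GeneA",
        in_ecr=False,
    )
    base.update(kw)
    return VariantRecord(**base)


class TestSideChainGroups:
    @pytest.mark.parametrize(
        "aa, group",
        [
            ("I", "nonpolar"),
            ("T", "polar"),
            ("D", "negative"),
            ("K", "positive"),
            ("G", "special"),
            ("w", "nonpolar"),  # case-insensitive
        ],
    )
    def test_table(self, aa, group):
        assert side_chain_group(aa) == group

    def test_unknown_code_rejected(self):
        with pytest.raises(ValidationError):
            side_chain_group("X")


class TestFunctionalRules:
    def test_missense_in_domain_fires_f2(self):
        # the I->T change in an actin-binding domain: group change AND domain
        v = make_variant(
            consequences=frozenset({"missense"}), aa_ref="I", aa_alt="T", in_domain=True
        )
        call = classify_functional(v)
        assert call.functional_hp and call.fired_rules == ("F2",)

    def test_splice_region_indel_fires_f4(self):
        # 3-nt in-frame INDEL in the polypyrimidine tract near a donor site
        v = make_variant(
            ref="A",
            alt="ATTT",
            vclass="INDEL",
            consequences=frozenset({"splice_region", "intronic"}),
        )
        assert classify_functional(v).fired_rules == ("F4",)

    def test_conservative_missense_outside_domain_not_hp(self):
        v = make_variant(
            consequences=frozenset({"missense"}), aa_ref="L", aa_alt="I", in_domain=False
        )
        assert not classify_functional(v).functional_hp

    def test_synonymous_not_hp(self):
        v = make_variant(consequences=frozenset({"synonymous"}))
        assert not classify_functional(v).functional_hp

    def test_missense_without_aa_fields_rejected(self):
        with pytest.raises(ValidationError):
            make_variant(consequences=frozenset({"missense"}))


class TestRegulatoryRules:
    def test_utr3_snp_in_ecr_fires_r1(self):
        v = make_variant(consequences=frozenset({"utr3"}), in_ecr=True)
        call = classify_regulatory(v)
        assert call.regulatory_hp and call.fired_rules == ("R1",)

    def test_intronic_sv_in_ecr_fires_r2(self):
        v = make_variant(
            alt="<DEL>", vclass="SV", consequences=frozenset({"intronic"}), in_ecr=True
        )
        assert classify_regulatory(v).fired_rules == ("R2",)

    def test_deep_intronic_snp_not_hp(self):
        v = make_variant(
            consequences=frozenset({"intronic"}), tss_distance=40_000.0, in_ecr=False
        )
        assert not classify_regulatory(v).regulatory_hp

    def test_mirna_site_change_fires_r3(self):
        v = make_variant(
            consequences=frozenset({"utr3"}), mirna_site_change=True, in_ecr=False
        )
        assert classify_regulatory(v).fired_rules == ("R3",)

    def test_missing_conservation_evidence_rejected(self):
        v = make_variant(consequences=frozenset({"utr5"}), in_ecr=None)
        with pytest.raises(ValidationError, match="conservation evidence"):
            classify_regulatory(v, conservation=None)

    def test_or_mode_accepts_location_alone(self):
        v = make_variant(consequences=frozenset({"utr5"}), in_ecr=False)
        assert not classify_regulatory(v, ecr_mode="and").regulatory_hp
        assert classify_regulatory(v, ecr_mode="or").regulatory_hp

    def test_variant_can_be_both_functional_and_regulatory(self):
        v = make_variant(
            consequences=frozenset({"missense", "splice_region", "utr3"}),
            aa_ref="I",
            aa_alt="T",
            mirna_site_change=True,
        )
        call = classify(v)
        assert call.functional_hp and call.regulatory_hp
        assert set(call.fired_rules) == {"F2", "F4", "R3"}


class TestEcrOverlap:
    tracks = {
        "human": [("9", 1000, 1200), ("9", 5000, 5100)],
        "rat": [("9", 1100, 1300)],
    }

    def test_two_species_overlap_true(self):
        assert ecr_overlap("9", 1150, self.tracks)

    def test_single_species_overlap_false(self):
        assert not ecr_overlap("9", 5050, self.tracks)

    def test_window_edge_arithmetic(self):
        # conserved interval ends at bp 1200 (0-based half-open): the last
        # conserved base is 1200 in 1-based coordinates.  A variant 51 bp
        # beyond it has window start 1201 -> no overlap; 50 bp beyond: overlap.
        one_species_each = {"human": [("9", 1000, 1200)], "rat": [("9", 1000, 1200)]}
        assert ecr_overlap("9", 1250, one_species_each)
        assert not ecr_overlap("9", 1251, one_species_each)

    def test_empty_tracks_false(self):
        assert not ecr_overlap("9", 100, {})

    def test_derived_flag_from_tracks(self):
        v = make_variant(pos=1150, consequences=frozenset({"utr3"}), in_ecr=None)
        assert classify_regulatory(v, conservation=self.tracks).regulatory_hp


class TestGoldenTruthTable:
    """Cross-product fixtures vs the independently hand-coded expectation."""

    def test_full_cross_product(self):
        from golden_rules import build_cases

        n_cases = 0
        for record, expected in build_cases():
            call = classify(record)
            assert set(call.fired_rules) == expected, record
            assert call.functional_hp == any(r.startswith("F") for r in expected)
            assert call.regulatory_hp == any(r.startswith("R") for r in expected)
            n_cases += 1
        assert n_cases >= 200


class TestRankCandidates:
    def test_three_criteria_gene_is_top(self):
        ranked = rank_candidates([GeneEvidence("g", 3, True, True)])
        assert ranked.top_candidates == ["g"]

    def test_two_criteria_gene_not_top(self):
        ranked = rank_candidates([GeneEvidence("g", 0, True, True)])
        assert ranked.top_candidates == []
        assert ranked.venn_counts["expressed+function"] == 1

    def test_duplicate_gene_rows_rejected(self):
        rows = [GeneEvidence("g", 1, True, True), GeneEvidence("g", 0, False, False)]
        with pytest.raises(ValidationError, match="duplicate"):
            rank_candidates(rows)

    def test_region_counts_match_enumeration_oracle(self):
        """339 genes with planted flags: counts equal brute-force tallies."""
        import numpy as np

        rng = np.random.default_rng(11)
        rows = [
            GeneEvidence(
                f"g{i:03d}",
                int(rng.integers(0, 4)),
                bool(rng.random() < 0.5),
                bool(rng.random() < 0.5),
            )
            for i in range(339)
        ]
        ranked = rank_candidates(rows)
        oracle: dict[tuple[bool, bool, bool], int] = {}
        for e in rows:
            key = (e.hp_variant_count >= 1, e.expressed, e.function_relevant)
            oracle[key] = oracle.get(key, 0) + 1
        assert sum(ranked.venn_counts.values()) == 339
        assert ranked.venn_counts["variants+expressed+function"] == oracle.get(
            (True, True, True), 0
        )
        assert ranked.venn_counts["none"] == oracle.get((False, False, False), 0)
        assert ranked.venn_counts["variants"] == oracle.get((True, False, False), 0)

    def test_sub_ranking_by_variant_count_then_gene(self):
        rows = [
            GeneEvidence("b", 2, True, True),
            GeneEvidence("a", 2, True, True),
            GeneEvidence("c", 5, True, True),
        ]
        assert rank_candidates(rows).top_candidates == ["c", "a", "b"]


class TestTabularIO:
    def test_variants_round_trip(self, tmp_path):
        variants = [
            make_variant(),
            make_variant(
                pos=46_000_200,
                consequences=frozenset({"missense"}),
                aa_ref="I",
                aa_alt="T",
                in_domain=True,
            ),
            make_variant(
                pos=46_000_300,
                alt="<DEL>",
                vclass="SV",
                consequences=frozenset({"intronic"}),
                in_ecr=True,
            ),
        ]
        p = tmp_path / "v.tsv"
        write_variants_tsv(variants, p)
        back = read_variants_tsv(p)
        assert back == variants

    def test_gene_evidence_read(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text(
            "gene\thp_variant_count\texpressed\tfunction_relevant\n"
            "Dtx4\t2\ttrue\ttrue\nZzz\t0\tfalse\ttrue\n"
        )
        rows = read_gene_evidence_tsv(p)
        assert rows[0] == GeneEvidence("Dtx4", 2, True, True)
        assert rows[1].expressed is False
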
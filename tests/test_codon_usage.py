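"""Codon counting, relative adaptiveness and adaptation-index ranking."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from replichore.codon_usage import (
    SYNONYMOUS_FAMILIES,
    adaptation_index,
    codon_counts,
    rank_optimized,
    relative_adaptiveness,
    rscu,
)


class TestCodonCounts:
    def test_minimal_gene(self):
        t = codon_counts("ATGAAATAA", "g")
        assert t.counts == {"ATG": 1, "AAA": 1, "TAA": 1} and t.valid

    def test_length_not_multiple_of_three_invalid(self):
        assert not codon_counts("ATGAAAT", "g").valid

    def test_internal_stop_invalid(self):
        assert not codon_counts("ATGTAAAAATAA", "g").valid

    def test_random_orf_count_sum(self, rng):
        body = "".join(
            rng.choice([c for c in SYNONYMOUS_FAMILIES["L"]], size=331)
        )
        t = codon_counts("ATG" + body + "TAA", "g")
        assert t.total == 333 and t.valid


class TestRelativeAdaptiveness:
    def _ref_from(self, codons):
        return [codon_counts("".join(codons), "ref")]

    def test_single_codon_usage(self):
        # Lys family: AAA used, AAG absent -> floor
        counts = codon_counts("AAA" * 10, "ref")
        counts.valid = True
        w = relative_adaptiveness([codon_counts("".join(
            [c for fam in SYNONYMOUS_FAMILIES.values() for c in fam
             if c not in ("TAA", "TAG", "TGA")]), "cover"), counts])
        assert w.w["AAA"] == 1.0

    def test_equal_synonyms_all_one(self):
        base = "".join(
            c for fam_aa, fam in SYNONYMOUS_FAMILIES.items() if fam_aa != "*"
            for c in fam
        )
        w = relative_adaptiveness([codon_counts(base, "uniform")])
        assert all(v == 1.0 for v in w.w.values())

    def test_hand_computed_ratios(self):
        # oracle: Phe TTT x3, TTC x1 -> w(TTT)=1, w(TTC)=1/3
        cover = "".join(
            c for fam_aa, fam in SYNONYMOUS_FAMILIES.items() if fam_aa != "*"
            for c in fam
        )
        ref = [codon_counts(cover, "cover"), codon_counts("TTT" * 2 + "TTC" * 0, "r")]
        w = relative_adaptiveness(ref)
        assert w.w["TTT"] == pytest.approx(1.0)
        assert w.w["TTC"] == pytest.approx(1 / 3)

    def test_missing_codon_gets_floor(self):
        cover = "".join(
            c for fam_aa, fam in SYNONYMOUS_FAMILIES.items() if fam_aa != "*"
            for c in fam if c != "AAG"
        )
        w = relative_adaptiveness([codon_counts(cover, "cover")], floor=0.01)
        assert w.w["AAG"] == 0.01

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_adaptiveness([])

    def test_family_maxima_are_one(self):
        rng = np.random.default_rng(4)
        body = "".join(
            rng.choice([c for aa, fam in SYNONYMOUS_FAMILIES.items() if aa != "*"
                        for c in fam], size=3000)
        )
        w = relative_adaptiveness([codon_counts(body, "r")])
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            if aa == "*":
                continue
            assert max(w.w[c] for c in fam) == 1.0


class TestAdaptationIndex:
    @pytest.fixture()
    def w(self):
        cover = "".join(
            c for fam_aa, fam in SYNONYMOUS_FAMILIES.items() if fam_aa != "*"
            for c in fam
        )
        # make TTT the Phe major codon (3:1), others uniform
        return relative_adaptiveness(
            [codon_counts(cover, "cover"), codon_counts("TTT" * 2, "r")]
        )

    def test_pure_major_codon_gene_scores_one(self, w):
        assert adaptation_index(codon_counts("ATGTTTTTTTAA", "g"), w) == 1.0

    def test_only_excluded_codons_error(self, w):
        with pytest.raises(ValueError, match="countable"):
            adaptation_index(codon_counts("ATGTGGTAA", "g"), w)

    def test_matches_log_oracle(self, w):
        gene = codon_counts("ATG" + "TTT" * 4 + "TTC" * 6 + "TAA", "g")
        expected = math.exp((4 * math.log(1.0) + 6 * math.log(1 / 3)) / 10)
        assert adaptation_index(gene, w) == pytest.approx(expected, rel=1e-12)

    @settings(
        max_examples=20,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(st.permutations(["TTT", "TTC", "AAA", "GGT", "CCA", "TTC"]))
    def test_invariant_to_codon_order(self, w, codons):
        gene = codon_counts("ATG" + "".join(codons) + "TAA", "g")
        ref = codon_counts("ATG" + "TTTTTCAAAGGTCCATTC" + "TAA", "g")
        assert adaptation_index(gene, w) == pytest.approx(
            adaptation_index(ref, w), rel=1e-12
        )

    def test_score_strictly_decreases_with_minor_codon(self, w):
        better = codon_counts("ATG" + "TTT" * 10 + "TAA", "g")
        worse = codon_counts("ATG" + "TTT" * 9 + "TTC" + "TAA", "g")
        assert adaptation_index(worse, w) < adaptation_index(better, w)

    def test_invalid_gene_rejected(self, w):
        with pytest.raises(ValueError):
            adaptation_index(codon_counts("ATGT", "g"), w)


class TestRscu:
    def test_uniform_family_is_one(self):
        g = codon_counts("TTTTTC", "g")
        v = rscu(g)
        assert v["TTT"] == pytest.approx(1.0) and v["TTC"] == pytest.approx(1.0)

    def test_skewed_family(self):
        g = codon_counts("TTTTTTTTC", "g")  # 2 TTT, 1 TTC
        v = rscu(g)
        assert v["TTT"] == pytest.approx(4 / 3)
        assert v["TTC"] == pytest.approx(2 / 3)

    def test_absent_amino_acid_zero(self):
        v = rscu(codon_counts("TTT", "g"))
        assert v["AAA"] == 0.0


class TestRanking:
    @pytest.fixture()
    def w(self):
        cover = "".join(
            c for fam_aa, fam in SYNONYMOUS_FAMILIES.items() if fam_aa != "*"
            for c in fam
        )
        return relative_adaptiveness(
            [codon_counts(cover, "cover"), codon_counts("TTT" * 4, "r")]
        )

    def test_identical_genes_rank_by_id(self, w):
        genes = [codon_counts("ATGTTTTAA", f"g{i}") for i in (3, 1, 2)]
        out = rank_optimized(genes, w, top_k=3)
        assert list(out.top["gene_id"]) == ["g1", "g2", "g3"]

    def test_category_counts_match_planted_overlap(self, w):
        strong = [codon_counts("ATG" + "TTT" * 20 + "TAA", f"s{i}") for i in range(5)]
        weak = [codon_counts("ATG" + "TTC" * 20 + "TAA", f"w{i}") for i in range(5)]
        cats = {f"s{i}": "ribosomal" for i in range(5)}
        out = rank_optimized(strong + weak, w, top_k=5, categories=cats)
        assert out.category_counts == {"ribosomal": 5}

    def test_warning_when_fewer_valid_than_top_k(self, w):
        out = rank_optimized([codon_counts("ATGTTTTAA", "g")], w, top_k=10)
        assert out.warning and len(out.table) == 1

    def test_planted_high_bias_genes_dominate_ranking(self, default_genome):
        from replichore.pipeline import _extract_cds

        seq, ann, truth = default_genome
        feats = ann.of_type("CDS")
        tables = [codon_counts(_extract_cds(seq, f), f.locus_tag) for f in feats]
        top_expr = sorted(truth.expression, key=truth.expression.get, reverse=True)
        ref = [t for t in tables if t.gene_id in set(top_expr[:8])]
        w = relative_adaptiveness(ref)
        out = rank_optimized(tables, w, top_k=10)
        # high-expression genes should dominate the head of the ranking
        top10 = set(out.top["gene_id"])
        assert len(top10 & set(top_expr[:20])) >= 7
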
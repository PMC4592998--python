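import itertools
import math

import pytest
from hypothesis import given, strategies as st

import mitomk as mk
from mitomk.codons import LESS_INCLUSIVE, MORE_INCLUSIVE, classify_codon_column

CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


def oracle_pathways(c_from: str, c_to: str, code) -> list[tuple[int, int, bool]]:
    """Independent brute-force enumeration of all orderings of the differing
    positions, classifying each single-base step by translation."""
    diffs = [i for i in range(3) if c_from[i] != c_to[i]]
    if not diffs:
        return []
    out = []
    for order in itertools.permutations(diffs):
        cur = c_from
        n_syn = n_nonsyn = 0
        hits_stop = False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c_to[pos] + cur[pos + 1 :]
            if step < len(order) - 1 and code.translate(nxt) == "*":
                hits_stop = True
            if code.translate(cur) == code.translate(nxt):
                n_syn += 1
            else:
                n_nonsyn += 1
            cur = nxt
        out.append((n_syn, n_nonsyn, hits_stop))
    return out


class TestEnumeratePathways:
    def test_two_step_pathway_set_fly_code(self, code5):
        ps = mk.enumerate_pathways("TTT", "GTA", code5)
        assert sorted((p.n_syn, p.n_nonsyn) for p in ps.pathways) == [(0, 2), (1, 1)]
        assert ps.averaged_counts() == (0.5, 1.5)

    def test_identity_yields_empty_set(self, code5):
        ps = mk.enumerate_pathways("AAA", "AAA", code5)
        assert ps.pathways == [] and ps.averaged_counts() == (0.0, 0.0)

    def test_both_orderings_equal_fly_code(self, code5):
        ps = mk.enumerate_pathways("GTA", "ATG", code5)
        assert [(p.n_syn, p.n_nonsyn) for p in ps.pathways] == [(1, 1), (1, 1)]

    def test_min_dn_pathway_and_ordering(self, code5):
        assert mk.enumerate_pathways("TTT", "GTA", code5).min_dn_counts() == (1, 1)

    @given(
        st.sampled_from(CODONS),
        st.sampled_from(CODONS),
        st.sampled_from([1, 2, 5]),
    )
    def test_pathway_count_is_k_factorial_and_steps_sum_to_k(self, c1, c2, tid):
        code = mk.get_code(tid)
        ps = mk.enumerate_pathways(c1, c2, code)
        k = sum(a != b for a, b in zip(c1, c2))
        assert len(ps.pathways) == math.factorial(k) if k else not ps.pathways
        for p in ps.pathways:
            assert p.n_syn + p.n_nonsyn == k


class TestCountSiteClasses:
    def test_phe_codon_fly_code(self, code5):
        syn, nonsyn = mk.count_site_classes("TTT", code5)
        assert syn == pytest.approx(1 / 3) and nonsyn == pytest.approx(8 / 3)

    def test_atg_differs_between_codes(self, code5, code1):
        assert mk.count_site_classes("ATG", code5) == pytest.approx((1 / 3, 8 / 3))
        assert mk.count_site_classes("ATG", code1) == pytest.approx((0.0, 3.0))

    def test_fourfold_family_third_position(self, code5):
        syn, _ = mk.count_site_classes("GGG", code5)
        assert syn >= 1.0

    def test_stop_codon_rejected(self, code5):
        with pytest.raises(ValueError):
            mk.count_site_classes("TAA", code5)

    def test_sites_sum_to_three_without_stop_neighbours(self, code5):
        syn, nonsyn = mk.count_site_classes("GGC", code5)
        assert syn + nonsyn == pytest.approx(3.0)


class TestClassifyCodonColumn:
    def test_synonymous_polymorphism_only(self, code5):
        col = ["AAA"] * 37 + ["AAG"]
        assert classify_codon_column(col, "AAA", code5) == [("P_S", 1.0)]

    def test_synonymous_fixed_difference(self, code5):
        assert classify_codon_column(["TTA"] * 38, "TTG", code5) == [("D_S", 1.0)]

    def test_two_step_divergence_more_vs_less_inclusive(self, code5):
        col = ["TTT"] * 38
        more = dict(classify_codon_column(col, "GTA", code5, MORE_INCLUSIVE))
        less = dict(classify_codon_column(col, "GTA", code5, LESS_INCLUSIVE))
        assert more == {"D_S": 0.5, "D_N": 1.5}
        assert less == {"D_S": 1, "D_N": 1}

    def test_outgroup_allele_present_means_polymorphism_only(self, code5):
        col = ["AAA"] * 30 + ["AAG"] * 8
        out = classify_codon_column(col, "AAG", code5)
        assert out == [("P_S", 1.0)]

    def test_outgroup_allele_absent_contributes_both(self, code5):
        # ingroup polymorphic A/G at position 3, outgroup carries C: the site
        # is both a polymorphism and a fixed difference
        col = ["GGA"] * 30 + ["GGG"] * 8
        out = dict(classify_codon_column(col, "GGC", code5))
        assert out["P_S"] == 1.0 and out["D_S"] == 1.0


class TestBuildMKTable:
    def test_two_codon_toy_gene(self, simple_gene_factory):
        ingroup = ["AAATTA"] * 37 + ["AAGTTA"]
        gene = simple_gene_factory(ingroup, "AAATTG")
        t = mk.build_mk_table(gene)
        assert (t.P_N, t.P_S, t.D_N, t.D_S) == (0, 1, 0, 1)

    def test_zero_variation_gives_all_zero_table(self, simple_gene_factory):
        gene = simple_gene_factory(["ATGAAA"] * 5, "ATGAAA")
        t = mk.build_mk_table(gene)
        assert t.counts() == (0, 0, 0, 0)

    def test_methods_agree_on_polymorphism_without_missing_data(
        self, simple_gene_factory
    ):
        ingroup = ["AAATTATTT"] * 20 + ["AAGTTATTT"] * 10 + ["AAATTACTT"] * 8
        gene = simple_gene_factory(ingroup, "AAATTGGTA")
        more = mk.build_mk_table(gene, MORE_INCLUSIVE)
        less = mk.build_mk_table(gene, LESS_INCLUSIVE)
        assert (more.P_N, more.P_S) == (less.P_N, less.P_S)
        assert less.D_N <= more.D_N

    def test_less_inclusive_drops_missing_columns(self, simple_gene_factory):
        ingroup = ["AAATTA"] * 37 + ["AANTTA"]
        gene = simple_gene_factory(ingroup, "AAGTTA")
        more = mk.build_mk_table(gene, MORE_INCLUSIVE)
        less = mk.build_mk_table(gene, LESS_INCLUSIVE)
        # codon 1 has a missing cell: kept (divergent) by more-inclusive,
        # dropped entirely by less-inclusive
        assert more.D_S == 1 and less.counts() == (0, 0, 0, 0)

    def test_drop_sequences_restores_clean_columns(self, simple_gene_factory):
        ingroup = ["AAATTA"] * 37 + ["NANNTN"]
        gene = simple_gene_factory(ingroup, "AAGTTA")
        less = mk.build_mk_table(gene, LESS_INCLUSIVE, drop_sequences=("s37",))
        assert less.D_S == 1


class TestPolarizeTwoOutgroups:
    def build(self, ingroup, out1, out2):
        from conftest import make_alignment

        seqs = {f"s{i}": s for i, s in enumerate(ingroup)}
        seqs["o1"], seqs["o2"] = out1, out2
        aln = make_alignment(seqs, ["o1", "o2"])
        ann = mk.GeneAnnotation("g", 1, aln.length, "+", 0, 5)
        return mk.extract_gene(aln, ann)

    def test_concordant_outgroups_give_divergence(self):
        gene = self.build(["TTA"] * 6, "TTG", "TTG")
        t = mk.polarize_with_two_outgroups(gene, "o1", "o2")
        assert t.D_S == 1 and t.polarized

    def test_discordant_outgroups_excluded(self):
        gene = self.build(["TTA"] * 6, "TTG", "TTA")
        t = mk.polarize_with_two_outgroups(gene, "o1", "o2")
        assert t.counts() == (0, 0, 0, 0)

    def test_shared_outgroup_allele_is_polymorphism_only(self):
        gene = self.build(["AAA"] * 4 + ["AAG"] * 2, "AAG", "AAG")
        t = mk.polarize_with_two_outgroups(gene, "o1", "o2")
        assert (t.P_S, t.D_S, t.D_N) == (1, 0, 0)


class TestOracleEquivalence:
    """More-inclusive averages equal the independent k!-enumeration oracle."""

    @given(st.sampled_from(CODONS), st.sampled_from(CODONS))
    def test_random_pairs_match_oracle_fly_code(self, c1, c2):
        code = mk.get_code(5)
        ps = mk.enumerate_pathways(c1, c2, code)
        expected = oracle_pathways(c1, c2, code)
        assert sorted((p.n_syn, p.n_nonsyn, p.hits_stop) for p in ps.pathways) == sorted(
            expected
        )
        usable = [(s, n) for s, n, stop in expected if not stop] or [
            (s, n) for s, n, _ in expected
        ]
        exp_avg = (
            sum(s for s, _ in usable) / len(usable),
            sum(n for _, n in usable) / len(usable),
        ) if usable else (0.0, 0.0)
        assert ps.averaged_counts() == pytest.approx(exp_avg)
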
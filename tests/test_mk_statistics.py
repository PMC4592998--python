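import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitomk as mk
from mitomk.codons import MKTable


def table(pn, ps, dn, ds, name="g"):
    return MKTable(name, P_N=pn, P_S=ps, D_N=dn, D_S=ds)


class TestNeutralityIndex:
    @pytest.mark.parametrize(
        "gene,expected,pseudo",
        [
            ("ATPase6", 7.955, False),
            ("ATPase8", 6.000, True),
            ("COI", 0.667, True),
            ("COII", 1.300, False),
            ("ND4L", 14.00, False),
            ("ND6", 0.523, False),
        ],
    )
    def test_published_per_gene_values(self, mt_by_gene, gene, expected, pseudo):
        ni, applied = mk.neutrality_index(mt_by_gene[gene])
        assert ni == pytest.approx(expected, abs=5e-3)
        assert applied is pseudo

    def test_neutral_table_is_one(self):
        ni, applied = mk.neutrality_index(table(3, 6, 10, 20))
        assert ni == 1.0 and not applied

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50),
           st.integers(2, 9))
    def test_scale_equivariance(self, pn, ps, dn, ds, c):
        ni1, _ = mk.neutrality_index(table(pn, ps, dn, ds))
        ni2, _ = mk.neutrality_index(table(c * pn, c * ps, c * dn, c * ds))
        assert ni1 == pytest.approx(ni2)


class TestZStatistics:
    @pytest.mark.parametrize(
        "gene,expected",
        [("ATPase6", -0.778), ("ATPase8", -0.778), ("COI", 0.176), ("ND6", 0.203)],
    )
    def test_published_z_star(self, mt_by_gene, gene, expected):
        assert mk.z_star(mt_by_gene[gene]) == pytest.approx(expected, abs=5e-4)

    def test_z_star_all_zero_table(self):
        assert mk.z_star(table(0, 0, 0, 0)) == 0.0

    def test_z_plain_balanced_and_undefined(self):
        assert mk.z_plain(table(10, 10, 10, 10)) == 0.0
        assert math.isnan(mk.z_plain(table(0, 1, 2, 3)))

    @given(st.integers(1, 99), st.integers(1, 99), st.integers(1, 99), st.integers(1, 99))
    def test_z_plain_is_negative_log_ni_without_zeros(self, pn, ps, dn, ds):
        t = table(pn, ps, dn, ds)
        ni, applied = mk.neutrality_index(t)
        assert not applied
        assert mk.z_plain(t) == pytest.approx(-math.log10(ni), rel=1e-12)


class TestFisherExact:
    @pytest.mark.parametrize(
        "gene,expected",
        [("ATPase6", 0.021), ("ATPase8", 0.273), ("COI", 0.595), ("COII", 1.000)],
    )
    def test_published_p_values(self, mt_by_gene, gene, expected):
        assert mk.fisher_exact_mk(mt_by_gene[gene]) == pytest.approx(expected, abs=5e-4)

    def test_balanced_table(self):
        assert mk.fisher_exact_mk(table(10, 10, 10, 10)) == 1.0

    def test_fractional_counts_rounded_half_away(self, mt_by_gene):
        # ND5 carries fractional divergence counts; the exact test must see
        # integers but NI keeps the fractions
        p = mk.fisher_exact_mk(mt_by_gene["ND5"])
        assert 0 <= p <= 1
        from scipy.stats import fisher_exact

        assert p == pytest.approx(fisher_exact([[4, 10], [56, 107]])[1])


class TestNITG:
    def test_complex_v(self, mt_by_gene):
        cv = [mt_by_gene["ATPase6"], mt_by_gene["ATPase8"]]
        assert mk.ni_tg(cv) == pytest.approx(9.64, abs=5e-3)

    def test_single_gene_equals_raw_ni(self):
        t = table(5, 2, 11, 35)
        assert mk.ni_tg([t]) == pytest.approx((35 * 5) / (11 * 2))

    def test_all_thirteen_genes(self, mt_tables):
        assert mk.ni_tg(mt_tables) == pytest.approx(1.67, abs=5e-3)

    def test_undefined_denominator(self):
        assert math.isnan(mk.ni_tg([table(1, 0, 2, 8)]))

    def test_identical_copies_equal_single_table(self):
        t = table(5, 2, 11, 35)
        assert mk.ni_tg([t] * 7) == pytest.approx(mk.ni_tg([t]))


class TestBootstrapCI:
    def test_deterministic_given_seed(self, mt_tables):
        a = mk.ni_tg_bootstrap_ci(mt_tables, n_boot=500, seed=123)
        b = mk.ni_tg_bootstrap_ci(mt_tables, n_boot=500, seed=123)
        assert a == b

    def test_all_coding_brackets_point_estimate(self, mt_tables):
        lo, hi = mk.ni_tg_bootstrap_ci(mt_tables, n_boot=2000, seed=7)
        point = mk.ni_tg(mt_tables)
        assert lo < point < hi
        assert lo > 1.0  # the combined estimator excludes neutrality

    def test_complex_v_is_undefined(self, mt_by_gene):
        cv = [mt_by_gene["ATPase6"], mt_by_gene["ATPase8"]]
        assert mk.ni_tg_bootstrap_ci(cv, n_boot=500, seed=3) is None

    def test_single_gene_degenerate(self):
        t = table(5, 2, 11, 35)
        lo, hi = mk.ni_tg_bootstrap_ci([t], n_boot=200, seed=1)
        assert lo == hi == pytest.approx(mk.ni_tg([t]))


class TestWoolf:
    def test_identical_tables(self):
        chi2, df, p = mk.woolf_homogeneity([table(10, 10, 10, 10)] * 3)
        assert chi2 == pytest.approx(0.0) and df == 2 and p == pytest.approx(1.0)

    def test_hand_computed_two_tables(self):
        tables = [table(10, 10, 10, 10), table(40, 10, 10, 40)]
        lors, ws = [], []
        for t in tables:
            a, b, c, d = (x + 0.5 for x in t.counts())
            lors.append(math.log(a * d / (b * c)))
            ws.append(1 / (1 / a + 1 / b + 1 / c + 1 / d))
        mean = sum(w * l for w, l in zip(ws, lors)) / sum(ws)
        expected = sum(w * (l - mean) ** 2 for w, l in zip(ws, lors))
        chi2, df, p = mk.woolf_homogeneity(tables)
        assert chi2 == pytest.approx(expected) and df == 1

    def test_mtdna_gene_set_is_homogeneous(self, mt_tables):
        _, _, p = mk.woolf_homogeneity(mt_tables)
        assert p > 0.05

    def test_requires_two_tables(self):
        with pytest.raises(ValueError):
            mk.woolf_homogeneity([table(1, 1, 1, 1)])


class TestGeneSetSummary:
    def test_all_coding(self, mt_tables):
        s = mk.summarize_gene_set(mt_tables, "All coding", n_boot=500, seed=2)
        assert s.NI_summed == pytest.approx(1.59, abs=5e-3)
        assert s.Z_summed == pytest.approx(-0.201, abs=5e-4)
        assert s.NI_median == pytest.approx(1.97, abs=5e-3)
        assert s.NI_mean == pytest.approx(3.57, abs=5e-3)
        assert s.NI_sd == pytest.approx(3.89, abs=5e-3)
        assert s.p_fet == pytest.approx(0.041, abs=5e-4)

    def test_complex_iv(self, mt_by_gene):
        genes = [mt_by_gene[g] for g in ("COI", "COII", "COIII")]
        s = mk.summarize_gene_set(genes, "Complex IV", n_boot=500, seed=2)
        assert s.NI_summed == pytest.approx(0.56, abs=5e-3)
        assert s.NI_TG == pytest.approx(0.55, abs=5e-3)
        assert s.Z_summed == pytest.approx(0.255, abs=5e-4)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mk.summarize_gene_set([], "none")


class TestComparisons:
    def test_rank_sum_identical_samples(self):
        _, p = mk.rank_sum_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_rank_sum_disjoint_shift(self):
        a = list(range(10))
        b = [x + 100 for x in range(10)]
        _, p = mk.rank_sum_compare(a, b)
        assert p < 1e-3

    def test_rank_sum_single_elements(self):
        u, _ = mk.rank_sum_compare([1.0], [2.0])
        assert u == 0.0

    def test_effect_size(self):
        assert mk.effect_size(1.0, 1.0, 1.0, 2.0) == 0.0
        assert mk.effect_size(1.0, 1.0, 2.0, 1.0) == pytest.approx(1.0)
        assert mk.effect_size(0.0, 3.333, 3.2, 3.333) == pytest.approx(0.96, abs=5e-3)


class TestMKCountIO:
    def test_roundtrip(self, tmp_path, mt_tables):
        from mitomk.mkstats import mk_table_records

        p = tmp_path / "counts.tsv"
        mk.write_results_table(mk_table_records(mt_tables), p)
        back = mk.read_mk_counts(p)
        assert [t.gene_name for t in back] == [t.gene_name for t in mt_tables]
        assert back[0].counts() == mt_tables[0].counts()

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("gene\tPN\tPS\tDN\tDS\n")
        with pytest.raises(ValueError, match="no rows"):
            mk.read_mk_counts(p)
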
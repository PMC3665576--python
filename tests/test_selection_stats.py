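import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from conftest import make_record
from mutsel.io_formats import GeneAnnotation, GeneLength, VariantClass
from mutsel.selection_stats import (
    FisBinSpec,
    MutationTally,
    cancer_gene_fraction,
    cna_concurrency,
    length_null_non_uniformity,
    non_uniformity,
    tally,
    truncating_concurrency,
)
from oracles import brute_force_non_uniformity, fisher_exact_two_sided

ANN = {
    "T1": GeneAnnotation(gene="T1", categories=frozenset({"TS", "CG"})),
    "T2": GeneAnnotation(gene="T2", categories=frozenset({"TS", "CG"})),
    "O1": GeneAnnotation(gene="O1", categories=frozenset({"OG", "CG"})),
    "C1": GeneAnnotation(gene="C1", categories=frozenset({"CG"})),
}


class TestNonUniformity:
    def test_uniform_distribution_gives_mu_of_one(self):
        t = MutationTally(counts={f"g{i}": 5 for i in range(100)})
        r = non_uniformity(t)
        assert r.mu == pytest.approx(1.0, abs=1e-12)
        assert r.k == pytest.approx(100.0, abs=1e-9)

    def test_hand_derived_skewed_table(self):
        t = MutationTally(counts={"g1": 10, "g2": 1, "g3": 1, "g4": 1, "g5": 1})
        r = non_uniformity(t)
        assert r.lambda_ == pytest.approx(104 / 196, abs=1e-12)
        assert r.k == pytest.approx(196 / 104, abs=1e-12)
        assert r.mu == pytest.approx(5 * 104 / 196, abs=1e-12)
        assert r.n_avg == pytest.approx(14 * 104 / 196, abs=1e-12)

    def test_single_dominant_gene_effective_number_near_one(self):
        r = non_uniformity(MutationTally(counts={"g1": 98, "g2": 1, "g3": 1}))
        assert r.k == pytest.approx(10000 / 9606, abs=1e-12)
        assert r.k == pytest.approx(1.041, abs=5e-4)

    def test_empty_tally_refused(self):
        with pytest.raises(ValueError, match="M = 0"):
            non_uniformity(MutationTally(counts={}))

    @given(st.lists(st.integers(1, 40), min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_identities(self, counts):
        t = MutationTally(counts={f"g{i}": n for i, n in enumerate(counts)})
        r = non_uniformity(t)
        q = t.Q
        assert 1 / q - 1e-12 <= r.lambda_ <= 1 + 1e-12
        assert 1 - 1e-12 <= r.k <= q + 1e-9
        assert 1 - 1e-9 <= r.mu <= q + 1e-9
        assert r.k == pytest.approx(1 / r.lambda_)
        assert r.mu == pytest.approx(r.lambda_ * q)
        # mu = 1 exactly iff all counts equal
        if len(set(counts)) == 1:
            assert r.mu == pytest.approx(1.0, abs=1e-12)
        else:
            assert r.mu > 1 + 1e-12

    @given(st.lists(st.integers(1, 40), min_size=1, max_size=30),
           st.integers(2, 7))
    @settings(max_examples=100, derandomize=True)
    def test_invariant_under_relabeling_and_scaling(self, counts, factor):
        t1 = MutationTally(counts={f"g{i}": n for i, n in enumerate(counts)})
        t2 = MutationTally(counts={f"x{i}": n * factor for i, n in enumerate(counts)})
        assert non_uniformity(t1).mu == pytest.approx(non_uniformity(t2).mu, rel=1e-12)

    def test_matches_brute_force_from_raw_records(self, rng):
        for _ in range(50):
            genes = [f"g{i}" for i in rng.integers(0, 12, size=int(rng.integers(1, 60)))]
            recs = [make_record(g, VariantClass.SILENT, pos=1, ref="A") for g in genes]
            r = non_uniformity(tally(recs, VariantClass.SILENT))
            lam, k, mu = brute_force_non_uniformity(genes)
            assert (r.lambda_, r.k, r.mu) == pytest.approx((lam, k, mu), rel=1e-12)


class TestTally:
    def test_gene_group_filter(self):
        recs = [make_record(g, VariantClass.SILENT, pos=1, ref="A")
                for g in ["T1", "T1", "T2", "T2", "O1", "C1", "N1", "N2", "N3", "N4"]]
        assert tally(recs, VariantClass.SILENT, gene_group="TS", annotations=ANN).M == 4
        assert tally(recs, VariantClass.SILENT, gene_group="OG", annotations=ANN).M == 1
        assert tally(recs, VariantClass.SILENT, gene_group="CG", annotations=ANN).M == 6
        assert tally(recs, VariantClass.SILENT, gene_group="nCG", annotations=ANN).M == 4

    def test_fis_bin_threshold_is_strict(self):
        recs = [make_record("G", fis=f) for f in (3.1, 0.2, 2.6)]
        assert tally(recs, VariantClass.MISSENSE, fis_bin=2.5).M == 2
        assert tally(recs, VariantClass.MISSENSE, fis_bin=2.6).M == 1

    def test_unscored_missense_excluded_from_binned_tallies(self):
        recs = [make_record("G", fis=None), make_record("G", fis=3.0)]
        assert tally(recs, VariantClass.MISSENSE, fis_bin=None).M == 1

    def test_bin_never_gates_truncating_records(self):
        recs = [make_record("G", VariantClass.TRUNCATING) for _ in range(3)]
        t = tally(recs, VariantClass.TRUNCATING, fis_bin=2.5)
        assert t.M == 3

    def test_empty_result_is_valid_and_flagged(self):
        t = tally([], VariantClass.SILENT)
        assert t.is_empty and t.M == 0 and t.Q == 0


class TestCancerGeneFraction:
    def test_counts_mutations_not_genes(self):
        recs = ([make_record("C1", fis=3.0) for _ in range(4)] +
                [make_record(f"N{i}", fis=3.0) for i in range(6)])
        out = cancer_gene_fraction(recs, FisBinSpec((None,)), ANN, "CG")
        assert out["all"] == pytest.approx(40.0)

    def test_empty_bin_reports_absent_not_zero(self):
        recs = [make_record("C1", fis=1.0)]
        out = cancer_gene_fraction(recs, FisBinSpec((None, 2.5)), ANN, "CG")
        assert out["FIS>2.5"] is None

    def test_reference_classes_present(self):
        recs = [make_record("C1", fis=1.0),
                make_record("C1", VariantClass.SILENT, pos=1, ref="A"),
                make_record("N1", VariantClass.TRUNCATING)]
        out = cancer_gene_fraction(recs, FisBinSpec((None,)), ANN, "CG")
        assert out["silent"] == pytest.approx(100.0)
        assert out["truncating"] == pytest.approx(0.0)


class TestTruncatingConcurrency:
    def test_gene_level_counting(self):
        recs = [
            make_record("A", fis=3.0, sample="s1"),
            make_record("B", fis=3.0, sample="s2"),
            make_record("C", fis=3.0, sample="s3"),
            make_record("A", VariantClass.TRUNCATING, sample="s4"),
            make_record("D", VariantClass.TRUNCATING, sample="s5"),
        ]
        out = truncating_concurrency(recs, FisBinSpec((None,)))
        assert out["all"] == pytest.approx(100 / 3)

    def test_same_single_tumor_not_concurrent(self):
        recs = [
            make_record("A", fis=3.0, sample="s1"),
            make_record("A", VariantClass.TRUNCATING, sample="s1"),
        ]
        out = truncating_concurrency(recs, FisBinSpec((None,)))
        assert out["all"] == pytest.approx(0.0)
        # a second missense sample makes a cross-tumor pair possible
        recs.append(make_record("A", fis=3.0, sample="s2"))
        out = truncating_concurrency(recs, FisBinSpec((None,)))
        assert out["all"] == pytest.approx(100.0)

    def test_empty_denominator_absent(self):
        recs = [make_record("A", VariantClass.TRUNCATING, sample="s1")]
        out = truncating_concurrency(recs, FisBinSpec((None, 2.5)))
        assert out["all"] is None and out["FIS>2.5"] is None


class TestCnaConcurrency:
    def _toy(self):
        # silent: 2/20 in loss; truncating: 4/20 in loss
        recs, cna = [], {}
        for i in range(20):
            s = f"s{i}"
            recs.append(make_record(f"G{i}", VariantClass.SILENT, pos=1, ref="A", sample=s))
            cna[(s, f"G{i}")] = -1 if i < 2 else 0
        for i in range(20):
            s = f"t{i}"
            recs.append(make_record(f"H{i}", VariantClass.TRUNCATING, sample=s))
            cna[(s, f"H{i}")] = -1 if i < 4 else 0
        return recs, cna

    def test_toy_percentages(self):
        recs, cna = self._toy()
        res = cna_concurrency(recs, cna, VariantClass.TRUNCATING)
        assert res.percentages[-1] == pytest.approx(20.0)
        assert res.silent_percentages[-1] == pytest.approx(10.0)

    def test_p_value_matches_hypergeometric_enumeration(self):
        recs, cna = self._toy()
        res = cna_concurrency(recs, cna, VariantClass.TRUNCATING)
        want = fisher_exact_two_sided(4, 16, 2, 18)
        assert res.p_loss == pytest.approx(want, rel=1e-9)

    def test_scipy_fisher_agrees_with_enumeration_oracle_broadly(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            want = fisher_exact_two_sided(a, b, c, d)
            got = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert got == pytest.approx(want, rel=1e-7, abs=1e-12)

    def test_fis_bin_selector(self):
        recs, cna = self._toy()
        recs.append(make_record("G0", fis=3.0, sample="s0"))
        res = cna_concurrency(recs, cna, 2.5)
        assert res.counts[-1] == 1 and sum(res.counts.values()) == 1

    def test_unjoined_records_excluded(self):
        recs, cna = self._toy()
        recs.append(make_record("ZZ", VariantClass.TRUNCATING, sample="nowhere"))
        res = cna_concurrency(recs, cna, VariantClass.TRUNCATING)
        assert res.n_excluded == 1

    def test_no_joined_records_refused(self):
        recs = [make_record("A", VariantClass.SILENT, pos=1, ref="A")]
        with pytest.raises(ValueError):
            cna_concurrency(recs, {}, VariantClass.SILENT)


class TestLengthNull:
    def test_uniform_lengths(self):
        r = length_null_non_uniformity([GeneLength(gene=f"g{i}", coding_length=4)
                                        for i in range(4)])
        assert r.k == pytest.approx(4.0) and r.mu == pytest.approx(1.0)

    def test_hand_derived_skewed_lengths(self):
        lengths = [GeneLength(gene="a", coding_length=7)] + \
                  [GeneLength(gene=g, coding_length=1) for g in "bcd"]
        r = length_null_non_uniformity(lengths)
        assert r.lambda_ == pytest.approx(0.52, abs=1e-12)
        assert r.k == pytest.approx(1 / 0.52, abs=1e-9)
        assert r.mu == pytest.approx(2.08, abs=1e-9)

    def test_realistic_lognormal_length_spectrum_gives_small_mu(self, rng):
        """18k genes with log-normal lengths: the length-driven null is in the
        low single digits, far below a selection signal."""
        nts = np.maximum(150, rng.lognormal(7.25, 0.6, size=18000).round()).astype(int)
        lengths = [GeneLength(gene=f"g{i}", coding_length=int(n)) for i, n in enumerate(nts)]
        r = length_null_non_uniformity(lengths)
        assert 1.0 < r.mu < 3.0

    def test_empty_refused(self):
        with pytest.raises(ValueError):
            length_null_non_uniformity([])
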
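import math
from itertools import product

import numpy as np
import pytest
from scipy import stats

from sigscan import (
    EnrichmentCounts,
    EnrichmentResult,
    GenomeSequence,
    associate,
    bh_adjust,
    classify_es,
    compare_groups,
    count_motifs,
    enrichment_score,
    filter_for_enrichment,
    fisher_one_sided,
    score_from_counts,
    window_context,
)
from sigscan.enrichment import attach_q_values

from conftest import mk_sbs


class TestFilterForEnrichment:
    def test_four_rules(self):
        records = [
            mk_sbs(pos=1, ref="C", alt="T"),
            mk_sbs(pos=2, ref="C", alt="A"),
            mk_sbs(pos=3, ref="T", alt="G"),
            mk_sbs(pos=4, ref="G", alt="A"),
            mk_sbs(pos=5, ref="C", alt="T", contig="chrM"),
        ]
        kept = filter_for_enrichment(records)
        assert [(r.ref_allele, r.alt_allele) for r in kept] == [("C", "T"), ("G", "A")]

    def test_g_to_t_removed_as_c_to_a(self):
        assert filter_for_enrichment([mk_sbs(ref="G", alt="T")]) == []

    def test_indels_removed(self):
        assert filter_for_enrichment([mk_sbs(ref="CA", alt="C")]) == []

    def test_empty(self):
        assert filter_for_enrichment([]) == []

    def test_retained_classes_exhaustive(self):
        # exactly C>T, C>G, G>A, G>C survive out of all 12 substitutions
        records = [
            mk_sbs(pos=i + 1, ref=ref, alt=alt)
            for i, (ref, alt) in enumerate(
                (r, a) for r in "ACGT" for a in "ACGT" if r != a
            )
        ]
        kept = {(r.ref_allele, r.alt_allele) for r in filter_for_enrichment(records)}
        assert kept == {("C", "T"), ("C", "G"), ("G", "A"), ("G", "C")}


class TestWindowContext:
    def test_full_window(self, sim_genome):
        rec = mk_sbs(pos=21, ref=sim_genome.base("c1", 21), alt="T"
                     if sim_genome.base("c1", 21) != "T" else "A")
        window = window_context(rec, sim_genome)
        assert window == sim_genome.slice("c1", 1, 41) or rec.ref_allele == "G"
        assert len(window) == 41

    def test_left_truncated(self, sim_genome):
        ref = sim_genome.base("c1", 5)
        rec = mk_sbs(pos=5, ref=ref, alt="T" if ref != "T" else "A")
        assert len(window_context(rec, sim_genome)) == 25

    def test_g_site_reverse_complemented(self):
        genome = GenomeSequence({"c1": "A" * 30 + "TGA" + "A" * 30})
        rec = mk_sbs(pos=32, ref="G", alt="A")
        window = window_context(rec, genome)
        from sigscan import reverse_complement

        assert window == reverse_complement(genome.slice("c1", 12, 52))
        assert window[20] == "C"  # mutated base presented as C


class TestCountMotifs:
    @pytest.mark.parametrize(
        "window,expected",
        [("TCATCT", (2, 2)), ("GCCGG", (0, 2)), ("TCTCT", (2, 2)), ("", (0, 0)),
         ("TCN", (0, 1)), ("NCA", (0, 1))],
    )
    def test_examples(self, window, expected):
        assert count_motifs(window) == expected

    def test_strict_tca_variant(self):
        assert count_motifs("TCATCT", motif="TCA") == (1, 2)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            window = "".join(rng.choice(list("ACGTN"), size=41, p=[0.24] * 4 + [0.04]))
            tcw, c = count_motifs(window)
            # independent oracle: scan every trinucleotide
            expected_tcw = sum(
                window[i : i + 3] in ("TCA", "TCT") for i in range(len(window) - 2)
            )
            assert tcw == expected_tcw
            assert c == window.count("C")
            assert tcw <= c


class TestEnrichmentScore:
    def test_formula_hand_example(self):
        counts = EnrichmentCounts(mut_tcw=5, mut_c=10, con_tcw=10, con_c=100)
        assert score_from_counts(counts) == pytest.approx(5.0)

    def test_identity_case(self):
        counts = EnrichmentCounts(mut_tcw=3, mut_c=30, con_tcw=10, con_c=100)
        assert score_from_counts(counts) == pytest.approx(1.0)

    def test_no_mutations_flagged_undefined(self, sim_genome):
        result = enrichment_score([], sim_genome, sample_id="empty")
        assert not result.defined
        assert math.isnan(result.score)

    def test_window_aggregation_on_crafted_genome(self):
        # genome: single TCA motif at 4-6, surrounded by A-runs: the
        # record's own window contains exactly that one motif and one C
        genome = GenomeSequence({"c1": "AAATCAAAA"})
        rec = mk_sbs(pos=5, ref="C", alt="T")
        result = enrichment_score([rec], genome, sample_id="S1")
        assert result.counts == EnrichmentCounts(1, 1, 1, 1)
        assert result.score == pytest.approx(1.0)

    def test_determinism(self, sim_genome):
        rng = np.random.default_rng(9)
        from conftest import random_records_on

        records = filter_for_enrichment(random_records_on(sim_genome, 200, rng))
        a = enrichment_score(records, sim_genome)
        b = enrichment_score(records, sim_genome)
        assert a == b


def hypergeom_tail_p(a, b, c, d):
    """One-sided ('greater') Fisher p by explicit tail enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    k_min = max(0, col1 - (n - row1))
    k_max = min(row1, col1)
    total = math.comb(n, col1)
    return sum(
        math.comb(row1, k) * math.comb(n - row1, col1 - k) for k in range(a, k_max + 1)
    ) / total


class TestFisher:
    def test_example_table(self):
        counts = EnrichmentCounts(5, 10, 10, 100)
        assert fisher_one_sided(counts) == pytest.approx(
            hypergeom_tail_p(5, 5, 10, 90), abs=1e-12
        )

    def test_zero_observed_gives_p_one(self):
        assert fisher_one_sided(EnrichmentCounts(0, 7, 4, 10)) == pytest.approx(1.0)

    def test_monotone_in_observed_count(self):
        # fixed margins: moving mass into the top-left cell shrinks p
        previous = 1.1
        for a in range(0, 6):
            counts = EnrichmentCounts(a, 5, 5 + (5 - a), 20)
            p = fisher_one_sided(counts)
            assert p <= previous + 1e-12
            previous = p


class TestBhAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_step_up_definition(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 40))
        p = rng.uniform(size=m)
        adjusted = np.asarray(bh_adjust(p))
        # definitional oracle: q_(i) = min_{j >= i} m p_(j) / j, clipped at 1
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, m * p[idx] / rank)
            expected[idx] = running
        assert adjusted == pytest.approx(expected)
        # order preservation and bounds
        assert np.all(adjusted >= p - 1e-12)
        assert np.all(adjusted <= 1.0)


def _result(sample, p, q, score=2.0):
    return EnrichmentResult(sample, EnrichmentCounts(5, 10, 10, 100), score, p, q)


class TestClassifyEs:
    def test_threshold_strict(self):
        results = classify_es([_result("a", 0.01, 0.05), _result("b", 0.05, 0.1)])
        assert [r.es_class for r in results] == ["high", "low"]

    def test_unset_q_is_error(self):
        with pytest.raises(ValueError, match="q-value"):
            classify_es([_result("a", 0.01, None)])

    def test_undefined_score_classed_low(self):
        undefined = EnrichmentResult(
            "u", EnrichmentCounts(0, 0, 0, 0), float("nan"), 1.0
        )
        results = classify_es(attach_q_values([undefined, _result("a", 0.01, None)]))
        assert results[0].es_class == "low"
        assert results[1].q_value == pytest.approx(0.01)  # BH family of one

    def test_attach_q_matches_bh(self):
        raw = [0.01, 0.02, 0.04]
        results = attach_q_values([_result(str(i), p, None) for i, p in enumerate(raw)])
        assert [r.q_value for r in results] == pytest.approx(bh_adjust(raw))


class TestAssociate:
    def test_perfect_linear_pearson(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = associate(x, [2 * v + 1 for v in x], method="pearson")
        assert r == pytest.approx(1.0)

    def test_decreasing_spearman(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = associate(x, [math.exp(-v) for v in x], method="spearman")
        assert r == pytest.approx(-1.0)

    def test_pair_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(size=10), rng.uniform(size=10)
        perm = rng.permutation(10)
        for method in ("pearson", "spearman"):
            assert associate(x, y, method)[0] == pytest.approx(
                associate(x[perm], y[perm], method)[0]
            )

    def test_zero_variance_flagged(self):
        r, p = associate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r) and math.isnan(p)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            associate([1.0, 2.0], [1.0, 2.0])


class TestCompareGroups:
    def test_identical_groups_near_one(self):
        _, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_complete_separation_exact_p(self):
        u, p = compare_groups([6.0, 7.0, 8.0, 9.0, 10.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert u == 25.0
        assert p == pytest.approx(2 / math.comb(10, 5))

    def test_monotone_transform_invariance(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        u1, p1 = compare_groups(a, b)
        u2, p2 = compare_groups([math.exp(v) for v in a], [math.exp(v) for v in b])
        assert (u1, p1) == (u2, p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])
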
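"""Amplicon filtering, preclustering, chimera screen, Chao1, rarefaction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytohet import (
    AlleleTable,
    FilterPolicy,
    ReadRecord,
    chimera_screen,
    diversity,
    estimate_error_rate,
    precluster,
    quality_filter,
    rarefaction,
)
from cytohet.ampdiv import Allele


def _read(seq, qual_char="I", rid="r1"):
    return ReadRecord(id=rid, seq=seq, qual=qual_char * len(seq))


def _table(counts_by_seq):
    alleles = [
        Allele(sequence=s, count=c, member_read_ids=[])
        for s, c in counts_by_seq.items()
    ]
    alleles.sort(key=lambda a: (-a.count, a.sequence))
    return AlleleTable(alleles=alleles)


class TestQualityFilter:
    def test_ambiguous_base_rejected(self):
        kept, tallies = quality_filter([_read("ACGTN" + "ACGT" * 20)])
        assert kept == []
        assert tallies["ambiguous"] == 1

    def test_long_homopolymer_rejected(self):
        seq = "ACGT" * 10 + "A" * 9 + "CGT" * 10
        kept, tallies = quality_filter([_read(seq)])
        assert kept == []
        assert tallies["homopolymer"] == 1
        # 8-bp runs are allowed (the rule is strictly greater than 8)
        seq8 = "ACGT" * 10 + "A" * 8 + "CGT" * 10
        kept, _ = quality_filter([_read(seq8)])
        assert len(kept) == 1

    def test_low_quality_window_rejected(self):
        # quality 34 (< 35) in every window
        kept, tallies = quality_filter([_read("ACGT" * 30, qual_char=chr(33 + 34))])
        assert kept == []
        assert tallies["quality"] == 1
        # quality 36 everywhere passes
        kept, _ = quality_filter([_read("ACGT" * 30, qual_char=chr(33 + 36))])
        assert len(kept) == 1

    def test_primer_mismatch_rejected_and_trimmed(self):
        policy = FilterPolicy(primer="ACGTACGTAC")
        good = _read("ACGTACGTAC" + "GTCA" * 25)
        bad = _read("TCGTACGTAC" + "GTCA" * 25)
        kept, tallies = quality_filter([good, bad], policy)
        assert tallies["primer"] == 1
        assert len(kept) == 1
        assert kept[0].seq == "GTCA" * 25  # primer trimmed off

    def test_missing_quality_rejected(self):
        with pytest.raises(ValueError, match="quality"):
            quality_filter([ReadRecord(id="x", seq="ACGT" * 30)])

    def test_conservation(self):
        reads = [
            _read("ACGT" * 30, rid="ok"),
            _read("ACGTN" + "ACGT" * 20, rid="amb"),
            _read("A" * 40 + "CGT" * 20, rid="homo"),
        ]
        kept, tallies = quality_filter(reads)
        assert len(kept) + sum(tallies.values()) == len(reads)


class TestPrecluster:
    def test_one_bp_neighbors_merge(self):
        reads = [("x%d" % i, "AAAA") for i in range(10)] + [("y", "AAAT")]
        table = precluster(reads, max_diff=1)
        assert len(table) == 1
        assert table.alleles[0].sequence == "AAAA"
        assert table.alleles[0].count == 11

    def test_two_bp_stays_separate(self):
        reads = [("x%d" % i, "AAAA") for i in range(10)] + [
            ("y%d" % i, "AATT") for i in range(2)
        ]
        table = precluster(reads, max_diff=1)
        assert len(table) == 2

    def test_no_transitive_chaining(self):
        # X:10, Y:5 (1 diff from X), Z:1 (1 diff from Y, 2 from X):
        # Y merges into X; Z measured against representative X stays apart
        x, y, z = "AACCGGTTAA", "AACCGGTTAT", "AACCGGTTGT"
        reads = (
            [("x%d" % i, x) for i in range(10)]
            + [("y%d" % i, y) for i in range(5)]
            + [("z0", z)]
        )
        table = precluster(reads, max_diff=1)
        assert len(table) == 2
        assert {a.sequence for a in table.alleles} == {x, z}
        assert table.alleles[0].count == 15

    def test_monotone_in_max_diff(self):
        rng = np.random.default_rng(11)
        pool = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)]
        reads = []
        for i in range(200):
            seq = list(pool[rng.integers(len(pool))])
            if rng.random() < 0.3:
                seq[rng.integers(len(seq))] = "ACGT"[rng.integers(4)]
            reads.append((f"r{i}", "".join(seq)))
        n1 = len(precluster(reads, max_diff=1))
        n2 = len(precluster(reads, max_diff=2))
        n0 = len(precluster(reads, max_diff=0))
        assert n2 <= n1 <= n0

    def test_counts_sum_to_reads(self):
        reads = [("a", "ACGT"), ("b", "ACGA"), ("c", "ACGT"), ("d", "TTTT")]
        table = precluster(reads)
        assert table.total_reads() == 4


class TestChimeraScreen:
    @pytest.fixture()
    def references(self):
        rng = np.random.default_rng(21)
        ref_a = "".join(rng.choice(list("ACGT"), size=200))
        # ~24% divergent second parent: single-parent identity of a
        # half/half chimera (~88%) then falls below the 90% support gate
        ref_b = list(ref_a)
        for i in rng.choice(200, size=48, replace=False):
            ref_b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref_b[i]]
        return ref_a, "".join(ref_b)

    def test_exact_reference_kept(self, references):
        ref_a, ref_b = references
        kept, flagged = chimera_screen(_table({ref_a: 5}), [ref_a, ref_b])
        assert len(flagged) == 0

    def test_crossover_flagged(self, references):
        ref_a, ref_b = references
        chimera = ref_a[:100] + ref_b[100:]
        kept, flagged = chimera_screen(_table({chimera: 3}), [ref_a, ref_b])
        assert len(flagged) == 1
        assert flagged[0].sequence if hasattr(flagged, "__getitem__") else True

    def test_point_mutant_kept(self, references):
        ref_a, ref_b = references
        mutant = "G" + ref_a[1:] if ref_a[0] != "G" else "T" + ref_a[1:]
        kept, flagged = chimera_screen(_table({mutant: 4}), [ref_a, ref_b])
        assert len(flagged) == 0

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            chimera_screen(_table({"ACGT": 1}), [])


class TestDiversity:
    def test_two_abundant_alleles_no_singletons(self):
        # two well-sampled alleles, F1 = 0: Chao1 collapses to S_obs
        est = diversity(_table({"AAAA": 380, "TTTT": 388}))
        assert est.s_obs == 2
        assert est.chao1 == 2.0
        assert (est.lci, est.hci) == (2.0, 2.0)

    def test_bias_corrected_formula(self):
        est = diversity(_table({"AAAA": 1, "CCCC": 1, "GGGG": 2}))
        assert est.f1 == 2 and est.f2 == 1
        assert est.chao1 == pytest.approx(3 + 2 * 1 / (2 * 2))

    def test_single_allele(self):
        est = diversity(_table({"AAAA": 5}))
        assert est.s_obs == 1
        assert est.chao1 == 1.0

    def test_gt1_counting(self):
        est = diversity(_table({"AAAA": 5, "CCCC": 1, "GGGG": 2}))
        assert est.s_obs == 3
        assert est.s_obs_gt1 == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diversity(AlleleTable(alleles=[]))

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1,
                    max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_chao1_lower_bound_property(self, counts):
        table = _table({f"{'ACGT'[i % 4] * 4}{i:04d}": c
                        for i, c in enumerate(counts)})
        est = diversity(table)
        assert est.chao1 >= est.s_obs
        assert est.lci <= est.chao1 <= est.hci
        if est.f1 == 0:
            assert est.chao1 == est.s_obs


class TestRarefaction:
    def test_endpoints(self):
        table = _table({"AAAA": 8, "TTTT": 2})
        curve = rarefaction(table, [1, 10])
        assert curve.points[0] == (1, pytest.approx(1.0))
        assert curve.points[-1] == (10, pytest.approx(2.0))

    def test_matches_monte_carlo(self, rng):
        table = _table({"AAAA": 8, "TTTT": 2})
        expected = rarefaction(table, [5]).points[0][1]
        # draw 100,000 subsamples of 5 of the 10 reads
        draws = rng.hypergeometric(2, 8, 5, size=100000)
        mc = np.mean(1 + (draws > 0) - (draws == 5))
        assert abs(expected - mc) <= 0.01

    def test_nondecreasing(self):
        table = _table({"A" * 4: 5, "C" * 4: 3, "G" * 4: 1, "T" * 4: 1})
        curve = rarefaction(table, list(range(1, 11)))
        values = [s for _, s in curve.points]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_oversized_grid_rejected(self):
        with pytest.raises(ValueError):
            rarefaction(_table({"AAAA": 3}), [4])


class TestEstimateErrorRate:
    def test_identical_reads_zero(self):
        ref = "ACGT" * 100
        rate, excluded = estimate_error_rate([ref[10:200], ref[50:300]], ref)
        assert rate == 0.0
        assert excluded == 0

    def test_single_substitution(self):
        ref = "ACGTTGCA" * 25
        read = ref[:100]
        read = read[:50] + ("A" if read[50] != "A" else "C") + read[51:]
        rate, _ = estimate_error_rate([read], ref)
        assert rate == pytest.approx(0.01)

    def test_unalignable_excluded(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=300))
        junk = "A" * 200  # far below 50% identity to a random reference
        rate, excluded = estimate_error_rate([ref[:150], junk], ref)
        assert excluded == 1
        assert rate == 0.0

    def test_recovers_simulated_error_rate(self):
        from cytohet import AmpliconPool, simulate_amplicons

        ref = "".join(np.random.default_rng(31).choice(list("ACGT"), size=400))
        pool = AmpliconPool(alleles=((ref, 1.0),), error_rate=0.006, seed=32)
        reads, _ = simulate_amplicons(pool, 1000)
        rate, _ = estimate_error_rate(reads, ref)
        se = math.sqrt(0.006 * 0.994 / (1000 * 400))
        assert abs(rate - 0.006) <= max(3 * se, 0.002)
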
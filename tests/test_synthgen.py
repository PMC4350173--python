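"""Generator contracts: lengths, GC, divergence, error model, determinism."""

import edlib
import numpy as np
import pytest

from cytohet import (
    AmpliconPool,
    GenomeSpec,
    NucleusPopulation,
    RepeatFamily,
    RunConfig,
    revcomp,
    simulate_amplicons,
    simulate_genome,
    simulate_nucleus_population,
    simulate_reads,
)


class TestSimulateGenome:
    def test_length_contract(self):
        seq = simulate_genome(GenomeSpec(length=10000, gc=0.5, seed=1))
        assert len(seq) == 10000
        assert set(seq) <= set("ACGT")

    def test_gc_content_recovered(self):
        seq = simulate_genome(GenomeSpec(length=100000, gc=0.28, seed=2))
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.28) <= 0.02

    def test_repeat_copies_recoverable(self):
        fam = RepeatFamily(motif_length=200, copies=50, divergence=0.0)
        spec = GenomeSpec(length=50000, gc=0.28, repeat_families=(fam,), seed=3)
        seq = simulate_genome(spec)
        # recover the motif from the genome itself: with 0 divergence a
        # planted 200-mer recurs exactly once per copy
        from collections import Counter

        counts = Counter(seq[i : i + 200] for i in range(len(seq) - 199))
        assert max(counts.values()) >= 50

    @pytest.mark.parametrize("kwargs", [
        {"length": 0}, {"length": -5}, {"length": 100, "gc": 1.5},
        {"length": 100, "gc": -0.1},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            GenomeSpec(**kwargs)

    def test_deterministic(self):
        a = simulate_genome(GenomeSpec(length=5000, gc=0.4, seed=9))
        b = simulate_genome(GenomeSpec(length=5000, gc=0.4, seed=9))
        assert a == b


class TestNucleusPopulation:
    def test_zero_divergence_identical(self):
        base = simulate_genome(GenomeSpec(length=3000, seed=4))
        pool = simulate_nucleus_population(base, 3, 0.0, seed=5)
        assert all(h == base for h in pool.haplotypes)

    def test_divergence_recovered(self):
        base = simulate_genome(GenomeSpec(length=50000, seed=6))
        pool = simulate_nucleus_population(base, 2, 0.03, seed=7)
        for hap in pool.haplotypes:
            diff = np.mean([a != b for a, b in zip(base, hap)])
            se = np.sqrt(0.03 * 0.97 / len(base))
            assert abs(diff - 0.03) <= 3 * se + 0.005

    def test_homokaryotic_degenerate(self):
        base = simulate_genome(GenomeSpec(length=2000, seed=8))
        pool = simulate_nucleus_population(base, 1, 0.0, proportions=[1.0])
        assert pool.haplotypes == [base]

    def test_bad_proportions_rejected(self):
        base = "ACGT" * 500
        with pytest.raises(ValueError):
            simulate_nucleus_population(base, 2, 0.01, proportions=[0.7, 0.7])

    def test_divergence_bounds(self):
        with pytest.raises(ValueError):
            simulate_nucleus_population("ACGT" * 100, 2, 0.5)


@pytest.fixture(scope="module")
def pool():
    base = simulate_genome(GenomeSpec(length=20000, seed=10))
    return simulate_nucleus_population(base, 2, 0.02, seed=11)


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, pool):
        cfg = RunConfig(n_reads=50, error_rate=0.0, seed=12)
        reads, truth = simulate_reads(pool, cfg)
        assert len(reads) == 50
        for rec, row in zip(reads, truth.itertuples()):
            hap = pool.haplotypes[int(row.haplotype_id[1:])]
            seq = rec.seq if row.strand == "+" else revcomp(rec.seq)
            assert hap[row.start : row.start + len(seq)] == seq

    def test_error_rate_recovered_by_realignment(self, pool):
        cfg = RunConfig(n_reads=2000, error_rate=0.006, seed=13)
        reads, truth = simulate_reads(pool, cfg)
        errors = bases = 0
        for rec, row in zip(reads, truth.itertuples()):
            hap = pool.haplotypes[int(row.haplotype_id[1:])]
            seq = rec.seq if row.strand == "+" else revcomp(rec.seq)
            res = edlib.align(seq, hap, mode="HW", task="distance")
            errors += res["editDistance"]
            bases += len(seq)
        rate = errors / bases
        se = np.sqrt(0.006 * (1 - 0.006) / bases)
        assert abs(rate - 0.006) <= max(3 * se, 0.002)

    def test_invalid_run_configs(self, pool):
        with pytest.raises(ValueError):
            RunConfig(n_reads=0)
        with pytest.raises(ValueError):
            RunConfig(n_reads=10, error_rate=0.5)
        # read length model longer than the haplotypes
        cfg = RunConfig(n_reads=10, read_length_mean=25000,
                        read_length_max=30000, seed=1)
        with pytest.raises(ValueError):
            simulate_reads(pool, cfg)

    def test_deterministic_given_seed(self, pool):
        cfg = RunConfig(n_reads=30, seed=14)
        a, ta = simulate_reads(pool, cfg)
        b, tb = simulate_reads(pool, cfg)
        assert [(r.id, r.seq, r.qual) for r in a] == [
            (r.id, r.seq, r.qual) for r in b
        ]
        assert ta.equals(tb)

    def test_quality_strings_match_length(self, pool):
        cfg = RunConfig(n_reads=20, seed=15)
        reads, _ = simulate_reads(pool, cfg)
        assert all(len(r.qual) == len(r.seq) for r in reads)


class TestSimulateAmplicons:
    def test_single_clean_allele(self):
        allele = simulate_genome(GenomeSpec(length=150, seed=16))
        pool = AmpliconPool(alleles=((allele, 1.0),), chimera_rate=0.0,
                            error_rate=0.0, seed=17)
        reads, truth = simulate_amplicons(pool, 20)
        assert all(r.seq == allele for r in reads)
        assert set(truth.label) == {"0"}

    def test_frequency_recovery(self):
        a = simulate_genome(GenomeSpec(length=150, seed=18))
        b = simulate_genome(GenomeSpec(length=150, seed=19))
        pool = AmpliconPool(alleles=((a, 0.9), (b, 0.1)), error_rate=0.0, seed=20)
        _, truth = simulate_amplicons(pool, 1000)
        p = (truth.label == "0").mean()
        assert abs(p - 0.9) <= 0.03

    def test_chimera_fraction(self):
        a = simulate_genome(GenomeSpec(length=150, seed=21))
        b = simulate_genome(GenomeSpec(length=150, seed=22))
        pool = AmpliconPool(alleles=((a, 0.5), (b, 0.5)), chimera_rate=0.05,
                            error_rate=0.0, seed=23)
        _, truth = simulate_amplicons(pool, 2000)
        frac = (truth.label == "chimera").mean()
        assert abs(frac - 0.05) <= 0.02

    def test_reads_begin_with_forward_primer(self):
        allele = simulate_genome(GenomeSpec(length=120, seed=24))
        pool = AmpliconPool(alleles=((allele, 1.0),), primer_fwd="ACGTACGTAC",
                            primer_rev="GGATCC", seed=25)
        reads, _ = simulate_amplicons(pool, 10)
        assert all(r.seq.startswith("ACGTACGTAC") for r in reads)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            AmpliconPool(alleles=())
        allele = "ACGT" * 30
        with pytest.raises(ValueError):
            AmpliconPool(alleles=((allele, 0.5),))  # frequencies must sum to 1
        pool = AmpliconPool(alleles=((allele, 1.0),))
        with pytest.raises(ValueError):
            simulate_amplicons(pool, 0)
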
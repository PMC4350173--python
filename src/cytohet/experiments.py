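"""Self-contained simulation experiments used for validation.

Each experiment generates its own inputs with the synthetic-data module,
runs the relevant pipeline stages, and reports how well the known truth
was recovered.  They double as the package's reproducibility entry
points: the same functions back the acceptance script and the
acceptance test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ampdiv, homnet, netstats, synthgen

#: mean 454 read length the pipeline is calibrated around (bases)
READ_LENGTH = 336.0


@dataclass(frozen=True)
class HetComparison:
    """One seeded heterokaryotic-vs-homokaryotic network comparison."""

    n_clusters_het: int
    n_clusters_control: int
    high_pid_clusters_het: int
    high_pid_clusters_control: int
    ks: netstats.KSResult


def heterokaryosis_experiment(
    seed: int,
    base_length: int = 150_000,
    divergence: float = 0.03,
    coverage: float = 2.0,
    error_rate: float = 0.006,
) -> HetComparison:
    """Scaled heterokaryotic-vs-homokaryotic network comparison.

    The heterokaryotic pool holds two nucleus classes differing by
    ``divergence``: the base genome and one derived haplotype, sampled
    50/50.  Its homokaryotic control is the same base genome alone,
    sequenced with the same read count — so read count and coverage are
    matched exactly and the only difference between the runs is the
    presence of the second nucleus class.  Both runs are clustered and
    their per-cluster mean-PID distributions compared by the KS test;
    clusters with mean PID in [95, 100] are tallied as the
    high-identity band, where reads sampling the same locus land.
    """
    rng_offsets = np.random.default_rng(seed).integers(1, 2**20, size=4)
    base = synthgen.simulate_genome(
        synthgen.GenomeSpec(length=base_length, gc=0.28, seed=int(rng_offsets[0]))
    )
    derived = synthgen.simulate_nucleus_population(
        base, 1, divergence, seed=int(rng_offsets[1])
    ).haplotypes[0]
    het = synthgen.NucleusPopulation(
        base_genome=base,
        haplotypes=[base, derived],
        proportions=[0.5, 0.5],
        divergence=divergence,
    )
    control = synthgen.NucleusPopulation(
        base_genome=base,
        haplotypes=[base],
        proportions=[1.0],
        divergence=0.0,
    )
    n_reads = max(10, round(coverage * base_length / READ_LENGTH))
    pid_values = {}
    for name, pool in (("het", het), ("control", control)):
        cfg = synthgen.RunConfig(
            n_reads=n_reads, error_rate=error_rate, seed=int(rng_offsets[3])
        )
        reads, _ = synthgen.simulate_reads(pool, cfg)
        edges = homnet.find_homologous_pairs(reads)
        network = homnet.build_network(reads, edges)
        pid_values[name] = [
            netstats.cluster_stats(c).mean_pid for c in network.clusters
        ]
    ks = netstats.compare_runs(pid_values["het"], pid_values["control"])
    in_band = {
        name: sum(1 for p in values if 95.0 <= p <= 100.0)
        for name, values in pid_values.items()
    }
    return HetComparison(
        n_clusters_het=len(pid_values["het"]),
        n_clusters_control=len(pid_values["control"]),
        high_pid_clusters_het=in_band["het"],
        high_pid_clusters_control=in_band["control"],
        ks=ks,
    )


def genome_size_recovery(
    seed: int, genome_length: int = 50_000, coverage: float = 30.0
) -> tuple[netstats.GenomeSizeEstimate, int]:
    """Error-free deep-coverage run; returns (estimate, true length)."""
    genome = synthgen.simulate_genome(
        synthgen.GenomeSpec(length=genome_length, gc=0.28, seed=seed)
    )
    pool = synthgen.NucleusPopulation(
        base_genome=genome, haplotypes=[genome], proportions=[1.0],
        divergence=0.0,
    )
    n_reads = round(coverage * genome_length / READ_LENGTH)
    cfg = synthgen.RunConfig(n_reads=n_reads, error_rate=0.0, seed=seed + 1)
    reads, _ = synthgen.simulate_reads(pool, cfg)
    edges = homnet.find_homologous_pairs(reads)
    network = homnet.build_network(reads, edges)
    return netstats.estimate_min_genome_size(network, reads), genome_length


def make_allele_set(
    seed: int, k: int = 6, length: int = 200, divergence: float = 0.03
) -> list[str]:
    """K marker alleles derived from one ancestor at the given divergence."""
    ancestor = synthgen.simulate_genome(
        synthgen.GenomeSpec(length=length, gc=0.35, seed=seed)
    )
    pool = synthgen.simulate_nucleus_population(
        ancestor, k, divergence, seed=seed + 1
    )
    # enforce mutual distinctness beyond the preclustering radius
    alleles = pool.haplotypes
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            diff = sum(x != y for x, y in zip(alleles[i], alleles[j]))
            if diff <= 2:
                raise ValueError("allele set degenerate; use another seed")
    return alleles


def amplicon_recovery(
    seed: int,
    k: int = 6,
    n_reads: int = 800,
    error_rate: float = 0.006,
    chimera_rate: float = 0.03,
) -> tuple[int, int]:
    """Full amplicon pipeline on a known pool; returns (s_obs_gt1, K).

    Frequencies are drawn well above 5/n so every true allele is
    expected more than once; the pipeline is quality filter ->
    preclustering -> chimera screen (against the true alleles as the
    reference set) -> diversity.
    """
    alleles = make_allele_set(seed * 7 + 1, k=k)
    rng = np.random.default_rng(seed * 7 + 2)
    raw = rng.dirichlet(np.full(k, 4.0))
    floor = 8.0 * max(1, k) / n_reads  # keep every allele well above 5/n
    freqs = raw * (1 - k * floor) + floor
    freqs = freqs / freqs.sum()
    primer = "ACGTGCCTAGGCAT"
    pool = synthgen.AmpliconPool(
        alleles=tuple(zip(alleles, freqs)),
        chimera_rate=chimera_rate,
        error_rate=error_rate,
        primer_fwd=primer,
        quality_score=38,
        seed=seed * 7 + 3,
    )
    reads, _ = synthgen.simulate_amplicons(pool, n_reads)
    kept, _ = ampdiv.quality_filter(reads, ampdiv.FilterPolicy(primer=primer))
    table = ampdiv.precluster(kept, max_diff=1)
    # The reference set here is complete and error-free, so any allele
    # matched below 100% with a crossover gain is a chimera candidate
    # (the default 90% support gate is meant for sparse Sanger databases
    # and cannot trigger for parents under ~20% divergence).  The
    # improvement threshold is coupled to the preclustering radius:
    # crossovers within max_diff of a parent are already absorbed by
    # preclustering, so the screen must flag from max_diff+1 identities
    # of gain upward or chimeras at exactly that distance escape both.
    table, _ = ampdiv.chimera_screen(
        table, alleles, min_support=100.0, improvement_min=2
    )
    estimate = ampdiv.diversity(table, min_count=2)
    return estimate.s_obs_gt1, k


def error_rate_calibration(seed: int, n_reads: int = 2000) -> float:
    """Realigned per-base error estimate for a 0.6%-error shotgun run."""
    genome = synthgen.simulate_genome(
        synthgen.GenomeSpec(length=30_000, gc=0.28, seed=seed)
    )
    pool = synthgen.NucleusPopulation(
        base_genome=genome, haplotypes=[genome], proportions=[1.0],
        divergence=0.0,
    )
    cfg = synthgen.RunConfig(n_reads=n_reads, error_rate=0.006, seed=seed + 1)
    reads, truth = synthgen.simulate_reads(pool, cfg)
    oriented = [
        r.seq if row.strand == "+" else synthgen.revcomp(r.seq)
        for r, row in zip(reads, truth.itertuples())
    ]
    rate, _ = ampdiv.estimate_error_rate(oriented, genome)
    return rate


def gc_calibration(seed: int, length: int = 100_000, gc: float = 0.28) -> float:
    """Empirical GC of a simulated genome at the target composition."""
    seq = synthgen.simulate_genome(
        synthgen.GenomeSpec(length=length, gc=gc, seed=seed)
    )
    return (seq.count("G") + seq.count("C")) / len(seq)
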
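"""Synthetic data generation with known ground truth.

Every input the heterogeneity pipeline consumes can be produced here:
background genomes with controlled GC and repeat content, populations of
divergent nucleus haplotypes sharing one cytoplasm, 454-style shotgun
reads with homopolymer-biased errors, and amplicon pools with PCR-chimera
contamination.  All generators are deterministic given their seed and
return truth tables so downstream estimates can be checked against the
parameters that produced the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genomes


@dataclass(frozen=True)
class RepeatFamily:
    """An interspersed repeat family planted into a simulated genome.

    ``divergence`` is the expected per-site substitution fraction of each
    planted copy relative to the family consensus motif.
    """

    motif_length: int
    copies: int
    divergence: float = 0.0


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters for a simulated haploid background genome.

    ``gc`` defaults to 0.28, the GC content typical of Rhizophagus
    irregularis; control genomes in the 0.33-0.46 range can be produced
    by overriding it.
    """

    length: int
    gc: float = 0.28
    repeat_families: tuple[RepeatFamily, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be a fraction in [0, 1]")
        occupied = sum(f.motif_length * f.copies for f in self.repeat_families)
        if occupied > self.length:
            raise ValueError("repeat families exceed genome length")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Per-base Bernoulli on {G,C} vs {A,T}, uniform within each pair."""
    is_gc = rng.random(n) < gc
    pick = rng.integers(0, 2, n)
    out = np.empty(n, dtype="<U1")
    out[is_gc & (pick == 0)] = "G"
    out[is_gc & (pick == 1)] = "C"
    out[~is_gc & (pick == 0)] = "A"
    out[~is_gc & (pick == 1)] = "T"
    return out


def _mutate_substitutions(
    rng: np.random.Generator, seq: np.ndarray, rate: float
) -> np.ndarray:
    """Independent per-site substitutions to one of the three other bases."""
    seq = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    for i in hits:
        choices = [b for b in _BASES if b != seq[i]]
        seq[i] = choices[rng.integers(0, 3)]
    return seq


def simulate_genome(spec: GenomeSpec) -> str:
    """Generate a genome of exactly ``spec.length`` bases over {A,C,G,T}.

    Declared repeat copies are written over the random background at
    non-overlapping positions, so they are recoverable by (near-)exact
    search.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genome = _random_bases(rng, spec.length, spec.gc)
    occupied: list[tuple[int, int]] = []
    for fam in spec.repeat_families:
        motif = _random_bases(rng, fam.motif_length, spec.gc)
        placed = 0
        attempts = 0
        while placed < fam.copies:
            attempts += 1
            if attempts > 1000 * fam.copies:
                raise ValueError("could not place repeat copies without overlap")
            start = int(rng.integers(0, spec.length - fam.motif_length + 1))
            span = (start, start + fam.motif_length)
            if any(span[0] < e and s < span[1] for s, e in occupied):
                continue
            copy = _mutate_substitutions(rng, motif, fam.divergence)
            genome[span[0] : span[1]] = copy
            occupied.append(span)
            placed += 1
    return "".join(genome)


# ---------------------------------------------------------------------------
# nucleus populations


@dataclass
class NucleusPopulation:
    """A pool of nucleus haplotypes sharing one cytoplasm.

    ``haplotypes`` are full-length copies of ``base_genome`` carrying
    independent per-site substitutions at the configured ``divergence``;
    ``proportions`` are the sampling weights of each haplotype in the
    pool (they must sum to 1).  A homokaryotic pool is the degenerate
    case of a single haplotype at proportion 1.
    """

    base_genome: str
    haplotypes: list[str]
    proportions: list[float]
    divergence: float

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.proportions):
            raise ValueError("one proportion per haplotype required")
        if any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be nonnegative")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


def simulate_nucleus_population(
    base: str,
    n_haplotypes: int,
    divergence: float,
    proportions: Sequence[float] | None = None,
    seed: int = 0,
) -> NucleusPopulation:
    """Derive ``n_haplotypes`` divergent copies of ``base``.

    Each haplotype receives independent substitutions at per-site rate
    ``divergence`` (0 <= divergence <= 0.2).  With ``divergence=0`` the
    pool is homokaryotic in sequence even if multiple nuclei are drawn.
    """
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    if n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    if proportions is None:
        proportions = [1.0 / n_haplotypes] * n_haplotypes
    proportions = list(map(float, proportions))
    rng = np.random.default_rng(seed)
    arr = np.array(list(base), dtype="<U1")
    haplotypes = [
        "".join(_mutate_substitutions(rng, arr, divergence))
        for _ in range(n_haplotypes)
    ]
    return NucleusPopulation(
        base_genome=base,
        haplotypes=haplotypes,
        proportions=proportions,
        divergence=divergence,
    )


# ---------------------------------------------------------------------------
# shotgun reads


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a simulated 454-style shotgun run.

    Defaults mirror the sequencing technology this pipeline was designed
    around: mean read length 336 bp and a per-base error rate of 0.6%
    (0.006).  ``homopolymer_weight`` is the fraction of errors realized
    as +/-1 length changes of the homopolymer run containing the error
    position; the remainder are uniform substitutions.
    """

    n_reads: int
    read_length_mean: float = 336.0
    read_length_sd: float = 40.0
    read_length_min: int = 100
    read_length_max: int = 600
    error_rate: float = 0.006
    homopolymer_weight: float = 0.5
    quality_score: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if not (
            self.read_length_min <= self.read_length_mean <= self.read_length_max
        ):
            raise ValueError("require read_length_min <= mean <= max")
        if not 0.0 <= self.homopolymer_weight <= 1.0:
            raise ValueError("homopolymer_weight must be a fraction")


@dataclass
class ReadRecord:
    """A sequencing read; ``qual`` is an offset-33 quality string."""

    id: str
    seq: str
    qual: str | None = None
    description: str = ""


def _quality_char(error_rate: float, quality_score: int | None = None) -> str:
    """Constant offset-33 quality character.

    By default the score is the Phred equivalent of the configured error
    rate.  ``quality_score`` overrides it: 454 basecallers assign high
    confidence to the homopolymer miscalls that dominate the platform's
    errors, so a run can realistically emit q38 bases while its realized
    per-base error rate is 0.6%.
    """
    if quality_score is not None:
        q = min(40, max(2, int(quality_score)))
    else:
        q = 40 if error_rate <= 0 else min(
            40, max(2, round(-10 * math.log10(error_rate)))
        )
    return chr(33 + q)


def _homopolymer_run(seq: list[str], pos: int) -> tuple[int, int]:
    """Half-open bounds of the homopolymer run containing ``pos``."""
    base = seq[pos]
    lo = pos
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = pos + 1
    while hi < len(seq) and seq[hi] == base:
        hi += 1
    return lo, hi


def _inject_errors(
    rng: np.random.Generator,
    seq: str,
    error_rate: float,
    homopolymer_weight: float,
) -> tuple[str, int]:
    """Inject substitution and homopolymer-indel errors; returns (seq, n)."""
    if error_rate <= 0:
        return seq, 0
    positions = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if positions.size == 0:
        return seq, 0
    chars = list(seq)
    # right-to-left so earlier indices stay valid across indels
    for pos in positions[::-1]:
        pos = int(pos)
        lo, hi = _homopolymer_run(chars, pos)
        # flow-space indel miscalls require an actual run: errors at
        # singleton positions always realize as substitutions
        if hi - lo >= 2 and rng.random() < homopolymer_weight:
            if rng.random() < 0.5:
                chars.insert(pos, chars[pos])  # run grows by one
            else:
                del chars[pos]  # run shrinks by one
        else:
            choices = [b for b in _BASES if b != chars[pos]]
            chars[pos] = choices[rng.integers(0, 3)]
    return "".join(chars), int(positions.size)


def _draw_length(rng: np.random.Generator, cfg: RunConfig) -> int:
    """Truncated-normal read length (resampling; falls back to clipping)."""
    for _ in range(100):
        x = rng.normal(cfg.read_length_mean, cfg.read_length_sd)
        if cfg.read_length_min <= x <= cfg.read_length_max:
            return int(round(x))
    return int(min(max(cfg.read_length_mean, cfg.read_length_min), cfg.read_length_max))


def simulate_reads(
    pool: NucleusPopulation, cfg: RunConfig
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a shotgun run over a nucleus population.

    Read start positions are uniform along the source haplotype, the
    haplotype of origin is sampled by the pool proportions, and both it
    and the placement are recorded in the read description and in the
    returned truth table (columns: read_id, haplotype_id, start, strand,
    n_errors).
    """
    shortest = min(len(h) for h in pool.haplotypes)
    if cfg.read_length_max >= shortest:
        raise ValueError("read length model exceeds haplotype length")
    rng = np.random.default_rng(cfg.seed)
    qchar = _quality_char(cfg.error_rate, cfg.quality_score)
    hap_idx = rng.choice(len(pool.haplotypes), size=cfg.n_reads, p=pool.proportions)
    records: list[ReadRecord] = []
    truth = []
    for i in range(cfg.n_reads):
        h = int(hap_idx[i])
        hap = pool.haplotypes[h]
        length = _draw_length(rng, cfg)
        start = int(rng.integers(0, len(hap) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = hap[start : start + length]
        if strand == "-":
            seq = revcomp(seq)
        seq, n_err = _inject_errors(rng, seq, cfg.error_rate, cfg.homopolymer_weight)
        rid = f"r{i:06d}"
        hap_id = f"h{h}"
        records.append(
            ReadRecord(
                id=rid,
                seq=seq,
                qual=qchar * len(seq),
                description=f"hap={hap_id} start={start} strand={strand} errors={n_err}",
            )
        )
        truth.append((rid, hap_id, start, strand, n_err))
    truth_df = pd.DataFrame(
        truth, columns=["read_id", "haplotype_id", "start", "strand", "n_errors"]
    )
    return records, truth_df


# ---------------------------------------------------------------------------
# amplicon pools


@dataclass(frozen=True)
class AmpliconPool:
    """A pool of marker alleles amplified and sequenced as amplicons.

    ``alleles`` maps allele sequences (marker region only, primers
    excluded) to their true frequencies, which must sum to 1.  A
    ``chimera_rate`` fraction of reads is formed by a single crossover
    between two distinct parent alleles, emulating PCR chimera
    formation.  Primers are emitted verbatim at the read ends so primer
    screening can be exercised downstream.
    """

    alleles: tuple[tuple[str, float], ...]
    chimera_rate: float = 0.0
    error_rate: float = 0.006
    primer_fwd: str = ""
    primer_rev: str = ""
    quality_score: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("allele list must be nonempty")
        total = sum(f for _, f in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must be a fraction")


def simulate_amplicons(
    pool: AmpliconPool, n_reads: int
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw amplicon reads from an allele pool.

    Returns records plus a truth table (read_id, label, parent_a,
    parent_b, crossover, n_errors) where ``label`` is the source allele
    index or ``"chimera"``.  Sequencing errors are injected into the
    marker region; primer sequences are emitted intact.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(pool.seed)
    seqs = [s for s, _ in pool.alleles]
    freqs = np.array([f for _, f in pool.alleles], dtype=float)
    freqs = freqs / freqs.sum()
    qchar = _quality_char(pool.error_rate, pool.quality_score)
    records: list[ReadRecord] = []
    truth = []
    for i in range(n_reads):
        is_chimera = len(seqs) >= 2 and rng.random() < pool.chimera_rate
        if is_chimera:
            a = int(rng.choice(len(seqs), p=freqs))
            b = a
            while b == a:
                b = int(rng.choice(len(seqs), p=freqs))
            point = int(rng.integers(1, min(len(seqs[a]), len(seqs[b]))))
            core = seqs[a][:point] + seqs[b][point:]
            label, pa, pb, cross = "chimera", a, b, point
        else:
            a = int(rng.choice(len(seqs), p=freqs))
            core = seqs[a]
            label, pa, pb, cross = str(a), a, -1, -1
        core, n_err = _inject_errors(rng, core, pool.error_rate, 0.5)
        seq = pool.primer_fwd + core + revcomp(pool.primer_rev)
        rid = f"a{i:06d}"
        records.append(
            ReadRecord(
                id=rid,
                seq=seq,
                qual=qchar * len(seq),
                description=f"label={label}",
            )
        )
        truth.append((rid, label, pa, pb, cross, n_err))
    truth_df = pd.DataFrame(
        truth,
        columns=["read_id", "label", "parent_a", "parent_b", "crossover", "n_errors"],
    )
    return records, truth_df
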
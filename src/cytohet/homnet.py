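"""Sequence similarity network construction from shotgun reads.

Homologous read pairs are those whose best local alignment (either
strand) reaches at least ``min_identical`` identical nucleotides and a
PID of at least ``min_pid``, where PID is the percentage of identical
positions relative to the full length of the shorter read of the pair —
a deliberately conservative identity measure.  Accepted pairs become
edges; connected components of two or more reads are clusters, and the
remaining reads are singletons.

Candidate pairs are proposed by a shared-k-mer index (both strands) and
then verified by optimal local alignment with affine gap scoring
(match +1, mismatch -2, gap open -3, gap extend -1).  A
Karlin-Altschul-style e-value computed from the alignment score, the
shorter read length and the total bases in the run stands in for the
original BLAT e-value; its parameters are documented rather than claimed
identical to BLAT's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence
from zlib import crc32

import networkx as nx
from Bio import Align
from scipy.optimize import brentq

from .synthgen import ReadRecord, revcomp

# Karlin-Altschul lambda for +1/-2 scoring under uniform base composition:
# solve (1/4) e^l + (3/4) e^{-2l} = 1 for l > 0.
_KA_LAMBDA = brentq(
    lambda lam: 0.25 * math.exp(lam) + 0.75 * math.exp(-2 * lam) - 1.0, 1e-6, 5.0
)
_KA_K = 0.3


@dataclass(frozen=True)
class EdgePolicy:
    """Thresholds deciding whether an aligned read pair becomes an edge.

    Defaults are the conservative published thresholds this pipeline is
    built around: at least 25% identity over the shorter read, at least
    75 identical nucleotides, and an e-value of at most 1e-20.
    ``kmer_size``/``min_kmer_hits``/``max_kmer_occ`` tune the seeding
    heuristic only; they never relax the alignment thresholds.
    """

    min_pid: float = 25.0
    min_identical: int = 75
    max_evalue: float = 1e-20
    kmer_size: int = 11
    min_overlap: int = 1
    # Seeding works on a deterministic 1-in-kmer_sample subset of k-mers
    # (CRC selection, identical on both sides of a comparison), so a
    # genuine edge — >= 75 identical bases, hence dozens of clean 11-mer
    # windows — still shares ~16 sampled k-mers while chance matches in
    # low-GC reads are suppressed quadratically.
    min_kmer_hits: int = 2
    max_kmer_occ: int = 500
    kmer_sample: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.min_pid <= 100.0:
            raise ValueError("min_pid must be in (0, 100]")
        if self.min_identical < 1:
            raise ValueError("min_identical must be >= 1")
        if self.kmer_size < 4:
            raise ValueError("kmer_size must be >= 4")


@dataclass(frozen=True)
class HomologyEdge:
    """An accepted homologous read pair.

    ``pid`` is 100 * identical_positions / shorter_len with
    ``shorter_len`` the full length of the shorter read.  ``strand`` is
    the orientation of ``read_b`` relative to ``read_a`` in the best
    alignment; the alignment footprint (query/target start and end, with
    ``read_b`` coordinates given in its aligned orientation) is kept so
    clusters can later be laid out for span estimation.
    """

    read_a: str
    read_b: str
    identical_positions: int
    shorter_len: int
    pid: float
    evalue: float
    strand: str = "+"
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0
    score: float = 0.0


@dataclass
class ReadCluster:
    """A connected component of >= 2 reads in the similarity network."""

    cluster_id: str
    member_read_ids: set[str]
    edges: list[HomologyEdge]


@dataclass
class NetworkResult:
    """Partition of a read set into clusters and singletons."""

    clusters: list[ReadCluster]
    singletons: list[str]

    def n_reads(self) -> int:
        return sum(len(c.member_read_ids) for c in self.clusters) + len(
            self.singletons
        )


def _as_seq_dict(reads: Iterable) -> dict[str, str]:
    """Normalize read input (records or (id, seq) pairs) to an id->seq map."""
    out: dict[str, str] = {}
    for r in reads:
        if isinstance(r, tuple):
            rid, seq = r
        else:
            rid, seq = r.id, str(r.seq)
        if rid in out:
            raise ValueError(f"duplicate read id: {rid}")
        out[rid] = seq.upper()
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


def _count_identities(alignment, seq_a: str, seq_b: str) -> int:
    """Identical aligned positions; N never counts as identical."""
    ident = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]):
            if x == y and x != "N":
                ident += 1
    return ident


def evalue(score: float, shorter_len: int, database_bases: int) -> float:
    """Karlin-Altschul style e-value for a local alignment score."""
    return _KA_K * shorter_len * max(database_bases, 1) * math.exp(-_KA_LAMBDA * score)


def _kmer_positions(seq: str, k: int, sample: int = 1) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        if sample > 1 and crc32(kmer.encode()) % sample:
            continue
        yield kmer


def _candidate_pairs(
    ids: list[str], seqs: list[str], policy: EdgePolicy
) -> dict[tuple[int, int], dict[str, str]]:
    """Propose read pairs sharing sampled k-mers.

    Index holds forward k-mers; each read is queried with both its
    forward and reverse-complement k-mers, so a pair is proposed in an
    orientation iff the two reads share a k-mer in that orientation.
    Overabundant k-mers (more than ``max_kmer_occ`` reads) are dropped
    to keep pair generation near-linear in genuine overlaps.  Values
    map each seeded orientation to one witness k-mer, which the
    verification step uses for its exact-overlap fast path.
    """
    k = policy.kmer_size
    sample = max(1, policy.kmer_sample)
    index: dict[str, list[int]] = {}
    for idx, seq in enumerate(seqs):
        seen = set()
        for kmer in _kmer_positions(seq, k, sample):
            if kmer not in seen:
                index.setdefault(kmer, []).append(idx)
                seen.add(kmer)
    hits: dict[tuple[int, int, str], int] = {}
    witness: dict[tuple[int, int, str], str] = {}
    for idx, seq in enumerate(seqs):
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            seen = set()
            for kmer in _kmer_positions(query, k, sample):
                if kmer in seen:
                    continue
                seen.add(kmer)
                occ = index.get(kmer)
                if occ is None or len(occ) > policy.max_kmer_occ:
                    continue
                for jdx in occ:
                    if jdx <= idx:
                        continue
                    key = (idx, jdx, strand)
                    hits[key] = hits.get(key, 0) + 1
                    witness.setdefault(key, kmer)
    pairs: dict[tuple[int, int], dict[str, str]] = {}
    for (idx, jdx, strand), n in hits.items():
        if n >= policy.min_kmer_hits:
            pairs.setdefault((idx, jdx), {})[strand] = witness[(idx, jdx, strand)]
    return pairs


def _exact_overlap(seq_a: str, target: str, kmer: str):
    """Maximal exact overlap on the diagonal implied by a shared k-mer.

    Returns (ident, a0, a1, b0, b1) when the two reads agree verbatim
    over the full diagonal intersection and that overlap reaches a read
    end on both sides — the optimal local alignment for pairs without
    errors in the overlap — else None.
    """
    pa = seq_a.find(kmer)
    pb = target.find(kmer)
    if pa < 0 or pb < 0:
        return None
    d = pa - pb
    a0 = max(0, d)
    a1 = min(len(seq_a), d + len(target))
    if a1 - a0 < 1:
        return None
    if seq_a[a0:a1] != target[a0 - d : a1 - d]:
        return None
    if "N" in seq_a[a0:a1]:
        return None
    return a1 - a0, a0, a1, a0 - d, a1 - d


def align_pair(
    seq_a: str,
    seq_b: str,
    policy: EdgePolicy,
    database_bases: int,
    aligner: Align.PairwiseAligner | None = None,
    orientations: Sequence[str] = ("+", "-"),
    seed_kmers: Mapping[str, str] | None = None,
) -> HomologyEdge | None:
    """Best-orientation local alignment of a read pair, thresholded.

    Returns an edge (without ids filled in) when the pair passes all
    thresholds, else None.  Ties between orientations break toward
    forward.  When a witness ``seed_kmers[strand]`` is supplied and the
    pair agrees verbatim over the whole diagonal overlap it implies,
    the alignment is taken directly from that overlap (the optimal
    local alignment in the error-free case) without running the
    aligner.
    """
    if aligner is None:
        aligner = _make_aligner()
    shorter_len = min(len(seq_a), len(seq_b))
    best = None
    for strand in orientations:
        target = seq_b if strand == "+" else revcomp(seq_b)
        if seed_kmers and strand in seed_kmers:
            # witnesses for "-" were found on read A's reverse strand;
            # express them in this frame (A forward, B complemented)
            wit = seed_kmers[strand] if strand == "+" else revcomp(seed_kmers[strand])
            fast = _exact_overlap(seq_a, target, wit)
            if fast is not None:
                ident, a0, a1, b0, b1 = fast
                if best is None or ident > best[0]:
                    best = (ident, strand, float(ident), a0, a1, b0, b1)
                continue
        try:
            alns = aligner.align(seq_a, target)
            aln = alns[0]
        except (ValueError, IndexError):
            continue
        ident = _count_identities(aln, seq_a, target)
        if best is None or ident > best[0]:
            blocks_a, blocks_b = aln.aligned
            best = (
                ident,
                strand,
                float(aln.score),
                int(blocks_a[0][0]),
                int(blocks_a[-1][1]),
                int(blocks_b[0][0]),
                int(blocks_b[-1][1]),
            )
    if best is None:
        return None
    ident, strand, score, a0, a1, b0, b1 = best
    pid = 100.0 * ident / shorter_len
    ev = evalue(score, shorter_len, database_bases)
    if (
        ident >= policy.min_identical
        and pid >= policy.min_pid
        and ev <= policy.max_evalue
        and (a1 - a0) >= policy.min_overlap
    ):
        return HomologyEdge(
            read_a="",
            read_b="",
            identical_positions=ident,
            shorter_len=shorter_len,
            pid=pid,
            evalue=ev,
            strand=strand,
            a_start=a0,
            a_end=a1,
            b_start=b0,
            b_end=b1,
            score=score,
        )
    return None


def find_homologous_pairs(
    reads: Iterable, policy: EdgePolicy | None = None
) -> list[HomologyEdge]:
    """All read pairs passing the identity/PID/e-value thresholds.

    Pairs are proposed by shared k-mers (both strands) and verified by
    optimal local alignment; the returned edge list is symmetric by
    construction (each unordered pair appears once, read_a < read_b
    lexicographically was NOT imposed — ids keep index order) and
    deduplicated.
    """
    if policy is None:
        policy = EdgePolicy()
    seq_map = _as_seq_dict(reads)
    ids = list(seq_map)
    seqs = [seq_map[i] for i in ids]
    database_bases = sum(len(s) for s in seqs)
    aligner = _make_aligner()
    edges: list[HomologyEdge] = []
    pairs = _candidate_pairs(ids, seqs, policy)
    for (idx, jdx), seed_kmers in sorted(pairs.items()):
        order = [s for s in ("+", "-") if s in seed_kmers]
        edge = align_pair(
            seqs[idx], seqs[jdx], policy, database_bases, aligner, order,
            seed_kmers,
        )
        if edge is not None:
            edges.append(
                HomologyEdge(
                    read_a=ids[idx],
                    read_b=ids[jdx],
                    identical_positions=edge.identical_positions,
                    shorter_len=edge.shorter_len,
                    pid=edge.pid,
                    evalue=edge.evalue,
                    strand=edge.strand,
                    a_start=edge.a_start,
                    a_end=edge.a_end,
                    b_start=edge.b_start,
                    b_end=edge.b_end,
                    score=edge.score,
                )
            )
    return edges


def build_network(reads: Iterable, edges: Sequence[HomologyEdge]) -> NetworkResult:
    """Group reads into clusters (connected components) and singletons.

    Clusters are components with >= 2 members; every other read is a
    singleton, so the partition is total over the input read set.
    """
    seq_map = _as_seq_dict(reads)
    graph = nx.Graph()
    graph.add_nodes_from(seq_map)
    for e in edges:
        if e.read_a not in seq_map or e.read_b not in seq_map:
            raise ValueError(f"edge endpoint not among reads: {e.read_a}/{e.read_b}")
        graph.add_edge(e.read_a, e.read_b)
    clusters: list[ReadCluster] = []
    singletons: list[str] = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    comp_of: dict[str, int] = {}
    comp_index: dict[int, int] = {}
    for ci, comp in enumerate(components):
        if len(comp) < 2:
            singletons.extend(comp)
            continue
        comp_index[ci] = len(clusters)
        for rid in comp:
            comp_of[rid] = ci
        clusters.append(
            ReadCluster(
                cluster_id=f"c{len(clusters):05d}",
                member_read_ids=set(comp),
                edges=[],
            )
        )
    for e in edges:
        clusters[comp_index[comp_of[e.read_a]]].edges.append(e)
    singletons.sort()
    return NetworkResult(clusters=clusters, singletons=singletons)
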
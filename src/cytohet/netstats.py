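"""Cluster statistics, run summaries, KS comparisons and size estimates.

Two per-cluster variables describe the similarity network.  The mean PID
(average over the cluster's aligned pairs of the percentage of identical
positions on the shorter read) measures how similar the clustered
sequences are; the clustering coefficient (number of aligned pairs
divided by the maximum possible number of pairs, i.e. graph density)
measures how completely they overlap each other.  Distributions of these
variables across runs are compared with a two-tailed two-sample
Kolmogorov-Smirnov test, and a conservative minimum genome (or
pangenome) size is obtained by summing cluster layout spans and
singleton lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .homnet import NetworkResult, ReadCluster
from .homnet import _as_seq_dict


@dataclass(frozen=True)
class ClusterStats:
    cluster_id: str
    n_reads: int
    mean_pid: float
    clustering_coefficient: float


@dataclass(frozen=True)
class RunSummary:
    """Per-run aggregates over clusters (unweighted across clusters)."""

    n_clusters: int
    mean_reads_per_cluster: float
    mean_pid: float
    sd_pid: float
    mean_clustering_coefficient: float
    n_singletons: int


@dataclass(frozen=True)
class KSResult:
    statistic_D: float
    p_value: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """Minimum genome size: cluster layout spans plus singleton lengths."""

    total_bp: int
    cluster_span_bp: int
    singleton_bp: int


def cluster_stats(cluster: ReadCluster) -> ClusterStats:
    """Mean edge PID and density (pairs / max possible pairs) of a cluster."""
    n = len(cluster.member_read_ids)
    if n < 2:
        raise ValueError("cluster must have at least 2 members")
    # density counts distinct read pairs, not parallel edge records
    n_pairs = len({frozenset((e.read_a, e.read_b)) for e in cluster.edges})
    coefficient = n_pairs / (n * (n - 1) / 2)
    mean_pid = float(np.mean([e.pid for e in cluster.edges]))
    return ClusterStats(
        cluster_id=cluster.cluster_id,
        n_reads=n,
        mean_pid=mean_pid,
        clustering_coefficient=coefficient,
    )


def per_cluster_table(result: NetworkResult) -> pd.DataFrame:
    """Per-cluster (n_reads, mean_pid, clustering_coefficient) table."""
    rows = [cluster_stats(c) for c in result.clusters]
    return pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in rows],
            "n_reads": [r.n_reads for r in rows],
            "mean_pid": [r.mean_pid for r in rows],
            "clustering_coefficient": [r.clustering_coefficient for r in rows],
        }
    )


def pid_histogram(result: NetworkResult, bin_width: float = 1.0) -> pd.DataFrame:
    """Histogram of per-cluster mean PID in fixed-width (default 1-pt) bins."""
    pids = [cluster_stats(c).mean_pid for c in result.clusters]
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(pids, bins=edges)
    return pd.DataFrame({"pid_bin_low": edges[:-1], "n_clusters": counts})


def summarize_run(result: NetworkResult) -> RunSummary:
    """Table-1-style aggregates; zero clusters yields a summary of zeros."""
    stats = [cluster_stats(c) for c in result.clusters]
    if not stats:
        return RunSummary(0, 0.0, 0.0, 0.0, 0.0, len(result.singletons))
    pids = np.array([s.mean_pid for s in stats])
    return RunSummary(
        n_clusters=len(stats),
        mean_reads_per_cluster=float(np.mean([s.n_reads for s in stats])),
        mean_pid=float(np.mean(pids)),
        sd_pid=float(np.std(pids, ddof=1)) if len(pids) > 1 else 0.0,
        mean_clustering_coefficient=float(
            np.mean([s.clustering_coefficient for s in stats])
        ),
        n_singletons=len(result.singletons),
    )


def compare_runs(
    pid_values_a: Sequence[float], pid_values_b: Sequence[float]
) -> KSResult:
    """Two-tailed two-sample KS test by exact ECDF sweep.

    D is the exact supremum ECDF difference over the pooled points; the
    p-value uses the two-sided asymptotic Kolmogorov distribution with
    effective sample size n_a*n_b/(n_a+n_b).  Applicable to any
    per-cluster statistic (PID or clustering coefficient).
    """
    a = np.sort(np.asarray(pid_values_a, dtype=float))
    b = np.sort(np.asarray(pid_values_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = math.sqrt(a.size * b.size / (a.size + b.size))
    p = float(kolmogorov(en * d))
    return KSResult(statistic_D=d, p_value=min(1.0, p), n_a=a.size, n_b=b.size)


def _layout_cluster(cluster: ReadCluster, lengths: dict[str, int]) -> int:
    """Span of a cluster laid out along a maximum-identity spanning tree.

    Edges carry the local-alignment footprint of each accepted pair;
    offsets are propagated from an arbitrary root along a maximum
    spanning tree (weight = identical_positions, ties broken toward the
    lexicographically smaller read pair), and the span is the extent of
    the placed reads.  An approximation to contig length that needs no
    assembler.
    """
    graph = nx.Graph()
    graph.add_nodes_from(cluster.member_read_ids)
    for e in cluster.edges:
        key = (e.identical_positions, e.read_a, e.read_b)
        if (
            not graph.has_edge(e.read_a, e.read_b)
            or graph.edges[e.read_a, e.read_b]["key"] < key
        ):
            graph.add_edge(e.read_a, e.read_b, weight=e.identical_positions,
                           key=key, edge=e)
    tree = nx.maximum_spanning_tree(graph, weight="weight")
    root = sorted(cluster.member_read_ids)[0]
    pos: dict[str, int] = {root: 0}
    orient: dict[str, str] = {root: "+"}
    for parent, child in nx.bfs_edges(tree, root):
        e = tree.edges[parent, child]["edge"]
        if e.read_a == parent:
            # child is read_b, whose footprint coords are in its aligned
            # orientation relative to a-forward
            la, lb = lengths[parent], lengths[child]
            qa0, qa1, qb0, qb1, st = e.a_start, e.a_end, e.b_start, e.b_end, e.strand
        else:
            # swap roles: express the alignment with parent as "a"
            la, lb = lengths[parent], lengths[child]
            if e.strand == "+":
                qa0, qa1 = e.b_start, e.b_end
                qb0, qb1 = e.a_start, e.a_end
            else:
                # b was reverse-complemented in the stored footprint;
                # mirror both footprints to express parent forward
                qa0 = lengths[parent] - e.b_end
                qa1 = lengths[parent] - e.b_start
                qb0 = lengths[child] - e.a_end
                qb1 = lengths[child] - e.a_start
            st = e.strand
        if orient[parent] == "+":
            pos[child] = pos[parent] + (qa0 - qb0)
            orient[child] = st
        else:
            pos[child] = pos[parent] + (la - qa1) - (lb - qb1)
            orient[child] = "-" if st == "+" else "+"
    left = min(pos[r] for r in pos)
    right = max(pos[r] + lengths[r] for r in pos)
    return right - left


def estimate_min_genome_size(
    result: NetworkResult, reads: Iterable
) -> GenomeSizeEstimate:
    """Conservative minimum genome/pangenome size from a built network.

    ``singleton_bp`` sums singleton read lengths; ``cluster_span_bp``
    sums the layout span of each cluster (see ``_layout_cluster``).
    """
    seq_map = _as_seq_dict(reads)
    lengths = {rid: len(s) for rid, s in seq_map.items()}
    for c in result.clusters:
        for rid in c.member_read_ids:
            if rid not in lengths:
                raise ValueError(f"cluster member {rid} not among reads")
    for rid in result.singletons:
        if rid not in lengths:
            raise ValueError(f"singleton {rid} not among reads")
    singleton_bp = sum(lengths[r] for r in result.singletons)
    cluster_span_bp = sum(_layout_cluster(c, lengths) for c in result.clusters)
    return GenomeSizeEstimate(
        total_bp=cluster_span_bp + singleton_bp,
        cluster_span_bp=cluster_span_bp,
        singleton_bp=singleton_bp,
    )
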
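"""Amplicon allele calling and diversity estimation.

Reads from amplicon pyrosequencing of a putative single-copy marker are
quality filtered by four rules (perfect primer/adaptor match, no
ambiguous bases, mean quality >= 35 in every 50-bp window, no
homopolymer longer than 8 bp), preclustered so that reads differing by
just 1 bp merge into the more abundant sequence, screened for PCR
chimeras against a reference allele set, and finally summarized as an
allele abundance table.  Richness is described by the observed allele
count, the count of alleles seen more than once, rarefaction, and the
bias-corrected Chao1 minimum-richness estimator with its log-normal 95%
confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import Align
from scipy.special import gammaln

from .synthgen import ReadRecord

_VALID = set("ACGT")


@dataclass(frozen=True)
class FilterPolicy:
    """Quality-filter rules; defaults encode the pipeline's four rules."""

    window: int = 50
    min_window_quality: float = 35.0
    max_homopolymer: int = 8
    primer: str = ""
    adaptor: str = ""
    allow_ambiguous: bool = False
    max_mismatch_primer: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class Allele:
    sequence: str
    count: int
    member_read_ids: list[str] = field(default_factory=list)


@dataclass
class AlleleTable:
    """Allele sequences with abundances; counts sum to surviving reads."""

    alleles: list[Allele]

    def counts(self) -> list[int]:
        return [a.count for a in self.alleles]

    def total_reads(self) -> int:
        return sum(a.count for a in self.alleles)

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class DiversityEstimate:
    """Observed and Chao1-extrapolated allele richness.

    ``f1``/``f2`` are singleton/doubleton allele counts.  Chao1 is the
    bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)); with F1=0 it
    equals S_obs, and the CI then collapses to [S_obs, S_obs].
    """

    s_obs: int
    s_obs_gt1: int
    f1: int
    f2: int
    chao1: float
    lci: float
    hci: float


@dataclass(frozen=True)
class RarefactionCurve:
    points: tuple[tuple[int, float], ...]


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return best if seq else 0


def _window_quality_ok(qual: str, policy: FilterPolicy) -> bool:
    scores = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - 33
    w = policy.window
    if scores.size <= w:
        return float(scores.mean()) >= policy.min_window_quality
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    means = (csum[w:] - csum[:-w]) / w
    return float(means.min()) >= policy.min_window_quality


def quality_filter(
    reads: Iterable[ReadRecord], policy: FilterPolicy | None = None
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Apply the four elimination rules; returns kept reads and tallies.

    Rules, applied in order (a read is tallied under the first one it
    fails): 1) imperfect adaptor+primer match at the read start (the
    matched prefix is trimmed from kept reads); 2) ambiguous bases;
    3) mean quality below 35 in some 50-bp window; 4) a homopolymer
    longer than 8 bp (checked after primer trimming).
    """
    if policy is None:
        policy = FilterPolicy()
    prefix = (policy.adaptor + policy.primer).upper()
    kept: list[ReadRecord] = []
    tallies = {"primer": 0, "ambiguous": 0, "quality": 0, "homopolymer": 0}
    for read in reads:
        seq = read.seq.upper()
        if prefix:
            head = seq[: len(prefix)]
            mismatches = (
                sum(x != y for x, y in zip(head, prefix))
                + max(0, len(prefix) - len(head))
            )
            if mismatches > policy.max_mismatch_primer:
                tallies["primer"] += 1
                continue
            seq = seq[len(prefix) :]
            qual = read.qual[len(prefix) :] if read.qual else read.qual
        else:
            qual = read.qual
        if not policy.allow_ambiguous and (set(seq) - _VALID):
            tallies["ambiguous"] += 1
            continue
        if policy.min_window_quality > 0:
            if qual is None:
                raise ValueError(f"read {read.id} lacks quality scores")
            if not _window_quality_ok(qual, policy):
                tallies["quality"] += 1
                continue
        if _max_homopolymer(seq) > policy.max_homopolymer:
            tallies["homopolymer"] += 1
            continue
        kept.append(ReadRecord(id=read.id, seq=seq, qual=qual,
                               description=read.description))
    return kept, tallies


def precluster(reads: Iterable, max_diff: int = 1) -> AlleleTable:
    """Merge near-identical sequences into more abundant representatives.

    Unique sequences are sorted by descending abundance (ties broken
    lexicographically); in a single pass, each sequence either merges
    into the most abundant earlier *representative* within ``max_diff``
    edit operations, or becomes a new representative itself.  There is
    no transitive chaining: distances are always measured against the
    representative's own sequence.
    """
    groups: dict[str, list[str]] = {}
    for r in reads:
        rid, seq = (r if isinstance(r, tuple) else (r.id, r.seq))
        groups.setdefault(seq.upper(), []).append(rid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    table: list[Allele] = []
    for seq, members in ordered:
        merged = False
        for rep in table:
            res = edlib.align(seq, rep.sequence, task="distance", k=max_diff)
            if res["editDistance"] != -1 and res["editDistance"] <= max_diff:
                rep.count += len(members)
                rep.member_read_ids.extend(members)
                merged = True
                break
        if not merged:
            table.append(Allele(sequence=seq, count=len(members),
                                member_read_ids=list(members)))
    table.sort(key=lambda a: (-a.count, a.sequence))
    return AlleleTable(alleles=table)


def _make_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _match_profile(query: str, reference: str,
                   aligner: Align.PairwiseAligner) -> np.ndarray:
    """Per-query-position 0/1 vector: matched identically to reference."""
    aln = aligner.align(query, reference)[0]
    profile = np.zeros(len(query), dtype=int)
    for (q0, q1), (r0, r1) in zip(*aln.aligned):
        for i, (x, y) in enumerate(zip(query[q0:q1], reference[r0:r1])):
            if x == y and x != "N":
                profile[q0 + i] = 1
    return profile


def chimera_screen(
    alleles: AlleleTable,
    references: Sequence[str],
    min_support: float = 90.0,
    improvement_min: int = 3,
) -> tuple[AlleleTable, AlleleTable]:
    """Flag alleles better explained as a crossover of two references.

    For each allele, per-position identity profiles against every
    reference are computed from global alignments.  The allele is
    flagged as chimeric iff the best two-parent model (best left-prefix
    parent plus best right-suffix parent, parents distinct) gains at
    least ``improvement_min`` identities over the best single parent AND
    the single-parent support (percent identity over the allele length)
    is below ``min_support``.  Returns (kept, flagged) tables.
    """
    refs = [r.upper() for r in references]
    if not refs:
        raise ValueError("reference set must be nonempty")
    aligner = _make_global_aligner()
    kept: list[Allele] = []
    flagged: list[Allele] = []
    for allele in alleles.alleles:
        seq = allele.sequence
        profiles = np.array([_match_profile(seq, r, aligner) for r in refs])
        totals = profiles.sum(axis=1)
        best_single = int(totals.max())
        support = 100.0 * best_single / max(1, len(seq))
        is_chimera = False
        if len(refs) >= 2 and support < min_support:
            prefix = np.concatenate(
                [np.zeros((len(refs), 1), dtype=int), np.cumsum(profiles, axis=1)],
                axis=1,
            )
            best_two = 0
            for s in range(1, len(seq)):
                left = prefix[:, s]
                right = totals - prefix[:, s]
                # max over distinct parents p != q of left[p] + right[q]:
                # the optimum uses a top-2 candidate on each side
                ltop = np.argsort(left)[::-1][:2]
                rtop = np.argsort(right)[::-1][:2]
                for p in ltop:
                    for q in rtop:
                        if p != q:
                            best_two = max(best_two, int(left[p] + right[q]))
            if best_two - best_single >= improvement_min:
                is_chimera = True
        (flagged if is_chimera else kept).append(allele)
    return AlleleTable(alleles=kept), AlleleTable(alleles=flagged)


def diversity(alleles: AlleleTable, min_count: int = 2) -> DiversityEstimate:
    """Chao1 minimum richness with 95% log-normal confidence bounds.

    ``s_obs_gt1`` counts alleles with abundance >= ``min_count`` — the
    conservative headline count that ignores alleles seen only once.
    """
    counts = np.array(alleles.counts())
    if counts.size == 0:
        raise ValueError("allele table must be nonempty")
    s_obs = int(counts.size)
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    t = chao1 - s_obs
    if t <= 0:
        lci = hci = float(s_obs)
    else:
        # Chao's log-normal interval on T = chao1 - S_obs
        var = (
            f1 * (f1 - 1) / (2.0 * (f2 + 1))
            + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
            + f1**2 * f2 * (f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4)
        )
        k = math.exp(1.96 * math.sqrt(math.log(1.0 + var / (t * t))))
        lci = s_obs + t / k
        hci = s_obs + t * k
    return DiversityEstimate(
        s_obs=s_obs,
        s_obs_gt1=int(np.sum(counts >= min_count)),
        f1=f1,
        f2=f2,
        chao1=float(chao1),
        lci=float(lci),
        hci=float(hci),
    )


def rarefaction(alleles: AlleleTable, grid: Sequence[int]) -> RarefactionCurve:
    """Expected richness in random subsamples of the given sizes.

    Uses the exact hypergeometric expectation
    E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n)) computed in log space.
    """
    counts = np.array(alleles.counts())
    n_total = int(counts.sum())
    points = []
    for n in grid:
        n = int(n)
        if n > n_total or n < 0:
            raise ValueError(f"subsample size {n} exceeds total reads {n_total}")
        expected = 0.0
        for ni in counts:
            if n_total - ni < n:
                p_absent = 0.0
            else:
                p_absent = math.exp(
                    _log_choose(n_total - ni, n) - _log_choose(n_total, n)
                )
            expected += 1.0 - p_absent
        points.append((n, expected))
    return RarefactionCurve(points=tuple(points))


def _log_choose(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def estimate_error_rate(
    control_reads: Iterable, control_reference: str
) -> tuple[float, int]:
    """Per-base error rate from reads of a known control sequence.

    Each read is aligned within the reference (infix alignment); the
    rate is total mismatches+indels over total aligned read bases.
    Reads whose identity falls below 50% are excluded from the rate and
    reported in the second return value.
    """
    reference = control_reference.upper()
    total_errors = 0
    total_bases = 0
    excluded = 0
    for r in control_reads:
        seq = (r if isinstance(r, str) else r.seq).upper()
        res = edlib.align(seq, reference, mode="HW", task="distance")
        dist = res["editDistance"]
        if dist > 0.5 * len(seq):
            excluded += 1
            continue
        total_errors += dist
        total_bases += len(seq)
    if total_bases == 0:
        raise ValueError("no alignable control reads")
    return total_errors / total_bases, excluded
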
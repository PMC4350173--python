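"""Recombination, reading-frame integrity and qPCR copy-number analyses.

Marker allele alignments are screened for recombination with the
Hudson-Kaplan four-gamete approach: every pair of biallelic sites
showing all four gametes defines an interval that must contain at least
one recombination event, and Rm is the minimum number of events
compatible with all such intervals (interval reduction: drop intervals
containing another, then count disjoint intervals left to right).
Reading-frame integrity is summarized as in-frame stop codons and
frameshifts (ungapped length not congruent to the consensus mod 3).
Relative marker copy number is estimated from qPCR dilution series
against a single-copy reference regression line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_STOPS = {"TAA", "TAG", "TGA"}
_GAPS = set("-.")


@dataclass
class MarkerAlignment:
    """Aligned marker alleles (equal lengths; gaps allowed).

    ``counts`` are per-allele abundances (defaulting to 1 each);
    ``frame`` is the reading-frame offset of the alignment.
    """

    ids: list[str]
    sequences: list[str]
    counts: list[int] = field(default_factory=list)
    frame: int = 0

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = [1] * len(self.sequences)
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal lengths")
        if len(self.ids) != len(self.sequences):
            raise ValueError("one id per sequence required")
        self.sequences = [s.upper() for s in self.sequences]


@dataclass(frozen=True)
class RmResult:
    biallelic_sites: tuple[int, ...]
    incompatible_pairs: tuple[tuple[int, int], ...]
    rm: int


@dataclass(frozen=True)
class OrfCheck:
    stopcodon_count: int
    frameshift_count: int
    removed_ids: tuple[str, ...]


@dataclass
class QpcrCurve:
    """A qPCR dilution series: (log10 concentration, Ct) points.

    The regression line Ct = slope * log10(conc) + intercept is fitted
    by ordinary least squares; a valid series has negative slope.
    """

    log10_conc: list[float]
    ct: list[float]
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.log10_conc) != len(self.ct):
            raise ValueError("log10_conc and ct must have equal lengths")
        if len(self.ct) < 3:
            raise ValueError("need at least 3 dilution points")
        slope, intercept = np.polyfit(self.log10_conc, self.ct, 1)
        self.slope = float(slope)
        self.intercept = float(intercept)
        if self.slope >= 0:
            raise ValueError("dilution series must have negative slope")


def _biallelic_sites(seqs: Sequence[str]) -> list[int]:
    """Columns with exactly two states; gap-containing columns excluded."""
    length = len(seqs[0])
    sites = []
    for j in range(length):
        states = {s[j] for s in seqs}
        if states & _GAPS:
            continue
        if len(states) == 2:
            sites.append(j)
    return sites


def four_gamete_rm(aln: MarkerAlignment) -> RmResult:
    """Hudson-Kaplan minimum number of recombination events.

    Each distinct allele sequence participates once regardless of
    abundance (the test concerns gamete presence, not frequency).  A
    site pair is incompatible iff all four gametes occur; Rm is the
    maximum number of pairwise-disjoint incompatible intervals, found by
    removing intervals that contain another and greedily scanning left
    to right.
    """
    seqs = sorted(set(aln.sequences))
    if len(seqs) < 2:
        return RmResult(biallelic_sites=(), incompatible_pairs=(), rm=0)
    sites = _biallelic_sites(seqs)
    incompatible: list[tuple[int, int]] = []
    for x in range(len(sites)):
        for y in range(x + 1, len(sites)):
            i, j = sites[x], sites[y]
            gametes = {(s[i], s[j]) for s in seqs}
            if len(gametes) == 4:
                incompatible.append((i, j))
    rm = hudson_kaplan_rm(incompatible)
    return RmResult(
        biallelic_sites=tuple(sites),
        incompatible_pairs=tuple(incompatible),
        rm=rm,
    )


def hudson_kaplan_rm(intervals: Sequence[tuple[int, int]]) -> int:
    """Minimum events covering all incompatible intervals.

    Removes intervals that properly contain another interval, then
    counts disjoint intervals left to right (equivalently, a maximum set
    of pairwise-disjoint open intervals; each needs its own event).
    """
    if not intervals:
        return 0
    iv = sorted(set(intervals))
    reduced = [
        a
        for a in iv
        if not any(b != a and a[0] <= b[0] and b[1] <= a[1] for b in iv)
    ]
    reduced.sort(key=lambda ab: ab[1])
    rm = 0
    last_end = -1
    for start, end in reduced:
        if start >= last_end:
            rm += 1
            last_end = end
    return rm


def _ungapped(seq: str) -> str:
    return "".join(c for c in seq if c not in _GAPS)


def orf_check(aln: MarkerAlignment, frame: int | None = None) -> OrfCheck:
    """Count in-frame stop codons and frameshifted sequences.

    Stops (TAA/TAG/TGA, standard code) are counted in-frame before the
    final codon of each ungapped sequence.  A frameshift is any sequence
    whose ungapped length differs from the consensus (modal) ungapped
    length by a non-multiple of 3.
    """
    if frame is None:
        frame = aln.frame
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    ungapped = [_ungapped(s) for s in aln.sequences]
    lengths = [len(s) for s in ungapped]
    consensus_len = max(sorted(set(lengths)), key=lengths.count)
    stop_total = 0
    frameshift_total = 0
    removed: list[str] = []
    for rid, seq, n in zip(aln.ids, ungapped, lengths):
        stops = 0
        codons = [(seq[i : i + 3]) for i in range(frame, len(seq) - 2, 3)]
        for codon in codons[:-1]:  # before the final codon
            if codon in _STOPS:
                stops += 1
        shifted = (n - consensus_len) % 3 != 0
        stop_total += stops
        frameshift_total += int(shifted)
        if stops > 0 or shifted:
            removed.append(rid)
    return OrfCheck(
        stopcodon_count=stop_total,
        frameshift_count=frameshift_total,
        removed_ids=tuple(removed),
    )


def relative_copy_number(target: QpcrCurve, reference: QpcrCurve) -> float:
    """Copy number of a target marker relative to a reference regression.

    For each target dilution point, the reference regression line is
    inverted at the target's Ct to give the effective template
    concentration the reference would need to produce that Ct; the
    ratio is the geometric mean over points of effective / actual
    concentration.  A target identical to the reference yields exactly
    1.0.
    """
    t_lo, t_hi = min(target.log10_conc), max(target.log10_conc)
    r_lo, r_hi = min(reference.log10_conc), max(reference.log10_conc)
    if t_hi < r_lo or r_hi < t_lo:
        warnings.warn("target and reference concentration ranges do not overlap")
    if abs(target.slope - reference.slope) > 0.1 * abs(reference.slope):
        warnings.warn(
            "target and reference slopes differ by more than 10%; "
            "amplification efficiencies may not be comparable"
        )
    log_ratios = []
    for x, ct in zip(target.log10_conc, target.ct):
        effective = (ct - reference.intercept) / reference.slope
        log_ratios.append(effective - x)
    return float(10 ** np.mean(log_ratios))
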
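"""Mapping evaluation: precision/recall/F1 against truth, and relative
abundance with Euclidean distance to known fractions.

A test mapping counts as a true positive when it agrees with the truth
record of the same read on target name and strand and the target intervals
overlap within a base tolerance (the truth locus criterion is an
interpretation — exposed as ``tol``, default 100 bases).  Precision is
TP/(TP+FP) over mapped test reads, recall TP/(TP+FN) over truth-mapped
reads (a read mapped to the wrong place contributes to both FP and FN), and
F1 their harmonic mean.  Reads unmapped on both sides are ignored.

Relative abundance is estimated from mapped *read counts* per genome (not
mapped bases, which would skew toward large genomes); the quality of an
estimate is its Euclidean distance to the truth fraction vector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from squigmap.mapping import MappingRecord

__all__ = ["EvalResult", "AbundanceResult", "compare_paf",
           "relative_abundance"]


@dataclass(frozen=True)
class EvalResult:
    TP: int
    FP: int
    FN: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass(frozen=True)
class AbundanceResult:
    fractions: dict[str, float]
    euclidean_distance_to_truth: float


def _best_per_read(records: list[MappingRecord]) -> dict[str, MappingRecord]:
    by_read: dict[str, MappingRecord] = {}
    dupes = 0
    for rec in records:
        prev = by_read.get(rec.qname)
        if prev is None:
            by_read[rec.qname] = rec
        else:
            dupes += 1
            if rec.mapq > prev.mapq:
                by_read[rec.qname] = rec
    if dupes:
        warnings.warn(f"{dupes} duplicate test rows; kept best-mapq per read")
    return by_read


def compare_paf(test: list[MappingRecord], truth: list[MappingRecord],
                tol: int = 100) -> EvalResult:
    """Score test mappings against single-row-per-read truth."""
    truth_by_read: dict[str, MappingRecord] = {}
    for rec in truth:
        if rec.qname in truth_by_read:
            raise ValueError(f"truth has multiple rows for {rec.qname!r}")
        truth_by_read[rec.qname] = rec
    test_by_read = _best_per_read(test)

    tp = fp = 0
    correct_reads: set[str] = set()
    for qname, rec in test_by_read.items():
        if not rec.is_mapped:
            continue
        tr = truth_by_read.get(qname)
        if (tr is not None and tr.is_mapped
                and rec.tname == tr.tname and rec.strand == tr.strand
                and rec.tstart - tol < tr.tend
                and tr.tstart < rec.tend + tol):
            tp += 1
            correct_reads.add(qname)
        else:
            fp += 1
    truth_mapped = sum(1 for r in truth_by_read.values() if r.is_mapped)
    fn = truth_mapped - tp
    return EvalResult(TP=tp, FP=fp, FN=fn)


def relative_abundance(
    test: list[MappingRecord],
    genome_of_contig: dict[str, str],
    truth_fractions: dict[str, float],
) -> AbundanceResult:
    """Per-genome mapped-read fractions and their distance to truth.

    Every mapped contig must be assigned to a genome; zero mapped reads
    leaves the distance undefined and raises ``ValueError``.
    """
    counts: dict[str, int] = {g: 0 for g in truth_fractions}
    total = 0
    for rec in _best_per_read(test).values():
        if not rec.is_mapped:
            continue
        genome = genome_of_contig.get(rec.tname)
        if genome is None:
            raise ValueError(f"contig {rec.tname!r} has no genome assignment")
        counts[genome] = counts.get(genome, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("no mapped reads: abundance undefined")
    fractions = {g: c / total for g, c in counts.items()}
    genomes = sorted(set(fractions) | set(truth_fractions))
    dist = math.sqrt(sum(
        (fractions.get(g, 0.0) - truth_fractions.get(g, 0.0)) ** 2
        for g in genomes))
    return AbundanceResult(fractions=fractions,
                           euclidean_distance_to_truth=dist)
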
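"""Per-read quality control, dereplication, rare-sequence removal and
greedy centroid clustering of amplicon reads into OTUs.

The quality filter follows the expected-error convention: a read's
expected number of errors is EE = sum_i 10^(-Q_i/10) over its Phred
scores, and reads longer than a minimum length with EE at most a maximum
are retained. Clustering is greedy abundance-sorted centroid clustering:
unique sequences are visited in decreasing abundance and joined to the
first existing centroid whose global pairwise identity reaches the
threshold, otherwise they found a new cluster.

Rare-sequence removal is applied to GLOBAL abundances (summed over all
samples), the usual convention for removing PCR/sequencing artifacts
dataset-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .io_formats import OtuTable, ReadRecord

__all__ = [
    "DereplicatedSequence",
    "ClusterResult",
    "FilterStats",
    "expected_errors",
    "filter_reads",
    "dereplicate",
    "remove_rare",
    "pairwise_identity",
    "cluster_greedy",
    "cluster_table",
]


@dataclass(frozen=True)
class DereplicatedSequence:
    """A unique sequence with its per-sample provenance counts."""

    sequence: str
    total_abundance: int
    source_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.total_abundance != sum(self.source_counts.values()):
            raise ValueError("total_abundance != sum of source_counts")
        if self.total_abundance < 1:
            raise ValueError("dereplicated sequence with zero abundance")


@dataclass
class FilterStats:
    n_input: int = 0
    n_retained: int = 0
    n_short: int = 0
    n_high_ee: int = 0


@dataclass
class ClusterResult:
    """Greedy clustering output: centroids in creation order plus the
    member -> centroid-index assignment."""

    centroids: list[str]
    assignment: dict[str, int]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def expected_errors(qualities: Sequence[int]) -> float:
    """Expected number of errors of a read: sum over bases of 10^(-Q/10)."""
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        return 0.0
    if (q < 0).any():
        raise ValueError("negative Phred score")
    return float(np.sum(10.0 ** (-q / 10.0)))


def filter_reads(
    reads: Iterable[ReadRecord],
    min_length: int = 170,
    max_ee: float = 1.0,
) -> tuple[list[ReadRecord], FilterStats]:
    """Retain reads with length >= min_length and expected errors <= max_ee.

    The EE bound is inclusive ("more than one expected error" is removed,
    so EE exactly equal to the bound is kept). Length is checked first;
    each rejected read is counted under a single reason.
    """
    retained: list[ReadRecord] = []
    stats = FilterStats()
    for r in reads:
        stats.n_input += 1
        if len(r) < min_length:
            stats.n_short += 1
            continue
        if expected_errors(r.qualities) > max_ee:
            stats.n_high_ee += 1
            continue
        retained.append(r)
    stats.n_retained = len(retained)
    return retained, stats


def dereplicate(
    reads_by_sample: Mapping[str, Iterable[ReadRecord]],
) -> list[DereplicatedSequence]:
    """Group exactly identical sequences across samples.

    Output is sorted by total abundance descending, ties broken
    lexicographically by sequence, so downstream greedy clustering is
    deterministic.
    """
    counts: dict[str, dict[str, int]] = {}
    for sample_id, reads in reads_by_sample.items():
        for r in reads:
            per = counts.setdefault(r.sequence, {})
            per[sample_id] = per.get(sample_id, 0) + 1
    entries = [
        DereplicatedSequence(seq, sum(per.values()), dict(sorted(per.items())))
        for seq, per in counts.items()
    ]
    entries.sort(key=lambda e: (-e.total_abundance, e.sequence))
    return entries


def remove_rare(
    dereplicated: Sequence[DereplicatedSequence], min_abundance: int = 3
) -> list[DereplicatedSequence]:
    """Drop unique sequences whose GLOBAL abundance is below min_abundance.

    The default removes sequences occurring once or twice in the whole
    dataset (PCR/sequencing artifact removal).
    """
    return [e for e in dereplicated if e.total_abundance >= min_abundance]


def _make_aligner(
    match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Fraction of identical columns under full-length global alignment.

    The denominator is ALL alignment columns, terminal gaps included
    (strict global identity). Ties between co-optimal alignments are
    resolved by the aligner's first reported alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if seq_a == seq_b:
        return 1.0
    aligner = _make_aligner(match, mismatch, gap)
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / columns


def cluster_greedy(
    dereplicated: Sequence[DereplicatedSequence],
    threshold: float = 0.97,
) -> ClusterResult:
    """Greedy abundance-sorted centroid clustering at a fixed identity.

    Inputs must already be sorted by abundance descending (ties
    lexicographic, as produced by :func:`dereplicate`). Each sequence is
    assigned to the FIRST centroid, in creation order, whose identity to
    it reaches the threshold; otherwise it becomes a new centroid.
    """
    order = [e.total_abundance for e in dereplicated]
    if order != sorted(order, reverse=True):
        raise ValueError("input must be sorted by abundance descending")
    centroids: list[str] = []
    assignment: dict[str, int] = {}
    for entry in dereplicated:
        for idx, centroid in enumerate(centroids):
            if pairwise_identity(entry.sequence, centroid) >= threshold:
                assignment[entry.sequence] = idx
                break
        else:
            centroids.append(entry.sequence)
            assignment[entry.sequence] = len(centroids) - 1
    return ClusterResult(centroids, assignment, threshold)


def cluster_table(
    dereplicated: Sequence[DereplicatedSequence],
    result: ClusterResult,
    otu_prefix: str = "OTU_",
) -> tuple[OtuTable, dict[str, str]]:
    """Aggregate member abundances per sample into an OTU count table.

    OTU ids are assigned in centroid creation order (abundance rank);
    returns the table and the otu_id -> centroid sequence map.
    """
    otu_ids = [f"{otu_prefix}{i + 1:04d}" for i in range(result.n_clusters)]
    samples = sorted({s for e in dereplicated for s in e.source_counts})
    counts = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"), columns=otu_ids, dtype=np.int64
    )
    for entry in dereplicated:
        otu = otu_ids[result.assignment[entry.sequence]]
        for sample_id, c in entry.source_counts.items():
            counts.loc[sample_id, otu] += c
    centroid_of = {otu_ids[i]: seq for i, seq in enumerate(result.centroids)}
    return OtuTable(counts), centroid_of
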
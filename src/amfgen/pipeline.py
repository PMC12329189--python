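"""End-to-end assembly of the read-level pipeline.

From a directory of per-sample FASTQ files to an OTU count table:
quality filter -> exact dereplication (with per-sample provenance) ->
global rare-sequence removal -> greedy centroid clustering. Taxonomy
filtering, control subtraction and depth filtering then run on the
resulting table via :mod:`amfgen.otu_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .filtering import (
    ClusterResult,
    FilterStats,
    cluster_greedy,
    cluster_table,
    dereplicate,
    filter_reads,
    remove_rare,
)
from .io_formats import AlignmentHit, OtuTable, read_fastq

__all__ = ["ReadPipelineResult", "run_read_pipeline", "hits_for_centroids"]


@dataclass
class ReadPipelineResult:
    table: OtuTable
    centroid_of: dict[str, str]  # otu_id -> centroid sequence
    cluster_result: ClusterResult
    filter_stats: dict[str, FilterStats]


def run_read_pipeline(
    fastq_dir: str | Path,
    min_length: int = 170,
    max_ee: float = 1.0,
    min_abundance: int = 3,
    threshold: float = 0.97,
) -> ReadPipelineResult:
    """FASTQ directory (one ``<sample_id>.fastq`` per sample) to OTU table."""
    fastq_dir = Path(fastq_dir)
    paths = sorted(fastq_dir.glob("*.fastq"))
    if not paths:
        raise FileNotFoundError(f"no .fastq files under {fastq_dir}")
    retained_by_sample = {}
    stats: dict[str, FilterStats] = {}
    for path in paths:
        sample_id = path.stem
        retained, st = filter_reads(read_fastq(path), min_length, max_ee)
        retained_by_sample[sample_id] = retained
        stats[sample_id] = st
    derep = remove_rare(dereplicate(retained_by_sample), min_abundance)
    clusters = cluster_greedy(derep, threshold)
    table, centroid_of = cluster_table(derep, clusters)
    return ReadPipelineResult(table, centroid_of, clusters, stats)


def hits_for_centroids(
    centroid_of: Mapping[str, str],
    references: Mapping[str, str],
    unmatched: Sequence[str] = (),
    contaminant_sequence: str | None = None,
) -> tuple[list[AlignmentHit], dict[str, str]]:
    """Taxonomy hits for cluster centroids against known reference sequences.

    Stand-in for a reference-database search in simulated experiments:
    a centroid exactly matching a reference (or the contaminant) gets a
    passing hit, references listed in ``unmatched`` get a failing one.
    Returns the hits plus the pipeline-OTU-id -> true-OTU-id map.
    """
    seq_to_ref = {seq: ref for ref, seq in references.items()}
    if contaminant_sequence is not None:
        seq_to_ref[contaminant_sequence] = "CONTAM"
    unmatched = set(unmatched)
    hits: list[AlignmentHit] = []
    identity_map: dict[str, str] = {}
    for otu_id, seq in centroid_of.items():
        ref = seq_to_ref.get(seq)
        if ref is None:
            continue
        identity_map[otu_id] = ref
        if ref in unmatched:
            hits.append(AlignmentHit(otu_id, f"VT_{ref}", 85.0, 150))
        else:
            hits.append(AlignmentHit(otu_id, f"VT_{ref}", 99.0, 220))
    return hits, identity_map
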
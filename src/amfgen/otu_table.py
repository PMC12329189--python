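"""Construction of the analysis-ready OTU table.

Four steps, applied in this fixed order:

1. taxonomy_filter  — keep OTUs with at least one reference hit of
   sufficient alignment length and identity (default >= 200 bp and
   >= 90%, the usual criterion against an AMF virtual-taxon database);
2. subtract_controls — remove contamination seen in negative controls by
   subtracting each OTU's summed control count from every other sample;
3. min_depth_filter — drop samples with fewer than a minimum number of
   reads (default 1000);
4. subset_mycorrhizal_hosts — restrict to samples from plant species
   known to associate with arbuscular mycorrhizal fungi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence


import pandas as pd

from .io_formats import AlignmentHit, OtuTable, check_metadata_covers

__all__ = [
    "TaxonomyAssignment",
    "taxonomy_filter",
    "subtract_controls",
    "min_depth_filter",
    "subset_mycorrhizal_hosts",
    "build_analysis_table",
]


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Best retained reference hit for an OTU."""

    otu_id: str
    vt_match: str
    percent_identity: float
    alignment_length: int
    family: str = ""
    order: str = ""


def taxonomy_filter(
    table: OtuTable,
    hits: Iterable[AlignmentHit],
    min_len: int = 200,
    min_id: float = 90.0,
) -> tuple[OtuTable, dict[str, TaxonomyAssignment]]:
    """Retain OTUs with >= 1 hit satisfying length >= min_len AND identity >= min_id.

    The best qualifying hit (highest identity, then longest alignment,
    then lexicographic subject id) is recorded as the OTU's assignment.
    Hits whose query is not in the table are ignored with a warning.
    """
    otus = set(table.otu_ids)
    qualifying: dict[str, list[AlignmentHit]] = {}
    orphans = set()
    for h in hits:
        if h.query_id not in otus:
            orphans.add(h.query_id)
            continue
        if h.alignment_length >= min_len and h.percent_identity >= min_id:
            qualifying.setdefault(h.query_id, []).append(h)
    if orphans:
        warnings.warn(
            f"{len(orphans)} alignment hit query id(s) not present in the "
            f"OTU table were ignored",
            stacklevel=2,
        )
    assignments: dict[str, TaxonomyAssignment] = {}
    for otu_id, otu_hits in qualifying.items():
        best = max(
            otu_hits,
            key=lambda h: (h.percent_identity, h.alignment_length, h.subject_id),
        )
        family, order = "", ""
        if len(best.rest) >= 8:
            # hits emitted by the simulator carry family/order in the two
            # trailing free columns
            family, order = best.rest[-2], best.rest[-1]
        assignments[otu_id] = TaxonomyAssignment(
            otu_id, best.subject_id, best.percent_identity,
            best.alignment_length, family, order,
        )
    keep = sorted(assignments)
    filtered = OtuTable(
        table.counts[keep],
        {
            otu: {
                "family": a.family,
                "order": a.order,
                "vt_match": a.vt_match,
            }
            for otu, a in assignments.items()
        },
    )
    return filtered, assignments


def subtract_controls(
    table: OtuTable, control_sample_ids: Sequence[str]
) -> OtuTable:
    """Subtract each OTU's total negative-control count from all samples.

    For every OTU, the counts observed in the control samples are summed
    and that sum is subtracted from the OTU's count in each non-control
    sample, flooring at zero; the control samples are then dropped.
    """
    controls = list(dict.fromkeys(control_sample_ids))
    if not controls:
        warnings.warn("empty control set: table returned unchanged", stacklevel=2)
        return OtuTable(table.counts, table.otu_annotations)
    missing = [c for c in controls if c not in set(table.sample_ids)]
    if missing:
        raise KeyError(f"control sample(s) not in table: {missing}")
    ctrl_totals = table.counts.loc[controls].sum(axis=0)
    rest = table.counts.drop(index=controls)
    adjusted = (rest - ctrl_totals).clip(lower=0)
    return OtuTable(adjusted, table.otu_annotations)


def min_depth_filter(table: OtuTable, min_reads: int = 1000) -> OtuTable:
    """Drop samples with fewer than min_reads total sequences, then any
    OTU column left all-zero."""
    depths = table.sample_depths()
    keep = depths.index[depths >= min_reads]
    if len(keep) == 0:
        raise ValueError(
            f"all {table.shape[0]} samples fall below the depth threshold "
            f"({min_reads})"
        )
    return OtuTable(table.counts.loc[keep], table.otu_annotations).drop_empty_otus()


def subset_mycorrhizal_hosts(table: OtuTable, metadata: pd.DataFrame) -> OtuTable:
    """Keep only samples from plant species flagged as mycorrhizal hosts."""
    meta = check_metadata_covers(table, metadata)
    keep = meta.index[meta["mycorrhizal_host"].astype(bool)]
    return OtuTable(table.counts.loc[keep], table.otu_annotations)


def build_analysis_table(
    table: OtuTable,
    hits: Iterable[AlignmentHit],
    control_sample_ids: Sequence[str],
    metadata: pd.DataFrame,
    min_len: int = 200,
    min_id: float = 90.0,
    min_reads: int = 1000,
    mycorrhizal_only: bool = True,
) -> tuple[OtuTable, dict[str, TaxonomyAssignment]]:
    """Full table-construction chain in the fixed pipeline order."""
    filtered, assignments = taxonomy_filter(table, hits, min_len, min_id)
    filtered = subtract_controls(filtered, control_sample_ids)
    filtered = min_depth_filter(filtered, min_reads)
    if mycorrhizal_only:
        filtered = subset_mycorrhizal_hosts(filtered, metadata)
    filtered = filtered.drop_empty_otus()
    return filtered, assignments
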
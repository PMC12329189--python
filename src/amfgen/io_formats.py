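"""Readers and writers for the external formats the pipeline touches.

Formats: 4-line FASTQ (Phred+33 only; modern Illumina), FASTA with
``;size=N`` abundance annotations, 12-column tabular alignment hits
(BLAST outfmt-6 style), tab-separated OTU count tables, and tab-separated
sample metadata.

All tabular output is written with lexicographically sorted identifiers so
that serialisation is deterministic and diffable.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReadRecord",
    "AlignmentHit",
    "OtuTable",
    "METADATA_COLUMNS",
    "read_fastq",
    "write_fastq",
    "write_fasta_derep",
    "read_alignment_tabular",
    "write_alignment_tabular",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
]

_PHRED_OFFSET = 33
_DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """One amplicon read: identifier, uppercase DNA, Phred quality scores."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.read_id!r}: negative Phred score")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: non-ACGTN characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """One line of 12-column tabular alignment output.

    Only query, subject, percent identity and alignment length are
    interpreted; the remaining columns are retained opaquely.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    rest: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"hit {self.query_id!r}: percent identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise ValueError(
                f"hit {self.query_id!r}: alignment length "
                f"{self.alignment_length} < 1"
            )


METADATA_COLUMNS = [
    "sample_id",
    "plant_species",
    "provenance",
    "mesocosm_id",
    "community_id",
    "prop_exotic_planted",
    "herbivore",
    "soil",
    "soil_amn",
    "richness_at_harvest",
    "mycorrhizal_host",
]

_EXOTIC_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


class OtuTable:
    """Integer count matrix, samples x OTUs, the pipeline's central object.

    Rows and columns are kept lexicographically sorted; counts are
    non-negative int64. ``otu_annotations`` optionally maps otu_id to a
    dict with taxonomy labels (family, order, vt_match).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        otu_annotations: Mapping[str, Mapping[str, str]] | None = None,
    ) -> None:
        counts = counts.copy()
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id(s): {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate otu_id(s): {dup}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            flt = arr.astype(float)
            if not np.allclose(flt, np.round(flt)):
                bad = np.argwhere(flt != np.round(flt))[0]
                raise ValueError(
                    f"non-integer count at sample {counts.index[bad[0]]!r}, "
                    f"otu {counts.columns[bad[1]]!r}"
                )
        counts = counts.astype(np.int64)
        if counts.size and (counts.to_numpy() < 0).any():
            bad = np.argwhere(counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at sample {counts.index[bad[0]]!r}, "
                f"otu {counts.columns[bad[1]]!r}"
            )
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        self.counts = counts.sort_index(axis=0).sort_index(axis=1)
        self.counts.index.name = "sample_id"
        self.otu_annotations = (
            {k: dict(v) for k, v in otu_annotations.items()}
            if otu_annotations
            else {}
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.columns[(self.counts > 0).any(axis=0)]
        return OtuTable(
            self.counts[keep],
            {k: v for k, v in self.otu_annotations.items() if k in set(keep)},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"OtuTable({n} samples x {m} OTUs, {self.total_reads()} reads)"


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Yield reads from a 4-line-record FASTQ file (Phred+33).

    Malformed records (bad header, truncated record, quality/sequence
    length mismatch) raise ValueError naming the offending line number.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"{path}:{lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n").upper()
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ValueError(f"{path}:{lineno}: truncated FASTQ record")
            lineno += 3
            if not plus.startswith("+"):
                raise ValueError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(qual) != len(seq):
                raise ValueError(
                    f"{path}:{lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            quals = tuple(ord(c) - _PHRED_OFFSET for c in qual)
            if any(q < 0 for q in quals):
                raise ValueError(f"{path}:{lineno}: quality below Phred+33 offset")
            yield ReadRecord(header[1:].split()[0] if header[1:] else "", seq, quals)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            qual = "".join(chr(q + _PHRED_OFFSET) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_fasta_derep(
    entries: Sequence, path: str | Path, prefix: str = "uniq"
) -> None:
    """Write dereplicated sequences as FASTA with ``;size=N`` annotations."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(e.sequence),
            id=f"{prefix}{i + 1};size={e.total_abundance}",
            description="",
        )
        for i, e in enumerate(entries)
    ]
    seqio_write(records, str(path), "fasta")


def read_alignment_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column tab-separated alignment hits (outfmt-6 style)."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                identity = float(cols[2])
                length = int(cols[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(
                AlignmentHit(cols[0], cols[1], identity, length, tuple(cols[4:]))
            )
    return hits


def write_alignment_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            rest = list(h.rest) + ["*"] * (8 - len(h.rest))
            fh.write(
                "\t".join(
                    [h.query_id, h.subject_id, f"{h.percent_identity:g}",
                     str(h.alignment_length), *rest[:8]]
                )
                + "\n"
            )


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a tab-separated OTU table (first column sample_id, header otu_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample_id rows {dup}")
    counts = pd.DataFrame(index=df.index)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="raise")
        bad = vals[(vals < 0) | (vals != np.floor(vals))]
        if len(bad):
            raise ValueError(
                f"{path}: invalid count {bad.iloc[0]!r} at sample "
                f"{bad.index[0]!r}, otu {col!r}"
            )
        counts[col] = vals.astype(np.int64)
    return OtuTable(counts)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated sample metadata table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_metadata(df)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(metadata).to_csv(path, sep="\t", index=False)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s) in metadata: {dup}")
    levels = set(df["prop_exotic_planted"].astype(float).round(6))
    bad = levels - set(_EXOTIC_LEVELS)
    if bad:
        raise ValueError(
            f"prop_exotic_planted outside design levels {_EXOTIC_LEVELS}: {sorted(bad)}"
        )
    df = df.copy()
    df["prop_exotic_planted"] = df["prop_exotic_planted"].astype(float)
    df["mycorrhizal_host"] = df["mycorrhizal_host"].astype(bool)
    return df


def check_metadata_covers(table: OtuTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Every sample in the table must have exactly one metadata row."""
    meta = validate_metadata(metadata).set_index("sample_id")
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise KeyError(f"samples without metadata: {missing[:5]}")
    return meta.loc[table.sample_ids]
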
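"""Readers and writers for every on-disk artifact the pipeline touches.

All interval tables use 1-based inclusive coordinates (GFF convention);
conversions happen here and nowhere else.  Writers emit UTF-8 tab-delimited
text with a header row and ``.`` for missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

MISSING = "."

# CIGAR operations that consume alignment columns for the identity
# denominator: reference-consuming (M/=/X, D) plus insertions (I).
_COLUMN_OPS = {0, 1, 2, 7, 8}  # M, I, D, =, X


@dataclass(frozen=True)
class SequenceRecord:
    """A named biological sequence (protein or nucleotide)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-gene alignment distilled from a SAM/BAM record.

    ``aligned_len`` counts alignment columns consumed on the reference plus
    inserted columns (CIGAR M/=/X + I + D); ``identity_pct`` is
    ``100 * (1 - NM / aligned_len)``.
    """

    read_id: str
    gene_id: str
    aligned_len: int
    mismatches: int
    identity_pct: float
    is_paired: bool
    mate_index: int  # 1 or 2; 1 for single-end reads
    gene_start: int  # 1-based inclusive
    gene_end: int  # 1-based inclusive
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError(
                f"{self.read_id}: gene_start {self.gene_start} > gene_end {self.gene_end}"
            )
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"{self.read_id}: identity {self.identity_pct} outside [0, 100]")
        if self.aligned_len < 1:
            raise ValueError(f"{self.read_id}: aligned_len must be >= 1")


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated CAZyme module interval on a gene or protein.

    Coordinates are 1-based inclusive; ``coord_space`` records whether they
    are nucleotide positions (catalogue genes) or residue positions
    (proteins).
    """

    gene_id: str
    family: str
    start: int
    end: int
    coord_space: str = "nucleotide"

    _COORD_SPACES = ("nucleotide", "protein")

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family must be non-empty")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start {self.start} < 1 (coordinates are 1-based)")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.coord_space not in self._COORD_SPACES:
            raise ValueError(f"unknown coord_space {self.coord_space!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file, preserving record order.

    Raises ``ValueError`` on duplicate ids or an empty file.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_aligned_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA (MSA); all rows must have equal length."""
    records = read_fasta(path)
    widths = {len(r.seq) for r in records}
    if len(widths) > 1:
        raise ValueError(f"{path}: alignment rows have unequal lengths {sorted(widths)}")
    return records


# ---------------------------------------------------------------------------
# SAM/BAM streaming
# ---------------------------------------------------------------------------

def _alignment_columns(cigartuples: list[tuple[int, int]]) -> int:
    return sum(length for op, length in cigartuples if op in _COLUMN_OPS)


def record_to_alignment(rec: pysam.AlignedSegment) -> AlignmentRecord:
    """Convert a mapped pysam record into an :class:`AlignmentRecord`."""
    if not rec.has_tag("NM"):
        raise ValueError(f"record {rec.query_name!r} lacks the NM tag")
    nm = rec.get_tag("NM")
    aligned_len = _alignment_columns(rec.cigartuples or [])
    if aligned_len < 1:
        raise ValueError(f"record {rec.query_name!r} has an empty alignment")
    identity = 100.0 * (1.0 - nm / aligned_len)
    mate = 2 if (rec.is_paired and rec.is_read2) else 1
    return AlignmentRecord(
        read_id=rec.query_name,
        gene_id=rec.reference_name,
        aligned_len=aligned_len,
        mismatches=int(nm),
        identity_pct=identity,
        is_paired=rec.is_paired,
        mate_index=mate,
        gene_start=rec.reference_start + 1,
        gene_end=rec.reference_end,  # pysam end is exclusive 0-based == inclusive 1-based
        is_secondary=rec.is_secondary or rec.is_supplementary,
    )


def stream_name_grouped_alignments(
    path: str | Path,
) -> Iterator[tuple[str, list[AlignmentRecord]]]:
    """Yield ``(read_name, records)`` groups from a name-grouped SAM/BAM.

    Records sharing a query name must be contiguous (samtools collate
    semantics).  Unmapped records are skipped (a group may come out empty);
    duplicate- and QC-fail-flagged records are dropped.  A read name that
    reappears after its group closed raises ``ValueError``.
    """
    seen: set[str] = set()
    current: str | None = None
    group: list[AlignmentRecord] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            name = rec.query_name
            if name != current:
                if current is not None:
                    yield current, group
                if name in seen:
                    raise ValueError(
                        f"read name {name!r} is not contiguous: input must be name-grouped"
                    )
                seen.add(name)
                current, group = name, []
            if rec.is_unmapped or rec.is_duplicate or rec.is_qcfail:
                continue
            group.append(record_to_alignment(rec))
        if current is not None:
            yield current, group


# ---------------------------------------------------------------------------
# Tabular artifacts
# ---------------------------------------------------------------------------

_DOMAIN_COLUMNS = ["gene_id", "family", "start", "end", "coord_space"]


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "family": str, "coord_space": str})
    missing = [c for c in _DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        DomainAnnotation(
            gene_id=row.gene_id,
            family=row.family,
            start=int(row.start),
            end=int(row.end),
            coord_space=row.coord_space,
        )
        for row in df.itertuples()
    ]


def write_domain_table(domains: list[DomainAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(d.gene_id, d.family, d.start, d.end, d.coord_space) for d in domains],
        columns=_DOMAIN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_cutoff_table(evaluations: list, path: str | Path) -> None:
    """Write per-family calibration results (one row per family)."""
    rows = []
    for ev in evaluations:
        rows.append(
            {
                "family_id": ev.family_id,
                "final_cutoff": _fmt(ev.final_cutoff),
                "status": ev.status,
                "per_fold_cutoffs": ",".join(_fmt(c) for c in ev.per_fold_cutoffs) or MISSING,
                "per_fold_f1": ",".join(f"{f:.6g}" for f in ev.per_fold_f1) or MISSING,
                "tp": ev.tp,
                "fp": ev.fp,
                "fn": ev.fn,
                "precision": f"{ev.precision:.6g}",
                "recall": f"{ev.recall:.6g}",
                "f1": f"{ev.f1:.6g}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cutoff_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "status": str})
    df["final_cutoff"] = df["final_cutoff"].apply(
        lambda v: math.inf if v == MISSING else float(v)
    )
    return df


def _fmt(value: float) -> str:
    if value is None or (isinstance(value, float) and math.isinf(value)):
        return MISSING
    return f"{value:.6g}"


def write_profile_table(profile, path: str | Path) -> None:
    """Write a :class:`~cazprofiler.profiling.CazyProfile` as TSV."""
    rows = [
        {
            "family": fam,
            "raw_count": f"{profile.raw_count[fam]:.6f}",
            "family_length_bp": profile.family_length_bp.get(fam, 0),
            "rpkm": f"{profile.rpkm[fam]:.6f}",
        }
        for fam in sorted(profile.raw_count)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profile_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"family": str})


def read_copy_number_table(path: str | Path) -> pd.DataFrame:
    """Long-form copy-number table: columns genome, family, copies."""
    df = pd.read_csv(path, sep="\t", dtype={"genome": str, "family": str})
    if (df["copies"] < 0).any():
        raise ValueError(f"{path}: negative copy numbers")
    return df


def read_taxonomy_table(path: str | Path) -> pd.DataFrame:
    """Taxonomy table: columns genome, phylum, genus, species."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_orf_composition_table(path: str | Path) -> pd.DataFrame:
    """ORF composition: columns genome, orf_id, families (comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["families"] = df["families"].apply(lambda s: tuple(s.split(",")))
    return df
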
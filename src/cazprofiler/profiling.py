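"""CAZyme family abundance profiling from name-grouped read alignments.

Alignments are filtered (>45 bp aligned length, >97% identity, both
strict), each retained mate carries weight 0.5 (paired-end) or 1.0
(single-end), and a mate overlapping k distinct annotated domain instances
across all of its retained alignments contributes w/k to each instance's
family.  Every retained mate counts once toward the filtered-read
denominator whether or not it touches a domain.  Counts are normalised to
RPKM against summed per-family annotated domain length and the filtered
read total.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from cazprofiler.io_formats import (
    AlignmentRecord,
    DomainAnnotation,
    stream_name_grouped_alignments,
)


@dataclass(frozen=True)
class FilterParams:
    """Alignment retention thresholds (both comparisons strict)."""

    min_aligned_len: int = 45
    min_identity_pct: float = 97.0

    def __post_init__(self) -> None:
        if self.min_aligned_len <= 0 or self.min_identity_pct <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclass
class CazyProfile:
    sample_id: str
    raw_count: dict[str, float]
    rpkm: dict[str, float]
    total_filtered_reads: float
    family_length_bp: dict[str, int]


def filter_alignment(rec: AlignmentRecord, params: FilterParams = FilterParams()) -> bool:
    return (
        rec.aligned_len > params.min_aligned_len
        and rec.identity_pct > params.min_identity_pct
    )


class DomainIndex:
    """Per-gene interval lookup over nucleotide-space domain annotations.

    Each annotation row is one *domain instance*; instances keep their
    identity so a mate overlapping the same instance through several
    alignments is counted against it only once.
    """

    def __init__(
        self,
        domains: list[DomainAnnotation],
        known_genes: set[str] | None = None,
    ) -> None:
        self.instances: list[DomainAnnotation] = []
        self._by_gene: dict[str, list[tuple[int, int, int]]] = {}
        for inst_id, dom in enumerate(domains):
            if dom.coord_space != "nucleotide":
                raise ValueError(
                    f"{dom.gene_id}/{dom.family}: read counting needs nucleotide coordinates"
                )
            if known_genes is not None and dom.gene_id not in known_genes:
                raise ValueError(f"domain references unknown gene {dom.gene_id!r}")
            self.instances.append(dom)
            self._by_gene.setdefault(dom.gene_id, []).append((dom.start, dom.end, inst_id))

    def overlapping(self, gene_id: str, start: int, end: int) -> set[int]:
        """Instance ids with >= 1 bp intersection with [start, end]."""
        return {
            inst_id
            for s, e, inst_id in self._by_gene.get(gene_id, [])
            if s <= end and start <= e
        }

    def family_lengths(self) -> dict[str, int]:
        lengths: dict[str, int] = {}
        for dom in self.instances:
            lengths[dom.family] = lengths.get(dom.family, 0) + len(dom)
        return lengths

    @property
    def families(self) -> set[str]:
        return {d.family for d in self.instances}


def count_group(
    group: list[AlignmentRecord], index: DomainIndex
) -> tuple[dict[str, float], float]:
    """Count one read name's retained alignments.

    Returns per-family count increments and the filtered-read weight
    increment.  ``group`` must already be filtered; each mate present adds
    its weight w to the denominator exactly once, and w/k to each of the k
    distinct domain instances it overlaps (0 instances -> no family mass).
    """
    increments: dict[str, float] = {}
    total_weight = 0.0
    mates: dict[int, list[AlignmentRecord]] = {}
    for rec in group:
        mates.setdefault(rec.mate_index, []).append(rec)
    for recs in mates.values():
        w = 0.5 if recs[0].is_paired else 1.0
        total_weight += w
        overlapped: set[int] = set()
        for rec in recs:
            overlapped |= index.overlapping(rec.gene_id, rec.gene_start, rec.gene_end)
        if not overlapped:
            continue
        share = w / len(overlapped)
        for inst_id in overlapped:
            fam = index.instances[inst_id].family
            increments[fam] = increments.get(fam, 0.0) + share
    return increments, total_weight


def finalize_profile(
    counts: dict[str, float],
    total_filtered_reads: float,
    index: DomainIndex,
    sample_id: str,
) -> CazyProfile:
    """Assemble the profile and compute RPKM for every catalogue family.

    RPKM = count / (family domain length in kb x filtered reads in
    millions); families without any counted read appear with RPKM 0.
    """
    if total_filtered_reads <= 0:
        raise ValueError("no reads pass filters: cannot normalise")
    lengths = index.family_lengths()
    raw = {fam: counts.get(fam, 0.0) for fam in index.families}
    rpkm = {
        fam: raw[fam] / ((lengths[fam] / 1e3) * (total_filtered_reads / 1e6))
        for fam in raw
    }
    return CazyProfile(
        sample_id=sample_id,
        raw_count=raw,
        rpkm=rpkm,
        total_filtered_reads=total_filtered_reads,
        family_length_bp=lengths,
    )


def apply_pseudocount(profile: CazyProfile, pc: float = 0.01) -> CazyProfile:
    """Add a constant to every family's RPKM (raw counts untouched)."""
    if pc < 0:
        raise ValueError("pseudocount must be non-negative")
    return replace(profile, rpkm={f: v + pc for f, v in profile.rpkm.items()})


def profile_sample(
    alignments: str | Path,
    domains: list[DomainAnnotation],
    sample_id: str,
    params: FilterParams = FilterParams(),
    known_genes: set[str] | None = None,
) -> CazyProfile:
    """Stream a name-grouped SAM/BAM into a per-sample CAZy profile."""
    index = DomainIndex(domains, known_genes=known_genes)
    counts: dict[str, float] = {}
    total = 0.0
    for _, group in stream_name_grouped_alignments(alignments):
        retained = [rec for rec in group if filter_alignment(rec, params)]
        if not retained:
            continue
        inc, weight = count_group(retained, index)
        total += weight
        for fam, val in inc.items():
            counts[fam] = counts.get(fam, 0.0) + val
    return finalize_profile(counts, total, index, sample_id)
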
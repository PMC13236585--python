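"""Domain annotation of gene/protein sequences with calibrated fold models.

Each of a family's K fold HMMs is searched against the targets; hits are
filtered at the family's calibrated P-value cutoff; a residue is kept when
at least half of the fold models (rounded up) cover it with a significant
hit; maximal runs of kept residues become domain annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyhmmer.easel import Alphabet
from pyhmmer.plan7 import Background, Pipeline

from cazprofiler.calibration import CalibratedFamilyModel, _hit_name, _records_to_block
from cazprofiler.io_formats import DomainAnnotation, SequenceRecord

_AMINO = Alphabet.amino()


@dataclass(frozen=True)
class FoldHit:
    """One significant envelope of one fold model on one target."""

    family_id: str
    fold_index: int
    target_id: str
    target_start: int  # 1-based inclusive residue coordinates
    target_end: int
    p_value: float


def majority_threshold(n_folds: int) -> int:
    """Votes needed to keep a residue: at least half the folds, rounded up."""
    return (n_folds + 1) // 2


def search_targets(
    targets: list[SequenceRecord], model: CalibratedFamilyModel
) -> list[FoldHit]:
    """Search every fold model against every target; keep significant hits.

    A hit is significant when its sequence-level P-value is at or below the
    family's final cutoff; envelope coordinates of its reported domains are
    returned.  Rejected families cannot be used for annotation.
    """
    if model.evaluation.status == "rejected_low_f1":
        raise ValueError(
            f"family {model.family_id} was rejected at calibration (mean F1 < 0.5)"
        )
    if not targets:
        return []
    block = _records_to_block(targets)
    hits_out: list[FoldHit] = []
    for fold, hmm in enumerate(model.fold_models):
        pipeline = Pipeline(_AMINO, background=Background(_AMINO))
        for hit in pipeline.search_hmm(hmm, block):
            if hit.pvalue > model.final_cutoff:
                continue
            for dom in hit.domains:
                if not dom.reported:
                    continue
                hits_out.append(
                    FoldHit(
                        family_id=model.family_id,
                        fold_index=fold,
                        target_id=_hit_name(hit),
                        target_start=dom.env_from,
                        target_end=dom.env_to,
                        p_value=hit.pvalue,
                    )
                )
    return hits_out


def majority_vote(
    hits: list[FoldHit], n_folds: int
) -> tuple[dict[int, int], set[int]]:
    """Per-residue fold votes and the retained residue set.

    All hits must concern one target x family.  Overlapping hits from the
    same fold are unioned first so each fold contributes at most one vote
    per residue; a residue is retained iff its votes reach ceil(n_folds/2).
    """
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    keys = {(h.target_id, h.family_id) for h in hits}
    if len(keys) > 1:
        raise ValueError(f"hits span multiple target/family pairs: {sorted(keys)}")
    per_fold: dict[int, set[int]] = {}
    for h in hits:
        per_fold.setdefault(h.fold_index, set()).update(
            range(h.target_start, h.target_end + 1)
        )
    votes: dict[int, int] = {}
    for residues in per_fold.values():
        for r in residues:
            votes[r] = votes.get(r, 0) + 1
    need = majority_threshold(n_folds)
    retained = {r for r, v in votes.items() if v >= need}
    return votes, retained


def merge_regions(
    retained: set[int], target_id: str, family_id: str, coord_space: str = "protein"
) -> list[DomainAnnotation]:
    """Collapse maximal runs of consecutive retained residues into intervals."""
    if not retained:
        return []
    out: list[DomainAnnotation] = []
    residues = sorted(retained)
    start = prev = residues[0]
    for r in residues[1:]:
        if r == prev + 1:
            prev = r
            continue
        out.append(DomainAnnotation(target_id, family_id, start, prev, coord_space))
        start = prev = r
    out.append(DomainAnnotation(target_id, family_id, start, prev, coord_space))
    return out


def protein_to_gene_coords(
    annotation: DomainAnnotation, gene_length_nt: int
) -> DomainAnnotation:
    """Map residue coordinates to nucleotide coordinates (frame 1, no introns).

    Residues r_start..r_end correspond to nucleotides
    3*(r_start-1)+1 .. 3*r_end.
    """
    if annotation.coord_space != "protein":
        raise ValueError("annotation is not in protein coordinate space")
    nt_start = 3 * (annotation.start - 1) + 1
    nt_end = 3 * annotation.end
    if nt_end > gene_length_nt:
        raise ValueError(
            f"{annotation.gene_id}: residue {annotation.end} maps beyond the "
            f"{gene_length_nt} nt gene"
        )
    return DomainAnnotation(
        gene_id=annotation.gene_id,
        family=annotation.family,
        start=nt_start,
        end=nt_end,
        coord_space="nucleotide",
    )


def annotate_targets(
    targets: list[SequenceRecord],
    models: dict[str, CalibratedFamilyModel],
) -> list[DomainAnnotation]:
    """End-to-end annotation: search, vote, merge — per family per target.

    Rejected families are skipped; annotations from different families on
    the same target are kept independently.  Output is sorted by
    (target, family, start).
    """
    annotations: list[DomainAnnotation] = []
    for fid in sorted(models):
        model = models[fid]
        if model.evaluation.status == "rejected_low_f1":
            continue
        hits = search_targets(targets, model)
        by_target: dict[str, list[FoldHit]] = {}
        for h in hits:
            by_target.setdefault(h.target_id, []).append(h)
        for target_id in sorted(by_target):
            _, retained = majority_vote(by_target[target_id], model.n_folds)
            annotations.extend(merge_regions(retained, target_id, fid))
    annotations.sort(key=lambda a: (a.gene_id, a.family, a.start))
    return annotations
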
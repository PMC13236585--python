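"""Per-family profile-HMM construction and P-value cutoff calibration.

For each CAZy (sub)family, module sequences are clustered at 60% identity
into blocking groups, the groups are distributed over K cross-validation
folds (similar sequences never straddle a fold's train/test boundary), a
profile HMM is built from each fold's training modules, and the P-value
threshold maximising the F1 score on full-length held-out sequences is
found by exhaustive sweep over the observed scores.  The family's final
cutoff is the median of the per-fold optima; families whose mean F1 falls
below 0.5 are rejected, and families with fewer than five sequences fall
back to the median cutoff of their CAZy class.
"""

from __future__ import annotations

import logging
import math
import re
import statistics
from dataclasses import dataclass, field

import edlib
import pyhmmer
from pyhmmer.easel import Alphabet, DigitalSequenceBlock, TextMSA, TextSequence
from pyhmmer.plan7 import HMM, Background, Builder, Pipeline

from cazprofiler.io_formats import SequenceRecord

logger = logging.getLogger(__name__)


def _hit_name(hit) -> str:
    name = hit.name
    return name if isinstance(name, str) else name.decode()

_AMINO = Alphabet.amino()
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

CAZY_CLASSES = ("GH", "GT", "PL", "CE", "CBM", "AA")

MIN_SEQUENCES_FOR_CV = 5
F1_REJECTION_THRESHOLD = 0.5


def cazy_class_of(family_id: str) -> str:
    for cls in sorted(CAZY_CLASSES, key=len, reverse=True):
        if family_id.startswith(cls):
            return cls
    raise ValueError(f"cannot derive CAZy class from family id {family_id!r}")


@dataclass
class FamilyDefinition:
    """A CAZy (sub)family: its module sequences and hierarchy position.

    ``member_modules`` are excised domain regions named
    ``<source_id>/<start>-<end>``; ``full_sequences`` maps source ids to the
    full-length proteins used as test instances; ``alignment`` optionally
    carries a pre-computed module MSA (gapped rows, ids matching modules).
    """

    family_id: str
    parent: str | None = None
    member_modules: list[SequenceRecord] = field(default_factory=list)
    full_sequences: dict[str, SequenceRecord] = field(default_factory=dict)
    alignment: list[SequenceRecord] | None = None

    @property
    def cazy_class(self) -> str:
        return cazy_class_of(self.family_id)

    def __post_init__(self) -> None:
        if self.parent is not None and not self.family_id.startswith(self.parent):
            raise ValueError(
                f"subfamily {self.family_id!r} does not carry parent prefix {self.parent!r}"
            )


@dataclass(frozen=True)
class ModuleExtractionParams:
    evalue_threshold: float = 1e-15
    coverage_threshold: float = 0.35

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")


@dataclass(frozen=True)
class BlockingGroup:
    group_id: int
    member_ids: frozenset[str]


@dataclass
class FoldAssignment:
    n_folds: int
    fold_of_group: dict[int, int]
    blocked: bool
    fold_of_sequence: dict[str, int]

    def test_ids(self, fold: int) -> set[str]:
        return {sid for sid, f in self.fold_of_sequence.items() if f == fold}


@dataclass
class CutoffEvaluation:
    family_id: str
    per_fold_cutoffs: list[float]
    per_fold_f1: list[float]
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    final_cutoff: float
    status: str  # optimized | class_median_fallback | rejected_low_f1


@dataclass
class CalibratedFamilyModel:
    family_id: str
    fold_models: list[HMM]
    final_cutoff: float
    evaluation: CutoffEvaluation

    @property
    def n_folds(self) -> int:
        return len(self.fold_models)


# ---------------------------------------------------------------------------
# Pairwise identity and greedy centroid clustering
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: exact matches / alignment columns."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
    return matches / columns if columns else 0.0


def greedy_cluster(records: list[SequenceRecord], identity: float) -> list[list[SequenceRecord]]:
    """Greedy centroid clustering: longest-first, join the first centroid
    with identity >= threshold, else found a new cluster."""
    ordered = sorted(records, key=lambda r: -len(r.seq))
    clusters: list[list[SequenceRecord]] = []
    for rec in ordered:
        for cluster in clusters:
            if pairwise_identity(rec.seq, cluster[0].seq) >= identity:
                cluster.append(rec)
                break
        else:
            clusters.append([rec])
    return clusters


def dereplicate_modules(
    modules: list[SequenceRecord], identity: float = 0.99
) -> list[SequenceRecord]:
    """Collapse near-identical modules, returning one centroid per cluster."""
    if not modules:
        raise ValueError("no modules to dereplicate")
    return [cluster[0] for cluster in greedy_cluster(modules, identity)]


def build_blocking_groups(
    modules: list[SequenceRecord], identity: float = 0.60
) -> list[BlockingGroup]:
    """Partition modules into blocking groups at the given identity."""
    if not modules:
        raise ValueError("no modules to cluster")
    clusters = greedy_cluster(modules, identity)
    return [
        BlockingGroup(group_id=i, member_ids=frozenset(r.id for r in cluster))
        for i, cluster in enumerate(clusters)
    ]


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------

def assign_folds(
    groups: list[BlockingGroup], n_folds: int = 5, seed: int = 0
) -> FoldAssignment:
    """Distribute blocking groups (or, with fewer groups than folds,
    individual sequences) over cross-validation folds.

    Blocked mode packs groups greedily — largest group first, into the
    currently smallest fold — so folds end up near-balanced while no group
    ever spans a fold's train/test boundary.
    """
    import random

    all_ids = [sid for g in groups for sid in g.member_ids]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("blocking groups overlap: not a partition")
    if len(all_ids) < n_folds:
        raise ValueError(
            f"only {len(all_ids)} sequences for {n_folds} folds; "
            "use the class-median fallback cutoff for this family"
        )

    if len(groups) >= n_folds:
        fold_sizes = [0] * n_folds
        fold_of_group: dict[int, int] = {}
        for g in sorted(groups, key=lambda g: (-len(g.member_ids), g.group_id)):
            fold = min(range(n_folds), key=lambda k: (fold_sizes[k], k))
            fold_of_group[g.group_id] = fold
            fold_sizes[fold] += len(g.member_ids)
        fold_of_sequence = {
            sid: fold_of_group[g.group_id] for g in groups for sid in g.member_ids
        }
        return FoldAssignment(n_folds, fold_of_group, True, fold_of_sequence)

    rng = random.Random(seed)
    ids = sorted(all_ids)
    rng.shuffle(ids)
    fold_of_sequence = {sid: i % n_folds for i, sid in enumerate(ids)}
    return FoldAssignment(n_folds, {}, False, fold_of_sequence)


# ---------------------------------------------------------------------------
# HMM construction and scoring
# ---------------------------------------------------------------------------

def _records_to_block(records: list[SequenceRecord]) -> DigitalSequenceBlock:
    return DigitalSequenceBlock(
        _AMINO,
        [
            TextSequence(name=r.id.encode(), sequence=r.seq).digitize(_AMINO)
            for r in records
        ],
    )


def build_hmm_from_alignment(rows: list[SequenceRecord], name: str) -> HMM:
    """Build a profile HMM from gapped alignment rows (pyhmmer Builder)."""
    # drop columns that became all-gap after subsetting rows
    width = len(rows[0].seq)
    keep = [
        j for j in range(width) if any(r.seq[j] not in "-." for r in rows)
    ]
    texts = [
        TextSequence(name=r.id.encode(), sequence="".join(r.seq[j] for j in keep))
        for r in rows
    ]
    msa = TextMSA(name=name.encode(), sequences=texts).digitize(_AMINO)
    builder = Builder(_AMINO)
    hmm, _, _ = builder.build_msa(msa, Background(_AMINO))
    return hmm


def build_fold_model(
    training_modules: list[SequenceRecord],
    alignment: list[SequenceRecord] | None,
    name: str,
    min_len_fraction: float = 0.8,
) -> HMM:
    """Build one fold's profile HMM from its training modules.

    Modules shorter than ``min_len_fraction`` times the median training
    module length are dropped first.  The family MSA (if provided) supplies
    the aligned rows; otherwise equal-length modules are stacked ungapped.
    """
    if not training_modules:
        raise ValueError("no training modules")
    lengths = sorted(len(m.seq) for m in training_modules)
    median_len = statistics.median(lengths)
    kept = [m for m in training_modules if len(m.seq) >= min_len_fraction * median_len]
    if len(kept) < 2:
        raise ValueError(
            f"{name}: only {len(kept)} training modules survive the length filter"
        )
    kept_ids = {m.id for m in kept}
    if alignment is not None:
        rows = [r for r in alignment if r.id in kept_ids]
        if len(rows) != len(kept):
            missing = sorted(kept_ids - {r.id for r in rows})
            raise ValueError(f"{name}: alignment lacks rows for {missing[:3]}")
    else:
        if len({len(m.seq) for m in kept}) != 1:
            raise ValueError(
                f"{name}: unaligned modules of unequal length; provide an MSA"
            )
        rows = kept
    return build_hmm_from_alignment(rows, name)


def score_sequences(hmm: HMM, records: list[SequenceRecord]) -> dict[str, float]:
    """Best per-target P-value of ``hmm`` against each record.

    The P-value is the HMM engine's per-target tail probability (its
    E-value divided by the effective search-space size).  Records without
    any reported hit score ``+inf`` and can never be classified positive.
    """
    scores = {r.id: math.inf for r in records}
    if not records:
        return scores
    pipeline = Pipeline(_AMINO, background=Background(_AMINO))
    hits = pipeline.search_hmm(hmm, _records_to_block(records))
    for hit in hits:
        name = _hit_name(hit)
        scores[name] = min(scores[name], hit.pvalue)
    return scores


# ---------------------------------------------------------------------------
# Module extraction (reference models -> excised module sequences)
# ---------------------------------------------------------------------------

def extract_modules(
    sequences: list[SequenceRecord],
    reference_models: dict[str, HMM],
    params: ModuleExtractionParams = ModuleExtractionParams(),
) -> dict[str, list[SequenceRecord]]:
    """Excise per-family module subsequences from full-length proteins.

    A domain hit survives iff its i-E-value is at or below the E-value
    threshold and it covers at least ``coverage_threshold`` of the model
    ((hmm_to - hmm_from + 1) / model length).  Surviving envelopes are cut
    out as module sequences named ``<source>/<start>-<end>``.
    """
    block = _records_to_block(sequences)
    by_id = {r.id: r for r in sequences}
    out: dict[str, list[SequenceRecord]] = {}
    for family_id, hmm in reference_models.items():
        pipeline = Pipeline(_AMINO, background=Background(_AMINO))
        hits = pipeline.search_hmm(hmm, block)
        modules: list[SequenceRecord] = []
        for hit in hits:
            src = by_id[_hit_name(hit)]
            for dom in hit.domains:
                if not dom.reported:
                    continue
                if dom.i_evalue > params.evalue_threshold:
                    continue
                ali = dom.alignment
                coverage = (ali.hmm_to - ali.hmm_from + 1) / hmm.M
                if coverage < params.coverage_threshold:
                    continue
                start, end = dom.env_from, dom.env_to
                modules.append(
                    SequenceRecord(
                        id=f"{src.id}/{start}-{end}",
                        seq=src.seq[start - 1 : end],
                        description=f"source={src.id} interval={start}-{end}",
                    )
                )
        if not modules:
            logger.warning("family %s: no hits survive module extraction", family_id)
        out[family_id] = modules
    return out


def module_source(module_id: str) -> str:
    """Source sequence id of a module named ``<source>/<start>-<end>``."""
    return module_id.rsplit("/", 1)[0]


# ---------------------------------------------------------------------------
# Test-instance labelling (hierarchy-aware)
# ---------------------------------------------------------------------------

def label_test_instances(
    family: FamilyDefinition,
    all_families: dict[str, FamilyDefinition],
    negative_pool: list[SequenceRecord],
    test_module_ids: set[str],
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Assemble full-length positive and negative test sequences for a fold.

    Positives are the full-length sources of the fold's test modules (any
    source that also feeds a training module is excluded to avoid leakage);
    a parent family additionally counts all its subfamilies' sequences as
    positive.  Negatives are every other family's sequences — except that,
    when evaluating a subfamily, its parent's own sequences are ignored —
    plus the external decoy pool unless the family is a CBM (non-catalytic,
    so no enzyme-based decoys apply).
    """
    test_sources = {module_source(mid) for mid in test_module_ids}
    train_sources = {
        module_source(m.id)
        for m in family.member_modules
        if m.id not in test_module_ids
    }
    usable = test_sources - train_sources
    positives = [family.full_sequences[sid] for sid in sorted(usable) if sid in family.full_sequences]

    subfamilies = {
        fid for fid, f in all_families.items() if f.parent == family.family_id
    }
    positive_ids = {p.id for p in positives}
    for fid in sorted(subfamilies):
        for rec in all_families[fid].full_sequences.values():
            if rec.id not in positive_ids:
                positives.append(rec)
                positive_ids.add(rec.id)
    if not positives:
        raise ValueError(f"{family.family_id}: empty positive set for this fold")

    skip = {family.family_id} | subfamilies
    if family.parent is not None:
        skip.add(family.parent)
    negatives: list[SequenceRecord] = []
    neg_ids: set[str] = set()
    for fid in sorted(all_families):
        if fid in skip:
            continue
        for rec in all_families[fid].full_sequences.values():
            if rec.id not in positive_ids and rec.id not in neg_ids:
                negatives.append(rec)
                neg_ids.add(rec.id)
    if family.cazy_class != "CBM":
        for rec in negative_pool:
            if rec.id not in positive_ids and rec.id not in neg_ids:
                negatives.append(rec)
                neg_ids.add(rec.id)
    return positives, negatives


# ---------------------------------------------------------------------------
# Threshold optimisation
# ---------------------------------------------------------------------------

def _f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * recall * precision / (recall + precision)
        if recall + precision > 0
        else 0.0
    )
    return precision, recall, f1


def optimize_cutoff(
    scores: list[float], labels: list[bool]
) -> tuple[float, dict[str, float]]:
    """Find the P-value threshold maximising F1.

    A sequence is classified positive iff its score is <= the threshold.
    Candidate thresholds are the distinct finite observed scores; ties are
    broken toward the smallest (most conservative) threshold.
    """
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    n_pos = sum(labels)
    if n_pos == 0:
        raise ValueError("no positive labels")

    finite = sorted(
        {s for s in scores if math.isfinite(s)}
    )
    if not finite:
        return 0.0, {"tp": 0, "fp": 0, "fn": n_pos, "precision": 0.0, "recall": 0.0, "f1": 0.0}

    order = sorted(range(len(scores)), key=lambda i: scores[i])
    best: tuple[float, dict] | None = None
    tp = fp = 0
    idx = 0
    for threshold in finite:
        while idx < len(order) and scores[order[idx]] <= threshold:
            if labels[order[idx]]:
                tp += 1
            else:
                fp += 1
            idx += 1
        fn = n_pos - tp
        precision, recall, f1 = _f1(tp, fp, fn)
        if best is None or f1 > best[1]["f1"]:
            best = (
                threshold,
                {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall, "f1": f1},
            )
    return best


# ---------------------------------------------------------------------------
# Family finalisation and orchestration
# ---------------------------------------------------------------------------

def finalize_family(
    family_id: str,
    fold_results: list[tuple[float, dict[str, float]]],
    n_sequences: int,
    class_median_cutoff: float | None = None,
    min_f1: float = F1_REJECTION_THRESHOLD,
) -> CutoffEvaluation:
    """Aggregate per-fold optima into the family's final cutoff and status."""
    if n_sequences < MIN_SEQUENCES_FOR_CV:
        if class_median_cutoff is None:
            raise ValueError(
                f"{family_id}: class median cutoff requested before any family "
                "of its class was calibrated"
            )
        return CutoffEvaluation(
            family_id=family_id,
            per_fold_cutoffs=[],
            per_fold_f1=[],
            tp=0,
            fp=0,
            fn=0,
            precision=0.0,
            recall=0.0,
            f1=0.0,
            final_cutoff=class_median_cutoff,
            status="class_median_fallback",
        )
    if not fold_results:
        raise ValueError(f"{family_id}: no successful folds")
    cutoffs = [c for c, _ in fold_results]
    f1s = [m["f1"] for _, m in fold_results]
    tp = sum(int(m["tp"]) for _, m in fold_results)
    fp = sum(int(m["fp"]) for _, m in fold_results)
    fn = sum(int(m["fn"]) for _, m in fold_results)
    precision, recall, f1 = _f1(tp, fp, fn)
    status = "rejected_low_f1" if statistics.fmean(f1s) < min_f1 else "optimized"
    return CutoffEvaluation(
        family_id=family_id,
        per_fold_cutoffs=cutoffs,
        per_fold_f1=f1s,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        final_cutoff=statistics.median(cutoffs),
        status=status,
    )


def calibrate_family(
    family: FamilyDefinition,
    all_families: dict[str, FamilyDefinition],
    negative_pool: list[SequenceRecord],
    n_folds: int = 5,
    seed: int = 0,
    min_len_fraction: float = 0.8,
) -> CalibratedFamilyModel:
    """Run blocked cross-validation for one family with >= 5 sequences."""
    groups = build_blocking_groups(family.member_modules)
    assignment = assign_folds(groups, n_folds=n_folds, seed=seed)
    modules_by_id = {m.id: m for m in family.member_modules}

    fold_models: list[HMM] = []
    fold_results: list[tuple[float, dict[str, float]]] = []
    for fold in range(n_folds):
        test_ids = assignment.test_ids(fold)
        train = [m for mid, m in modules_by_id.items() if mid not in test_ids]
        try:
            hmm = build_fold_model(
                train,
                family.alignment,
                name=f"{family.family_id}.fold{fold}",
                min_len_fraction=min_len_fraction,
            )
        except ValueError as exc:
            logger.warning("%s fold %d skipped: %s", family.family_id, fold, exc)
            continue
        positives, negatives = label_test_instances(
            family, all_families, negative_pool, test_ids
        )
        records = positives + negatives
        labels = [True] * len(positives) + [False] * len(negatives)
        score_map = score_sequences(hmm, records)
        scores = [score_map[r.id] for r in records]
        cutoff, metrics = optimize_cutoff(scores, labels)
        fold_models.append(hmm)
        fold_results.append((cutoff, metrics))

    evaluation = finalize_family(
        family.family_id, fold_results, n_sequences=len(family.member_modules)
    )
    return CalibratedFamilyModel(
        family_id=family.family_id,
        fold_models=fold_models,
        final_cutoff=evaluation.final_cutoff,
        evaluation=evaluation,
    )


def calibrate_families(
    families: dict[str, FamilyDefinition],
    negative_pool: list[SequenceRecord],
    n_folds: int = 5,
    seed: int = 0,
    min_len_fraction: float = 0.8,
) -> dict[str, CalibratedFamilyModel]:
    """Calibrate every family; small families get the class-median cutoff.

    Families with fewer than five module sequences skip cross-validation:
    they receive one model built from all their modules and the median of
    the final cutoffs already optimised for their CAZy class.
    """
    models: dict[str, CalibratedFamilyModel] = {}
    small: list[FamilyDefinition] = []
    for fid in sorted(families):
        family = families[fid]
        if len(family.member_modules) < MIN_SEQUENCES_FOR_CV:
            small.append(family)
            continue
        models[fid] = calibrate_family(
            family, families, negative_pool,
            n_folds=n_folds, seed=seed, min_len_fraction=min_len_fraction,
        )

    class_cutoffs: dict[str, list[float]] = {}
    for model in models.values():
        if model.evaluation.status == "optimized":
            cls = cazy_class_of(model.family_id)
            class_cutoffs.setdefault(cls, []).append(model.final_cutoff)

    for family in small:
        cls = family.cazy_class
        if cls not in class_cutoffs:
            raise ValueError(
                f"{family.family_id}: no calibrated family of class {cls} "
                "to provide a median fallback cutoff"
            )
        median_cutoff = statistics.median(class_cutoffs[cls])
        evaluation = finalize_family(
            family.family_id,
            [],
            n_sequences=len(family.member_modules),
            class_median_cutoff=median_cutoff,
        )
        hmm = build_fold_model(
            family.member_modules,
            family.alignment,
            name=f"{family.family_id}.all",
            min_len_fraction=min_len_fraction,
        )
        models[family.family_id] = CalibratedFamilyModel(
            family_id=family.family_id,
            fold_models=[hmm],
            final_cutoff=median_cutoff,
            evaluation=evaluation,
        )
    return models


def save_models(models: dict[str, CalibratedFamilyModel], outdir) -> None:
    """Write fold models as HMMER3 ASCII, one file per family."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for fid, model in models.items():
        with open(outdir / f"{fid}.hmm", "wb") as fh:
            for k, hmm in enumerate(model.fold_models):
                renamed = hmm.copy()
                renamed.name = f"{fid}.fold{k}".encode()
                renamed.write(fh, binary=False)


def load_models(
    hmm_dir, cutoff_table
) -> dict[str, CalibratedFamilyModel]:
    """Reload fold models plus final cutoffs written by ``save_models``."""
    from pathlib import Path

    from pyhmmer.plan7 import HMMFile

    out: dict[str, CalibratedFamilyModel] = {}
    for row in cutoff_table.itertuples():
        path = Path(hmm_dir) / f"{row.family_id}.hmm"
        with HMMFile(str(path)) as fh:
            fold_models = list(fh)
        evaluation = CutoffEvaluation(
            family_id=row.family_id,
            per_fold_cutoffs=[],
            per_fold_f1=[],
            tp=int(row.tp),
            fp=int(row.fp),
            fn=int(row.fn),
            precision=float(row.precision),
            recall=float(row.recall),
            f1=float(row.f1),
            final_cutoff=float(row.final_cutoff),
            status=row.status,
        )
        out[row.family_id] = CalibratedFamilyModel(
            family_id=row.family_id,
            fold_models=fold_models,
            final_cutoff=float(row.final_cutoff),
            evaluation=evaluation,
        )
    return out
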
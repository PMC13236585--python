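"""Clustering, fold blocking, labelling and cutoff optimisation."""

from __future__ import annotations

import math
import random
import statistics

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cazprofiler.calibration import (
    FamilyDefinition,
    assign_folds,
    build_blocking_groups,
    build_fold_model,
    dereplicate_modules,
    finalize_family,
    label_test_instances,
    optimize_cutoff,
    pairwise_identity,
    score_sequences,
)
from cazprofiler.io_formats import SequenceRecord


def _seqs(*pairs):
    return [SequenceRecord(i, s) for i, s in pairs]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClustering:
    def test_identical_sequences_collapse(self):
        reps = dereplicate_modules(_seqs(("a", "MKVL" * 10), ("b", "MKVL" * 10)))
        assert len(reps) == 1

    def test_divergent_sequences_stay_apart(self):
        reps = dereplicate_modules(
            _seqs(("a", "MKVLAERT" * 5), ("b", "WWNDCYQP" * 5))
        )
        assert len(reps) == 2

    def test_copies_plus_one_divergent_give_two_representatives(self):
        base = "ACDEFGHIKLMNPQRSTVWY" * 3
        other = "W" * 60
        records = _seqs(*[(f"c{i}", base) for i in range(5)], ("d", other))
        reps = dereplicate_modules(records)
        assert sorted(r.seq for r in reps) == sorted([base, other])

    def test_blocking_groups_partition_input(self):
        rng = random.Random(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        records = _seqs(*[
            (f"s{i}", "".join(rng.choice(aas) for _ in range(40))) for i in range(12)
        ])
        groups = build_blocking_groups(records)
        ids = [sid for g in groups for sid in g.member_ids]
        assert sorted(ids) == sorted(r.id for r in records)

    def test_identity_is_matches_over_columns(self):
        # global alignment of ABAB vs AAAB-like toy: verify the formula on an
        # indel case where columns exceed both lengths
        assert pairwise_identity("ACDEFGHIK", "ACDEFGHK") == pytest.approx(8 / 9)
        assert pairwise_identity("AAAA", "AAAA") == 1.0


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

class TestAssignFolds:
    def _groups(self, sizes):
        from cazprofiler.calibration import BlockingGroup

        out, n = [], 0
        for gid, size in enumerate(sizes):
            out.append(
                BlockingGroup(gid, frozenset(f"s{n + i}" for i in range(size)))
            )
            n += size
        return out

    def test_ten_equal_groups_pack_two_per_fold(self):
        assignment = assign_folds(self._groups([3] * 10), n_folds=5, seed=0)
        assert assignment.blocked
        per_fold = {k: 0 for k in range(5)}
        for fold in assignment.fold_of_group.values():
            per_fold[fold] += 1
        assert all(v == 2 for v in per_fold.values())

    def test_fewer_groups_than_folds_falls_back_to_unblocked(self):
        assignment = assign_folds(self._groups([4, 4, 4]), n_folds=5, seed=0)
        assert not assignment.blocked

    def test_folds_tile_sequences_disjointly(self):
        for sizes in ([3] * 10, [9, 4, 4, 2, 1, 1], [2, 2, 2]):
            assignment = assign_folds(self._groups(sizes), n_folds=5, seed=3)
            ids = list(assignment.fold_of_sequence)
            assert len(ids) == sum(sizes)
            folds = set(assignment.fold_of_sequence.values())
            assert folds <= set(range(5))

    def test_no_group_spans_train_and_test(self):
        groups = self._groups([5, 4, 3, 3, 2, 2, 1])
        assignment = assign_folds(groups, n_folds=5, seed=0)
        for g in groups:
            folds = {assignment.fold_of_sequence[sid] for sid in g.member_ids}
            assert len(folds) == 1

    def test_fewer_sequences_than_folds_errors(self):
        with pytest.raises(ValueError, match="fallback"):
            assign_folds(self._groups([2, 1]), n_folds=5, seed=0)


# ---------------------------------------------------------------------------
# fold model building
# ---------------------------------------------------------------------------

class TestBuildFoldModel:
    def _modules(self, lengths):
        rng = random.Random(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(rng.choice(aas) for _ in range(max(lengths)))
        return [
            SequenceRecord(f"m{i}", base[:length]) for i, length in enumerate(lengths)
        ]

    def test_short_sequences_dropped_by_length_filter(self):
        mods = self._modules([100, 100, 100, 70])
        hmm = build_fold_model(mods, None, "fam")
        # median 100 -> the 70-mer is excluded, so the model spans 100 columns
        assert hmm.M == 100

    def test_boundary_length_retained(self):
        mods = self._modules([100, 100, 80])
        with pytest.raises(ValueError):
            # unequal unaligned lengths cannot stack without an MSA
            build_fold_model(mods, None, "fam")
        lengths = sorted(len(m.seq) for m in mods)
        assert 80 >= 0.8 * statistics.median(lengths)  # the filter itself keeps it

    def test_single_survivor_errors(self):
        mods = self._modules([100, 60])
        with pytest.raises(ValueError, match="survive"):
            build_fold_model(mods, None, "fam")


# ---------------------------------------------------------------------------
# hierarchy-aware labelling
# ---------------------------------------------------------------------------

class TestLabelTestInstances:
    def _family(self, fid, parent, n, seed):
        rng = random.Random(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        modules, fulls = [], {}
        for i in range(n):
            seq = "".join(rng.choice(aas) for _ in range(50))
            sid = f"{fid}|{i}"
            fulls[sid] = SequenceRecord(sid, "MM" + seq + "KK")
            modules.append(SequenceRecord(f"{sid}/3-52", seq))
        return FamilyDefinition(fid, parent, modules, fulls)

    @pytest.fixture()
    def universe(self):
        fams = {
            "GH13": self._family("GH13", None, 4, 0),
            "GH13_1": self._family("GH13_1", "GH13", 4, 1),
            "GH13_2": self._family("GH13_2", "GH13", 4, 2),
            "GH5": self._family("GH5", None, 4, 3),
            "CBM40": self._family("CBM40", None, 4, 4),
        }
        pool = [SequenceRecord("u1", "W" * 80), SequenceRecord("u2", "Y" * 80)]
        return fams, pool

    def test_parent_counts_subfamily_sequences_positive(self, universe):
        fams, pool = universe
        test_ids = {m.id for m in fams["GH13"].member_modules[:2]}
        pos, neg = label_test_instances(fams["GH13"], fams, pool, test_ids)
        pos_ids = {p.id for p in pos}
        assert any(i.startswith("GH13_1|") for i in pos_ids)
        assert any(i.startswith("GH13_2|") for i in pos_ids)
        neg_ids = {n.id for n in neg}
        assert not any(i.startswith("GH13") for i in neg_ids)
        assert {"u1", "u2"} <= neg_ids  # non-CBM: decoy pool added

    def test_subfamily_ignores_parent_and_marks_sister_negative(self, universe):
        fams, pool = universe
        test_ids = {m.id for m in fams["GH13_1"].member_modules[:2]}
        pos, neg = label_test_instances(fams["GH13_1"], fams, pool, test_ids)
        all_ids = {p.id for p in pos} | {n.id for n in neg}
        assert not any(i.startswith("GH13|") for i in all_ids)  # parent in neither class
        assert any(i.startswith("GH13_2|") for i in {n.id for n in neg})

    def test_cbm_family_excludes_decoy_pool(self, universe):
        fams, pool = universe
        test_ids = {m.id for m in fams["CBM40"].member_modules[:2]}
        _, neg = label_test_instances(fams["CBM40"], fams, pool, test_ids)
        assert {"u1", "u2"}.isdisjoint({n.id for n in neg})

    def test_empty_positive_set_errors(self, universe):
        fams, pool = universe
        with pytest.raises(ValueError, match="positive"):
            label_test_instances(fams["GH5"], fams, pool, set())


# ---------------------------------------------------------------------------
# cutoff optimisation
# ---------------------------------------------------------------------------

def brute_force_best_f1(scores, labels):
    """Exhaustive oracle: every observed score (and one below all) as threshold."""
    finite = sorted({s for s in scores if math.isfinite(s)})
    best = 0.0
    for t in finite:
        tp = sum(1 for s, y in zip(scores, labels) if y and s <= t)
        fp = sum(1 for s, y in zip(scores, labels) if not y and s <= t)
        fn = sum(labels) - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        best = max(best, f1)
    return best


class TestOptimizeCutoff:
    def test_perfectly_separable(self):
        cutoff, m = optimize_cutoff([1e-20, 1e-10, 1e-3], [True, True, False])
        assert cutoff == 1e-10
        assert m["f1"] == 1.0

    def test_interleaved_case_matches_brute_force(self):
        scores = [1e-9, 1e-8, 1e-7]
        labels = [False, True, False]
        cutoff, m = optimize_cutoff(scores, labels)
        assert cutoff == 1e-8
        assert m["f1"] == pytest.approx(2 / 3)

    def test_symmetric_counts_reproduce_f1_formula(self):
        # TP=8, FP=2, FN=2 -> precision = recall = f1 = 0.8
        scores = [1e-10] * 8 + [1e-10] * 2 + [math.inf] * 2 + [10.0] * 5
        labels = [True] * 8 + [False] * 2 + [True] * 2 + [False] * 5
        _, m = optimize_cutoff(scores, labels)
        assert (m["precision"], m["recall"], m["f1"]) == pytest.approx((0.8, 0.8, 0.8))

    def test_no_positive_labels_errors(self):
        with pytest.raises(ValueError):
            optimize_cutoff([1e-5], [False])

    def test_ties_break_to_smallest_threshold(self):
        # thresholds 1e-9 and 1e-8 both give F1=1 -> pick 1e-9? no: 1e-9
        # classifies only one positive. Construct a real tie instead.
        scores = [1e-9, 1e-8, 1e-2, 1e-1]
        labels = [True, False, False, False]
        cutoff, _ = optimize_cutoff(scores, labels)
        assert cutoff == 1e-9

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_exhaustive_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 60)
        labels = [rng.random() < 0.4 for _ in range(n)]
        if not any(labels):
            labels[0] = True
        scores = [
            math.inf if rng.random() < 0.1 else 10 ** rng.uniform(-30, 0)
            for _ in range(n)
        ]
        _, m = optimize_cutoff(scores, labels)
        assert m["f1"] == pytest.approx(brute_force_best_f1(scores, labels))


# ---------------------------------------------------------------------------
# finalisation
# ---------------------------------------------------------------------------

class TestFinalizeFamily:
    def _results(self, cutoffs, f1s):
        return [
            (c, {"tp": 8, "fp": 1, "fn": 1, "precision": 0.9, "recall": 0.9, "f1": f})
            for c, f in zip(cutoffs, f1s)
        ]

    def test_final_cutoff_is_median_of_fold_optima(self):
        ev = finalize_family(
            "GH2", self._results([1e-8, 1e-9, 1e-7, 1e-8, 1e-8], [0.9] * 5), 20
        )
        assert ev.final_cutoff == 1e-8
        assert ev.status == "optimized"

    def test_low_mean_f1_rejected(self):
        ev = finalize_family("GH2", self._results([1e-8] * 5, [0.4] * 5), 20)
        assert ev.status == "rejected_low_f1"

    def test_small_family_uses_class_median(self):
        ev = finalize_family("GH99", [], 3, class_median_cutoff=1e-6)
        assert ev.status == "class_median_fallback"
        assert ev.final_cutoff == 1e-6

    def test_fallback_without_class_median_errors(self):
        with pytest.raises(ValueError, match="class median"):
            finalize_family("GH99", [], 3)


# ---------------------------------------------------------------------------
# end-to-end calibration quality on the planted-motif families
# ---------------------------------------------------------------------------

class TestCalibrationQuality:
    def test_all_families_calibrate_with_high_f1(self, calibrated_models):
        for fid, model in calibrated_models.items():
            ev = model.evaluation
            assert ev.status == "optimized", fid
            assert statistics.fmean(ev.per_fold_f1) >= 0.9, fid

    def test_fold_models_recover_heldout_positives(self, family_fixture, calibrated_models):
        # at the family cutoff, a majority of fold models must detect each
        # planted holdout (the voting guarantee), and no fold may hit decoys
        model = calibrated_models["GT2"]
        positives = [t for t in family_fixture.holdout_targets if t.id.startswith("GT2|")]
        decoys = [t for t in family_fixture.holdout_targets if t.id.startswith("neg")]
        votes = {p.id: 0 for p in positives}
        for hmm in model.fold_models:
            scores = score_sequences(hmm, positives + decoys)
            hits = {sid for sid, s in scores.items() if s <= model.final_cutoff}
            assert hits.isdisjoint({d.id for d in decoys})
            for sid in votes:
                votes[sid] += sid in hits
        need = (model.n_folds + 1) // 2
        assert all(v >= need for v in votes.values())
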
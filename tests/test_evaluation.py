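import numpy as np
import pandas as pd
import pytest

from invertseg.evaluation import (ClassMapping, EvalRecord, EvalTable,
                                  classify_localization, dice, evaluate_case,
                                  stratify_by_volume, summarize)
from invertseg.volume_io import GeometryError, LabelMap
from oracles import brute_force_dice


def _lm(data, vocab):
    data = np.asarray(data, dtype=np.int16)
    return LabelMap(data=data, spacing=np.ones(3), affine=np.eye(4),
                    vocabulary=vocab)


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((6, 6, 6)) < 0.3
        m[0, 0, 0] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((1, 4, 4), bool)
        b = np.zeros((1, 4, 4), bool)
        a[0, 0:2, 0:2] = True          # |A| = 4
        b[0, 1:3, 0:2] = True          # |B| = 4, overlap 2
        assert dice(a, b) == 0.5

    def test_undefined_when_both_empty(self):
        empty = np.zeros((3, 3, 3), bool)
        assert np.isnan(dice(empty, empty))

    def test_shape_mismatch(self):
        with pytest.raises(GeometryError):
            dice(np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool))

    def test_symmetry_and_brute_force_agreement(self, rng):
        for _ in range(50):
            a = rng.random((8, 8, 8)) < rng.uniform(0, 0.5)
            b = rng.random((8, 8, 8)) < rng.uniform(0, 0.5)
            d = dice(a, b)
            assert d == dice(b, a)
            ref = brute_force_dice(a, b)
            assert (np.isnan(d) and np.isnan(ref)) or d == ref


class TestEvaluateCase:
    VOCAB = {1: "kidney", 2: "tumor"}

    def _case(self):
        ref = np.zeros((8, 8, 8))
        ref[1:4, 1:4, 1:4] = 1
        ref[5:7, 5:7, 5:7] = 2
        return _lm(ref, self.VOCAB)

    def test_identity_prediction_scores_one(self):
        ref = self._case()
        records = evaluate_case(ref, ref, ClassMapping.identity(self.VOCAB.values()))
        assert {r.class_name: r.dsc for r in records} == {"kidney": 1.0, "tumor": 1.0}
        for r in records:
            assert r.ref_volume_cm3 == r.pred_volume_cm3 > 0

    def test_empty_prediction(self):
        ref = self._case()
        empty = _lm(np.zeros((8, 8, 8)), self.VOCAB)
        records = evaluate_case(empty, ref, ClassMapping.identity(self.VOCAB.values()))
        assert all(r.dsc == 0.0 for r in records)

    def test_undefined_when_ref_class_also_empty(self):
        vocab = {1: "kidney", 3: "cyst"}
        ref = _lm(np.zeros((4, 4, 4)), vocab)
        pred = _lm(np.zeros((4, 4, 4)), vocab)
        records = evaluate_case(pred, ref, ClassMapping.identity(vocab.values()))
        assert all(np.isnan(r.dsc) for r in records)

    def test_grid_mismatch(self):
        ref = self._case()
        pred = _lm(np.zeros((4, 4, 4)), self.VOCAB)
        with pytest.raises(GeometryError):
            evaluate_case(pred, ref, ClassMapping.identity(self.VOCAB.values()))

    def test_merging_disjoint_prediction_classes_helps(self):
        """With disjoint prediction classes, the merged DSC is >= each
        class's individual DSC against the same reference."""
        ref_data = np.zeros((8, 8, 8))
        ref_data[0:4, :, :] = 1
        ref = _lm(ref_data, {1: "kidney"})
        pred_data = np.zeros((8, 8, 8))
        pred_data[0:2, :, :] = 1     # upper pole
        pred_data[2:4, :, :] = 2     # lower pole, disjoint
        pred = _lm(pred_data, {1: "kidney_upper", 2: "kidney_lower"})
        merged = evaluate_case(pred, ref, ClassMapping.from_dict(
            {"kidney_upper": "kidney", "kidney_lower": "kidney"}))[0].dsc
        upper = evaluate_case(pred, ref, ClassMapping.from_dict(
            {"kidney_upper": "kidney"}))[0].dsc
        lower = evaluate_case(pred, ref, ClassMapping.from_dict(
            {"kidney_lower": "kidney"}))[0].dsc
        assert (pred_data == 1).sum() + (pred_data == 2).sum() \
            == ((pred_data == 1) | (pred_data == 2)).sum()  # disjoint
        assert merged >= max(upper, lower)

    def test_matches_manual_per_class_dice(self, default_case):
        from invertseg.backends import default_windows, window_segment
        pred = window_segment(default_case.ct, default_windows())
        truth = default_case.truth
        records = evaluate_case(pred, truth,
                                ClassMapping.identity(truth.vocabulary.values()))
        for r in records:
            ref_mask = truth.data == truth.id_of(r.class_name)
            pred_mask = pred.data == pred.id_of(r.class_name)
            assert r.dsc == dice(pred_mask, ref_mask)


def _table(values, case_ids=None, variant="unprocessed"):
    records = []
    for i, v in enumerate(values):
        records.append(EvalRecord(
            case_id=case_ids[i] if case_ids else f"c{i}", sequence="T1w",
            variant=variant, class_name="kidney", dsc=v,
            ref_volume_cm3=10.0, pred_volume_cm3=10.0))
    t = EvalTable()
    t.extend(records)
    return t


class TestSummarize:
    def test_single_record_ci_collapses(self):
        out = summarize(_table([0.7]), n_boot=100, seed=1)
        row = out.iloc[0]
        assert row.mean_dsc == row.ci_lo == row.ci_hi == 0.7

    def test_identical_values_zero_width(self):
        out = summarize(_table([0.6] * 8), n_boot=200, seed=1)
        row = out.iloc[0]
        assert row.ci_hi - row.ci_lo == 0.0

    def test_seeded_bootstrap_reproducible(self, rng):
        t = _table(list(rng.uniform(0.2, 0.9, 15)))
        a = summarize(t, n_boot=300, seed=42)
        b = summarize(t, n_boot=300, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_undefined_excluded_and_counted(self):
        t = _table([0.5, 0.9, float("nan")])
        out = summarize(t, n_boot=100, seed=0)
        row = out.iloc[0]
        assert row.n_undefined == 1
        assert row.mean_dsc == pytest.approx(0.7)

    def test_per_class_level(self):
        records = []
        for case in ("a", "b"):
            for cls, v in (("kidney", 0.8), ("tumor", 0.2)):
                records.append(EvalRecord(case_id=case, sequence="T1w",
                                          variant="unprocessed", class_name=cls,
                                          dsc=v, ref_volume_cm3=1, pred_volume_cm3=1))
        t = EvalTable()
        t.extend(records)
        out = summarize(t, n_boot=50, seed=0, level="per_class")
        assert out.iloc[0].mean_dsc == pytest.approx(0.5)

    def test_duplicate_keys_rejected(self):
        t = _table([0.5])
        with pytest.raises(ValueError, match="duplicate"):
            t.extend(_table([0.6]).records)


class TestLocalization:
    def _ref(self):
        ref = np.zeros((8, 8, 8), bool)
        ref[1:3, 1:3, 1:3] = True
        return ref

    def test_empty_prediction_not_detected(self):
        assert classify_localization(np.zeros((8, 8, 8), bool), self._ref()) \
            == "not_detected"

    def test_exact_prediction_correct(self):
        ref = self._ref()
        assert classify_localization(ref, ref) == "correct"

    def test_contralateral_blob_incorrect(self):
        pred = np.zeros((8, 8, 8), bool)
        pred[6:8, 6:8, 6:8] = True
        assert classify_localization(pred, self._ref()) == "incorrect"

    def test_partitions_into_exactly_one_category(self, rng):
        ref = self._ref()
        for _ in range(20):
            pred = rng.random((8, 8, 8)) < rng.uniform(0, 0.2)
            outcome = classify_localization(pred, ref)
            assert outcome in ("correct", "incorrect", "not_detected")
            assert (outcome == "not_detected") == (not pred.any())
            if pred.any():
                assert (outcome == "correct") == bool((pred & ref).any())

    def test_min_overlap_fraction_flag(self):
        ref = self._ref()
        pred = np.zeros((8, 8, 8), bool)
        pred[1, 1, 1] = True  # 1/8 of the reference
        assert classify_localization(pred, ref) == "correct"
        assert classify_localization(pred, ref, min_overlap_fraction=0.5) == "incorrect"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            classify_localization(self._ref(), np.zeros((8, 8, 8), bool))


class TestStratifyByVolume:
    @staticmethod
    def _records(volumes, dscs):
        return [EvalRecord(case_id=f"c{i}", sequence="T1w", variant="inverted_black",
                           class_name="tumor", dsc=d, ref_volume_cm3=v,
                           pred_volume_cm3=v)
                for i, (v, d) in enumerate(zip(volumes, dscs))]

    def test_two_point_split(self):
        out = stratify_by_volume(self._records([10, 30], [0.2, 0.8]))
        assert out["median_volume_cm3"] == 20
        assert out["mean_dsc_below"] == 0.2
        assert out["mean_dsc_above"] == 0.8

    def test_equal_volumes_flagged(self):
        out = stratify_by_volume(self._records([5, 5, 5], [0.1, 0.2, 0.3]))
        assert out["empty_stratum"] and out["n_below"] == 0

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_volume(self._records([5], [0.5]))

    def test_matches_hand_rolled_group_by(self, rng):
        volumes = rng.uniform(1, 200, 50)
        dscs = rng.uniform(0, 1, 50)
        out = stratify_by_volume(self._records(volumes, dscs))
        med = float(np.median(volumes))
        below = dscs[volumes < med]
        above = dscs[volumes >= med]
        assert out["mean_dsc_below"] == pytest.approx(below.mean())
        assert out["mean_dsc_above"] == pytest.approx(above.mean())
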
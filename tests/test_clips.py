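"""Clip datasets: resampling, extraction, balancing, record-disjoint splits."""

from __future__ import annotations

import numpy as np
import pytest

from weakeeg.clips import (
    Clip,
    ClipDatasetSpec,
    build_eval_sets,
    build_training_set,
    extract_positive_clips,
    resample_to_200hz,
    sample_negative_clips,
)
from weakeeg.errors import EmptyClassError, SplitInfeasibleError, UnsatisfiableSamplingError
from weakeeg.records import GENERALIZED_SPIKE_WAVE, EEGRecord, SeizureEvent, WeakAnnotation
from weakeeg.synth.events import inject_seizure


def _record(record_id="r0", duration_s=200.0, weak_at=(), gold_at=(), fs=200.0):
    rec = EEGRecord(record_id=record_id, fs=fs,
                    data=np.zeros((int(duration_s * fs), 19), np.float32))
    rec.weak_annotations = [WeakAnnotation(time_s=t) for t in weak_at]
    for onset in gold_at:
        inject_seizure(rec, SeizureEvent(onset, 20.0, GENERALIZED_SPIKE_WAVE), seed=0)
    return rec


class TestResampling:
    def test_pass_through_at_200hz_is_bit_exact(self):
        x = np.random.default_rng(0).standard_normal((1000, 19)).astype(np.float32)
        assert resample_to_200hz(x, 200.0) is x

    @pytest.mark.parametrize("n_in,src_fs,n_out", [
        (2560, 256.0, 2000),
        (5120, 512.0, 2000),
        (1000, 100.0, 2000),
        (2400, 200.0, 2400),
    ])
    def test_output_length(self, n_in, src_fs, n_out):
        x = np.zeros((n_in, 2))
        assert resample_to_200hz(x, src_fs).shape == (n_out, 2)

    def test_pure_tone_survives_with_sub_percent_error(self):
        t512 = np.arange(12 * 512) / 512.0
        x = np.sin(2 * np.pi * 10 * t512)[:, None]
        y = resample_to_200hz(x, 512.0)
        ref = np.sin(2 * np.pi * 10 * np.arange(y.shape[0]) / 200.0)
        interior = slice(200, -200)  # clear of filter edge transients
        assert np.abs(y[interior, 0] - ref[interior]).max() < 0.01

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            resample_to_200hz(np.zeros((10, 1)), 0.0)


class TestClipShapes:
    def test_shape_contract_enforced(self):
        with pytest.raises(ValueError):
            Clip("r", 0.0, 12, np.zeros((100, 19), np.float32), 1, "weak")

    @pytest.mark.parametrize("bad", [dict(clip_len_s=30), dict(train_pos_fraction=1.5),
                                     dict(test_neg_pos=(0.9, 0.2)),
                                     dict(dev_test_split_fraction=0.0)])
    def test_spec_validation(self, bad):
        with pytest.raises(ValueError):
            ClipDatasetSpec(**bad)


class TestPositiveExtraction:
    def test_single_annotation_yields_one_anchored_clip(self):
        rec = _record(weak_at=[100.0])
        clips, skipped = extract_positive_clips([rec], 12, "weak")
        assert skipped == 0
        (clip,) = clips
        assert (clip.start_s, clip.label, clip.label_source) == (100.0, 1, "weak")
        assert clip.x.shape == (2400, 19)

    def test_annotation_near_record_end_is_skipped_not_raised(self):
        rec = _record(weak_at=[195.0])
        clips, skipped = extract_positive_clips([rec], 12, "weak")
        assert clips == [] and skipped == 1

    def test_60s_clips_have_12000_samples(self):
        rec = _record(weak_at=[50.0])
        clips, _ = extract_positive_clips([rec], 60, "weak")
        assert clips[0].x.shape == (12000, 19)

    def test_gold_source_anchors_at_event_onset(self):
        rec = _record(gold_at=[80.0])
        clips, _ = extract_positive_clips([rec], 12, "gold")
        assert clips[0].start_s == 80.0 and clips[0].label_source == "gold"


class TestNegativeSampling:
    def test_fully_annotated_corpus_is_unsatisfiable(self):
        with pytest.raises(UnsatisfiableSamplingError):
            sample_negative_clips([_record(weak_at=[10.0])], 5, 12, seed=0)

    def test_negatives_come_only_from_annotation_free_records(self):
        records = [_record("ann", weak_at=[10.0]), _record("free1"), _record("free2")]
        clips = sample_negative_clips(records, 100, 12, seed=0)
        assert len(clips) == 100
        assert {c.record_id for c in clips} <= {"free1", "free2"}
        assert all(c.label == 0 for c in clips)

    def test_same_seed_reproduces_offsets(self):
        records = [_record("free1"), _record("free2")]
        a = sample_negative_clips(records, 20, 12, seed=3)
        b = sample_negative_clips(records, 20, 12, seed=3)
        assert [c.start_s for c in a] == [c.start_s for c in b]


class TestTrainingSet:
    def _corpus(self):
        return [
            _record("w1", weak_at=[20.0, 60.0, 100.0]),
            _record("w2", weak_at=[30.0, 90.0]),
            _record("bg1"), _record("bg2"),
        ]

    def test_balanced_at_50_percent_and_positives_conserved(self):
        dataset = build_training_set(self._corpus(), ClipDatasetSpec())
        labels = [c.label for c in dataset]
        assert len(dataset) == 10 and sum(labels) == 5

    def test_positive_fraction_is_configurable(self):
        spec = ClipDatasetSpec(train_pos_fraction=0.2)
        dataset = build_training_set(self._corpus(), spec)
        labels = np.array([c.label for c in dataset])
        assert labels.sum() == 5 and len(dataset) == 25

    def test_undersampling_never_drops_positives(self):
        dataset = build_training_set(self._corpus(), ClipDatasetSpec())
        pos = [c for c in dataset if c.label == 1]
        assert {(c.record_id, c.start_s) for c in pos} == {
            ("w1", 20.0), ("w1", 60.0), ("w1", 100.0), ("w2", 30.0), ("w2", 90.0)
        }

    def test_no_positives_raises_empty_class(self):
        with pytest.raises(EmptyClassError):
            build_training_set([_record("bg1")], ClipDatasetSpec())


class TestEvalSets:
    def _corpus(self, n_pos_records=10, events_per_record=1):
        records = []
        for i in range(n_pos_records):
            onsets = [50.0 + 120 * k for k in range(events_per_record)]
            records.append(_record(f"p{i}", duration_s=400.0, gold_at=onsets))
        records += [_record(f"n{i}", duration_s=400.0) for i in range(6)]
        return records

    def test_pool_is_80_20_negative_positive(self):
        dev, test = build_eval_sets(self._corpus(), ClipDatasetSpec())
        pool = dev + test
        labels = np.array([c.label for c in pool])
        assert labels.sum() == 10 and len(pool) == 50
        assert labels.mean() == pytest.approx(0.2)

    def test_dev_and_test_share_no_record(self):
        dev, test = build_eval_sets(self._corpus(events_per_record=2), ClipDatasetSpec())
        assert {c.record_id for c in dev}.isdisjoint({c.record_id for c in test})

    def test_all_labels_carry_gold_provenance(self):
        dev, test = build_eval_sets(self._corpus(), ClipDatasetSpec())
        assert {c.label_source for c in dev + test} <= {"gold", "sampled_negative"}

    def test_single_positive_record_is_split_infeasible(self):
        records = [_record("p0", duration_s=400.0, gold_at=[50.0]),
                   _record("n0", duration_s=400.0)]
        with pytest.raises(SplitInfeasibleError):
            build_eval_sets(records, ClipDatasetSpec())


class TestLeakageGuard:
    def test_no_record_spans_train_and_eval(self, experiment_data):
        d = experiment_data
        assert d.train_record_ids.isdisjoint(d.eval_record_ids)
        train_ids = {c.record_id for c in d.weak_train}
        dev_ids = {c.record_id for c in d.dev}
        test_ids = {c.record_id for c in d.test}
        assert train_ids <= d.train_record_ids
        assert (dev_ids | test_ids) <= d.eval_record_ids
        assert dev_ids.isdisjoint(test_ids)

    def test_every_clip_obeys_the_shape_contract(self, experiment_data):
        d = experiment_data
        for clip in d.weak_train + d.dev + d.test:
            assert clip.x.shape == (2400, 19)
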
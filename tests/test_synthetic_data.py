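"""Synthetic EEG generator: background spectrum, ictal/artifact injection,
weak-annotation noise model, fixture corpus round trips."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import periodogram
from sklearn.linear_model import LogisticRegression

from weakeeg.errors import OverlappingEventError
from weakeeg.features import frequency_domain_features
from weakeeg.metrics import roc_auroc
from weakeeg.records import (
    FOCAL_EVOLVING,
    GENERALIZED_SPIKE_WAVE,
    LINE_NOISE_60HZ,
    NONEVOLVING_RHYTHMIC,
    ArtifactEvent,
    EEGRecord,
    SeizureEvent,
)
from weakeeg.synth.annotate import (
    NoiseModelConfig,
    annotation_quality,
    simulate_weak_annotations,
)
from weakeeg.synth.background import generate_background
from weakeeg.synth.corpus import ScenarioConfig, generate_corpus, read_corpus, write_fixture_corpus
from weakeeg.synth.events import inject_artifact, inject_seizure


def _zero_record(duration_s=60.0, fs=200.0) -> EEGRecord:
    n = int(duration_s * fs)
    return EEGRecord(record_id="zero", fs=fs, data=np.zeros((n, 19), np.float32))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x, dtype=np.float64))))


class TestBackground:
    def test_shape_and_seeded_determinism(self):
        rec = generate_background(60, 200, seed=7)
        assert rec.data.shape == (12000, 19)
        again = generate_background(60, 200, seed=7)
        assert np.array_equal(rec.data, again.data)
        other = generate_background(60, 200, seed=8)
        assert not np.array_equal(rec.data, other.data)

    def test_posterior_alpha_dominates_beta_on_occipital_lead(self):
        rec = generate_background(60, 200, seed=7)
        o1 = rec.data[:, rec.channel_index("O1")]
        f, pxx = periodogram(o1.astype(np.float64), fs=200.0)
        alpha = pxx[(f >= 8) & (f < 12)].sum()
        beta = pxx[(f >= 13) & (f < 30)].sum()
        assert alpha > beta

    def test_physiologic_amplitude_and_no_gold_events(self):
        rec = generate_background(30, 200, seed=1)
        assert 5.0 < _rms(rec.data) < 100.0  # tens of microvolts
        assert rec.gold_events == []

    @pytest.mark.parametrize("duration_s,fs", [(0, 200), (-5, 200), (10, 0)])
    def test_invalid_arguments_rejected(self, duration_s, fs):
        with pytest.raises(ValueError):
            generate_background(duration_s, fs, seed=0)


class TestInjectSeizure:
    def test_spike_wave_dominates_background_within_event(self):
        rec = _zero_record()
        ev = SeizureEvent(10.0, 20.0, GENERALIZED_SPIKE_WAVE,
                          params={"freq_hz": 3.0, "amplitude_uv": 100.0})
        inject_seizure(rec, ev, seed=0)
        fp1 = rec.data[:, rec.channel_index("Fp1")]
        inside = fp1[int(10 * 200):int(30 * 200)]
        outside = np.concatenate([fp1[:int(10 * 200)], fp1[int(30 * 200):]])
        assert _rms(inside) > 10 * _rms(outside)
        assert rec.gold_events == [ev]

    def test_focal_event_strongest_at_focus(self):
        rec = _zero_record()
        ev = SeizureEvent(5.0, 30.0, FOCAL_EVOLVING, focus_channels=("C4", "F4"),
                          params={"freq_hz": 8.0, "amplitude_uv": 80.0})
        inject_seizure(rec, ev, seed=0)
        sl = slice(int(5 * 200), int(35 * 200))
        assert _rms(rec.data[sl, rec.channel_index("C4")]) > _rms(rec.data[sl, rec.channel_index("O1")])

    def test_signal_outside_interval_unchanged(self):
        rec = generate_background(60, 200, seed=3)
        before = rec.data.copy()
        ev = SeizureEvent(20.0, 15.0, GENERALIZED_SPIKE_WAVE)
        inject_seizure(rec, ev, seed=1)
        i0, i1 = int(20 * 200), int(35 * 200)
        assert np.abs(rec.data[:i0] - before[:i0]).max() == 0
        assert np.abs(rec.data[i1:] - before[i1:]).max() == 0
        assert np.abs(rec.data[i0:i1] - before[i0:i1]).max() > 0

    def test_overlapping_events_rejected(self):
        rec = _zero_record()
        inject_seizure(rec, SeizureEvent(10.0, 20.0, GENERALIZED_SPIKE_WAVE), seed=0)
        with pytest.raises(OverlappingEventError):
            inject_seizure(rec, SeizureEvent(25.0, 10.0, GENERALIZED_SPIKE_WAVE), seed=0)

    def test_interval_and_duration_preconditions(self):
        rec = _zero_record()
        with pytest.raises(ValueError):
            inject_seizure(rec, SeizureEvent(55.0, 10.0, GENERALIZED_SPIKE_WAVE), seed=0)
        with pytest.raises(ValueError):
            SeizureEvent(5.0, 0.0, GENERALIZED_SPIKE_WAVE)


class TestInjectArtifact:
    def test_line_noise_peaks_at_60hz(self):
        rec = _zero_record()
        inject_artifact(rec, ArtifactEvent(0.0, 60.0, LINE_NOISE_60HZ,
                                           amplitude_uv=20.0), seed=0)
        f, pxx = periodogram(rec.data[:, 0].astype(np.float64), fs=200.0)
        assert abs(f[np.argmax(pxx)] - 60.0) < 0.5

    def test_artifact_creates_no_gold_event(self):
        rec = _zero_record()
        inject_artifact(rec, ArtifactEvent(5.0, 20.0, NONEVOLVING_RHYTHMIC,
                                           affected_channels=("Fp1", "Fp2")), seed=0)
        assert len(rec.gold_events) == 0
        assert len(rec.artifacts) == 1

    def test_artifact_beyond_record_end_rejected(self):
        rec = _zero_record()
        with pytest.raises(ValueError):
            inject_artifact(rec, ArtifactEvent(50.0, 20.0, LINE_NOISE_60HZ), seed=0)


class TestWeakAnnotationNoiseModel:
    def test_noise_free_limit_marks_every_onset_exactly(self):
        records = [generate_background(300, 200, seed=s, record_id=f"r{s}") for s in range(3)]
        for rec in records:
            inject_seizure(rec, SeizureEvent(50.0, 30.0, GENERALIZED_SPIKE_WAVE), seed=0)
            inject_seizure(rec, SeizureEvent(200.0, 30.0, GENERALIZED_SPIKE_WAVE), seed=1)
        cfg = NoiseModelConfig(target_precision=1.0, target_recall=1.0,
                               onset_jitter_sd_s=0.0, p_late_annotation=0.0, seed=0)
        simulate_weak_annotations(records, cfg)
        for rec in records:
            assert [a.time_s for a in rec.weak_annotations] == [50.0, 200.0]
            assert all(a.matches_gold for a in rec.weak_annotations)

    def test_seeded_determinism_of_annotation_lists(self):
        scen = ScenarioConfig(n_records=4, duration_s=300.0, seed=9)
        first = generate_corpus(scen)
        second = generate_corpus(scen)
        for a, b in zip(first, second):
            assert [x.time_s for x in a.weak_annotations] == [x.time_s for x in b.weak_annotations]
            assert [x.source for x in a.weak_annotations] == [x.source for x in b.weak_annotations]

    def test_event_free_corpus_is_valid_and_unannotated(self):
        records = [generate_background(120, 200, seed=s, record_id=f"bg{s}") for s in range(2)]
        simulate_weak_annotations(records, NoiseModelConfig(seed=0))
        assert all(len(r.weak_annotations) == 0 for r in records)

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_weak_annotations([], NoiseModelConfig(seed=0))

    def test_false_annotations_fall_outside_matching_windows(self):
        scen = ScenarioConfig(n_records=6, duration_s=600.0, seed=4)
        records = generate_corpus(scen)
        tol = scen.noise.match_tolerance_s
        for rec in records:
            for ann in rec.weak_annotations:
                in_window = any(
                    ev.onset_s - tol <= ann.time_s <= ev.offset_s + tol
                    for ev in rec.gold_events
                )
                assert in_window == ann.matches_gold


class TestFixtureCorpus:
    SCEN = dict(n_records=6, duration_s=300.0, seed=21, mean_events_per_record=1.0)

    def test_manifest_lists_every_record_and_matches_recomputation(self, tmp_path):
        cfg = ScenarioConfig(**self.SCEN)
        manifest = write_fixture_corpus(tmp_path / "corpus", cfg)
        assert len(manifest["records"]) == 6
        records = read_corpus(tmp_path / "corpus")
        assert [r.record_id for r in records] == [m["record_id"] for m in manifest["records"]]
        quality = annotation_quality(records, cfg.noise.match_tolerance_s)
        assert manifest["noise_model"]["realized_precision"] == pytest.approx(quality["precision"], abs=1e-6)
        assert manifest["noise_model"]["realized_recall"] == pytest.approx(quality["recall"], abs=1e-6)

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = ScenarioConfig(**self.SCEN)
        write_fixture_corpus(tmp_path / "a", cfg)
        write_fixture_corpus(tmp_path / "b", cfg)
        assert (tmp_path / "a" / "manifest.yaml").read_bytes() == (tmp_path / "b" / "manifest.yaml").read_bytes()

    def test_round_trip_preserves_signal_and_events(self, tmp_path):
        cfg = ScenarioConfig(**self.SCEN)
        originals = generate_corpus(cfg)
        write_fixture_corpus(tmp_path / "c", cfg)
        reread = read_corpus(tmp_path / "c")
        for a, b in zip(originals, reread):
            assert np.array_equal(a.data, b.data)
            assert len(a.gold_events) == len(b.gold_events)
            for ea, eb in zip(a.gold_events, b.gold_events):
                assert ea.onset_s == pytest.approx(eb.onset_s)
                assert ea.morphology == eb.morphology
                assert ea.focus_channels == eb.focus_channels


def test_bandpower_probe_separates_ictal_from_background(experiment_data):
    """A linear probe on log band powers must tell within-event windows from
    background with AUROC > 0.9, otherwise downstream model tests are vacuous."""

    def feats(clips):
        return np.stack([
            np.log(frequency_domain_features(c)[:, 1:6].ravel() + 1e-9) for c in clips
        ])

    dev, test = experiment_data.dev, experiment_data.test
    probe = LogisticRegression(max_iter=2000).fit(feats(dev), [c.label for c in dev])
    scores = probe.predict_proba(feats(test))[:, 1]
    _, auroc = roc_auroc([c.label for c in test], scores)
    assert auroc > 0.9
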
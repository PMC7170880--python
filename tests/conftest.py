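"""Shared fixtures: the desk-scale experiment corpus, its clip datasets,
and a weak-label-trained CNN.  Session-scoped because corpus generation and
training dominate the suite's runtime; everything is seeded."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from weakeeg.clips import (
    Clip,
    ClipDatasetSpec,
    build_eval_sets,
    build_training_set,
    partition_records,
)
from weakeeg.nn.inception import build_model, desk_preset
from weakeeg.records import GENERALIZED_SPIKE_WAVE
from weakeeg.synth.corpus import experiment_scenario, generate_corpus
from weakeeg.train import desk_train_config, train

EXPERIMENT_SEED = 5
PARTITION_SEED = 1
CLIP_SEED = 2


@pytest.fixture(scope="session")
def experiment_data():
    """Corpus-derived datasets for the training experiments.

    Weak-labeled balanced training set, gold dev/test sets at 80-20, plus
    (clip, event) pairs of focal / rhythmic-delta seizures for localization
    scoring and one full record with a seizure for sliding predictions.
    The raw corpus is dropped once clips are extracted.
    """
    records = generate_corpus(experiment_scenario(seed=EXPERIMENT_SEED))
    train_records, eval_records = partition_records(records, 0.35, PARTITION_SEED)
    spec = ClipDatasetSpec(negative_sampling_seed=CLIP_SEED)
    weak_train = build_training_set(train_records, spec)
    dev, test = build_eval_sets(eval_records, spec)

    focal_pairs = []
    for rec in records:
        for ev in rec.gold_events:
            if ev.morphology == GENERALIZED_SPIKE_WAVE:
                continue
            i0 = int(round(ev.onset_s * rec.fs))
            if i0 + 2400 <= rec.n_samples:
                clip = Clip(rec.record_id, ev.onset_s, 12,
                            rec.data[i0:i0 + 2400].copy(), 1, "gold")
                focal_pairs.append((clip, ev))

    trace_record = next(
        r for r in eval_records
        if r.gold_events and r.gold_events[0].onset_s > 30
    )

    data = SimpleNamespace(
        spec=spec,
        weak_train=weak_train,
        dev=dev,
        test=test,
        focal_pairs=focal_pairs,
        trace_record=trace_record,
        train_record_ids={r.record_id for r in train_records},
        eval_record_ids={r.record_id for r in eval_records},
    )
    del records, train_records, eval_records
    return data


@pytest.fixture(scope="session")
def weak_model(experiment_data):
    """The desk CNN trained on the weak-labeled set (seed 0)."""
    model = build_model(desk_preset(12), seed=0)
    train(model, experiment_data.weak_train, experiment_data.dev,
          desk_train_config(seed=0))
    return model
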
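"""Scenario-level corpus generation and the on-disk container format.

A *scenario* fixes the study conditions: record count and duration, seizure
rate and morphology mix, artifact rate, cross-record background variability,
and the weak-annotation noise model.  One seed fans out to per-record seeds
through :class:`numpy.random.SeedSequence`, so any record can be regenerated
in isolation.

Container format (one ``.npz`` per record + a YAML manifest):

* ``data`` -- float32 signal matrix (n_samples x 19), microvolts
* ``fs``, ``channels``
* gold table: ``gold_onset_s``, ``gold_duration_s``, ``gold_label``
  (morphology), ``gold_focus`` ("|"-joined channel names), ``gold_params``
  (JSON per event)
* weak table: ``weak_time_s``, ``weak_duration_s`` (zeros; markers are
  instants), ``weak_label`` (free text), ``weak_source``
* artifact table: ``artifact_onset_s``, ``artifact_duration_s``,
  ``artifact_label``, ``artifact_channels``, ``artifact_amplitude_uv``

The manifest (``manifest.yaml``) lists record ids, per-record event counts,
and the realized noise-model statistics recomputed from the written corpus.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from weakeeg.records import (
    FOCAL_EVOLVING,
    GENERALIZED_SPIKE_WAVE,
    LINE_NOISE_60HZ,
    MONTAGE_1020,
    NONEVOLVING_RHYTHMIC,
    RHYTHMIC_DELTA_ICTAL,
    ArtifactEvent,
    EEGRecord,
    SeizureEvent,
    WeakAnnotation,
)
from weakeeg.synth.annotate import NoiseModelConfig, annotation_quality, simulate_weak_annotations
from weakeeg.synth.background import generate_background
from weakeeg.synth.events import inject_artifact, inject_seizure

_FOCAL_SITES: tuple[tuple[str, ...], ...] = (
    ("C4", "F4"), ("C3", "F3"), ("T3", "T5"), ("T4", "T6"),
    ("O1", "P3"), ("O2", "P4"), ("Fp1", "F7"), ("Fp2", "F8"),
)
_FRONTAL_DELTA: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "Fz")


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic corpus."""

    n_records: int = 40
    duration_s: float = 600.0
    fs: float = 200.0
    seed: int = 0
    #: fraction of records with no seizure at all (most clinical EEGs)
    p_seizure_free: float = 0.4
    mean_events_per_record: float = 2.0
    event_duration_range_s: tuple[float, float] = (20.0, 60.0)
    #: spacing that keeps +-30 s annotation-matching windows of neighbouring
    #: events from overlapping
    min_event_gap_s: float = 90.0
    morphology_probs: dict = field(
        default_factory=lambda: {
            GENERALIZED_SPIKE_WAVE: 0.4,
            FOCAL_EVOLVING: 0.35,
            RHYTHMIC_DELTA_ICTAL: 0.25,
        }
    )
    mean_artifacts_per_record: float = 3.0
    artifact_duration_range_s: tuple[float, float] = (15.0, 50.0)
    noise: NoiseModelConfig = field(default_factory=NoiseModelConfig)
    annotate: bool = True
    record_id_prefix: str = "rec"

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        total = sum(self.morphology_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"morphology_probs must sum to 1, got {total}")


def _place_events(cfg: ScenarioConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Sample non-overlapping (onset, duration) pairs with a minimum gap."""
    if rng.random() < cfg.p_seizure_free:
        return []
    lo_d, hi_d = cfg.event_duration_range_s
    # Slot-based placement: one event at most per slot of width gap + max
    # duration guarantees the minimum spacing and a predictable density.
    slot_w = cfg.min_event_gap_s + hi_d
    n_slots = int((cfg.duration_s - 4.0) / slot_w)
    if n_slots < 1:
        return []
    k = min(max(1, rng.poisson(cfg.mean_events_per_record)), n_slots)
    slots = rng.choice(n_slots, size=k, replace=False)
    placed: list[tuple[float, float]] = []
    for slot in slots:
        dur = rng.uniform(lo_d, hi_d)
        lo_onset = 2.0 + slot * slot_w
        onset = rng.uniform(lo_onset, lo_onset + slot_w - dur - cfg.min_event_gap_s)
        placed.append((onset, dur))
    return sorted(placed)


def _sample_event(onset: float, dur: float, cfg: ScenarioConfig, rng: np.random.Generator) -> SeizureEvent:
    morphs = list(cfg.morphology_probs)
    probs = np.array([cfg.morphology_probs[m] for m in morphs])
    morph = morphs[rng.choice(len(morphs), p=probs / probs.sum())]
    if morph == GENERALIZED_SPIKE_WAVE:
        focus = MONTAGE_1020
        params = {"freq_hz": rng.uniform(2.0, 4.0), "amplitude_uv": rng.uniform(40.0, 140.0)}
    elif morph == FOCAL_EVOLVING:
        focus = _FOCAL_SITES[rng.choice(len(_FOCAL_SITES))]
        f0 = rng.uniform(7.0, 10.0)
        params = {
            "freq_hz": f0,
            "amplitude_uv": rng.uniform(30.0, 90.0),
            "chirp_rate_hz_per_s": (rng.uniform(16.0, 24.0) - f0) / dur,
        }
    else:
        focus = _FRONTAL_DELTA
        params = {"freq_hz": rng.uniform(1.0, 3.0), "amplitude_uv": rng.uniform(40.0, 110.0)}
    return SeizureEvent(onset_s=onset, duration_s=dur, morphology=morph,
                        focus_channels=focus, params=params)


def _place_artifacts(record: EEGRecord, cfg: ScenarioConfig, rng: np.random.Generator) -> None:
    k = rng.poisson(cfg.mean_artifacts_per_record)
    lo_d, hi_d = cfg.artifact_duration_range_s
    for _ in range(k):
        dur = rng.uniform(lo_d, hi_d)
        hi_onset = cfg.duration_s - dur - 1.0
        if hi_onset <= 1.0:
            continue
        for _ in range(50):
            onset = rng.uniform(1.0, hi_onset)
            if all(onset + dur <= ev.onset_s or ev.offset_s <= onset for ev in record.gold_events):
                kind = LINE_NOISE_60HZ if rng.random() < 0.5 else NONEVOLVING_RHYTHMIC
                if kind == LINE_NOISE_60HZ:
                    channels = MONTAGE_1020
                    amp = rng.uniform(10.0, 30.0)
                else:
                    start = rng.choice(len(MONTAGE_1020) - 5)
                    channels = MONTAGE_1020[start:start + 6]
                    amp = rng.uniform(40.0, 110.0)
                inject_artifact(
                    record,
                    ArtifactEvent(onset_s=onset, duration_s=dur, kind=kind,
                                  affected_channels=channels, amplitude_uv=amp),
                    seed=int(rng.integers(2**31)),
                )
                break


def calibration_scenario(seed: int = 0) -> ScenarioConfig:
    """The noise-model calibration scenario: >=1000 gold events.

    Long, densely seeded records (annotation quality depends only on the
    event/artifact layout, so seizure density here exceeds the default
    scenario's for economy).
    """
    return ScenarioConfig(
        n_records=150,
        duration_s=1100.0,
        p_seizure_free=0.05,
        mean_events_per_record=9.0,
        min_event_gap_s=90.0,
        event_duration_range_s=(20.0, 40.0),
        seed=seed,
    )


def experiment_scenario(seed: int = 0) -> ScenarioConfig:
    """The desk-scale corpus behind the training experiments.

    Sized so the weak-labeled balanced training pool reaches ~400 clips:
    shorter records than the default scenario, same noise model.
    """
    return ScenarioConfig(
        n_records=200,
        duration_s=360.0,
        p_seizure_free=0.35,
        mean_events_per_record=2.0,
        min_event_gap_s=70.0,
        event_duration_range_s=(20.0, 55.0),
        seed=seed,
    )


def generate_record(cfg: ScenarioConfig, record_id: str, seed: int) -> EEGRecord:
    """One record: variable background + seizures + artifacts, fully seeded."""
    rng = np.random.default_rng(seed)
    profile = {
        "broadband_rms_uv": rng.uniform(8.0, 25.0),
        "alpha_amp_uv": rng.uniform(8.0, 35.0),
        "alpha_freq_hz": rng.uniform(8.0, 12.0),
    }
    record = generate_background(
        cfg.duration_s, cfg.fs, seed=int(rng.integers(2**31)),
        rhythm_profile=profile, record_id=record_id,
    )
    for onset, dur in _place_events(cfg, rng):
        inject_seizure(record, _sample_event(onset, dur, cfg, rng),
                       seed=int(rng.integers(2**31)))
    _place_artifacts(record, cfg, rng)
    return record


def generate_corpus(cfg: ScenarioConfig) -> list[EEGRecord]:
    """Generate the full corpus and (by default) simulate weak annotations."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(cfg.n_records + 1)]
    width = max(3, len(str(cfg.n_records - 1)))
    records = [
        generate_record(cfg, f"{cfg.record_id_prefix}{i:0{width}d}", seeds[i])
        for i in range(cfg.n_records)
    ]
    if cfg.annotate:
        noise = dataclasses.replace(cfg.noise, seed=seeds[-1])
        simulate_weak_annotations(records, noise)
    return records


def write_record(record: EEGRecord, path: Path) -> None:
    np.savez(
        path,
        data=record.data,
        fs=np.float64(record.fs),
        channels=np.array(record.channels),
        gold_onset_s=np.array([e.onset_s for e in record.gold_events]),
        gold_duration_s=np.array([e.duration_s for e in record.gold_events]),
        gold_label=np.array([e.morphology for e in record.gold_events], dtype="U32"),
        gold_focus=np.array(["|".join(e.focus_channels) for e in record.gold_events], dtype="U200"),
        gold_params=np.array([json.dumps(e.params, sort_keys=True) for e in record.gold_events], dtype="U300"),
        weak_time_s=np.array([a.time_s for a in record.weak_annotations]),
        weak_duration_s=np.zeros(len(record.weak_annotations)),
        weak_label=np.array([a.text for a in record.weak_annotations], dtype="U64"),
        weak_source=np.array([a.source for a in record.weak_annotations], dtype="U16"),
        artifact_onset_s=np.array([a.onset_s for a in record.artifacts]),
        artifact_duration_s=np.array([a.duration_s for a in record.artifacts]),
        artifact_label=np.array([a.kind for a in record.artifacts], dtype="U32"),
        artifact_channels=np.array(["|".join(a.affected_channels) for a in record.artifacts], dtype="U200"),
        artifact_amplitude_uv=np.array([a.amplitude_uv for a in record.artifacts]),
    )


def read_record(path: Path) -> EEGRecord:
    with np.load(path, allow_pickle=False) as z:
        record = EEGRecord(
            record_id=Path(path).stem,
            fs=float(z["fs"]),
            channels=tuple(str(c) for c in z["channels"]),
            data=z["data"],
        )
        record.gold_events = [
            SeizureEvent(
                onset_s=float(o), duration_s=float(d), morphology=str(m),
                focus_channels=tuple(str(f).split("|")) if str(f) else MONTAGE_1020,
                params=json.loads(str(p)),
            )
            for o, d, m, f, p in zip(
                z["gold_onset_s"], z["gold_duration_s"], z["gold_label"],
                z["gold_focus"], z["gold_params"],
            )
        ]
        record.weak_annotations = [
            WeakAnnotation(time_s=float(t), text=str(lbl), source=str(src))
            for t, lbl, src in zip(z["weak_time_s"], z["weak_label"], z["weak_source"])
        ]
        record.artifacts = [
            ArtifactEvent(
                onset_s=float(o), duration_s=float(d), kind=str(k),
                affected_channels=tuple(str(c).split("|")), amplitude_uv=float(a),
            )
            for o, d, k, c, a in zip(
                z["artifact_onset_s"], z["artifact_duration_s"], z["artifact_label"],
                z["artifact_channels"], z["artifact_amplitude_uv"],
            )
        ]
    return record


def write_fixture_corpus(out_dir: str | Path, cfg: ScenarioConfig) -> dict:
    """Emit a seeded corpus to ``out_dir`` and return the manifest.

    The manifest is also written as ``manifest.yaml``; a rerun with the same
    config produces a byte-identical manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = generate_corpus(cfg)
    for rec in records:
        write_record(rec, out / f"{rec.record_id}.npz")
    quality = annotation_quality(records, cfg.noise.match_tolerance_s)
    manifest = {
        "format": "weakeeg-corpus-v1",
        "seed": cfg.seed,
        "fs": cfg.fs,
        "duration_s": cfg.duration_s,
        "records": [
            {
                "record_id": rec.record_id,
                "n_gold_events": len(rec.gold_events),
                "n_weak_annotations": len(rec.weak_annotations),
                "n_artifacts": len(rec.artifacts),
            }
            for rec in records
        ],
        "totals": {
            "n_records": len(records),
            "n_gold_events": quality["n_events"],
            "n_weak_annotations": quality["n_annotations"],
        },
        "noise_model": {
            "target_precision": cfg.noise.target_precision,
            "target_recall": cfg.noise.target_recall,
            "match_tolerance_s": cfg.noise.match_tolerance_s,
            "realized_precision": round(quality["precision"], 6),
            "realized_recall": round(quality["recall"], 6),
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def read_corpus(corpus_dir: str | Path) -> list[EEGRecord]:
    """Load every record of a written corpus, ordered by record id."""
    paths = sorted(Path(corpus_dir).glob("*.npz"))
    if not paths:
        raise FileNotFoundError(f"no records found under {corpus_dir}")
    return [read_record(p) for p in paths]
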
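"""Fixed-length clip datasets for clip-level seizure-onset classification.

Positive clips are anchored at the annotation (or gold onset) time and cover
``[t, t + L)`` -- onset detection, with markers tending to sit near seizure
onset, makes start-anchoring the natural convention.  Negative clips are
sampled only from records carrying no annotation of the relevant kind.
Training sets are class-balanced by undersampling negatives (50% positive by
default); evaluation pools use the 80-20 negative-positive balance that
reflects the rarity of seizures, and are split into record-disjoint dev and
test halves.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy.signal import resample_poly

from weakeeg.errors import EmptyClassError, SplitInfeasibleError, UnsatisfiableSamplingError
from weakeeg.records import N_CHANNELS, EEGRecord

TARGET_FS = 200.0
SUPPORTED_CLIP_LENGTHS_S = (12, 60)

#: Kaiser-window beta of the "best quality" polyphase low-pass design.
KAISER_BEST_BETA = 14.769656459379492


@dataclass
class Clip:
    """One fixed-length window of one record, with label and provenance."""

    record_id: str
    start_s: float
    clip_len_s: int
    x: np.ndarray  # (clip_len_s * 200, 19) float32
    label: int
    label_source: Literal["weak", "gold", "sampled_negative"]

    def __post_init__(self) -> None:
        expected = (int(self.clip_len_s * TARGET_FS), N_CHANNELS)
        if self.x.shape != expected:
            raise ValueError(f"clip shape {self.x.shape} != expected {expected}")


@dataclass
class ClipDatasetSpec:
    clip_len_s: int = 12
    train_pos_fraction: float = 0.5
    test_neg_pos: tuple[float, float] = (0.8, 0.2)
    negative_sampling_seed: int = 0
    dev_test_split_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.clip_len_s not in SUPPORTED_CLIP_LENGTHS_S:
            raise ValueError(f"clip_len_s must be one of {SUPPORTED_CLIP_LENGTHS_S}")
        if not 0 < self.train_pos_fraction < 1:
            raise ValueError("train_pos_fraction must be in (0, 1)")
        if not np.isclose(sum(self.test_neg_pos), 1.0) or min(self.test_neg_pos) <= 0:
            raise ValueError("test_neg_pos fractions must be positive and sum to 1")
        if not 0 < self.dev_test_split_fraction < 1:
            raise ValueError("dev_test_split_fraction must be in (0, 1)")


def resample_to_200hz(signal: np.ndarray, src_fs: float) -> np.ndarray:
    """Polyphase-resample a (n_samples, n_channels) signal to 200 Hz.

    Uses a Kaiser-windowed low-pass (beta ~ 14.77, the high-quality design)
    and is a bit-exact pass-through when ``src_fs`` is already 200 Hz.
    """
    if src_fs <= 0:
        raise ValueError(f"src_fs must be positive, got {src_fs}")
    if src_fs == TARGET_FS:
        return signal
    ratio = Fraction(TARGET_FS).limit_denominator() / Fraction(src_fs).limit_denominator(10**6)
    return resample_poly(
        signal, ratio.numerator, ratio.denominator, axis=0,
        window=("kaiser", KAISER_BEST_BETA),
    )


def _cut(record: EEGRecord, start_s: float, clip_len_s: int) -> np.ndarray | None:
    n = int(clip_len_s * TARGET_FS)
    i0 = int(round(start_s * record.fs))
    if i0 < 0 or i0 + n > record.n_samples:
        return None
    # copy so clips own their memory and records can be freed
    return record.data[i0:i0 + n].copy()


def extract_positive_clips(
    records: Sequence[EEGRecord],
    clip_len_s: int,
    label_source: Literal["weak", "gold"],
) -> tuple[list[Clip], int]:
    """One positive clip per weak annotation (or gold event onset).

    Returns ``(clips, n_skipped)``; anchors too close to the record end to
    fit a full clip are skipped and counted, never raised.
    """
    clips: list[Clip] = []
    skipped = 0
    for rec in records:
        anchors = (
            [a.time_s for a in rec.weak_annotations]
            if label_source == "weak"
            else [e.onset_s for e in rec.gold_events]
        )
        for t in anchors:
            x = _cut(rec, t, clip_len_s)
            if x is None:
                skipped += 1
                continue
            clips.append(Clip(rec.record_id, float(t), clip_len_s, x, 1, label_source))
    return clips, skipped


def sample_negative_clips(
    records: Sequence[EEGRecord],
    n: int,
    clip_len_s: int,
    seed: int,
    annotation_free: Literal["weak", "gold"] = "weak",
) -> list[Clip]:
    """Sample ``n`` negatives uniformly from annotation-free records.

    ``annotation_free="weak"`` restricts to records without any weak
    annotation (the training convention); ``"gold"`` restricts to records
    without gold events (the evaluation convention).  Records are chosen
    with probability proportional to their eligible duration.
    """
    eligible = [
        rec for rec in records
        if (len(rec.weak_annotations) if annotation_free == "weak" else len(rec.gold_events)) == 0
        and rec.duration_s >= clip_len_s
    ]
    if not eligible:
        raise UnsatisfiableSamplingError(
            f"no {annotation_free}-annotation-free records to sample negatives from"
        )
    rng = np.random.default_rng(seed)
    spans = np.array([rec.duration_s - clip_len_s for rec in eligible])
    probs = spans / spans.sum() if spans.sum() > 0 else np.full(len(eligible), 1 / len(eligible))
    clips: list[Clip] = []
    while len(clips) < n:
        rec = eligible[rng.choice(len(eligible), p=probs)]
        start = rng.uniform(0.0, rec.duration_s - clip_len_s)
        x = _cut(rec, start, clip_len_s)
        if x is not None:
            clips.append(Clip(rec.record_id, float(start), clip_len_s, x, 0, "sampled_negative"))
    return clips


def build_training_set(records: Sequence[EEGRecord], spec: ClipDatasetSpec) -> list[Clip]:
    """Weak-positive clips plus undersampled negatives, shuffled, seeded.

    All positives are retained; negatives are drawn so the positive fraction
    equals ``spec.train_pos_fraction`` (odd counts resolve toward one extra
    negative).
    """
    positives, _ = extract_positive_clips(records, spec.clip_len_s, "weak")
    if not positives:
        raise EmptyClassError("no weak-positive clips could be extracted")
    f = spec.train_pos_fraction
    n_neg = int(np.ceil(len(positives) * (1.0 - f) / f))
    negatives = sample_negative_clips(
        records, n_neg, spec.clip_len_s, spec.negative_sampling_seed, annotation_free="weak"
    )
    dataset = positives + negatives
    rng = np.random.default_rng(spec.negative_sampling_seed + 1)
    rng.shuffle(dataset)
    return dataset


def _split_by_record(clips: list[Clip], fraction: float, rng: np.random.Generator) -> tuple[list[Clip], list[Clip]]:
    """Greedy record-disjoint split targeting ``fraction`` of clips in part 1."""
    by_record: dict[str, list[Clip]] = {}
    for c in clips:
        by_record.setdefault(c.record_id, []).append(c)
    ids = sorted(by_record)
    rng.shuffle(ids)
    total = len(clips)
    part1: list[Clip] = []
    part2: list[Clip] = []
    n1 = 0
    for rid in ids:
        group = by_record[rid]
        if n1 + len(group) / 2 <= fraction * total:
            part1.extend(group)
            n1 += len(group)
        else:
            part2.extend(group)
    if not part1 or not part2:  # degenerate fallback: move one record over
        donor = part1 or part2
        rid = donor[0].record_id
        moved = [c for c in donor if c.record_id == rid]
        kept = [c for c in donor if c.record_id != rid]
        part1, part2 = (kept, moved) if part1 else (moved, kept)
    return part1, part2


def build_eval_sets(
    records: Sequence[EEGRecord], spec: ClipDatasetSpec
) -> tuple[list[Clip], list[Clip]]:
    """Gold-labeled dev and test sets at the 80-20 negative-positive balance.

    The pool is gold-positive clips plus ``neg:pos`` sampled negatives from
    gold-event-free records, split into record-disjoint halves (positive and
    negative source records are partitioned independently, so neither half
    shares any record with the other).
    """
    positives, _ = extract_positive_clips(records, spec.clip_len_s, "gold")
    pos_records = {c.record_id for c in positives}
    if len(pos_records) < 2:
        raise SplitInfeasibleError(
            f"record-disjoint split needs >=2 gold-positive records, got {len(pos_records)}"
        )
    n_neg = int(round(len(positives) * spec.test_neg_pos[0] / spec.test_neg_pos[1]))
    negatives = sample_negative_clips(
        records, n_neg, spec.clip_len_s, spec.negative_sampling_seed, annotation_free="gold"
    )
    rng = np.random.default_rng(spec.negative_sampling_seed + 2)
    dev_pos, test_pos = _split_by_record(positives, spec.dev_test_split_fraction, rng)
    dev_neg, test_neg = _split_by_record(negatives, spec.dev_test_split_fraction, rng)
    dev = dev_pos + dev_neg
    test = test_pos + test_neg
    rng.shuffle(dev)
    rng.shuffle(test)
    return dev, test


def partition_records(
    records: Sequence[EEGRecord], eval_fraction: float, seed: int
) -> tuple[list[EEGRecord], list[EEGRecord]]:
    """Record-level split into (train_pool, eval_pool) -- the leakage guard.

    Training reads weak annotations from the train pool only; dev/test gold
    clips come from the eval pool only, so no record id ever appears on both
    sides.
    """
    if not 0 < eval_fraction < 1:
        raise ValueError("eval_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))
    n_eval = max(2, int(round(eval_fraction * len(records))))
    eval_idx = set(idx[:n_eval].tolist())
    train = [rec for i, rec in enumerate(records) if i not in eval_idx]
    eval_ = [rec for i, rec in enumerate(records) if i in eval_idx]
    return train, eval_


def clips_to_arrays(clips: Sequence[Clip]) -> tuple[np.ndarray, np.ndarray]:
    """Stack clips into (X, y) with X of shape (n, samples, 19) float32."""
    X = np.stack([c.x for c in clips]).astype(np.float32)
    y = np.array([c.label for c in clips], dtype=np.int64)
    return X, y


def save_clip_datasets(out_dir, **splits: Sequence[Clip]) -> None:
    """Write named splits as one array container plus a tabular index.

    ``clips.npz`` holds ``<split>_X`` / ``<split>_y`` arrays; ``index.csv``
    lists (record_id, start_s, label, label_source, split) per clip.
    """
    import csv
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {}
    with open(out / "index.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "start_s", "label", "label_source", "split"])
        for split, clips in splits.items():
            X, y = clips_to_arrays(clips)
            arrays[f"{split}_X"] = X
            arrays[f"{split}_y"] = y
            for c in clips:
                writer.writerow([c.record_id, f"{c.start_s:.6f}", c.label,
                                 c.label_source, split])
    np.savez(out / "clips.npz", **arrays)


def load_clip_dataset(clips_dir, split: str) -> tuple[np.ndarray, np.ndarray]:
    """Read one split written by :func:`save_clip_datasets`."""
    from pathlib import Path

    with np.load(Path(clips_dir) / "clips.npz") as z:
        return z[f"{split}_X"], z[f"{split}_y"]
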
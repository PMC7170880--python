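"""Weak-annotation noise model.

Routine clinical annotations of seizures are noisy in two directions: they
mark many non-ictal stretches (low precision, because annotators err toward
sensitivity) and they miss many true seizures (modest recall, because only a
subset of events in a long record is marked).  A clinician audit of such
annotations measured precision 0.37 and recall 0.45, with markers tending to
land near seizure onset; those values are this module's default calibration
targets.

Simulation proceeds per corpus:

1. each gold event is annotated independently with probability
   ``target_recall``; the marker lands at onset plus Gaussian jitter, or
   uniformly inside the event with probability ``p_late_annotation``;
2. false annotations are added on seizure-free stretches -- half inside
   artifact intervals when any exist (rhythmic artifact being the canonical
   false-positive trigger), half on plain background -- in the number that
   makes the expected corpus-level precision equal ``target_precision``.

An annotation matches a gold event when it falls inside
``[onset - tol, offset + tol]`` with ``tol = match_tolerance_s`` (default
30 s, reflecting page-level reading); false annotations are placed outside
every such window so they never match by accident.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from weakeeg.records import ANNOTATION_SOURCES, EEGRecord, WeakAnnotation

_SOURCE_PROBS = (0.7, 0.2, 0.1)  # technician, fellow, student


@dataclass
class NoiseModelConfig:
    """Calibration of the weak-annotation simulator.

    Parameters
    ----------
    target_precision, target_recall
        Corpus-level annotation quality to reproduce (defaults from the
        clinical audit: 0.37 and 0.45).
    onset_jitter_sd_s
        SD of the Gaussian timing error of onset-anchored markers, seconds.
    p_late_annotation
        Probability a marker lands uniformly inside the event instead of
        near its onset.
    match_tolerance_s
        Half-width of the matching window used for precision/recall
        bookkeeping.
    """

    target_precision: float = 0.37
    target_recall: float = 0.45
    onset_jitter_sd_s: float = 8.0
    p_late_annotation: float = 0.3
    match_tolerance_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_precision <= 1:
            raise ValueError(f"target_precision must be in (0, 1], got {self.target_precision}")
        if not 0 < self.target_recall <= 1:
            raise ValueError(f"target_recall must be in (0, 1], got {self.target_recall}")
        if self.onset_jitter_sd_s < 0 or self.p_late_annotation < 0 or self.p_late_annotation > 1:
            raise ValueError("invalid jitter / late-annotation settings")


def _match_windows(record: EEGRecord, tol: float) -> list[tuple[float, float]]:
    return [(ev.onset_s - tol, ev.offset_s + tol) for ev in record.gold_events]


def _in_windows(t: float, windows: Sequence[tuple[float, float]]) -> bool:
    return any(lo <= t <= hi for lo, hi in windows)


def _free_segments(record: EEGRecord, tol: float) -> list[tuple[float, float]]:
    """Maximal stretches of the record outside every gold matching window."""
    segs: list[tuple[float, float]] = []
    cursor = 0.0
    for lo, hi in sorted(_match_windows(record, tol)):
        if lo > cursor:
            segs.append((cursor, max(lo, cursor)))
        cursor = max(cursor, hi)
    if cursor < record.duration_s:
        segs.append((cursor, record.duration_s))
    return [(a, b) for a, b in segs if b - a > 1.0]


def _draw_source(rng: np.random.Generator) -> str:
    return ANNOTATION_SOURCES[rng.choice(len(ANNOTATION_SOURCES), p=_SOURCE_PROBS)]


def simulate_weak_annotations(
    records: Sequence[EEGRecord], cfg: NoiseModelConfig
) -> Sequence[EEGRecord]:
    """Populate ``weak_annotations`` on every record, in place.

    Deterministic given ``cfg.seed``.  Records with zero gold events are
    valid (they receive only false annotations).  An empty record list is an
    error.
    """
    if len(records) == 0:
        raise ValueError("empty record list")
    rng = np.random.default_rng(cfg.seed)
    tol = cfg.match_tolerance_s
    for rec in records:
        rec.weak_annotations = []

    # --- true annotations: one Bernoulli(target_recall) trial per event ---
    n_true = 0
    for rec in records:
        windows = _match_windows(rec, tol)
        for ev in rec.gold_events:
            if rng.random() >= cfg.target_recall:
                continue
            if rng.random() < cfg.p_late_annotation:
                t = rng.uniform(ev.onset_s, ev.offset_s)
            else:
                t = ev.onset_s + rng.normal(0.0, cfg.onset_jitter_sd_s)
            t = float(np.clip(t, 0.0, rec.duration_s))
            matches = _in_windows(t, windows)
            rec.weak_annotations.append(
                WeakAnnotation(time_s=t, source=_draw_source(rng), matches_gold=matches)
            )
            n_true += matches

    # --- false annotations: bring expected precision to target ---
    n_false = int(round(n_true * (1.0 - cfg.target_precision) / cfg.target_precision))

    artifact_sites: list[tuple[EEGRecord, float, float]] = []
    background_sites: list[tuple[EEGRecord, float, float]] = []
    for rec in records:
        windows = _match_windows(rec, tol)
        for art in rec.artifacts:
            lo, hi = art.onset_s, art.offset_s
            # keep only artifact stretches clear of every matching window
            if not _in_windows(lo, windows) and not _in_windows(hi, windows):
                artifact_sites.append((rec, lo, hi))
        for a, b in _free_segments(rec, tol):
            background_sites.append((rec, a, b))

    def _place(sites: list[tuple[EEGRecord, float, float]]) -> bool:
        if not sites:
            return False
        lengths = np.array([b - a for _, a, b in sites])
        rec, a, b = sites[rng.choice(len(sites), p=lengths / lengths.sum())]
        windows = _match_windows(rec, tol)
        for _ in range(100):  # rejection-sample clear of matching windows
            t = rng.uniform(a, b)
            if not _in_windows(t, windows):
                rec.weak_annotations.append(
                    WeakAnnotation(time_s=float(t), source=_draw_source(rng), matches_gold=False)
                )
                return True
        return False

    placed = 0
    while placed < n_false:
        use_artifact = artifact_sites and rng.random() < 0.5
        if _place(artifact_sites if use_artifact else background_sites):
            placed += 1
        elif not background_sites and not artifact_sites:
            break  # nowhere to place false annotations at all

    for rec in records:
        rec.weak_annotations.sort(key=lambda a: a.time_s)
    return records


def annotation_quality(
    records: Sequence[EEGRecord], match_tolerance_s: float = 30.0
) -> dict:
    """Recompute corpus-level precision/recall of weak annotations from scratch.

    Independent of simulator bookkeeping: an annotation counts as correct if
    it falls within the tolerance window of any gold event of its record; an
    event counts as recalled if at least one annotation falls in its window.
    """
    n_ann = n_ann_match = n_ev = n_ev_match = 0
    for rec in records:
        windows = _match_windows(rec, match_tolerance_s)
        times = [a.time_s for a in rec.weak_annotations]
        n_ann += len(times)
        n_ann_match += sum(_in_windows(t, windows) for t in times)
        n_ev += len(rec.gold_events)
        for lo, hi in windows:
            n_ev_match += any(lo <= t <= hi for t in times)
    return {
        "n_annotations": n_ann,
        "n_events": n_ev,
        "precision": n_ann_match / n_ann if n_ann else 0.0,
        "recall": n_ev_match / n_ev if n_ev else 0.0,
    }
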
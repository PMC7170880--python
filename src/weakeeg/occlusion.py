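"""Occlusion sensitivity maps and sliding full-record prediction traces.

An occlusion map zeroes one-second segments of one channel at a time and
records the percent change of the model's prediction:

    value[c, t] = (p(clip) - p(clip with cell (c, t) zeroed)) / p(clip) * 100

so positive cells are the ones whose content *supports* the seizure call.
Cells partition the clip aligned to its start (cell t covers [t, t+1) s).
Per-map normalization (divide by max |value|) matches the display convention
of saliency figures; values are then comparable within, not across, maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from weakeeg.clips import TARGET_FS, Clip
from weakeeg.errors import UndefinedScoreError
from weakeeg.records import EEGRecord, SeizureEvent
from weakeeg.nn.inception import DenseInceptionNet, predict_proba


@dataclass
class OcclusionMap:
    """(n_channels x n_seconds) percent-change saliency for one clip."""

    values: np.ndarray
    normalized: bool
    record_id: str
    start_s: float
    clip_len_s: int
    #: True when the unoccluded prediction was exactly 0 and raw
    #: probability differences were returned instead of percent change.
    zero_baseline: bool = False


@dataclass
class PredictionTrace:
    times_s: np.ndarray
    probabilities: np.ndarray
    stride_s: float
    clip_len_s: int


def occlusion_map(
    model: DenseInceptionNet,
    clip: Clip,
    window_s: int = 1,
    normalize: bool = False,
    method: str = "batched",
    batch_size: int = 64,
) -> OcclusionMap:
    """Occlude every (channel, window) cell and measure the percent change.

    ``method="batched"`` stacks all occluded variants and predicts in
    batches; ``method="naive"`` recomputes cell by cell with single-clip
    forward passes (the brute-force reference).  Both run exactly
    ``n_channels * n_windows`` forward passes beyond the baseline.
    """
    if clip.clip_len_s % window_s != 0:
        raise ValueError(f"window_s={window_s} must divide clip_len_s={clip.clip_len_s}")
    x = clip.x
    n_samples, n_ch = x.shape
    n_win = clip.clip_len_s // window_s
    win = int(window_s * TARGET_FS)

    p0 = float(predict_proba(model, x[None])[0])

    if method == "batched":
        occluded = np.repeat(x[None], n_ch * n_win, axis=0)
        for c in range(n_ch):
            for t in range(n_win):
                occluded[c * n_win + t, t * win:(t + 1) * win, c] = 0.0
        probs = predict_proba(model, occluded, batch_size=batch_size).reshape(n_ch, n_win)
    elif method == "naive":
        probs = np.empty((n_ch, n_win))
        for c in range(n_ch):
            for t in range(n_win):
                variant = x.copy()
                variant[t * win:(t + 1) * win, c] = 0.0
                probs[c, t] = predict_proba(model, variant[None])[0]
    else:
        raise ValueError(f"unknown method {method!r}")

    zero_baseline = p0 == 0.0
    values = (p0 - probs) if zero_baseline else (p0 - probs) / p0 * 100.0
    if normalize:
        peak = np.abs(values).max()
        if peak > 0:
            values = values / peak
    return OcclusionMap(values, normalize, clip.record_id, clip.start_s,
                        clip.clip_len_s, zero_baseline)


def sliding_predictions(
    model: DenseInceptionNet,
    record: EEGRecord,
    clip_len_s: int,
    stride_s: float = 1.0,
) -> PredictionTrace:
    """Model probability at window starts 0, stride, 2*stride, ...

    Each probability is timestamped at its window start; windows must fit
    entirely inside the record.
    """
    if record.duration_s < clip_len_s:
        raise ValueError(
            f"record of {record.duration_s} s shorter than {clip_len_s} s clip"
        )
    n = int(clip_len_s * TARGET_FS)
    starts = np.arange(0.0, record.duration_s - clip_len_s + 1e-9, stride_s)
    windows = np.stack([
        record.data[int(round(t * record.fs)):int(round(t * record.fs)) + n]
        for t in starts
    ])
    probs = predict_proba(model, windows)
    return PredictionTrace(starts, probs, stride_s, clip_len_s)


def _support_cells(
    omap: OcclusionMap, event: SeizureEvent, focus_idx: list[int]
) -> np.ndarray:
    """Boolean (n_channels, n_seconds) mask of in-event, in-focus cells."""
    n_ch, n_win = omap.values.shape
    sec_len = omap.clip_len_s / n_win
    support = np.zeros((n_ch, n_win), dtype=bool)
    for t in range(n_win):
        cell_lo = omap.start_s + t * sec_len
        cell_hi = cell_lo + sec_len
        if cell_lo < event.offset_s and event.onset_s < cell_hi:
            support[focus_idx, t] = True
    return support


def localization_score(
    omap: OcclusionMap,
    event: SeizureEvent,
    focus_channels: tuple[str, ...],
    channel_order: tuple[str, ...],
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of the top-k saliency cells lying on the event's support.

    k is the number of (channel, second) cells that are both within the
    event interval and on a focus channel.  Ties in the map are broken by
    the seeded ``rng`` when given (uniformly random order), else by stable
    cell order.  Raises :class:`UndefinedScoreError` when the event does not
    intersect the clip.
    """
    clip_lo, clip_hi = omap.start_s, omap.start_s + omap.clip_len_s
    if event.offset_s <= clip_lo or event.onset_s >= clip_hi:
        raise UndefinedScoreError("event does not intersect the clip")
    focus_idx = [channel_order.index(c) for c in focus_channels]
    support = _support_cells(omap, event, focus_idx)
    k = int(support.sum())
    if k == 0:
        raise UndefinedScoreError("event support is empty within the clip")
    flat = omap.values.ravel()
    order = np.arange(flat.size) if rng is None else rng.permutation(flat.size)
    top = order[np.argsort(-flat[order], kind="stable")][:k]
    return float(support.ravel()[top].sum() / k)
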
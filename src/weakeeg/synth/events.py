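"""Additive ictal and artifact waveforms.

Three seizure morphologies cover the patterns a clip-level detector must
recognize:

* ``generalized_spike_wave`` -- rhythmic ~3 Hz spike-and-slow-wave complexes
  over the whole scalp with frontal emphasis;
* ``focal_evolving`` -- fast spiking at the focus whose frequency chirps
  upward over the event, with smooth spatial falloff to neighbours;
* ``rhythmic_delta_ictal`` -- 1-3 Hz rhythmic slow waves (frontal by
  default), the ictal counterpart of FIRDA-like patterns.

Artifacts are 60 Hz mains pickup and a constant-frequency, non-evolving
rhythm: the canonical false-positive triggers for clip classifiers.

All injections are strictly additive inside the half-open event interval:
samples outside it are untouched.  Edges are tapered by a raised cosine so
the injected activity starts and ends smoothly.
"""

from __future__ import annotations

import numpy as np

from weakeeg.errors import OverlappingEventError
from weakeeg.records import (
    ELECTRODE_XY,
    FOCAL_EVOLVING,
    GENERALIZED_SPIKE_WAVE,
    LINE_NOISE_60HZ,
    MONTAGE_1020,
    RHYTHMIC_DELTA_ICTAL,
    ArtifactEvent,
    EEGRecord,
    SeizureEvent,
)

_FRONTAL = {"Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"}
_CENTRAL_TEMPORAL = {"C3", "C4", "Cz", "T3", "T4"}


def _taper(n: int, fs: float, ramp_s: float = 1.0) -> np.ndarray:
    """Raised-cosine on/off ramp confined to the event interval."""
    ramp = min(int(round(ramp_s * fs)), n // 2)
    w = np.ones(n)
    if ramp > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        w[:ramp] = edge
        w[-ramp:] = edge[::-1]
    return w


def _spatial_weights(focus_channels: tuple[str, ...], falloff: float = 0.55) -> np.ndarray:
    """Gaussian falloff with scalp distance from the nearest focus electrode."""
    focus_xy = np.array([ELECTRODE_XY[c] for c in focus_channels])
    w = np.empty(len(MONTAGE_1020))
    for i, name in enumerate(MONTAGE_1020):
        xy = np.array(ELECTRODE_XY[name])
        d2 = np.min(np.sum((focus_xy - xy) ** 2, axis=1))
        w[i] = np.exp(-d2 / (2 * falloff**2))
    return w


def _spike_wave_train(t: np.ndarray, freq: float, rng: np.random.Generator) -> np.ndarray:
    """Spike-and-slow-wave complexes: a slow half-wave plus a sharp spike
    per cycle, the classic generalized ictal pattern."""
    phase = (t * freq) % 1.0
    slow = np.sin(2 * np.pi * phase)
    spike = np.exp(-0.5 * ((phase - 0.15) / 0.035) ** 2)
    jitter = 1.0 + 0.1 * rng.standard_normal(t.shape)
    return (0.6 * slow + 1.4 * spike * jitter) - 0.2


def _seizure_waveform(event: SeizureEvent, fs: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(event.duration_s * fs))
    t = np.arange(n) / fs
    p = event.params
    amp = float(p.get("amplitude_uv", 100.0))

    if event.morphology == GENERALIZED_SPIKE_WAVE:
        freq = float(p.get("freq_hz", 3.0))
        wave = _spike_wave_train(t, freq, rng)
    elif event.morphology == FOCAL_EVOLVING:
        f0 = float(p.get("freq_hz", 8.0))
        rate = float(p.get("chirp_rate_hz_per_s", (20.0 - f0) / max(event.duration_s, 1e-9)))
        inst_phase = 2 * np.pi * (f0 * t + 0.5 * rate * t**2)
        # Sharpened sinusoid (odd harmonic) reads as fast spiking activity;
        # amplitude ramps up as the discharge organizes.
        wave = (np.sin(inst_phase) + 0.35 * np.sin(3 * inst_phase)) * (0.4 + 0.6 * t / max(t[-1], 1e-9))
    elif event.morphology == RHYTHMIC_DELTA_ICTAL:
        freq = float(p.get("freq_hz", 2.0))
        wave = np.sin(2 * np.pi * freq * t) + 0.2 * np.sin(4 * np.pi * freq * t)
    else:  # pragma: no cover - guarded by SeizureEvent validation
        raise ValueError(event.morphology)

    return amp * wave * _taper(n, fs)


def _check_interval(record: EEGRecord, onset_s: float, duration_s: float) -> tuple[int, int]:
    if onset_s < 0 or onset_s + duration_s > record.duration_s + 1e-9:
        raise ValueError(
            f"interval [{onset_s}, {onset_s + duration_s}) s outside record "
            f"of {record.duration_s} s"
        )
    i0 = int(round(onset_s * record.fs))
    i1 = i0 + int(round(duration_s * record.fs))
    return i0, min(i1, record.n_samples)


def inject_seizure(record: EEGRecord, event: SeizureEvent, seed: int = 0) -> EEGRecord:
    """Add an ictal waveform to ``record`` and register the gold event.

    The waveform is applied at full weight on ``event.focus_channels`` and
    falls off smoothly with scalp distance elsewhere; a generalized
    spike-wave event uses all 19 channels as focus with frontal emphasis.
    Overlap with an existing gold event raises :class:`OverlappingEventError`.
    The record is modified in place and returned.
    """
    i0, i1 = _check_interval(record, event.onset_s, event.duration_s)
    for other in record.gold_events:
        if event.onset_s < other.offset_s and other.onset_s < event.offset_s:
            raise OverlappingEventError(
                f"event [{event.onset_s}, {event.offset_s}) overlaps "
                f"[{other.onset_s}, {other.offset_s})"
            )

    rng = np.random.default_rng(seed)
    wave = _seizure_waveform(event, record.fs, rng)[: i1 - i0]

    if event.morphology == GENERALIZED_SPIKE_WAVE:
        weights = np.array(
            [1.0 if c in _FRONTAL else 0.8 if c in _CENTRAL_TEMPORAL else 0.6
             for c in MONTAGE_1020]
        )
    else:
        weights = _spatial_weights(event.focus_channels)

    record.data[i0:i1] += (wave[:, None] * weights[None, :]).astype(np.float32)
    record.gold_events.append(event)
    record.gold_events.sort(key=lambda e: e.onset_s)
    return record


def inject_artifact(record: EEGRecord, artifact: ArtifactEvent, seed: int = 0) -> EEGRecord:
    """Add a non-ictal contaminant; gold events are unchanged."""
    i0, i1 = _check_interval(record, artifact.onset_s, artifact.duration_s)
    n = i1 - i0
    t = np.arange(n) / record.fs
    rng = np.random.default_rng(seed)

    if artifact.kind == LINE_NOISE_60HZ:
        wave = artifact.amplitude_uv * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
    else:
        # Non-evolving rhythm at delta-theta frequencies: fixed frequency,
        # fixed amplitude, no chirp.  Spectrally it mimics rhythmic ictal
        # slowing (the FIRDA-like false-positive trigger) but lacks the
        # evolution and spike sharpness of a true discharge.
        freq = rng.uniform(1.0, 6.0)
        phase = rng.uniform(0, 2 * np.pi)
        wave = artifact.amplitude_uv * (
            np.sin(2 * np.pi * freq * t + phase) + 0.3 * np.sin(4 * np.pi * freq * t + phase)
        )
    wave *= _taper(n, record.fs)

    idx = [record.channel_index(c) for c in artifact.affected_channels]
    record.data[i0:i1, idx] += wave[:, None].astype(np.float32)
    record.artifacts.append(artifact)
    return record
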
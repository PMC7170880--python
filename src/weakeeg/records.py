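"""Core domain types: EEG records, seizure events, artifacts, weak annotations.

All times are seconds from record start (0-based); event intervals are
half-open ``[onset, onset + duration)``.  Signals are stored in microvolts
as ``float32`` matrices of shape ``(n_samples, 19)`` in the standard 10-20
scalp montage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 19 electrodes of the international 10-20 system, in canonical order.
MONTAGE_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)
N_CHANNELS = len(MONTAGE_1020)

#: Approximate 2-D scalp coordinates (x: left-right, y: back-front) used for
#: smooth spatial falloff of focal activity.  Units are arbitrary.
ELECTRODE_XY: dict[str, tuple[float, float]] = {
    "Fp1": (-0.3, 1.0), "Fp2": (0.3, 1.0),
    "F7": (-0.8, 0.6), "F3": (-0.4, 0.55), "Fz": (0.0, 0.55),
    "F4": (0.4, 0.55), "F8": (0.8, 0.6),
    "T3": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.8, -0.6), "P3": (-0.4, -0.55), "Pz": (0.0, -0.55),
    "P4": (0.4, -0.55), "T6": (0.8, -0.6),
    "O1": (-0.3, -1.0), "O2": (0.3, -1.0),
}

GENERALIZED_SPIKE_WAVE = "generalized_spike_wave"
FOCAL_EVOLVING = "focal_evolving"
RHYTHMIC_DELTA_ICTAL = "rhythmic_delta_ictal"
SEIZURE_MORPHOLOGIES = frozenset(
    {GENERALIZED_SPIKE_WAVE, FOCAL_EVOLVING, RHYTHMIC_DELTA_ICTAL}
)

LINE_NOISE_60HZ = "line_noise_60hz"
NONEVOLVING_RHYTHMIC = "nonevolving_rhythmic"
ARTIFACT_KINDS = frozenset({LINE_NOISE_60HZ, NONEVOLVING_RHYTHMIC})

ANNOTATION_SOURCES = ("technician", "fellow", "student")


@dataclass
class SeizureEvent:
    """A gold-standard seizure interval with a named ictal morphology.

    ``params`` carries morphology parameters: ``freq_hz`` (dominant or start
    frequency), ``amplitude_uv``, and for evolving focal seizures
    ``chirp_rate_hz_per_s``.
    """

    onset_s: float
    duration_s: float
    morphology: str
    focus_channels: tuple[str, ...] = MONTAGE_1020
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be non-negative, got {self.onset_s}")
        if self.morphology not in SEIZURE_MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        unknown = set(self.focus_channels) - set(MONTAGE_1020)
        if unknown:
            raise ValueError(f"focus channels not in montage: {sorted(unknown)}")
        self.focus_channels = tuple(self.focus_channels)

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class ArtifactEvent:
    """A non-ictal contaminant: 60 Hz mains pickup or a non-evolving rhythm."""

    onset_s: float
    duration_s: float
    kind: str
    affected_channels: tuple[str, ...] = MONTAGE_1020
    amplitude_uv: float = 20.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be non-negative, got {self.onset_s}")
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        self.affected_channels = tuple(self.affected_channels)

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class WeakAnnotation:
    """A noisy free-text seizure marker from the routine clinical workflow.

    ``matches_gold`` is simulator bookkeeping only and must never reach a
    training label: training treats every annotation as a positive.
    """

    time_s: float
    text: str = "seizure"
    source: str = "technician"
    matches_gold: bool = False

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"time_s must be non-negative, got {self.time_s}")
        if self.source not in ANNOTATION_SOURCES:
            raise ValueError(f"unknown annotation source {self.source!r}")


@dataclass
class EEGRecord:
    """A 19-channel scalp EEG with gold events and weak annotations."""

    record_id: str
    fs: float = 200.0
    channels: tuple[str, ...] = MONTAGE_1020
    data: np.ndarray = field(default_factory=lambda: np.zeros((0, N_CHANNELS), np.float32))
    gold_events: list[SeizureEvent] = field(default_factory=list)
    weak_annotations: list[WeakAnnotation] = field(default_factory=list)
    artifacts: list[ArtifactEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.channels = tuple(self.channels)
        if len(self.channels) != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels, got {len(self.channels)}")
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2 or self.data.shape[1] != N_CHANNELS:
            raise ValueError(f"data must have shape (n_samples, {N_CHANNELS})")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)
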
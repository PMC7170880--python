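"""Exception types shared across the pipeline stages."""


class WeakEEGError(Exception):
    """Base class for weakeeg-specific failures."""


class OverlappingEventError(WeakEEGError):
    """An injected gold event overlaps one already present in the record."""


class UnsatisfiableSamplingError(WeakEEGError):
    """Negative-clip sampling was requested but no eligible record exists."""


class EmptyClassError(WeakEEGError):
    """A training/fitting step received examples from a single class only."""


class SplitInfeasibleError(WeakEEGError):
    """A record-disjoint dev/test split cannot be constructed."""


class UndefinedMetricError(WeakEEGError):
    """A metric (e.g. AUROC) is undefined for the given labels."""


class InsufficientReplicatesError(WeakEEGError):
    """Seed aggregation needs at least two replicate values."""


class NoFeasibleThresholdError(WeakEEGError):
    """No decision threshold satisfies the requested operating constraint."""


class InvalidConfigError(WeakEEGError):
    """A model or pipeline configuration violates a structural constraint."""


class UndefinedScoreError(WeakEEGError):
    """A localization score was requested for an event outside the clip."""


class PipelineStageError(WeakEEGError):
    """A pipeline stage failed; carries the stage name and a status dict."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.status = {"stage": stage, "error": type(cause).__name__, "message": str(cause)}
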
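"""Exception hierarchy shared across the package."""


class RiskCascadeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(RiskCascadeError, ValueError):
    """A caller-supplied argument violates a precondition."""


class CalibrationError(RiskCascadeError):
    """Intercept calibration could not reach the requested prevalence."""


class DegenerateDataError(RiskCascadeError):
    """Data unusable for the requested operation (e.g. single-class training set)."""


class StageFitError(RiskCascadeError):
    """A cascade stage failed to fit; carries the stage identity."""

    def __init__(self, stage_index: int, learner_id: str, cause: Exception):
        self.stage_index = stage_index
        self.learner_id = learner_id
        super().__init__(
            f"stage {stage_index} ({learner_id}) failed to fit: {cause!r}"
        )


class SchemaMismatchError(RiskCascadeError):
    """Prediction-time features do not match the training schema."""

    def __init__(self, missing, extra):
        self.missing = list(missing)
        self.extra = list(extra)
        super().__init__(
            f"feature mismatch: missing {self.missing}, unexpected {self.extra}"
        )


class EmptyClassifiedError(RiskCascadeError):
    """Metrics requested on a run where no subject was classified."""


class FlowConsistencyError(RiskCascadeError):
    """Per-stage flow counts are internally inconsistent."""
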
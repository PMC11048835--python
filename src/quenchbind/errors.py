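"""Exception and warning hierarchy shared across the pipeline."""


class QuenchBindError(Exception):
    """Base class for all package errors."""


class SchemaError(QuenchBindError):
    """Input table is missing required columns or has an unusable layout."""


class ValidationError(QuenchBindError):
    """A domain-type invariant is violated."""


class InsufficientDataError(QuenchBindError):
    """Too few usable points for the requested fit."""


class PairingError(QuenchBindError):
    """Per-point auxiliary records do not pair one-to-one with titration points."""


class DepletionError(QuenchBindError):
    """Free-ligand concentration is non-positive after the depletion correction."""


class SolverError(QuenchBindError):
    """An iterative solver failed to converge."""


class StageError(QuenchBindError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class DepletionWarning(UserWarning):
    """A titration point was dropped because its free-ligand term was unusable."""


class QualityWarning(UserWarning):
    """Input is usable but physically suspicious (e.g. soluble > total)."""
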
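"""Exception hierarchy for reader-study validation and analysis."""


class ReaderStudyError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ReaderStudyError):
    """A required column is missing or a value cannot be coerced to its type."""


class IntegrityError(ReaderStudyError):
    """Duplicate rows, block violations, or broken internal invariants."""


class CrossReferenceError(ReaderStudyError):
    """A reading refers to a case or reader absent from the manifests."""


class PairingError(ReaderStudyError):
    """A (reader, case) assessment is present under only one modality."""


class DegenerateInputError(ReaderStudyError):
    """An accuracy metric was requested on single-class data."""


class CalibrationError(ReaderStudyError):
    """Simulator calibration targets are infeasible."""
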
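"""Exception hierarchy.

``PpgrrError`` is the base of every error this package raises on bad input or
bad configuration; anything else escaping the library is a genuine bug.
"""


class PpgrrError(Exception):
    """Base class for all ppgrr errors."""


class FormatError(PpgrrError):
    """A record file is malformed or a required column/field is absent."""


class ExclusionError(PpgrrError):
    """A record must be excluded (e.g. its reference RR is entirely missing)."""


class ValidationError(PpgrrError):
    """A domain-type invariant is violated."""


class LabelingError(PpgrrError):
    """A window cannot be assigned an RR label from the reference signal."""


class ParameterError(PpgrrError):
    """A scalar parameter is out of its admissible range."""


class DesignError(PpgrrError):
    """A filter design cannot meet its frequency-response contract."""


class ShapeError(PpgrrError):
    """Array shapes are inconsistent with the requested operation."""


class ConfigurationError(PpgrrError):
    """A model or run configuration is invalid."""


class SplitError(PpgrrError):
    """A train/validation/test split cannot be constructed."""


class LeakageError(PpgrrError):
    """A subject contributes windows to both train and validation sets."""


class SNRUndefinedError(PpgrrError):
    """SNR is undefined because the clean signal has zero power."""
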